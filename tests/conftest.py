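import numpy as np
import pandas as pd
import pytest

from mixobal.gas import GasStreamSeries
from mixobal.simulate import SimScenario, simulate_chemostat, simulate_fedbatch
from mixobal.stoichiometry import load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def het_result():
    """Noise-free heterotrophic (N2-sparged) chemostat steady state."""
    return simulate_chemostat(SimScenario.heterotrophic())


@pytest.fixture(scope="session")
def high_result():
    """Noise-free high-syngas chemostat with C-1 assimilation."""
    return simulate_chemostat(SimScenario.high_syngas())


@pytest.fixture(scope="session")
def fedbatch_result():
    return simulate_fedbatch(SimScenario(mode="fedbatch", dt_h=0.02, t_end_h=30.0))


def make_gas_series(time_h, flow_l_h=12.48, **fractions) -> GasStreamSeries:
    """Uniform gas series with the given %v/v channels; N2 fills the rest."""
    t = np.asarray(time_h, float)
    cols = {"time_h": t}
    total = np.zeros_like(t)
    for g in ("o2", "co", "co2", "h2", "ar"):
        val = np.broadcast_to(np.asarray(fractions.get(g, 0.0), float), t.shape)
        cols[f"{g}_pct"] = val
        total = total + val
    cols["n2_pct"] = 100.0 - total
    cols["flow_l_h"] = np.broadcast_to(np.asarray(flow_l_h, float), t.shape)
    return GasStreamSeries(pd.DataFrame(cols))
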