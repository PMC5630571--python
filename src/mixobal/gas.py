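"""Off-gas series handling: fractions to molar flows, Henry solubility,
endogenous baselines and net consumption.

Sign convention throughout: positive net rates mean consumption by the
culture, negative rates mean generation, matching the baseline-subtraction
logic of sparged-bioreactor off-gas analysis.  The consumption of a gas is

    C = I + E - O

where I is the molar inflow, O the molar outflow and E the endogenous
generation rate measured under an inert (N2) sparge.  O = I + E (the cells
add their endogenous gas and take nothing) gives C = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GAS_COLUMNS",
    "HENRY_CONSTANTS_G_L_ATM",
    "R_L_ATM",
    "GasStreamSeries",
    "GasConsumptionResult",
    "henry_concentration",
    "fraction_to_molar_flow",
    "molar_flow_to_fraction",
    "endogenous_baseline",
    "net_gas_consumption",
]

GASES = ("o2", "n2", "co", "co2", "h2", "ar")
GAS_COLUMNS = tuple(f"{g}_pct" for g in GASES)

#: Henry solubility constants at 37 degC, g/L of dissolved gas per atm of
#: partial pressure.  The CO2 value of 1 g/L is kept as tabulated in the
#: source method even though handbook values differ; override via the
#: ``constants`` argument if desired.
HENRY_CONSTANTS_G_L_ATM = {"co": 0.0225, "co2": 1.0, "o2": 0.033, "h2": 0.0014}

R_L_ATM = 0.082057  # L atm / (mol K)


@dataclass
class GasStreamSeries:
    """Time-stamped off-gas composition at a stated total flow.

    ``data`` holds columns ``time_h``, one ``<gas>_pct`` column per gas in
    %v/v, and ``flow_l_h``.  Fractions must lie in [0, 100] and sum to
    100 +/- 5 at every time point (analyzer drift tolerance); times must be
    strictly increasing.
    """

    data: pd.DataFrame
    temperature_c: float = 37.0
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = {"time_h", "flow_l_h", *GAS_COLUMNS} - set(df.columns)
        if missing:
            raise ValueError(f"gas series missing columns: {sorted(missing)}")
        t = df["time_h"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        frac = df[list(GAS_COLUMNS)].to_numpy(float)
        if np.any(frac < 0) or np.any(frac > 100):
            raise ValueError("gas fractions must lie in [0, 100] %v/v")
        totals = frac.sum(axis=1)
        if len(totals) and (totals.min() < 95 or totals.max() > 105):
            raise ValueError(
                f"gas fractions must sum to 100 +/- 5 %% (found "
                f"[{totals.min():.2f}, {totals.max():.2f}])"
            )
        if np.any(df["flow_l_h"].to_numpy(float) <= 0):
            raise ValueError("flow_l_h must be positive")
        self.data = df

    @property
    def time_h(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    def fraction(self, gas: str) -> np.ndarray:
        return self.data[f"{gas}_pct"].to_numpy(float)

    def molar_flow(self, gas: str) -> np.ndarray:
        """Molar flow of one gas over time, mol/h (ideal gas at the stream's
        reference temperature/pressure)."""
        return fraction_to_molar_flow(
            self.fraction(gas),
            self.data["flow_l_h"].to_numpy(float),
            self.temperature_c,
            self.pressure_atm,
        )

    def partial_pressure(self, gas: str) -> np.ndarray:
        return self.fraction(gas) / 100.0 * self.pressure_atm

    def resampled(self, time_h: np.ndarray, order: int = 1) -> "GasStreamSeries":
        """Linear (order=1) or nearest (order=0) interpolation onto a new grid."""
        t = self.time_h
        out = {"time_h": np.asarray(time_h, float)}
        for col in (*GAS_COLUMNS, "flow_l_h"):
            y = self.data[col].to_numpy(float)
            if order == 0:
                idx = np.clip(np.searchsorted(t, time_h), 0, len(t) - 1)
                out[col] = y[idx]
            else:
                out[col] = np.interp(time_h, t, y)
        return GasStreamSeries(pd.DataFrame(out), self.temperature_c, self.pressure_atm)


@dataclass
class GasConsumptionResult:
    """Net gas exchange rates; positive = consumed, negative = generated."""

    net_mol_h: dict[str, float]
    dissolved_g_l: dict[str, float] = field(default_factory=dict)
    sign_convention: str = "positive_consumption"


def henry_concentration(
    gas: str,
    partial_pressure_atm: float,
    constants: dict[str, float] | None = None,
) -> float:
    """Equilibrium dissolved concentration C = k * p, g/L.

    Uses the tabulated 37 degC constants (:data:`HENRY_CONSTANTS_G_L_ATM`)
    unless overridden.  N2 and Ar have no tabulated constant and are
    rejected.
    """
    if partial_pressure_atm < 0:
        raise ValueError("partial pressure must be nonnegative")
    k_table = HENRY_CONSTANTS_G_L_ATM if constants is None else constants
    gas = gas.lower()
    if gas not in k_table:
        raise ValueError(f"{gas}: no Henry constant provided in source")
    return k_table[gas] * partial_pressure_atm


def fraction_to_molar_flow(
    fraction_pct,
    total_flow_l_h,
    temperature_c: float = 37.0,
    pressure_atm: float = 1.0,
):
    """Convert a %v/v fraction at a total volumetric flow to mol/h.

    Ideal-gas conversion at the stated reference conditions; the default
    reference is reactor conditions, 37 degC and 1 atm.
    """
    frac = np.asarray(fraction_pct, float)
    flow = np.asarray(total_flow_l_h, float)
    if np.any(frac < 0) or np.any(frac > 100):
        raise ValueError("fraction must lie in [0, 100] %v/v")
    if np.any(flow <= 0):
        raise ValueError("total flow must be positive")
    out = flow * (frac / 100.0) * pressure_atm / (R_L_ATM * (temperature_c + 273.15))
    return float(out) if out.ndim == 0 else out


def molar_flow_to_fraction(
    mol_h, total_flow_l_h, temperature_c: float = 37.0, pressure_atm: float = 1.0
):
    """Inverse of :func:`fraction_to_molar_flow`."""
    rate = np.asarray(mol_h, float)
    flow = np.asarray(total_flow_l_h, float)
    out = 100.0 * rate * R_L_ATM * (temperature_c + 273.15) / (flow * pressure_atm)
    return float(out) if out.ndim == 0 else out


def endogenous_baseline(
    n2_run: GasStreamSeries,
    window: tuple[float, float],
    inlet_fraction_pct: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Endogenous per-gas generation rate under an inert sparge.

    Means and standard errors of each gas's net molar outflow (outflow
    minus inlet) over a steady window of a nitrogen-sparged control run.
    ``inlet_fraction_pct`` defaults to pure N2.

    Returns a DataFrame indexed by gas with columns ``rate_mol_h``,
    ``se_mol_h`` and ``n``.
    """
    t0, t1 = window
    mask = (n2_run.time_h >= t0) & (n2_run.time_h <= t1)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("steady window must contain at least 3 samples")
    inlet = {g: 0.0 for g in GASES}
    inlet["n2"] = 100.0
    if inlet_fraction_pct:
        inlet.update({k.lower(): v for k, v in inlet_fraction_pct.items()})
    flow = n2_run.data["flow_l_h"].to_numpy(float)[mask]
    rows = {}
    for gas in GASES:
        out_flow = fraction_to_molar_flow(
            n2_run.fraction(gas)[mask], flow, n2_run.temperature_c, n2_run.pressure_atm
        )
        in_flow = fraction_to_molar_flow(
            np.full(n, inlet[gas]), flow, n2_run.temperature_c, n2_run.pressure_atm
        )
        net = out_flow - in_flow
        rows[gas] = {
            "rate_mol_h": float(net.mean()),
            "se_mol_h": float(net.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "n": n,
        }
    return pd.DataFrame(rows).T


def net_gas_consumption(output_mol_h, input_mol_h, endogenous_mol_h):
    """Net consumption C = I + E - O (positive = consumed by the culture).

    I is the inlet molar flow, O the outlet molar flow and E the endogenous
    generation measured under inert sparge; O = I + E yields exactly 0.
    """
    out = np.asarray(output_mol_h, float)
    inp = np.asarray(input_mol_h, float)
    endo = np.asarray(endogenous_mol_h, float)
    if np.any(out < 0) or np.any(inp < 0):
        raise ValueError("molar flows must be nonnegative")
    net = inp + endo - out
    return float(net) if net.ndim == 0 else net
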