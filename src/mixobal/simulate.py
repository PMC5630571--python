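"""Synthetic chemostat and fed-batch fermentation data.

The generator embodies the carbon-electron flow logic of a mixotrophic
ABE fermentation sparged with synthesis gas (nominal blend: 20 % CO,
20 % CO2, 10 % H2, 50 % N2 at full strength):

1. sugars are fermented to the ABE spectrum plus biomass, CO2 and H2 by a
   reference heterotrophic stoichiometry that closes carbon and electron
   balances exactly;
2. if the inlet CO2 fraction is below a switch threshold (default 5 % v/v)
   CO is oxidized, CO + H2O -> CO2 + H2, one-for-one;
3. above the threshold, C-1 assimilation routes consumed CO2/CO carbon
   into acetyl-CoA-derived products (butanol and butyrate), without
   changing biomass, with the required electrons drawn from consumed H2
   (and the CO share of the captured carbon).

Steady states are generated algebraically from the configured fluxes, not
by ODE integration: the downstream analysis consumes steady windows and
transients, not mechanisms.  Fed-batch dynamics are a two-rate exponential
biomass rise with a phenomenological bounded limit cycle superimposed on
the gas channels once they cross the oscillation onset.  Every configured
flux is stored in a truth record so each analysis module can be checked by
round trip.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .gas import GasStreamSeries, R_L_ATM, fraction_to_molar_flow
from .io import LiquidSeries
from .stoichiometry import CompoundRegistry, load_default_registry

__all__ = [
    "SYNGAS_BLEND_PCT",
    "SimScenario",
    "ChemostatTruth",
    "SimResult",
    "simulate_chemostat",
    "simulate_fedbatch",
    "inject_nitrite_pulses",
    "add_measurement_noise",
]

#: Full-strength synthesis gas composition, % v/v.
SYNGAS_BLEND_PCT = {"co": 20.0, "co2": 20.0, "h2": 10.0, "n2": 50.0}

#: Reference heterotrophic spectrum, C-mol of product per C-mol of sugar.
#: Chosen to close the carbon balance at exactly 1 together with biomass
#: and CO2, and the electron balance at exactly 1 with the H2 yield below.
BASE_PRODUCT_YIELDS = {
    "butanol": 0.20,
    "acetone": 0.06,
    "ethanol": 0.04,
    "acetate": 0.08,
    "butyrate": 0.15,
}
BASE_BIOMASS_YIELD = 0.10
BASE_H2_YIELD_MOL_PER_CMOL = 0.375  # closes the electron balance exactly


@dataclass
class SimScenario:
    """Generator parameters; defaults are the study's chemostat conditions."""

    mode: str = "chemostat"  # chemostat | fedbatch
    seed: int = 0
    # reactor
    dilution_rate_per_h: float = 0.135
    volume_l: float = 0.7
    sparge_flow_l_h: float = 12.48
    temperature_c: float = 37.0
    pressure_atm: float = 1.0
    # sparge composition: % of the full-strength syngas blend in the feed gas
    syngas_fraction_pct: float = 0.0
    measured_inlet_pct: dict | None = None  # e.g. {"co": 11.17, "co2": 11.01, "h2": 4.40}
    # liquid feed
    feed_sucrose_g_l: float = 30.0
    feed_fructose_g_l: float = 15.0
    sugar_conversion: float = 0.80  # fraction of fed sugar consumed
    # heterotrophic reference stoichiometry (C-mol/C-mol; H2 in mol/C-mol)
    product_yields: dict = field(default_factory=lambda: dict(BASE_PRODUCT_YIELDS))
    biomass_yield: float = BASE_BIOMASS_YIELD
    h2_yield_mol_per_cmol: float = BASE_H2_YIELD_MOL_PER_CMOL
    # mixotrophic capture (carbon-electron flow logic)
    regime: str = "auto"  # auto | none | oxidation | c1
    co2_switch_threshold_pct: float = 5.0
    c1_carbon_fraction: float = 0.0  # extra product C-mol per sugar C-mol
    electron_capture_fraction: float = 0.0  # extra product electrons per sugar electron
    c1_co_share: float = 0.3  # share of captured carbon drawn from CO
    c1_product_split: dict = field(default_factory=lambda: {"butanol": 0.7, "butyrate": 0.3})
    co_oxidation_fraction: float = 0.6  # share of inlet CO oxidized in regime 2
    # time grid / settling
    t_end_h: float = 60.0
    dt_h: float = 0.1
    settle: bool = False  # exponential approach to steady state with time constant 1/D
    # fed-batch dynamics
    fedbatch_mu1_per_h: float = 0.30
    fedbatch_mu2_per_h: float = 0.10
    fedbatch_break_h: float = 10.0
    fedbatch_x0_g_l: float = 0.05
    fedbatch_xmax_g_l: float = 4.0
    fedbatch_gas_max_pct: dict = field(default_factory=lambda: {"h2": 6.0, "co2": 8.0})
    fedbatch_feed_rate_l_h: float = 0.00008
    osc_period_h: float = 2.0
    osc_amplitude_pct: float = 0.5
    osc_onset_pct: float = 3.0
    # nitrite electron-sink stoichiometries
    h2_per_no2_mol_mol: float = 2.5
    co_per_no2_mol_mol: float = 1.0
    biomass_gain_g_per_mmol: float = 0.05
    washout_threshold_mM: float = 24.0
    pulse_tau_h: float = 0.75
    # measurement noise (SD per channel family)
    noise_gas_pct: float = 0.0
    noise_liquid_g_l: float = 0.0
    noise_biomass_g_l: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("chemostat", "fedbatch"):
            raise ValueError("mode must be 'chemostat' or 'fedbatch'")
        if not 0 <= self.syngas_fraction_pct <= 100:
            raise ValueError("syngas_fraction_pct must be in [0, 100]")
        if abs(sum(SYNGAS_BLEND_PCT.values()) - 100.0) > 1e-9:
            raise ValueError("blend fractions must sum to 100")
        for name, value in (
            ("dilution_rate_per_h", self.dilution_rate_per_h),
            ("volume_l", self.volume_l),
            ("sparge_flow_l_h", self.sparge_flow_l_h),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sugar_conversion <= 1:
            raise ValueError("sugar_conversion must be in (0, 1]")
        if self.c1_carbon_fraction < 0 or self.electron_capture_fraction < 0:
            raise ValueError("capture fractions must be nonnegative")
        if any(v < 0 for v in self.product_yields.values()) or self.biomass_yield < 0:
            raise ValueError("yields must be nonnegative")
        carbon = sum(self.product_yields.values()) + self.biomass_yield
        if carbon > 1 + 1e-12:
            raise ValueError(
                "heterotrophic product + biomass carbon exceeds sugar carbon "
                f"({carbon:.3f} C-mol/C-mol); conservation violation"
            )

    # --- convenience presets -------------------------------------------------

    @classmethod
    def heterotrophic(cls, **kw) -> "SimScenario":
        """N2-sparged control chemostat."""
        return cls(syngas_fraction_pct=0.0, regime="none", **kw)

    @classmethod
    def low_syngas(cls, **kw) -> "SimScenario":
        """9 % syngas: inlet CO2 below the switch, CO-oxidation regime."""
        return cls(syngas_fraction_pct=9.0, **kw)

    @classmethod
    def medium_syngas(cls, **kw) -> "SimScenario":
        """32 % syngas: C-1 assimilation at the medium-condition capture."""
        kw.setdefault("c1_carbon_fraction", 0.11)
        kw.setdefault("electron_capture_fraction", 0.19)
        kw.setdefault("sugar_conversion", 0.85)
        return cls(syngas_fraction_pct=32.0, **kw)

    @classmethod
    def high_syngas(cls, **kw) -> "SimScenario":
        """60 % syngas: C-1 assimilation at the high-condition capture."""
        kw.setdefault("c1_carbon_fraction", 0.17)
        kw.setdefault("electron_capture_fraction", 0.27)
        kw.setdefault("sugar_conversion", 0.85)
        return cls(syngas_fraction_pct=60.0, **kw)

    def control(self) -> "SimScenario":
        """The matching N2-sparged heterotrophic control scenario."""
        return replace(
            self,
            syngas_fraction_pct=0.0,
            measured_inlet_pct=None,
            regime="none",
            c1_carbon_fraction=0.0,
            electron_capture_fraction=0.0,
        )

    # --- derived quantities --------------------------------------------------

    def inlet_fraction_pct(self) -> dict[str, float]:
        """Inlet gas composition, % v/v (nominal blend or measured override)."""
        if self.measured_inlet_pct is not None:
            inlet = {g: 0.0 for g in ("o2", "co", "co2", "h2", "ar")}
            inlet.update({k.lower(): float(v) for k, v in self.measured_inlet_pct.items()})
            inlet["n2"] = 100.0 - sum(inlet.values())
            if inlet["n2"] < 0:
                raise ValueError("measured inlet fractions exceed 100 %")
            return inlet
        f = self.syngas_fraction_pct / 100.0
        inlet = {g: 0.0 for g in ("o2", "ar")}
        for g in ("co", "co2", "h2"):
            inlet[g] = SYNGAS_BLEND_PCT[g] * f
        inlet["n2"] = 100.0 - inlet["co"] - inlet["co2"] - inlet["h2"]
        return inlet

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ChemostatTruth:
    """Every configured flux of a chemostat scenario, for round-trip tests."""

    regime: str
    sugar_flux_cmol_h: float
    sugar_consumed_cmol_l: float
    inlet_mol_h: dict
    outlet_mol_h: dict
    endogenous_mol_h: dict  # gross fermentative generation (CO2, H2)
    consumption_mol_h: dict  # positive = consumed by the culture
    product_yields_cmol: dict  # realized, including capture and redox shift
    biomass_yield_cmol: float
    c1_carbon_fraction: float
    electron_capture_fraction: float
    expected_carbon_recovery: float
    expected_electron_recovery: float
    carbon_residual: float
    electron_residual: float


@dataclass
class SimResult:
    gas: GasStreamSeries
    liquid: LiquidSeries
    truth: object
    scenario: SimScenario


def _feed_cmol_l(scenario: SimScenario, registry: CompoundRegistry) -> float:
    suc = registry["sucrose"]
    fru = registry["fructose"]
    return (
        scenario.feed_sucrose_g_l * suc.cmol_per_gram
        + scenario.feed_fructose_g_l * fru.cmol_per_gram
    )


def _resolve_regime(scenario: SimScenario, inlet: dict[str, float]) -> str:
    if scenario.regime != "auto":
        return scenario.regime
    if inlet["co"] <= 0 and inlet["co2"] <= 0:
        return "none"
    if inlet["co2"] >= scenario.co2_switch_threshold_pct:
        return "c1" if scenario.c1_carbon_fraction > 0 else "none"
    return "oxidation" if inlet["co"] > 0 else "none"


def _settle_profile(t: np.ndarray, v0: float, v_ss: float, rate: float, settle: bool) -> np.ndarray:
    if not settle:
        return np.full_like(t, v_ss)
    return v_ss - (v_ss - v0) * np.exp(-rate * t)


def simulate_chemostat(scenario: SimScenario, registry: CompoundRegistry | None = None) -> SimResult:
    """Algebraic chemostat steady state under the carbon-electron flow logic.

    Balances hold exactly (residuals ~1e-16) before measurement noise; the
    truth record stores every configured flux and the apparent recoveries
    the analysis pipeline should report.
    """
    if scenario.mode != "chemostat":
        raise ValueError("scenario.mode must be 'chemostat'")
    reg = registry or load_default_registry()
    gamma = {name: reg.gamma(name) for name in
             (*scenario.product_yields, "biomass", "sucrose", "co", "h2")}
    gamma_s = gamma["sucrose"]  # = 4 for both sugars

    D, V = scenario.dilution_rate_per_h, scenario.volume_l
    feed_cmol = _feed_cmol_l(scenario, reg)
    consumed_cmol_l = scenario.sugar_conversion * feed_cmol
    S = consumed_cmol_l * D * V  # C-mol/h of sugar carbon consumed

    inlet_pct = scenario.inlet_fraction_pct()
    inlet_mol = {
        g: fraction_to_molar_flow(p, scenario.sparge_flow_l_h, scenario.temperature_c,
                                  scenario.pressure_atm)
        for g, p in inlet_pct.items()
    }
    regime = _resolve_regime(scenario, inlet_pct)

    yields = dict(scenario.product_yields)
    Yx = scenario.biomass_yield
    co2_yield = 1.0 - sum(yields.values()) - Yx  # closes carbon exactly
    E_co2 = co2_yield * S
    E_h2 = scenario.h2_yield_mol_per_cmol * S

    cons = {g: 0.0 for g in ("co", "co2", "h2")}
    h2_from_oxidation = 0.0
    if regime == "oxidation":
        cox = scenario.co_oxidation_fraction * inlet_mol["co"]
        cons["co"] = cox
        E_co2 += cox  # CO + H2O -> CO2 + H2, mol for mol
        E_h2 += cox
        h2_from_oxidation = cox
    elif regime == "c1":
        f_c = scenario.c1_carbon_fraction
        f_e = scenario.electron_capture_fraction
        E_C = f_c * S  # captured carbon flux, C-mol/h
        split = scenario.c1_product_split
        if abs(sum(split.values()) - 1.0) > 1e-9:
            raise ValueError("c1_product_split must sum to 1")
        gamma_mix = sum(frac * gamma[p] for p, frac in split.items())
        co_uptake = min(scenario.c1_co_share * E_C, inlet_mol["co"])
        co2_uptake = E_C - co_uptake
        # redox shift: move carbon from acetate to butanol (carbon neutral,
        # +2 electrons per C-mol shifted) to hit the configured electron capture
        shift = (f_e * gamma_s * S - gamma_mix * E_C) / (gamma["butanol"] - gamma["acetate"])
        shift_yield = shift / S
        if shift_yield > yields.get("acetate", 0.0) + 1e-12:
            raise ValueError(
                "electron_capture_fraction needs a larger acetate pool to shift; "
                "infeasible scenario"
            )
        if -shift_yield > yields.get("butanol", 0.0) + 1e-12:
            raise ValueError("negative redox shift exceeds the butanol pool")
        yields["acetate"] = yields.get("acetate", 0.0) - shift_yield
        yields["butanol"] = yields.get("butanol", 0.0) + shift_yield
        for p, frac in split.items():
            yields[p] = yields.get(p, 0.0) + frac * f_c
        # electrons: extra product electrons come from consumed CO and H2
        electrons_needed = gamma_mix * E_C + (gamma["butanol"] - gamma["acetate"]) * shift
        h2_uptake = (electrons_needed - gamma["co"] * co_uptake) / 2.0
        if h2_uptake < -1e-12:
            raise ValueError("CO electrons exceed capture demand; reduce c1_co_share")
        if co2_uptake < 0:
            raise ValueError("c1_co_share too large for the configured carbon capture")
        cons.update({"co": co_uptake, "co2": co2_uptake, "h2": h2_uptake})

    outlet_mol = {
        "o2": inlet_mol["o2"],
        "ar": inlet_mol["ar"],
        "n2": inlet_mol["n2"],
        "co": inlet_mol["co"] - cons["co"],
        "co2": inlet_mol["co2"] + E_co2 - cons["co2"],
        "h2": inlet_mol["h2"] + E_h2 - cons["h2"],
    }
    for g, rate in outlet_mol.items():
        if rate < -1e-12:
            raise ValueError(
                f"scenario infeasible: outlet {g} flow negative "
                f"({rate:.4g} mol/h); consumption exceeds supply"
            )
        outlet_mol[g] = max(rate, 0.0)

    # --- conservation bookkeeping (exact by construction) --------------------
    # carbon in: sugar + consumed CO/CO2; carbon out: products + biomass +
    # fermentative CO2 (captured CO2 carbon sits inside the products)
    product_flux = {p: y * S for p, y in yields.items()}
    carbon_in = S + cons["co"] + cons["co2"]
    carbon_out = sum(product_flux.values()) + Yx * S + E_co2
    carbon_residual = carbon_in - carbon_out
    electrons_in = gamma_s * S + 2.0 * cons["h2"] + gamma["co"] * cons["co"]
    electrons_out = (
        sum(product_flux[p] * gamma[p] for p in product_flux)
        + Yx * S * gamma["biomass"]
        + 2.0 * E_h2
    )
    electron_residual = electrons_in - electrons_out

    expected_carbon = 1.0 + (scenario.c1_carbon_fraction if regime == "c1" else 0.0)
    expected_electron = 1.0 + (scenario.electron_capture_fraction if regime == "c1" else 0.0)

    truth = ChemostatTruth(
        regime=regime,
        sugar_flux_cmol_h=S,
        sugar_consumed_cmol_l=consumed_cmol_l,
        inlet_mol_h=inlet_mol,
        outlet_mol_h=outlet_mol,
        endogenous_mol_h={"co2": E_co2, "h2": E_h2, "co": 0.0,
                          "h2_from_oxidation": h2_from_oxidation},
        consumption_mol_h=dict(cons),
        product_yields_cmol=dict(yields),
        biomass_yield_cmol=Yx,
        c1_carbon_fraction=scenario.c1_carbon_fraction if regime == "c1" else 0.0,
        electron_capture_fraction=(
            scenario.electron_capture_fraction if regime == "c1" else 0.0
        ),
        expected_carbon_recovery=expected_carbon,
        expected_electron_recovery=expected_electron,
        carbon_residual=carbon_residual,
        electron_residual=electron_residual,
    )

    # --- time series ----------------------------------------------------------
    t = np.arange(0.0, scenario.t_end_h + scenario.dt_h / 2, scenario.dt_h)
    total_out = sum(outlet_mol.values())
    out_pct_ss = {g: 100.0 * outlet_mol[g] / total_out for g in outlet_mol}
    out_flow_ss = total_out * R_L_ATM * (scenario.temperature_c + 273.15) / scenario.pressure_atm

    gas_cols = {"time_h": t}
    for g in ("o2", "n2", "co", "co2", "h2", "ar"):
        gas_cols[f"{g}_pct"] = _settle_profile(t, inlet_pct.get(g, 0.0), out_pct_ss[g], D,
                                               scenario.settle)
    gas_cols["flow_l_h"] = _settle_profile(t, scenario.sparge_flow_l_h, out_flow_ss, D,
                                           scenario.settle)
    gas = GasStreamSeries(pd.DataFrame(gas_cols), scenario.temperature_c, scenario.pressure_atm)

    residual_fraction = 1.0 - scenario.sugar_conversion
    liquid_cols = {"time_h": t}
    liquid_cols["sucrose_g_l"] = _settle_profile(
        t, scenario.feed_sucrose_g_l, residual_fraction * scenario.feed_sucrose_g_l, D,
        scenario.settle)
    liquid_cols["fructose_g_l"] = _settle_profile(
        t, scenario.feed_fructose_g_l, residual_fraction * scenario.feed_fructose_g_l, D,
        scenario.settle)
    for p, y in yields.items():
        spec = reg[p]
        conc = y * consumed_cmol_l / spec.cmol_per_gram
        liquid_cols[f"{p}_g_l"] = _settle_profile(t, 0.0, conc, D, scenario.settle)
    x_conc = Yx * consumed_cmol_l * reg["biomass"].molar_mass
    liquid_cols["biomass_g_l"] = _settle_profile(t, 0.02 * x_conc, x_conc, D, scenario.settle)
    liquid = LiquidSeries(pd.DataFrame(liquid_cols))

    return SimResult(gas=gas, liquid=liquid, truth=truth, scenario=scenario)


@dataclass
class FedbatchTruth:
    mu1_per_h: float
    mu2_per_h: float
    break_h: float
    osc_period_h: float
    osc_amplitude_pct: float
    onset_h: dict  # per-gas ramp crossing time of the onset fraction
    osc_start_h: float | None = None  # shared limit-cycle start (later crossing)


def simulate_fedbatch(scenario: SimScenario) -> SimResult:
    """Fed-batch run: two-rate exponential biomass, ramping H2/CO2 emission
    and a bounded limit-cycle component past the oscillation onset."""
    if scenario.mode != "fedbatch":
        raise ValueError("scenario.mode must be 'fedbatch'")
    t = np.arange(0.0, scenario.t_end_h + scenario.dt_h / 2, scenario.dt_h)
    mu1, mu2, tb = (scenario.fedbatch_mu1_per_h, scenario.fedbatch_mu2_per_h,
                    scenario.fedbatch_break_h)
    x = scenario.fedbatch_x0_g_l * np.exp(mu1 * np.minimum(t, tb) + mu2 * np.maximum(t - tb, 0.0))
    x = np.minimum(x, scenario.fedbatch_xmax_g_l)

    gas_cols = {"time_h": t, "o2_pct": np.zeros_like(t), "ar_pct": np.zeros_like(t),
                "co_pct": np.zeros_like(t)}
    activity = x / scenario.fedbatch_xmax_g_l
    ramps, onset = {}, {}
    for g, fmax in scenario.fedbatch_gas_max_pct.items():
        ramp = fmax * activity
        ramps[g] = ramp
        cross = np.flatnonzero(ramp >= scenario.osc_onset_pct)
        if len(cross):
            i = int(cross[0])
            if i > 0:
                t0, t1, y0, y1 = t[i - 1], t[i], ramp[i - 1], ramp[i]
                onset[g] = float(t0 + (scenario.osc_onset_pct - y0) * (t1 - t0) / (y1 - y0))
            else:
                onset[g] = float(t[0])
        else:
            onset[g] = None
    # the limit cycle is shared and in phase: it starts once BOTH gases
    # have crossed the onset fraction
    starts = [v for v in onset.values() if v is not None]
    t_osc = max(starts) if len(starts) == len(onset) and starts else None
    for g, ramp in ramps.items():
        series = ramp
        if t_osc is not None and scenario.osc_amplitude_pct > 0:
            phase = 2.0 * np.pi * (t - t_osc) / scenario.osc_period_h
            series = np.where(t >= t_osc,
                              ramp + scenario.osc_amplitude_pct * np.sin(phase), ramp)
        gas_cols[f"{g}_pct"] = np.clip(series, 0.0, None)
    gas_cols["n2_pct"] = 100.0 - gas_cols["h2_pct"] - gas_cols["co2_pct"]
    gas_cols["flow_l_h"] = np.full_like(t, scenario.sparge_flow_l_h)
    gas = GasStreamSeries(pd.DataFrame(gas_cols), scenario.temperature_c, scenario.pressure_atm)

    volume = scenario.volume_l + scenario.fedbatch_feed_rate_l_h * t
    liquid = LiquidSeries(pd.DataFrame({
        "time_h": t,
        "biomass_g_l": x,
        "volume_l": volume,
    }))
    truth = FedbatchTruth(
        mu1_per_h=mu1, mu2_per_h=mu2, break_h=tb,
        osc_period_h=scenario.osc_period_h,
        osc_amplitude_pct=scenario.osc_amplitude_pct,
        onset_h=onset,
        osc_start_h=t_osc,
    )
    return SimResult(gas=gas, liquid=liquid, truth=truth, scenario=scenario)


@dataclass
class PulseTruth:
    events: list  # of PulseEvent
    expected_co_displaced_mol: list
    expected_h2_extra_mol: list
    expected_biomass_increase_g: list
    washout: list
    h2_per_no2_mol_mol: float
    co_per_no2_mol_mol: float
    biomass_gain_g_per_mmol: float


def _alpha_pulse(s: np.ndarray, tau: float) -> np.ndarray:
    """Unit-area transient shape (s/tau^2) exp(-s/tau) for s >= 0."""
    out = np.where(s >= 0, s / tau**2 * np.exp(-np.clip(s, 0, None) / tau), 0.0)
    return out


def inject_nitrite_pulses(result: SimResult, schedule_mM: list[tuple[float, float]]) -> SimResult:
    """Superimpose nitrite-pulse transients on a chemostat steady state.

    ``schedule_mM`` is a list of (time_h, concentration_mM).  Each dose
    below the washout threshold displaces CO uptake by ``co_per_no2 x
    dose`` mol in total, adds ``h2_per_no2 x dose`` mol of H2 uptake and
    raises the biomass plateau by the configured gain; a dose above the
    threshold triggers exponential washout of the culture at rate D.
    Transients must not overlap.
    """
    from .pulses import PulseEvent

    scn = result.scenario
    if scn.settle:
        raise ValueError(
            "pulse injection requires an established steady state; "
            "simulate with settle=False"
        )
    truth: ChemostatTruth = result.truth
    t = result.gas.time_h
    dt_span = 8.0 * scn.pulse_tau_h
    times = [tt for tt, _ in schedule_mM]
    if any(b - a < dt_span for a, b in zip(times, times[1:])):
        raise ValueError(f"pulse transients overlap; space pulses by >= {dt_span} h")

    events = [PulseEvent(time_h=tt, concentration_mM=c, volume_l=scn.volume_l)
              for tt, c in schedule_mM]

    # reconstruct per-gas outlet molar flows over time, then modify
    out_mol = {g: np.full_like(t, truth.outlet_mol_h[g]) for g in truth.outlet_mol_h}
    biomass = result.liquid.concentration("biomass").copy()

    exp_co, exp_h2, exp_bio, washed = [], [], [], []
    washout_active_from = None
    for ev in events:
        s = t - ev.time_h
        if ev.washout:
            washed.append(True)
            exp_co.append(np.nan)
            exp_h2.append(np.nan)
            exp_bio.append(np.nan)
            if washout_active_from is None:
                washout_active_from = ev.time_h
            continue
        washed.append(False)
        dose_mol = ev.dose_mmol / 1e3
        shape = _alpha_pulse(s, scn.pulse_tau_h)
        # displaced CO uptake -> more CO leaves; extra H2 uptake -> less H2 leaves
        out_mol["co"] = out_mol["co"] + scn.co_per_no2_mol_mol * dose_mol * shape
        out_mol["h2"] = out_mol["h2"] - scn.h2_per_no2_mol_mol * dose_mol * shape
        rise = np.where(s >= 0, 1.0 - np.exp(-np.clip(s, 0, None) / 0.5), 0.0)
        biomass = biomass + scn.biomass_gain_g_per_mmol * ev.dose_mmol / scn.volume_l * rise
        exp_co.append(scn.co_per_no2_mol_mol * dose_mol)
        exp_h2.append(scn.h2_per_no2_mol_mol * dose_mol)
        exp_bio.append(scn.biomass_gain_g_per_mmol * ev.dose_mmol)

    if np.any(out_mol["h2"] < -1e-12):
        raise ValueError("H2 demand exceeds supply during a pulse; lower the dose")
    out_mol["h2"] = np.clip(out_mol["h2"], 0.0, None)

    if washout_active_from is not None:
        decay = np.where(t >= washout_active_from,
                         np.exp(-scn.dilution_rate_per_h * (t - washout_active_from)), 1.0)
        biomass = biomass * decay
        for g in ("co2", "h2"):
            bio_term = truth.endogenous_mol_h[g] - truth.consumption_mol_h.get(g, 0.0)
            out_mol[g] = truth.inlet_mol_h[g] + bio_term * decay
        out_mol["co"] = truth.inlet_mol_h["co"] - truth.consumption_mol_h["co"] * decay

    total = sum(out_mol.values())
    gas_cols = {"time_h": t}
    for g in ("o2", "n2", "co", "co2", "h2", "ar"):
        gas_cols[f"{g}_pct"] = 100.0 * out_mol[g] / total
    gas_cols["flow_l_h"] = total * R_L_ATM * (scn.temperature_c + 273.15) / scn.pressure_atm
    gas = GasStreamSeries(pd.DataFrame(gas_cols), scn.temperature_c, scn.pressure_atm)

    liquid_df = result.liquid.data.copy()
    liquid_df["biomass_g_l"] = biomass
    ptruth = PulseTruth(
        events=events,
        expected_co_displaced_mol=exp_co,
        expected_h2_extra_mol=exp_h2,
        expected_biomass_increase_g=exp_bio,
        washout=washed,
        h2_per_no2_mol_mol=scn.h2_per_no2_mol_mol,
        co_per_no2_mol_mol=scn.co_per_no2_mol_mol,
        biomass_gain_g_per_mmol=scn.biomass_gain_g_per_mmol,
    )
    out = SimResult(gas=gas, liquid=LiquidSeries(liquid_df), truth=ptruth, scenario=scn)
    out.chemostat_truth = truth  # keep the underlying steady-state truth
    return out


def add_measurement_noise(result: SimResult, seed: int | None = None) -> SimResult:
    """Add iid Gaussian analyzer/assay noise, truncated at physical bounds.

    SDs come from the scenario (``noise_gas_pct`` per gas channel,
    ``noise_liquid_g_l`` per concentration, ``noise_biomass_g_l`` for
    biomass); the seed (scenario's unless overridden) makes the output
    bit-reproducible.
    """
    scn = result.scenario
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    gas_df = result.gas.data.copy()
    if scn.noise_gas_pct > 0:
        for g in ("o2", "n2", "co", "co2", "h2", "ar"):
            col = f"{g}_pct"
            noisy = gas_df[col].to_numpy(float) + rng.normal(0, scn.noise_gas_pct, len(gas_df))
            gas_df[col] = np.clip(noisy, 0.0, 100.0)
    liquid_df = result.liquid.data.copy()
    for col in liquid_df.columns:
        if col == "time_h":
            continue
        sd = scn.noise_biomass_g_l if col == "biomass_g_l" else scn.noise_liquid_g_l
        if sd > 0:
            liquid_df[col] = np.clip(
                liquid_df[col].to_numpy(float) + rng.normal(0, sd, len(liquid_df)), 0.0, None
            )
    out = SimResult(
        gas=GasStreamSeries(gas_df, result.gas.temperature_c, result.gas.pressure_atm),
        liquid=LiquidSeries(liquid_df),
        truth=copy.deepcopy(result.truth),
        scenario=scn,
    )
    if hasattr(result, "chemostat_truth"):
        out.chemostat_truth = result.chemostat_truth
    return out
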