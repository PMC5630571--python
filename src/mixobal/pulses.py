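"""Nitrite-pulse transient quantification and dose-response stoichiometry.

Nitrite acts as a preferred electron sink: a pulse transiently displaces
CO uptake, draws extra H2 and raises the biomass plateau.  Each response
is the time integral of the deviation of the gas uptake rate from its
pre-pulse steady-state baseline, taken from the pulse to the first return
to baseline (within 2 SE) and capped at one residence time.  Regressing
the integrated responses against dose gives the electron-sink
stoichiometries (mol gas per mol nitrite, g biomass per mmol nitrite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gas import GasStreamSeries, fraction_to_molar_flow
from .steady_state import SteadyStateRecord

__all__ = [
    "PulseEvent",
    "PulseResponse",
    "SlopeFit",
    "uptake_timeseries",
    "quantify_pulse_response",
    "stoichiometry_slopes",
]

WASHOUT_THRESHOLD_MM = 24.0


@dataclass(frozen=True)
class PulseEvent:
    """A nitrite addition: time, final concentration and absolute dose."""

    time_h: float
    concentration_mM: float
    volume_l: float = 0.7

    def __post_init__(self) -> None:
        if self.concentration_mM <= 0:
            raise ValueError("pulse concentration must be positive")
        if self.volume_l <= 0:
            raise ValueError("culture volume must be positive")

    @property
    def dose_mmol(self) -> float:
        return self.concentration_mM * self.volume_l

    @property
    def washout(self) -> bool:
        """Doses above the toxicity threshold wash the culture out and are
        flagged rather than analyzed."""
        return self.concentration_mM > WASHOUT_THRESHOLD_MM


@dataclass
class PulseResponse:
    """Integrated transient response to one nitrite pulse."""

    event: PulseEvent
    co_displaced_mol: float
    h2_extra_mol: float
    biomass_increase_g: float
    window_h: tuple[float, float]
    complete: bool  # False when the transient did not return to baseline


@dataclass
class SlopeFit:
    """One dose-response regression line."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    stderr: float
    r_squared: float
    n: int
    units: str


def uptake_timeseries(
    gas: GasStreamSeries,
    inlet_fraction_pct: dict[str, float],
    endogenous_mol_h: dict[str, float],
    inlet_flow_l_h: float | None = None,
    gases: tuple[str, ...] = ("co", "h2", "co2"),
) -> pd.DataFrame:
    """Per-gas uptake rate C(t) = I + E - O from an off-gas series.

    ``inlet_fraction_pct`` is the (constant) inlet composition at the
    sparge flow ``inlet_flow_l_h`` (the series' flow column is the outlet
    flow and must not be used for the inlet; it defaults to the first
    flow value only when no sparge flow is given).  ``endogenous_mol_h``
    holds the endogenous generation rates from the N2-sparged control.
    Positive values are consumption.
    """
    flow = gas.data["flow_l_h"].to_numpy(float)
    sparge = float(flow[0]) if inlet_flow_l_h is None else float(inlet_flow_l_h)
    out = {"time_h": gas.time_h}
    for g in gases:
        o = gas.molar_flow(g)
        i = fraction_to_molar_flow(
            inlet_fraction_pct.get(g, 0.0), sparge, gas.temperature_c, gas.pressure_atm
        )
        out[f"{g}_uptake_mol_h"] = i + endogenous_mol_h.get(g, 0.0) - o
    return pd.DataFrame(out)


def quantify_pulse_response(
    uptake: pd.DataFrame,
    biomass: pd.DataFrame,
    event: PulseEvent,
    baseline: SteadyStateRecord,
    dilution_rate_per_h: float = 0.135,
    next_event_h: float | None = None,
) -> PulseResponse:
    """Integrate the deviation from baseline after one nitrite pulse.

    ``uptake`` must carry ``co_uptake_mol_h``/``h2_uptake_mol_h`` columns
    (see :func:`uptake_timeseries`); ``biomass`` a ``biomass_g_l`` column.
    ``baseline`` is the pre-pulse steady state providing means and SEs.

    Displaced CO is the integral of (baseline - observed) CO uptake, extra
    H2 the integral of (observed - baseline) H2 uptake.  The window runs
    from the pulse to the first post-peak return of both deviations within
    max(2 SE, 1 % of peak), capped at one residence time and at the next
    event; an unfinished transient is flagged ``complete=False``.
    """
    if event.washout:
        raise ValueError(
            f"{event.concentration_mM} mM exceeds the {WASHOUT_THRESHOLD_MM} mM "
            "washout threshold; washout events are flagged, not analyzed"
        )
    t = uptake["time_h"].to_numpy(float)
    cap = event.time_h + 1.0 / dilution_rate_per_h
    if next_event_h is not None:
        cap = min(cap, next_event_h)
    mask = (t >= event.time_h) & (t <= cap)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 samples in the response window")
    tw = t[mask]

    dev_co = baseline.means["co_uptake_mol_h"] - uptake["co_uptake_mol_h"].to_numpy(float)[mask]
    dev_h2 = uptake["h2_uptake_mol_h"].to_numpy(float)[mask] - baseline.means["h2_uptake_mol_h"]

    def tol(name: str, dev: np.ndarray) -> float:
        return max(2.0 * baseline.ses.get(name, 0.0), 0.01 * float(np.max(np.abs(dev))), 1e-15)

    # first index after the joint deviation peak where both channels are back
    mag = np.abs(dev_co) / tol("co_uptake_mol_h", dev_co) + np.abs(dev_h2) / tol(
        "h2_uptake_mol_h", dev_h2
    )
    peak = int(np.argmax(mag))
    back = np.flatnonzero(
        (np.abs(dev_co) <= tol("co_uptake_mol_h", dev_co))
        & (np.abs(dev_h2) <= tol("h2_uptake_mol_h", dev_h2))
    )
    back = back[back > peak]
    if len(back):
        end = int(back[0])
        complete = True
    else:
        end = len(tw) - 1
        complete = False

    co_displaced = float(np.trapezoid(dev_co[: end + 1], tw[: end + 1]))
    h2_extra = float(np.trapezoid(dev_h2[: end + 1], tw[: end + 1]))

    tb = biomass["time_h"].to_numpy(float)
    xb = biomass["biomass_g_l"].to_numpy(float)
    plateau_mask = (tb >= tw[end]) & (tb <= cap)
    if plateau_mask.sum() == 0:  # transient filled the cap; use its tail
        plateau_mask = (tb >= tw[max(end - 2, 0)]) & (tb <= cap)
    plateau = float(xb[plateau_mask].mean())
    biomass_increase = (plateau - baseline.means["biomass_g_l"]) * event.volume_l

    return PulseResponse(
        event=event,
        co_displaced_mol=co_displaced,
        h2_extra_mol=h2_extra,
        biomass_increase_g=biomass_increase,
        window_h=(float(tw[0]), float(tw[end])),
        complete=complete,
    )


def stoichiometry_slopes(
    responses: list[PulseResponse],
    fit_intercept: bool = True,
    alpha: float = 0.05,
) -> dict[str, SlopeFit]:
    """Dose-response OLS slopes with confidence intervals.

    Gas responses are regressed in mol against mol of nitrite (slope is a
    mol/mol stoichiometry); the biomass response in g against mmol (slope
    g/mmol).  Washout-flagged events must be excluded upstream.  Requires
    at least two distinct doses.
    """
    import statsmodels.api as sm

    usable = [r for r in responses if not r.event.washout]
    if len(usable) < 2:
        raise ValueError("at least two non-washout doses are required")
    if fit_intercept and len({r.event.dose_mmol for r in usable}) < 2:
        raise ValueError(
            "at least two distinct doses are required to fit an intercept "
            "(singular design)"
        )

    dose_mmol = np.array([r.event.dose_mmol for r in usable])
    targets = {
        "h2_per_no2_mol_mol": (np.array([r.h2_extra_mol for r in usable]), dose_mmol / 1e3, "mol H2 / mol NO2"),
        "co_per_no2_mol_mol": (np.array([r.co_displaced_mol for r in usable]), dose_mmol / 1e3, "mol CO / mol NO2"),
        "biomass_g_per_mmol": (np.array([r.biomass_increase_g for r in usable]), dose_mmol, "g / mmol NO2"),
    }
    fits: dict[str, SlopeFit] = {}
    for name, (y, x, units) in targets.items():
        design = sm.add_constant(x) if fit_intercept else x[:, None]
        model = sm.OLS(y, design).fit()
        slope_idx = 1 if fit_intercept else 0
        ci = model.conf_int(alpha=alpha)
        fits[name] = SlopeFit(
            slope=float(model.params[slope_idx]),
            intercept=float(model.params[0]) if fit_intercept else 0.0,
            ci_low=float(ci[slope_idx][0]),
            ci_high=float(ci[slope_idx][1]),
            stderr=float(model.bse[slope_idx]),
            r_squared=float(model.rsquared) if np.var(y) > 0 else 1.0,
            n=len(y),
            units=units,
        )
    return fits
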