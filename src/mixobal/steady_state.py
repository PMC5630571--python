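"""Chemostat steady-state detection and summary.

A chemostat run is accepted as steady over a window when, for every
monitored variable, the fitted linear trend over the window is negligible
relative to the window mean, and the window starts no earlier than a
minimum number of residence times (1/D each) after the last perturbation.
The default acceptance rule is |slope x window length| < rel_tol x |mean|
with rel_tol = 2 %, evaluated per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SteadyStateRecord", "detect_steady_state", "summarize"]

#: Floor used when a variable's window mean is ~0 (e.g. an absent gas):
#: the trend tolerance falls back to rel_tol x this fraction of the
#: variable's overall range so that identically-zero channels pass.
_ZERO_MEAN_FLOOR = 0.05


@dataclass
class SteadyStateRecord:
    """Summary of one accepted steady window."""

    start_h: float
    end_h: float
    residence_times_elapsed: float
    n_samples: int
    means: dict[str, float] = field(default_factory=dict)
    ses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residence_times_elapsed < 0:
            raise ValueError("residence_times_elapsed must be nonnegative")
        if any(se < 0 for se in self.ses.values()):
            raise ValueError("standard errors must be nonnegative")


def _trend_ok(t: np.ndarray, y: np.ndarray, rel_tol: float, scale_floor: float) -> tuple[bool, float]:
    """Is the linear drift across the window small relative to the mean?

    Returns (ok, drift_ratio) where drift_ratio = |slope*span| / tolerance
    scale; ratios > 1 fail.
    """
    span = t[-1] - t[0]
    if span <= 0:
        return False, np.inf
    slope = np.polyfit(t, y, 1)[0]
    mean = y.mean()
    scale = max(abs(mean), _ZERO_MEAN_FLOOR * scale_floor, 1e-12)
    ratio = abs(slope * span) / (rel_tol * scale)
    return ratio <= 1.0, ratio


def detect_steady_state(
    series: pd.DataFrame,
    dilution_rate_per_h: float,
    variables: list[str] | None = None,
    perturbations_h: list[float] | None = None,
    min_residence: float = 3.0,
    rel_tol: float = 0.02,
    min_window_residence: float = 1.0,
) -> tuple[list[SteadyStateRecord], dict]:
    """Find maximal steady windows in a time-indexed series.

    Parameters
    ----------
    series : DataFrame
        Must contain a ``time_h`` column; all other (or the listed)
        columns are monitored variables.
    dilution_rate_per_h : float
        D; the residence time is 1/D.
    perturbations_h : list of float
        Times of known perturbations (pulses, gas-blend switches).
        Windows never start before ``min_residence/D`` after the latest
        perturbation preceding them.  The series start (first sample) is
        always treated as a perturbation.
    rel_tol : float
        Maximum |trend slope x window length| as a fraction of the window
        mean, per variable.
    min_window_residence : float
        Minimum accepted window length in residence times (default 1;
        sampling is spread over at least one residence-time interval, and
        a slowly drifting signal cannot sneak in as a short quiet tail).

    Returns
    -------
    (windows, diagnostics)
        ``windows`` is a list of :class:`SteadyStateRecord`; when empty,
        ``diagnostics['worst_variable']`` names the variable whose drift
        most exceeded tolerance.
    """
    if dilution_rate_per_h <= 0:
        raise ValueError("dilution rate must be positive")
    if "time_h" not in series.columns:
        raise ValueError("series must contain a 'time_h' column")
    t_all = series["time_h"].to_numpy(float)
    cols = variables if variables is not None else [c for c in series.columns if c != "time_h"]
    tau = 1.0 / dilution_rate_per_h
    settle = min_residence * tau

    marks = sorted(set([t_all[0], *(perturbations_h or [])]))
    segments = []
    for i, p in enumerate(marks):
        seg_end = marks[i + 1] if i + 1 < len(marks) else np.inf
        segments.append((p + settle, seg_end))

    windows: list[SteadyStateRecord] = []
    worst_name, worst_ratio = None, -np.inf
    for lo, hi in segments:
        mask = (t_all >= lo) & (t_all < hi)
        idx = np.flatnonzero(mask)
        if len(idx) < 3:
            continue
        # grow the window start forward until every variable's trend passes
        found = None
        for start in idx:
            sub = np.arange(start, idx[-1] + 1)
            if len(sub) < 3:
                break
            t = t_all[sub]
            if t[-1] - t[0] < min_window_residence * tau:
                break
            ok_all = True
            for c in cols:
                y = series[c].to_numpy(float)[sub]
                floor = float(np.ptp(series[c].to_numpy(float))) or 1.0
                ok, ratio = _trend_ok(t, y, rel_tol, floor)
                if not ok:
                    ok_all = False
                    if ratio > worst_ratio:
                        worst_name, worst_ratio = c, ratio
                    break
            if ok_all:
                found = sub
                break
        if found is not None:
            t = t_all[found]
            rec = summarize(series, (float(t[0]), float(t[-1])), dilution_rate_per_h, cols)
            # residence times elapsed from the governing perturbation to the
            # window end; >= min_residence by construction
            rec.residence_times_elapsed = (float(t[-1]) - (lo - settle)) * dilution_rate_per_h
            windows.append(rec)
    diagnostics = {"worst_variable": worst_name, "worst_drift_ratio": worst_ratio}
    return windows, diagnostics


def summarize(
    series: pd.DataFrame,
    window: tuple[float, float],
    dilution_rate_per_h: float,
    variables: list[str] | None = None,
) -> SteadyStateRecord:
    """Mean, standard error and sample count per variable over a window."""
    t0, t1 = window
    t_all = series["time_h"].to_numpy(float)
    mask = (t_all >= t0) & (t_all <= t1)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("steady-state summary requires at least 3 samples in the window")
    cols = variables if variables is not None else [c for c in series.columns if c != "time_h"]
    means, ses = {}, {}
    for c in cols:
        y = series[c].to_numpy(float)[mask]
        means[c] = float(y.mean())
        ses[c] = float(y.std(ddof=1) / np.sqrt(n))
    return SteadyStateRecord(
        start_h=t0,
        end_h=t1,
        residence_times_elapsed=(t1 - t0) * dilution_rate_per_h,
        n_samples=n,
        means=means,
        ses=ses,
    )
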