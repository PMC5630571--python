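"""Pulse-response integration and dose-response slope estimation."""

import numpy as np
import pandas as pd
import pytest

from mixobal.pulses import (
    PulseEvent,
    PulseResponse,
    quantify_pulse_response,
    stoichiometry_slopes,
)
from mixobal.steady_state import SteadyStateRecord


def flat_baseline(co=0.006, h2=0.06, biomass=3.0):
    return SteadyStateRecord(
        start_h=0.0,
        end_h=10.0,
        residence_times_elapsed=3.0,
        n_samples=50,
        means={"co_uptake_mol_h": co, "h2_uptake_mol_h": h2, "biomass_g_l": biomass},
        ses={"co_uptake_mol_h": 0.0, "h2_uptake_mol_h": 0.0, "biomass_g_l": 0.0},
    )


def uptake_frame(t, co, h2):
    return pd.DataFrame({"time_h": t, "co_uptake_mol_h": co, "h2_uptake_mol_h": h2})


def biomass_frame(t, x):
    return pd.DataFrame({"time_h": t, "biomass_g_l": x})


class TestPulseEvent:
    def test_dose_from_concentration_and_volume(self):
        ev = PulseEvent(time_h=10.0, concentration_mM=6.2, volume_l=0.7)
        assert ev.dose_mmol == pytest.approx(4.34)

    def test_washout_flag(self):
        assert PulseEvent(time_h=0, concentration_mM=30.0).washout
        assert not PulseEvent(time_h=0, concentration_mM=12.4).washout

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            PulseEvent(time_h=0, concentration_mM=0.0)


class TestQuantify:
    def test_no_deviation_gives_zero_responses(self):
        t = np.arange(0, 20, 0.05)
        base = flat_baseline()
        resp = quantify_pulse_response(
            uptake_frame(t, np.full_like(t, 0.006), np.full_like(t, 0.06)),
            biomass_frame(t, np.full_like(t, 3.0)),
            PulseEvent(time_h=10.0, concentration_mM=3.1),
            base,
        )
        assert resp.co_displaced_mol == pytest.approx(0.0, abs=1e-12)
        assert resp.h2_extra_mol == pytest.approx(0.0, abs=1e-12)
        assert resp.biomass_increase_g == pytest.approx(0.0, abs=1e-12)

    def test_rectangular_deviation_integrates_to_area(self):
        t = np.arange(0, 20, 0.01)
        co = np.full_like(t, 0.006)
        co[(t >= 10.0) & (t < 12.0)] -= 0.003  # displaced uptake, area 0.006
        h2 = np.full_like(t, 0.06)
        h2[(t >= 10.0) & (t < 12.0)] += 0.005  # extra uptake, area 0.010
        resp = quantify_pulse_response(
            uptake_frame(t, co, h2),
            biomass_frame(t, np.full_like(t, 3.0)),
            PulseEvent(time_h=10.0, concentration_mM=3.1),
            flat_baseline(),
        )
        assert resp.co_displaced_mol == pytest.approx(0.006, rel=0.02)
        assert resp.h2_extra_mol == pytest.approx(0.010, rel=0.02)

    def test_doubling_deviation_doubles_response(self):
        t = np.arange(0, 20, 0.01)

        def make(scale):
            co = np.full_like(t, 0.006)
            co[(t >= 10.0) & (t < 12.0)] -= scale * 0.002
            return quantify_pulse_response(
                uptake_frame(t, co, np.full_like(t, 0.06)),
                biomass_frame(t, np.full_like(t, 3.0)),
                PulseEvent(time_h=10.0, concentration_mM=3.1),
                flat_baseline(),
            ).co_displaced_mol

        assert make(2.0) == pytest.approx(2.0 * make(1.0), rel=1e-6)

    def test_biomass_plateau_increase(self):
        t = np.arange(0, 20, 0.01)
        x = np.where(t >= 10.0, 3.5, 3.0)
        resp = quantify_pulse_response(
            uptake_frame(t, np.full_like(t, 0.006), np.full_like(t, 0.06)),
            biomass_frame(t, x),
            PulseEvent(time_h=10.0, concentration_mM=3.1, volume_l=0.7),
            flat_baseline(biomass=3.0),
        )
        assert resp.biomass_increase_g == pytest.approx(0.5 * 0.7, rel=0.02)

    def test_washout_dose_rejected(self):
        t = np.arange(0, 20, 0.05)
        with pytest.raises(ValueError, match="washout"):
            quantify_pulse_response(
                uptake_frame(t, np.full_like(t, 0.006), np.full_like(t, 0.06)),
                biomass_frame(t, np.full_like(t, 3.0)),
                PulseEvent(time_h=10.0, concentration_mM=30.0),
                flat_baseline(),
            )

    def test_unfinished_transient_flagged(self):
        t = np.arange(0, 20, 0.01)
        co = np.full_like(t, 0.006)
        co[t >= 10.0] -= 0.003  # never returns to baseline
        resp = quantify_pulse_response(
            uptake_frame(t, co, np.full_like(t, 0.06)),
            biomass_frame(t, np.full_like(t, 3.0)),
            PulseEvent(time_h=10.0, concentration_mM=3.1),
            flat_baseline(),
        )
        assert not resp.complete


def exact_responses(doses_mM, h2_slope=2.5, co_slope=1.0, bio_gain=0.05, volume=0.7):
    out = []
    t0 = 10.0
    for c in doses_mM:
        ev = PulseEvent(time_h=t0, concentration_mM=c, volume_l=volume)
        d_mol = ev.dose_mmol / 1e3
        out.append(
            PulseResponse(
                event=ev,
                co_displaced_mol=co_slope * d_mol,
                h2_extra_mol=h2_slope * d_mol,
                biomass_increase_g=bio_gain * ev.dose_mmol,
                window_h=(t0, t0 + 5),
                complete=True,
            )
        )
        t0 += 10.0
    return out


class TestSlopes:
    def test_exact_data_recovers_slopes(self):
        fits = stoichiometry_slopes(exact_responses([3.1, 6.2, 12.4]))
        assert fits["h2_per_no2_mol_mol"].slope == pytest.approx(2.5, abs=1e-9)
        assert fits["co_per_no2_mol_mol"].slope == pytest.approx(1.0, abs=1e-9)
        assert fits["biomass_g_per_mmol"].slope == pytest.approx(0.05, abs=1e-9)

    def test_single_dose_through_origin(self):
        # two repeats of one dose with no intercept: slope = r/d
        fits = stoichiometry_slopes(exact_responses([6.2, 6.2]), fit_intercept=False)
        assert fits["h2_per_no2_mol_mol"].slope == pytest.approx(2.5, abs=1e-9)

    def test_all_equal_doses_with_intercept_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            stoichiometry_slopes(exact_responses([6.2, 6.2]))

    def test_washout_events_excluded(self):
        responses = exact_responses([3.1, 6.2, 12.4, 30.0])
        fits = stoichiometry_slopes(responses)
        assert fits["h2_per_no2_mol_mol"].n == 3

    def test_confidence_interval_brackets_slope(self):
        rng = np.random.default_rng(3)
        responses = exact_responses([3.1, 6.2, 12.4, 24.0])
        for r in responses:
            r.h2_extra_mol *= 1 + rng.normal(0, 0.02)
        fit = stoichiometry_slopes(responses)["h2_per_no2_mol_mol"]
        assert fit.ci_low < fit.slope < fit.ci_high


class TestSimulatedPulseRoundTrip:
    def test_noise_free_schedule_recovers_stoichiometries(self):
        from mixobal.pipeline import run_pulse_experiment
        from mixobal.simulate import SimScenario

        fits, responses, truth = run_pulse_experiment(
            SimScenario.high_syngas(), [(25.0, 3.1), (35.0, 6.2), (45.0, 12.4)]
        )
        assert fits["h2_per_no2_mol_mol"].slope == pytest.approx(2.5, rel=0.02)
        assert fits["co_per_no2_mol_mol"].slope == pytest.approx(1.0, rel=0.02)
        assert fits["biomass_g_per_mmol"].slope == pytest.approx(0.05, rel=0.02)
        assert all(r.complete for r in responses)

    def test_response_additive_over_disjoint_windows(self):
        from mixobal.pipeline import run_pulse_experiment
        from mixobal.simulate import SimScenario

        _, responses, _ = run_pulse_experiment(
            SimScenario.high_syngas(), [(25.0, 6.2), (40.0, 6.2)]
        )
        # same dose twice in disjoint windows: equal integrated responses
        assert responses[0].h2_extra_mol == pytest.approx(responses[1].h2_extra_mol, rel=0.01)
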