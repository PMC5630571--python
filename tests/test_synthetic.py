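"""Generator conservation laws and analysis round trips."""

import dataclasses

import numpy as np
import pytest

from mixobal.pipeline import analyze_run, balance_against_control
from mixobal.simulate import (
    SimScenario,
    add_measurement_noise,
    inject_nitrite_pulses,
    simulate_chemostat,
    simulate_fedbatch,
)
from mixobal.stoichiometry import load_default_registry


def random_feasible_scenario(rng: np.random.Generator) -> SimScenario:
    """Draw a conservation-feasible chemostat scenario at random.

    The capture parameters are capped by the gas the sparge and the
    fermentation actually supply, mirroring the physical feasibility the
    generator enforces.
    """
    from mixobal.gas import fraction_to_molar_flow

    names = ["butanol", "acetone", "ethanol", "acetate", "butyrate"]
    raw = rng.uniform(0.2, 1.0, len(names))
    total = rng.uniform(0.40, 0.60)  # non-CO2 product carbon
    yields = dict(zip(names, raw / raw.sum() * total))
    yields["acetate"] = max(yields["acetate"], 0.06)
    biomass = rng.uniform(0.05, 0.15)
    gamma = {"butanol": 6.0, "acetone": 16 / 3, "ethanol": 6.0, "acetate": 4.0,
             "butyrate": 5.0}
    e_products = sum(yields[p] * gamma[p] for p in yields) + biomass * 4.2
    h2_yield = (4.0 - e_products) / 2.0  # closes the electron balance exactly
    while h2_yield < 0.05:
        yields = {p: y * 0.9 for p, y in yields.items()}
        e_products = sum(yields[p] * gamma[p] for p in yields) + biomass * 4.2
        h2_yield = (4.0 - e_products) / 2.0
    conversion = float(rng.uniform(0.6, 0.95))
    kw = dict(
        product_yields=yields,
        biomass_yield=float(biomass),
        h2_yield_mol_per_cmol=float(h2_yield),
        sugar_conversion=conversion,
        t_end_h=30.0,
        dt_h=0.5,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    regime = rng.choice(["none", "oxidation", "c1"])
    if regime == "none":
        return SimScenario.heterotrophic(**kw)
    if regime == "oxidation":
        return SimScenario(
            syngas_fraction_pct=float(rng.uniform(3, 20)),
            regime="oxidation",
            co_oxidation_fraction=float(rng.uniform(0.1, 0.9)),
            **kw,
        )
    # C-1 regime: cap capture by what the gas phase can supply
    syngas = float(rng.uniform(30, 80))
    feed_cmol_l = 30.0 * 12 / 342.30 + 15.0 * 6 / 180.16
    S = conversion * feed_cmol_l * 0.135 * 0.7
    inlet_h2 = fraction_to_molar_flow(10.0 * syngas / 100.0, 12.48)
    inlet_co = fraction_to_molar_flow(20.0 * syngas / 100.0, 12.48)
    gamma_mix = 0.7 * 6.0 + 0.3 * 5.0
    co_share = float(rng.uniform(0.0, 0.5))
    f_c = float(rng.uniform(0.02, 0.15))
    a = min(co_share * f_c * S, 0.9 * inlet_co)
    h2_avail_e = 2.0 * 0.9 * (inlet_h2 + h2_yield * S)
    carried_e = gamma_mix * f_c * S - 2.0 * a
    if carried_e > h2_avail_e:
        scale = h2_avail_e / carried_e * 0.99
        f_c *= scale
        a *= scale
        carried_e = gamma_mix * f_c * S - 2.0 * a
    spare_h2_e = max(h2_avail_e - carried_e, 0.0)
    shift_max_e = 2.0 * 0.9 * yields["acetate"] * S
    extra_e = float(rng.uniform(0.0, min(spare_h2_e, shift_max_e)))
    f_e = (gamma_mix * f_c * S + extra_e) / (4.0 * S)
    return SimScenario(
        syngas_fraction_pct=syngas,
        regime="c1",
        c1_carbon_fraction=f_c,
        electron_capture_fraction=f_e,
        c1_co_share=co_share,
        **kw,
    )


def conservation_residuals(truth, registry) -> tuple[float, float]:
    """Recompute carbon/electron residuals independently of the generator."""
    S = truth.sugar_flux_cmol_h
    cons = truth.consumption_mol_h
    prod = truth.product_yields_cmol
    carbon_in = S + cons.get("co", 0.0) + cons.get("co2", 0.0)
    carbon_out = sum(prod.values()) * S + truth.biomass_yield_cmol * S + truth.endogenous_mol_h["co2"]
    e_in = 4.0 * S + 2.0 * cons.get("h2", 0.0) + 2.0 * cons.get("co", 0.0)
    e_out = (
        sum(prod[p] * registry.gamma(p) for p in prod) * S
        + truth.biomass_yield_cmol * S * registry.gamma("biomass")
        + 2.0 * truth.endogenous_mol_h["h2"]
    )
    return carbon_in - carbon_out, e_in - e_out


class TestConservation:
    def test_hundred_random_scenarios_conserve_to_1e9(self, registry):
        rng = np.random.default_rng(42)
        for _ in range(100):
            scn = random_feasible_scenario(rng)
            result = simulate_chemostat(scn)
            c_res, e_res = conservation_residuals(result.truth, registry)
            scale = result.truth.sugar_flux_cmol_h
            assert abs(c_res) / scale < 1e-9, scn
            assert abs(e_res) / scale < 1e-9, scn
            assert abs(result.truth.carbon_residual) / scale < 1e-9
            assert abs(result.truth.electron_residual) / scale < 1e-9

    def test_infeasible_scenario_rejected(self):
        with pytest.raises(ValueError, match="conservation"):
            SimScenario(product_yields={"butanol": 0.9, "acetate": 0.2})

    def test_overdrawn_electron_shift_rejected(self):
        with pytest.raises(ValueError, match="acetate"):
            simulate_chemostat(
                SimScenario(
                    syngas_fraction_pct=60.0,
                    c1_carbon_fraction=0.05,
                    electron_capture_fraction=0.50,
                )
            )


class TestRegimes:
    def test_heterotrophic_balances_close_through_pipeline(self, het_result):
        summary = analyze_run(het_result)
        report = balance_against_control(
            summary, summary, het_result.scenario.inlet_fraction_pct()
        )
        assert report.control["carbon_recovery"] == pytest.approx(1.0, abs=1e-6)
        assert report.control["electron_recovery"] == pytest.approx(1.0, abs=1e-6)
        assert report.excess_carbon_pct == pytest.approx(0.0, abs=1e-6)

    def test_low_syngas_co_oxidation_is_one_to_one(self):
        scn = SimScenario.low_syngas()
        result = simulate_chemostat(scn)
        truth = result.truth
        assert truth.regime == "oxidation"
        cox = truth.consumption_mol_h["co"]
        assert cox > 0
        # CO + H2O -> CO2 + H2: the oxidized CO reappears mol-for-mol
        het = simulate_chemostat(scn.control()).truth
        assert truth.endogenous_mol_h["co2"] - het.endogenous_mol_h["co2"] == pytest.approx(cox, rel=1e-9)
        assert truth.endogenous_mol_h["h2"] - het.endogenous_mol_h["h2"] == pytest.approx(cox, rel=1e-9)

    def test_inlet_co2_fraction_selects_the_regime(self):
        low = simulate_chemostat(SimScenario(syngas_fraction_pct=9.0, c1_carbon_fraction=0.1))
        high = simulate_chemostat(SimScenario(syngas_fraction_pct=60.0, c1_carbon_fraction=0.1,
                                              electron_capture_fraction=0.16))
        assert low.truth.regime == "oxidation"  # inlet CO2 1.8 % < 5 %
        assert high.truth.regime == "c1"  # inlet CO2 12 % > 5 %

    def test_high_syngas_round_trip_of_capture_fractions(self, high_result, het_result):
        cond = analyze_run(high_result)
        ctrl = analyze_run(het_result)
        report = balance_against_control(
            cond, ctrl, high_result.scenario.inlet_fraction_pct()
        )
        assert report.excess_carbon_pct == pytest.approx(17.0, abs=1e-6)
        assert report.excess_electron_pct == pytest.approx(27.0, abs=1e-6)
        assert report.c1_fraction == pytest.approx(0.17, abs=1e-6)
        assert report.carbon_closure == pytest.approx(1.0, abs=1e-6)
        assert report.electron_closure == pytest.approx(1.0, abs=1e-6)

    def test_measured_inlet_override(self):
        scn = SimScenario.high_syngas(
            measured_inlet_pct={"co": 11.17, "co2": 11.01, "h2": 4.40}
        )
        inlet = scn.inlet_fraction_pct()
        assert inlet["n2"] == pytest.approx(100 - 11.17 - 11.01 - 4.40)
        result = simulate_chemostat(scn)
        assert result.truth.regime == "c1"


class TestNoise:
    def test_zero_sd_is_identity(self, het_result):
        noisy = add_measurement_noise(het_result, seed=5)
        assert np.array_equal(noisy.gas.data.to_numpy(), het_result.gas.data.to_numpy())
        assert np.array_equal(noisy.liquid.data.to_numpy(), het_result.liquid.data.to_numpy())

    def test_same_seed_bit_reproducible(self):
        scn = SimScenario.heterotrophic(noise_gas_pct=0.1, noise_liquid_g_l=0.05, seed=9)
        a = add_measurement_noise(simulate_chemostat(scn))
        b = add_measurement_noise(simulate_chemostat(scn))
        assert np.array_equal(a.gas.data.to_numpy(), b.gas.data.to_numpy())
        assert np.array_equal(a.liquid.data.to_numpy(), b.liquid.data.to_numpy())

    def test_sample_sd_matches_configured(self):
        scn = SimScenario.heterotrophic(noise_gas_pct=0.2, t_end_h=100.0, dt_h=0.1, seed=3)
        noisy = add_measurement_noise(simulate_chemostat(scn))
        resid = noisy.gas.fraction("co2") - simulate_chemostat(scn).gas.fraction("co2")
        assert np.std(resid) == pytest.approx(0.2, rel=0.15)

    def test_zero_bio_exchange_nets_to_zero_consumption(self):
        """A sterile sparge run shows zero net consumption within noise."""
        scn = SimScenario(
            syngas_fraction_pct=60.0, regime="none", sugar_conversion=1e-9,
            product_yields={}, biomass_yield=0.0, h2_yield_mol_per_cmol=0.0,
            noise_gas_pct=0.05, seed=21,
        )
        result = add_measurement_noise(simulate_chemostat(scn))
        from mixobal.pulses import uptake_timeseries

        up = uptake_timeseries(
            result.gas, scn.inlet_fraction_pct(), {"co2": 0.0, "h2": 0.0, "co": 0.0},
            inlet_flow_l_h=scn.sparge_flow_l_h,
        )
        for g in ("co", "h2"):
            assert abs(up[f"{g}_uptake_mol_h"].mean()) < 3e-4  # analyzer-noise scale


class TestPulseInjection:
    def test_empty_schedule_leaves_series_unchanged(self, high_result):
        out = inject_nitrite_pulses(high_result, [])
        assert np.allclose(out.gas.data.to_numpy(), high_result.gas.data.to_numpy())

    def test_overlapping_schedule_rejected(self, high_result):
        with pytest.raises(ValueError, match="overlap"):
            inject_nitrite_pulses(high_result, [(25.0, 3.1), (26.0, 3.1)])

    def test_washout_dose_decays_biomass_at_dilution_rate(self, high_result):
        scn = high_result.scenario
        out = inject_nitrite_pulses(high_result, [(30.0, 30.0)])
        assert out.truth.washout == [True]
        t = out.liquid.time_h
        x = out.liquid.concentration("biomass")
        i0 = np.searchsorted(t, 30.0)
        i1 = np.searchsorted(t, 40.0)
        observed = np.log(x[i0] / x[i1]) / (t[i1] - t[i0])
        assert observed == pytest.approx(scn.dilution_rate_per_h, rel=1e-6)

    def test_truth_records_expected_integrals(self, high_result):
        out = inject_nitrite_pulses(high_result, [(25.0, 6.2)])
        dose_mol = 6.2 * high_result.scenario.volume_l / 1e3
        assert out.truth.expected_h2_extra_mol[0] == pytest.approx(2.5 * dose_mol)
        assert out.truth.expected_co_displaced_mol[0] == pytest.approx(1.0 * dose_mol)


def test_fedbatch_amplitude_zero_is_monotone_ramp():
    fb = simulate_fedbatch(SimScenario(mode="fedbatch", osc_amplitude_pct=0.0, t_end_h=30.0, dt_h=0.05))
    h2 = fb.gas.fraction("h2")
    assert np.all(np.diff(h2) >= -1e-12)
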