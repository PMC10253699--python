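"""Composed liver ODE: baseline stationarity, injury kinetics, summaries."""

import numpy as np
import pytest

from hepatoqst.liver_core import (StateIndex, baseline_state,
                                  build_bile_constants, necrosis_rate,
                                  regeneration_rate, simulate, summarize,
                                  SimulationError, _uln_category)
from hepatoqst.params import PhysiologyParams, derive_bilirubin_constants


class TestBaseline:
    def test_construction_is_a_fixed_point(self, phys):
        """Drug-free RHS residual at the constructed baseline is ~0
        (verified via integration drift over 1000 days)."""
        res = simulate(duration_days=1000.0, grid_dt=24.0)
        ref = np.where(res.baseline == 0, 1.0, res.baseline)
        drift = np.abs((res.states[-1] - res.baseline) / ref)
        assert drift.max() < 5e-3  # < 0.5 %

    def test_twelve_week_alt_band(self, baseline_12wk):
        alt = baseline_12wk.alt
        assert alt.min() > 24.9 and alt.max() < 25.1

    def test_baseline_values(self, phys):
        y = baseline_state(phys)
        assert y[StateIndex.ALT] == pytest.approx(25.0, abs=0.01)
        assert np.all(y[StateIndex.VIABLE] == 1.0)
        assert y[StateIndex.TG] == 1.0

    def test_elevated_il6_context_changes_cyp_but_stays_stationary(self):
        res = simulate(context="elevated", duration_days=28.0)
        assert res["cyp3a4"][-1] < 0.6  # suppressed by the cytokine tone
        ref = np.where(res.baseline == 0, 1.0, res.baseline)
        assert np.abs((res.states[-1] - res.baseline) / ref).max() < 5e-3

    def test_infeasible_susceptibility_rejected(self):
        with pytest.raises(SimulationError):
            baseline_state(PhysiologyParams().with_overrides(
                {"bile_acid_tox_ec50": 0.3}))


class TestAltKinetics:
    def test_perturbed_alt_relaxes_with_47h_half_life(self, phys):
        y0 = baseline_state(phys)
        y0 = y0.copy()
        y0[StateIndex.ALT] = 50.0
        res = simulate(duration_days=21.0, y0=y0)
        excess = res.alt - 25.0
        # fit the washout rate over the first 10 days
        mask = (res.times > 0) & (res.times < 240) & (excess > 0.5)
        slope = np.polyfit(res.times[mask], np.log(excess[mask]), 1)[0]
        t_half = -np.log(2) / slope
        assert t_half == pytest.approx(47.0, rel=0.02)

    def test_impulse_response_shape(self):
        res = simulate(injury_impulse=0.05, duration_days=42.0)
        assert res.alt.max() > 25.0
        assert res.alt[-1] == pytest.approx(25.0, abs=1.0)  # returns to baseline

    def test_impulse_auc_linear_in_mass_lost(self):
        fracs = (0.01, 0.02, 0.05)
        aucs = []
        for f in fracs:
            res = simulate(injury_impulse=f, duration_days=42.0)
            aucs.append(np.trapezoid(res.alt - 25.0, res.times))
        r = np.corrcoef(fracs, aucs)[0, 1]
        assert r ** 2 > 0.99


class TestRateLaws:
    def test_necrosis_zero_at_healthy_atp(self, phys):
        assert np.all(necrosis_rate(np.ones(3), np.ones(3), phys) == 0.0)

    def test_necrosis_saturates_at_zero_atp(self, phys):
        rate = necrosis_rate(np.zeros(3), np.ones(3), phys)
        assert np.all(rate > 0.7 * phys.k_nec)
        assert np.all(rate <= phys.k_nec)

    def test_necrosis_monotone_in_deficit(self, phys):
        atps = np.linspace(0.0, phys.atp_death_threshold, 30)
        rates = [float(necrosis_rate(a, 1.0, phys)) for a in atps]
        assert all(r1 >= r2 for r1, r2 in zip(rates, rates[1:]))

    def test_regeneration_zero_at_full_liver(self, phys):
        assert np.all(regeneration_rate(np.ones(3), phys) == 0.0)

    def test_regeneration_linear_in_il6_multiplier(self, phys):
        v = np.array([0.8, 0.9, 0.85])
        r1 = regeneration_rate(v, phys, il6_regen_mult=1.0)
        r2 = regeneration_rate(v, phys, il6_regen_mult=0.5)
        assert np.allclose(r2, 0.5 * r1)


class TestNonNegativity:
    def test_states_stay_nonnegative_under_random_susceptibility(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ov = {"ros_damage_gain": rng.uniform(0.5, 2.0),
                  "gsh_synthesis": rng.uniform(0.3, 1.5),
                  "mito_sensitivity": rng.uniform(0.7, 1.5)}
            res = simulate(overrides=ov, duration_days=28.0,
                           injury_impulse=0.1, context="elevated")
            assert res.states.min() >= -1e-9


class TestSummaries:
    @pytest.mark.parametrize("peak,cat", [(39.0, "<1x"), (41.0, "1-3x"),
                                          (121.0, "3-5x"), (201.0, ">5x")])
    def test_uln_categories(self, peak, cat):
        assert _uln_category(peak, 40.0) == cat

    def test_control_self_reference_is_100(self, invitro_control):
        s = summarize(invitro_control, control=invitro_control,
                      readout_day=10.0)
        assert s.steatosis_pct == 100.0
        assert s.ros_pct == 100.0

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            simulate(overrides={"necrosis_speed": 2.0}, duration_days=1.0)

    def test_exposure_for_unknown_drug_rejected(self, tcz):
        with pytest.raises(ValueError):
            simulate(drugs=[], exposures={"tocilizumab": None},
                     duration_days=1.0)


class TestRhsConsistency:
    def test_bilirubin_rhs_matches_module_functions(self, phys):
        """The inlined RHS bilirubin block equals bile_bilirubin.bilirubin_derivs."""
        from hepatoqst.bile_bilirubin import bilirubin_derivs

        bconsts = derive_bilirubin_constants(phys)
        pools = np.array([0.5, 0.2, 0.12, 0.11])
        mult = {"oatp1b3_bilirubin_uptake": 0.7,
                "mrp3_bilirubin_basolateral": 1.5}
        d, fx = bilirubin_derivs(pools, mult, 0.93, bconsts)
        # mass balance: d(total) = production - biliary - clearance
        assert d.sum() == pytest.approx(
            fx["production"] - fx["biliary"] - fx["clearance"], abs=1e-12)

    def test_steady_state_bilirubin_mass_balance(self, baseline_12wk):
        """At baseline, production = biliary excretion + plasma clearance."""
        from hepatoqst.bile_bilirubin import bilirubin_fluxes

        phys = baseline_12wk.phys
        bconsts = derive_bilirubin_constants(phys)
        pools = baseline_12wk.states[-1, StateIndex.BILI]
        fx = bilirubin_fluxes(pools, {}, 1.0, bconsts)
        assert fx["production"] == pytest.approx(
            fx["biliary"] + fx["clearance"], rel=1e-6)
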