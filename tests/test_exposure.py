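"""Pharmacokinetic surrogate: two-compartment PK, partition fits, oral APAP."""

import numpy as np
import pytest

from hepatoqst.exposure import (ApapPK, DoseProtocol, ExposureError,
                                GGF2_PARTITION_ANCHORS,
                                TCZ_PARTITION_ANCHORS, MacromoleculePK,
                                apap_plasma_conc, constant_exposure,
                                fit_partition, ggf2_partition,
                                interstitial_concentration, simulate_apap_pk,
                                simulate_plasma, tocilizumab_partition,
                                tocilizumab_pk)


def linear_pk():
    """Two-compartment parameters with purely linear elimination."""
    return MacromoleculePK(150_000.0, 0.05, 0.06, 0.01, 5e-4, 0.0, 1.0)


def biexponential(t, pk, dose):
    """Closed-form single-IV-bolus solution of the linear two-compartment model."""
    k10 = pk.linear_clearance / pk.central_volume
    k12 = pk.intercompartment_clearance / pk.central_volume
    k21 = pk.intercompartment_clearance / pk.peripheral_volume
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4 * k10 * k21)
    lam1, lam2 = (s + disc) / 2, (s - disc) / 2
    c0 = dose / pk.central_volume
    a = c0 * (lam1 - k21) / (lam1 - lam2)
    b = c0 * (k21 - lam2) / (lam1 - lam2)
    return a * np.exp(-lam1 * t) + b * np.exp(-lam2 * t)


class TestSimulatePlasma:
    def test_matches_analytic_biexponential(self):
        pk = linear_pk()
        prot = DoseProtocol("iv_bolus", 5.0, n_doses=1, duration=14.0)
        grid = np.linspace(0.0, 14 * 24.0, 300)
        prof = simulate_plasma(pk, prot, grid)
        expected = biexponential(grid[1:], pk, 5.0)
        assert np.allclose(prof.plasma[1:], expected, rtol=1e-3)

    def test_zero_dose_gives_zero_profile(self):
        prot = DoseProtocol("iv_bolus", 0.0, n_doses=1, duration=7.0)
        prof = simulate_plasma(linear_pk(), prot, np.linspace(0, 168, 50))
        assert np.all(prof.plasma == 0)

    def test_dose_proportionality_without_tmdd(self):
        pk = linear_pk()
        grid = np.linspace(0, 500, 200)
        prot1 = DoseProtocol("iv_bolus", 2.0, interval=168.0, n_doses=3,
                             duration=21.0)
        prot2 = DoseProtocol("iv_bolus", 8.0, interval=168.0, n_doses=3,
                             duration=21.0)
        p1 = simulate_plasma(pk, prot1, grid).plasma
        p2 = simulate_plasma(pk, prot2, grid).plasma
        assert np.allclose(p2[1:], 4.0 * p1[1:], rtol=1e-7)

    def test_tmdd_makes_auc_over_dose_increase_with_dose(self):
        pk = tocilizumab_pk()
        grid = np.linspace(0, 2000, 800)
        aucs = []
        for dose in (1.0, 8.0):
            prot = DoseProtocol("iv_bolus", dose, n_doses=1, duration=84.0)
            prof = simulate_plasma(pk, prot, grid)
            aucs.append(np.trapezoid(prof.plasma, grid) / dose)
        assert aucs[1] > 1.2 * aucs[0]

    def test_clinical_tocilizumab_steady_state_cmax(self):
        prot = DoseProtocol("iv_bolus", 8.0, interval=672.0, n_doses=3,
                            duration=84.0)
        grid = np.arange(0.0, 84 * 24.0 + 0.25, 0.25)
        prof = simulate_plasma(tocilizumab_pk(), prot, grid,
                               partition=tocilizumab_partition())
        cmax_ss = prof.plasma[prof.times >= 2 * 672.0].max()
        assert cmax_ss == pytest.approx(232.0, rel=0.15)


class TestPartition:
    def test_log_linear_fit_reproduces_anchors(self):
        part = tocilizumab_partition()
        assert part.params["s"] == pytest.approx(0.0030868, rel=1e-3)
        assert part.params["a"] == pytest.approx(0.209049, rel=1e-3)
        for plasma, inter in TCZ_PARTITION_ANCHORS:
            assert interstitial_concentration(part, plasma) == pytest.approx(
                inter, rel=1e-6)

    def test_saturable_fit_reproduces_anchors(self):
        part = ggf2_partition()
        assert part.params["a"] == pytest.approx(0.6924, rel=1e-3)
        assert part.params["b"] == pytest.approx(2.6871, rel=1e-3)
        assert part.params["k"] == pytest.approx(1363.9, rel=1e-3)
        for plasma, inter in GGF2_PARTITION_ANCHORS:
            assert interstitial_concentration(part, plasma) == pytest.approx(
                inter, rel=1e-6)

    def test_identical_ratio_anchors_give_constant_ratio(self):
        part = fit_partition([(10.0, 5.0), (100.0, 50.0)], "log_linear_ratio")
        assert part.params["s"] == 0.0
        assert part.params["a"] == pytest.approx(0.5)
        part3 = fit_partition([(10.0, 5.0), (100.0, 50.0), (400.0, 200.0)],
                              "saturable_ratio")
        assert part3.params["b"] == 0.0
        assert part3.params["a"] == pytest.approx(0.5)

    def test_extrapolation_is_clamped(self):
        part = tocilizumab_partition()
        # one decade past the highest anchor the ratio stops changing
        r_hi = interstitial_concentration(part, 7250.0) / 7250.0
        r_higher = interstitial_concentration(part, 1e6) / 1e6
        assert r_hi == pytest.approx(r_higher, rel=1e-12)
        assert interstitial_concentration(part, 0.0) == 0.0

    def test_zero_plasma_maps_to_zero(self):
        assert interstitial_concentration(ggf2_partition(), 0.0) == 0.0

    def test_negative_plasma_rejected(self):
        with pytest.raises(ExposureError):
            interstitial_concentration(tocilizumab_partition(), -1.0)


class TestConstantExposure:
    @pytest.mark.parametrize("media,expected", [(232.0, 52.4), (725.0, 166.3)])
    def test_tocilizumab_interstitial_anchors(self, media, expected):
        prof = constant_exposure(tocilizumab_pk(), media, 10.0,
                                 partition=tocilizumab_partition())
        assert prof.interstitial[0] == pytest.approx(expected, rel=1e-6)
        assert np.all(prof.plasma == media)

    @pytest.mark.parametrize("media,expected",
                             [(382.0, 1066.4), (10.0, 33.6)])
    def test_ggf2_interstitial_anchors(self, media, expected):
        prof = constant_exposure(ggf2_pk_fixture(), media, 10.0,
                                 partition=ggf2_partition())
        assert prof.interstitial[0] == pytest.approx(expected, rel=1e-6)

    def test_zero_media_gives_zero(self):
        prof = constant_exposure(tocilizumab_pk(), 0.0, 10.0,
                                 partition=tocilizumab_partition())
        assert np.all(prof.interstitial == 0)

    def test_negative_media_rejected(self):
        with pytest.raises(ExposureError):
            constant_exposure(tocilizumab_pk(), -5.0, 10.0)

    def test_matches_infusion_steady_state(self):
        """Constant exposure equals the t→∞ limit of a rate-matched infusion."""
        pk = tocilizumab_pk()
        target = 232.0
        # infusion rate holding steady state at `target` (per-kg amounts)
        rate = (pk.linear_clearance * target
                + pk.saturable_clearance_vmax * target
                / (pk.saturable_clearance_km + target))
        duration = 6000.0  # h; long relative to the terminal half-life
        prot = DoseProtocol("iv_infusion", rate * duration, n_doses=1,
                            duration=duration / 24.0)
        grid = np.linspace(0, duration, 400)
        prof = simulate_plasma(pk, prot, grid)
        assert prof.plasma[-1] == pytest.approx(target, rel=0.005)


def ggf2_pk_fixture():
    from hepatoqst.exposure import ggf2_pk

    return ggf2_pk()


class TestApapPK:
    def test_single_dose_tmax_matches_analytic(self):
        pk = ApapPK()
        prot = DoseProtocol("oral", 1.0, n_doses=1, duration=2.0)
        grid = np.linspace(0, 24, 20001)
        conc = apap_plasma_conc(grid, pk, prot)
        tmax = grid[np.argmax(conc)]
        ka, ke = pk.ka, pk.ke
        tmax_analytic = np.log(ka / ke) / (ka - ke)
        assert tmax == pytest.approx(tmax_analytic, rel=0.01)

    def test_periodic_steady_state_by_day_three(self):
        pk = ApapPK()
        prot = DoseProtocol("oral", 1.0, interval=6.0, n_doses=336,
                            duration=84.0)
        t_day3 = np.linspace(72, 78, 61)
        t_day10 = t_day3 + 7 * 24
        c3 = apap_plasma_conc(t_day3, pk, prot)
        c10 = apap_plasma_conc(t_day10, pk, prot)
        assert np.allclose(c3, c10, rtol=1e-3)
        assert c3.min() > 0  # trough above zero at steady state

    def test_zero_dose_gives_zero(self):
        prot = DoseProtocol("oral", 0.0, interval=6.0, n_doses=4, duration=1.0)
        prof = simulate_apap_pk(ApapPK(), prot)
        assert np.all(prof.plasma == 0)

    def test_superposition_matches_explicit_sum(self):
        """Geometric-series dosing sum equals the naive per-dose summation."""
        pk = ApapPK()
        prot = DoseProtocol("oral", 1.0, interval=6.0, n_doses=20,
                            duration=10.0)
        t = np.linspace(0.5, 200, 777)
        fast = apap_plasma_conc(t, pk, prot)
        dose_ug = 1e6
        coef = dose_ug * pk.ka / (pk.v_f * 1000 * (pk.ka - pk.ke))
        slow = np.zeros_like(t)
        for j in range(20):
            dt = t - j * 6.0
            m = dt >= 0
            slow[m] += coef * (np.exp(-pk.ke * dt[m]) - np.exp(-pk.ka * dt[m]))
        assert np.allclose(fast, slow, rtol=1e-10, atol=1e-12)


class TestProtocolValidation:
    def test_multidose_requires_interval(self):
        with pytest.raises(ExposureError):
            DoseProtocol("iv_bolus", 8.0, interval=0.0, n_doses=3)

    def test_unknown_route_rejected(self):
        with pytest.raises(ExposureError):
            DoseProtocol("intrathecal", 1.0)

    def test_nonpositive_pk_parameters_rejected(self):
        with pytest.raises(ExposureError):
            MacromoleculePK(1e5, -0.04, 0.05, 0.01, 1e-4)
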