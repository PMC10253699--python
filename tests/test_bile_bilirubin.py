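"""Bile acid network, transporter regulation, bilirubin disposition."""

import math

import numpy as np
import pytest

from hepatoqst.bile_bilirubin import (ba_secretion_readout, bile_acid_fluxes,
                                      bile_acid_toxicity, bilirubin_derivs,
                                      regulation_multiplier)
from hepatoqst.liver_core import (ConstantExposure, StateIndex,
                                  build_bile_constants, simulate)
from hepatoqst.params import (PhysiologyParams, RegulationEffect,
                              default_ggf2, derive_bilirubin_constants)
from hepatoqst.population import GGF2_CLINICAL_PROTOCOL


def baseline_ba_dict(consts):
    ba = {"unam": consts["unam0"].copy(), "unam_blood": 0.0}
    efflux = consts["k_unam_efflux"] * consts["unam0"]
    ba["unam_blood"] = efflux.sum() / consts["k_renal_unam"]
    for sp in ("cdca_am", "ca_am"):
        k = consts["species"][sp]
        ba[sp] = {"blood": k["blood0"], "hep": k["h0"].copy(),
                  "gut": k["gut0"]}
    return ba


class TestRegulationMultiplier:
    def test_no_drug_identity(self):
        eff = RegulationEffect("ntcp_uptake", "down", 0.5, 10.0)
        t = np.linspace(0, 200, 101)
        m = regulation_multiplier(lambda tt: 0.0, eff, t)
        assert np.allclose(m, 1.0)

    def test_step_reaches_indirect_response_target(self):
        eff = RegulationEffect("mrp4_basolateral", "down", 0.4, 10.0,
                               kout=0.1)
        t = np.linspace(0, 400, 801)
        m = regulation_multiplier(lambda tt: 90.0, eff, t)
        assert m[-1] == pytest.approx(eff.target(90.0), rel=1e-4)

    def test_washout_returns_exponentially_at_kout(self):
        eff = RegulationEffect("bsep_biliary", "down", 0.5, 10.0, kout=0.05)
        t = np.linspace(0, 600, 6001)
        t_off = 300.0
        m = regulation_multiplier(lambda tt: 1e6 if tt < t_off else 0.0,
                                  eff, t)
        m0 = m[t >= t_off][0]
        post = t >= t_off
        analytic = 1.0 - (1.0 - m0) * np.exp(-eff.kout * (t[post] - t_off))
        assert np.allclose(m[post], analytic, atol=1e-3)

    def test_full_down_regulation_rejected(self):
        with pytest.raises(ValueError):
            RegulationEffect("ntcp_uptake", "down", 1.0, 10.0)


class TestFluxes:
    def test_baseline_fluxes_balance(self, phys):
        consts = build_bile_constants(phys)
        ba = baseline_ba_dict(consts)
        fx = bile_acid_fluxes(ba, {}, np.ones(3), consts,
                              f_ehc=consts["f_ehc"])
        for sp in ("cdca_am", "ca_am"):
            f = fx[sp]
            hep_in = f["uptake"] + f["amidation"]
            hep_out = f["biliary"] + f["basolat"]
            assert np.allclose(hep_in, hep_out, rtol=1e-10)

    def test_ntcp_block_abolishes_uptake(self, phys):
        consts = build_bile_constants(phys)
        ba = baseline_ba_dict(consts)
        fx = bile_acid_fluxes(ba, {"ntcp_uptake": 0.0}, np.ones(3), consts,
                              f_ehc=consts["f_ehc"])
        assert np.all(fx["cdca_am"]["uptake"] == 0.0)

    @pytest.mark.parametrize("pathway,flux", [("bsep_biliary", "biliary"),
                                              ("mrp4_basolateral", "basolat")])
    def test_efflux_multiplier_halves_flux_at_fixed_substrate(self, phys,
                                                              pathway, flux):
        consts = build_bile_constants(phys)
        ba = baseline_ba_dict(consts)
        full = bile_acid_fluxes(ba, {}, np.ones(3), consts, 0.95)
        half = bile_acid_fluxes(ba, {pathway: 0.5}, np.ones(3), consts, 0.95)
        assert np.allclose(half["cdca_am"][flux],
                           0.5 * full["cdca_am"][flux], rtol=1e-12)


class TestConservation:
    def test_closed_system_mass_conserved(self):
        res = simulate(duration_days=30.0, closed_bile=True,
                       rtol=1e-9, atol=1e-12)
        pools = list(range(StateIndex.CDCA.start, StateIndex.UNAM_BLOOD + 1))
        total = res.states[:, pools].sum(axis=1)
        assert np.abs(total - total[0]).max() / total[0] < 1e-9


class TestToxicity:
    def test_near_zero_at_baseline(self, phys):
        assert bile_acid_toxicity(1.0, phys) < 0.01

    def test_strong_at_tenfold_accumulation(self, phys):
        assert bile_acid_toxicity(10.0, phys) > 0.5

    def test_monotone_nondecreasing(self, phys):
        c = np.linspace(0, 12, 100)
        sig = bile_acid_toxicity(c, phys)
        assert np.all(np.diff(sig) >= 0)


class TestSecretionReadout:
    def test_control_against_itself_is_100(self, invitro_control):
        out = ba_secretion_readout(invitro_control, invitro_control, (4, 6))
        assert out["cdca_am"] == pytest.approx(100.0)
        assert out["ca_am"] == pytest.approx(100.0)

    def test_mismatched_grids_rejected(self, invitro_control):
        short = simulate(mode="invitro", duration_days=5.0)
        with pytest.raises(ValueError):
            ba_secretion_readout(short, invitro_control, (1, 2))

    def test_ggf2_dose_response_is_monotone(self, invitro_control):
        """Higher interstitial GGF2 suppresses conjugate secretion more."""
        ggf2 = default_ggf2()
        pcts = []
        for conc in (33.6, 1066.4):
            res = simulate(drugs=[ggf2],
                           exposures={"ggf2": ConstantExposure(
                               interstitial=conc, media=0.0)},
                           mode="invitro", duration_days=10.0)
            pcts.append(ba_secretion_readout(res, invitro_control,
                                             (4, 6))["cdca_am"])
        assert pcts[1] < pcts[0] < 100.0


class TestBilirubin:
    def test_baseline_total_is_0p6(self, baseline_12wk):
        assert baseline_12wk.total_bilirubin[-1] == pytest.approx(0.6,
                                                                  abs=1e-6)

    def test_oatp_inhibition_raises_total_bilirubin(self, phys):
        bconsts = derive_bilirubin_constants(phys)
        c = phys.bilirubin
        pools = np.array([c.plasma_ub0, c.plasma_cb0, c.hepatic_ub0,
                          c.hepatic_cb0])
        d, _ = bilirubin_derivs(pools, {"oatp1b3_bilirubin_uptake": 0.5},
                                1.0, bconsts)
        assert d[0] > 0  # plasma UB rising when uptake is halved

    def test_hepatocyte_loss_alone_barely_moves_tb(self):
        """10% uniform viable loss raises TB by < 0.1 mg/dL at steady state."""
        res = simulate(injury_impulse=0.10, duration_days=84.0,
                       overrides={"k_reg": 1e-6})  # suppress regrowth
        tb = res.total_bilirubin
        assert tb.max() - 0.6 < 0.1


class TestGgf2Clinical:
    def test_all_effects_off_is_drug_free(self):
        inert = default_ggf2()
        inert = type(inert)(drug_id=inert.drug_id, pk=inert.pk,
                            partition=inert.partition, regulation=())
        res = simulate(drugs=[inert],
                       exposures={"ggf2": GGF2_CLINICAL_PROTOCOL},
                       duration_days=14.0)
        ref = np.where(res.baseline == 0, 1.0, res.baseline)
        assert np.abs((res.states[-1] - res.baseline) / ref).max() < 1e-6
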