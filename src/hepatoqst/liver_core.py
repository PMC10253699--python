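"""The composed liver ODE system: hepatocyte life cycle, ATP, injury biomarkers.

State vector (39 components):

====  =========================================================
0:3   viable hepatocyte fraction per zone (PP, MZ, CL)
3:6   ATP per zone (fraction of baseline)
6     ROS (fraction of baseline production-matched level)
7     GSH (fraction of baseline)
8     hepatic triglyceride (fraction of baseline)
9     plasma ALT (U/L)
10:12 CYP3A4, CYP2E1 activity multipliers
12:18 transporter/enzyme regulation multipliers (PATHWAYS order)
18    hepatic macrophage pool (fraction of baseline recruitment)
19:23 bilirubin: plasma UB, plasma CB, hepatic UB, hepatic CB (mg/dL)
23:28 CDCA-amidated bile acid: blood, hepatocyte (PP,MZ,CL), gut
28:33 CA-amidated bile acid: same layout
33:36 unamidated bile acid, hepatocyte per zone
36    unamidated bile acid, blood
37    free NAPQI (normalized)
38    NAPQI protein adduct (normalized)
====  =========================================================

ROS, GSH and TG are intensive (per viable hepatocyte) whole-liver pools, so
cell loss does not dilute them.  Injury couples through ATP: ROS above a
threshold, the centrilobular bile acid signal, circulating bile acid burden
and the NAPQI adduct inhibit ATP synthesis; ATP below the death threshold
drives necrosis (steep Hill in the normalized deficit), which releases ALT
and engages IL-6-modulated regeneration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import bile_bilirubin as bb
from . import il6_pathway as il6
from .apap_ddi import napqi_disposition, napqi_formation
from .exposure import (DoseProtocol, apap_plasma_conc, simulate_plasma)
from .lipid_ros import drug_ros_production, lipotox_ros, vldl_inhibition
from .params import (PATHWAYS, PhysiologyParams, DrugModel,
                     derive_bile_baseline, derive_bilirubin_constants)

__all__ = [
    "StateIndex",
    "ConstantExposure",
    "SimResult",
    "BiomarkerSummary",
    "baseline_state",
    "necrosis_rate",
    "regeneration_rate",
    "simulate",
    "summarize",
    "build_bile_constants",
]

N_STATES = 39


class StateIndex:
    VIABLE = slice(0, 3)
    ATP = slice(3, 6)
    ROS = 6
    GSH = 7
    TG = 8
    ALT = 9
    CYP3A4 = 10
    CYP2E1 = 11
    REG = slice(12, 18)
    MACROPHAGE = 18
    BILI = slice(19, 23)
    CDCA = slice(23, 28)  # blood, hep x3, gut
    CA = slice(28, 33)
    UNAM = slice(33, 36)
    UNAM_BLOOD = 36
    NAPQI = 37
    ADDUCT = 38


STATE_NAMES = (
    ["viable_pp", "viable_mz", "viable_cl", "atp_pp", "atp_mz", "atp_cl",
     "ros", "gsh", "tg", "plasma_alt", "cyp3a4", "cyp2e1"]
    + [f"reg_{p}" for p in PATHWAYS]
    + ["macrophage", "plasma_ub", "plasma_cb", "hep_ub", "hep_cb"]
    + [f"cdca_{c}" for c in ("blood", "pp", "mz", "cl", "gut")]
    + [f"ca_{c}" for c in ("blood", "pp", "mz", "cl", "gut")]
    + ["unam_pp", "unam_mz", "unam_cl", "unam_blood", "napqi", "adduct"]
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConstantExposure:
    """In-vitro-like exposure: constant media and/or interstitial concentration.

    If only ``media`` is given the interstitial concentration comes from the
    drug's partition model; a direct ``interstitial`` value overrides it.
    """

    media: float | None = None
    interstitial: float | None = None

    def resolve(self, drug: DrugModel):
        plasma = self.media if self.media is not None else 0.0
        if self.interstitial is not None:
            inter = self.interstitial
        elif self.media is not None and drug.partition is not None:
            from .exposure import interstitial_concentration
            inter = interstitial_concentration(drug.partition, self.media)
        else:
            inter = 0.0
        if plasma < 0 or inter < 0:
            raise ValueError("exposure concentrations must be >= 0")
        return float(plasma), float(inter)


def build_bile_constants(phys: PhysiologyParams) -> dict:
    """Assemble the flat bile acid constant set used by the ODE right-hand side."""
    base = derive_bile_baseline(phys)
    b = phys.bile
    sp_names = ("cdca_am", "ca_am")
    consts = {
        "Q": b.sinusoidal_flow,
        "k_gut": b.k_gut,
        "k_amid": base["k_amid"],
        "k_unam_efflux": base["k_unam_efflux"],
        "uptake_cl0": base["uptake_cl0"],
        "synthesis_unam": b.synthesis_total * np.array(phys.zone_mass),
        "k_renal_unam": 0.4,
        "species": {},
    }
    amid_frac = {"cdca_am": b.frac_cdca, "ca_am": 1.0 - b.frac_cdca}
    for sp in sp_names:
        k = base["species"][sp]
        consts["species"][sp] = {
            "h0": k["h0"], "vmax_bil": k["vmax_bil"], "km_bil": k["km_bil"],
            "k_basol": k["k_basol"], "k_renal": k["k_renal"],
            "blood0": k["blood0"], "gut0": k["gut0"],
            "amid_frac": amid_frac[sp],
        }
    # whole unamidated pool baseline: synthesis/turnover
    consts["unam0"] = b.synthesis_total * np.array(phys.zone_mass) / b.unam_turnover
    consts["f_ehc"] = b.f_ehc
    return consts


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

def necrosis_rate(atp, viable, phys: PhysiologyParams, mac_amp=1.0):
    """Per-zone fractional necrosis rate from the normalized ATP deficit.

    rate = k_nec · viable · Hill(deficit), deficit = max(0, 1 − ATP/threshold);
    zero whenever ATP ≥ threshold, saturating toward k_nec·viable at ATP → 0.
    """
    atp = np.asarray(atp, dtype=float)
    d = np.maximum(0.0, 1.0 - atp / phys.atp_death_threshold)
    dn = d ** phys.nec_hill_n
    hill = dn / (dn + phys.nec_hill_d50 ** phys.nec_hill_n)
    return phys.k_nec * np.asarray(viable) * hill * mac_amp


def regeneration_rate(viable, phys: PhysiologyParams, il6_regen_mult=1.0):
    """Per-zone regeneration: proportional to whole-liver deficit and IL-6 tone."""
    viable = np.asarray(viable, dtype=float)
    deficit = max(0.0, 1.0 - float(np.dot(phys.zone_mass, viable)))
    return phys.k_reg * deficit * il6_regen_mult * viable


# ---------------------------------------------------------------------------
# Baseline construction
# ---------------------------------------------------------------------------

def _context_il6(phys: PhysiologyParams, context) -> float:
    if context == "healthy":
        return phys.il6.il6_healthy
    if context == "elevated":
        return phys.il6.il6_elevated
    return float(context)


def baseline_state(phys: PhysiologyParams, context="healthy",
                   consts: dict | None = None,
                   bconsts: dict | None = None) -> np.ndarray:
    """Drug-free steady state for the given IL-6 context.

    Built by construction: the bile acid, bilirubin and biomarker constants
    are derived from their baselines, and the remaining fixed points (ATP,
    ROS, CYP, macrophage) have closed forms.  The residual of the drug-free
    right-hand side at the returned state is verified to be < 1e-8.
    """
    consts = consts or build_bile_constants(phys)
    bconsts = bconsts or derive_bilirubin_constants(phys)
    s = _context_il6(phys, context)
    y = np.zeros(N_STATES)
    y[StateIndex.VIABLE] = 1.0
    gsh0 = phys.gsh_baseline
    phi = np.clip(gsh0 / phys.gsh_clear_knee, phys.gsh_clear_floor, 1.0)
    ros0 = 1.0 / phi
    y[StateIndex.ROS] = ros0
    y[StateIndex.GSH] = gsh0
    y[StateIndex.TG] = 1.0
    y[StateIndex.ALT] = phys.alt_baseline
    cyp0 = il6.cyp_target(s, phys.il6)
    y[StateIndex.CYP3A4] = cyp0
    y[StateIndex.CYP2E1] = cyp0
    y[StateIndex.REG] = 1.0
    y[StateIndex.MACROPHAGE] = il6.macrophage_target(s, 0.0, phys.il6)
    c = phys.bilirubin
    y[StateIndex.BILI] = [c.plasma_ub0, c.plasma_cb0, c.hepatic_ub0,
                          c.hepatic_cb0]
    for sp, sl in (("cdca_am", StateIndex.CDCA), ("ca_am", StateIndex.CA)):
        k = consts["species"][sp]
        y[sl] = np.concatenate([[k["blood0"]], k["h0"], [k["gut0"]]])
    y[StateIndex.UNAM] = consts["unam0"]
    # blood unamidated: efflux in, renal clearance out
    efflux = consts["k_unam_efflux"] * consts["unam0"]
    y[StateIndex.UNAM_BLOOD] = efflux.sum() / consts["k_renal_unam"]
    # ATP fixed point under baseline signals
    ba_sig = bb.bile_acid_toxicity(1.0, phys)
    x_base = phys.mito_sensitivity * (
        phys.ros_damage_gain * max(0.0, ros0 - phys.ros_atp_threshold)
        + phys.ba_tox_gain * 0.0)
    x = np.full(3, x_base)
    x[2] += phys.mito_sensitivity * phys.ba_tox_gain * ba_sig
    y[StateIndex.ATP] = 1.0 / (1.0 + x)
    leak0 = phys.alt_leak_gain * np.maximum(0.0, 1.0 - y[StateIndex.ATP]) ** 2
    y[StateIndex.ALT] = (phys.alt_baseline
                         + phys.alt_release * float(np.dot(phys.zone_mass, leak0))
                         / phys.alt_kout)
    # necrosis at baseline must be zero for ALT to hold near its baseline
    if np.any(y[StateIndex.ATP] < phys.atp_death_threshold):
        raise SimulationError("no drug-free steady state: baseline ATP below "
                              "the death threshold (check susceptibility "
                              "multipliers)")
    return y


# ---------------------------------------------------------------------------
# Exposure resolution
# ---------------------------------------------------------------------------

def _build_exposure_fns(drugs, exposures, duration_h, mode):
    """Return per-drug (plasma_fn, interstitial_fn) closures."""
    fns = {}
    for drug in drugs:
        exp = exposures.get(drug.drug_id)
        if exp is None:
            fns[drug.drug_id] = (lambda t: 0.0, lambda t: 0.0)
            continue
        if isinstance(exp, ConstantExposure):
            plasma, inter = exp.resolve(drug)
            fns[drug.drug_id] = ((lambda t, p=plasma: p),
                                 (lambda t, i=inter: i))
        elif isinstance(exp, DoseProtocol):
            if drug.apap is not None:
                pk = drug.apap.pk
                fns[drug.drug_id] = (
                    (lambda t, pk=pk, pr=exp: apap_plasma_conc(t, pk, pr)),
                    (lambda t, pk=pk, pr=exp:
                     apap_plasma_conc(t, pk, pr) * pk.liver_plasma_ratio))
            else:
                grid = np.arange(0.0, duration_h + 0.5, 0.5)
                prof = simulate_plasma(drug.pk, exp, grid,
                                       partition=drug.partition,
                                       drug_id=drug.drug_id)
                tt, pp, ii = prof.times, prof.plasma, prof.interstitial
                fns[drug.drug_id] = (
                    (lambda t, tt=tt, pp=pp: float(np.interp(t, tt, pp))),
                    (lambda t, tt=tt, ii=ii: float(np.interp(t, tt, ii))))
        else:
            raise TypeError(f"unsupported exposure spec for {drug.drug_id!r}")
    return fns


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Dense simulation output plus the pieces needed for readouts."""

    times: np.ndarray  # h
    states: np.ndarray  # (n_times, N_STATES)
    phys: PhysiologyParams
    baseline: np.ndarray
    context: str
    mode: str
    consts: dict = field(repr=False, default=None)
    bconsts: dict = field(repr=False, default=None)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def alt(self) -> np.ndarray:
        return self[ "plasma_alt"]

    @property
    def total_bilirubin(self) -> np.ndarray:
        return self["plasma_ub"] + self["plasma_cb"]

    @property
    def viable_total(self) -> np.ndarray:
        mf = np.array(self.phys.zone_mass)
        return self.states[:, StateIndex.VIABLE] @ mf

    @property
    def atp_min_zone(self) -> np.ndarray:
        return self.states[:, StateIndex.ATP].min(axis=1)

    @property
    def secretion_flux(self) -> dict:
        """Biliary + basolateral amidated efflux per species over time."""
        out = {}
        viable = self.states[:, StateIndex.VIABLE]
        regs = self.states[:, StateIndex.REG]
        mult_names = list(PATHWAYS)
        for sp, sl in (("cdca_am", StateIndex.CDCA), ("ca_am", StateIndex.CA)):
            k = self.consts["species"][sp]
            hep = self.states[:, sl][:, 1:4]
            c_rel = hep / k["h0"]
            m_bsep = regs[:, mult_names.index("bsep_biliary")][:, None]
            m_mrp4 = regs[:, mult_names.index("mrp4_basolateral")][:, None]
            biliary = (m_bsep * viable * k["vmax_bil"] * c_rel
                       / (k["km_bil"] + c_rel)).sum(axis=1)
            basolat = (m_mrp4 * viable * k["k_basol"] * c_rel).sum(axis=1)
            out[sp] = biliary + basolat
        return out

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df["total_bilirubin"] = self.total_bilirubin
        df["viable_total"] = self.viable_total
        return df


@dataclass(frozen=True)
class BiomarkerSummary:
    peak_alt: float  # U/L
    alt_uln_category: str  # <1x | 1-3x | 3-5x | >5x
    peak_tb: float  # mg/dL
    min_atp: float  # fraction of baseline (worst zone)
    min_viable: float  # whole-liver viable fraction
    steatosis_pct: float  # % of control at readout day
    ros_pct: float  # % of control at readout day
    time_to_recovery: float  # days to regain 90% viable (nan if n/a)


def _uln_category(peak_alt: float, uln: float) -> str:
    ratio = peak_alt / uln
    if ratio <= 1.0:
        return "<1x"
    if ratio <= 3.0:
        return "1-3x"
    if ratio <= 5.0:
        return "3-5x"
    return ">5x"


def summarize(result: SimResult, control: SimResult | None = None,
              readout_day: float | None = None) -> BiomarkerSummary:
    """Reduce a simulation to its biomarker summary.

    ``control`` (a drug-free run on the same grid) normalizes the steatosis
    and ROS percent-of-control readouts; without it the drug-free baseline
    values serve as the reference.  ``readout_day`` defaults to the final
    timepoint.
    """
    if result.times.size == 0:
        raise ValueError("empty simulation result")
    t = result.times
    idx = (t.size - 1 if readout_day is None
           else int(np.argmin(np.abs(t - readout_day * 24.0))))
    if control is not None:
        tg_ref = control["tg"][idx]
        ros_ref = control["ros"][idx]
    else:
        tg_ref = result.baseline[StateIndex.TG]
        ros_ref = result.baseline[StateIndex.ROS]
    viable = result.viable_total
    peak_alt = float(result.alt.max())
    imin = int(np.argmin(viable))
    t_rec = math.nan
    if viable[imin] < result.phys.recovery_target:
        after = np.nonzero(viable[imin:] >= result.phys.recovery_target)[0]
        if after.size:
            j = imin + after[0]
            # linear interpolation of the crossing
            t0, t1 = t[j - 1], t[j]
            v0, v1 = viable[j - 1], viable[j]
            frac = (result.phys.recovery_target - v0) / (v1 - v0)
            t_rec = (t0 + frac * (t1 - t0)) / 24.0
    return BiomarkerSummary(
        peak_alt=peak_alt,
        alt_uln_category=_uln_category(peak_alt, result.phys.alt_uln),
        peak_tb=float(result.total_bilirubin.max()),
        min_atp=float(result.atp_min_zone.min()),
        min_viable=float(viable.min()),
        steatosis_pct=float(100.0 * result["tg"][idx] / tg_ref),
        ros_pct=float(100.0 * result["ros"][idx] / ros_ref),
        time_to_recovery=t_rec,
    )


def simulate(drugs=(), exposures=None, phys: PhysiologyParams | None = None,
             context="healthy", mode="clinical", duration_days=84.0,
             overrides=None, injury_impulse=0.0, closed_bile=False,
             grid_dt=1.0, rtol=1e-8, atol=1e-10, method="LSODA",
             y0=None) -> SimResult:
    """Integrate the composed liver model.

    Parameters
    ----------
    drugs : sequence of DrugModel
    exposures : dict drug_id -> DoseProtocol | ConstantExposure
    context : "healthy" | "elevated" | IL-6 level in ng/mL
    mode : "clinical" (enterohepatic recirculation on) | "invitro"
        (flow-through: blood bile acid pools clamped, no recirculation)
    overrides : susceptibility multipliers, see
        :meth:`PhysiologyParams.with_overrides`
    injury_impulse : fraction of hepatocytes removed at t=0 (uniformly
        across zones), for impulse-response studies
    closed_bile : freeze bile acid synthesis and losses (conservation runs)
    """
    phys = (phys or PhysiologyParams()).with_overrides(overrides or {})
    if mode not in ("clinical", "invitro"):
        raise ValueError("mode must be 'clinical' or 'invitro'")
    exposures = exposures or {}
    unknown = set(exposures) - {d.drug_id for d in drugs}
    if unknown:
        raise ValueError(f"exposures given for unknown drugs: {sorted(unknown)}")
    duration_h = duration_days * 24.0
    consts = build_bile_constants(phys)
    bconsts = derive_bilirubin_constants(phys)
    y_base = baseline_state(phys, context, consts, bconsts) if y0 is None else y0
    y_init = y_base.copy()
    if injury_impulse:
        if not 0 <= injury_impulse < 1:
            raise ValueError("injury_impulse must be a fraction in [0, 1)")
        y_init[StateIndex.VIABLE] *= (1.0 - injury_impulse)
        # the lost hepatocytes release their ALT content instantaneously
        y_init[StateIndex.ALT] += phys.alt_release * injury_impulse

    fns = _build_exposure_fns(drugs, exposures, duration_h, mode)
    s_ctx = _context_il6(phys, context)
    mac0 = float(y_base[StateIndex.MACROPHAGE])
    invitro = mode == "invitro"
    f_ehc = 0.0 if invitro else consts["f_ehc"]

    tcz = next((d for d in drugs if d.blocks_il6), None)
    ggf2 = next((d for d in drugs if d.regulation), None)
    apap = next((d for d in drugs if d.apap is not None), None)
    intrinsic = [d for d in drugs
                 if d.intrinsic_effects and (d.steatosis or d.ros)]

    reg_effects = []
    if ggf2 is not None:
        for e in ggf2.regulation:
            reg_effects.append((PATHWAYS.index(e.pathway), e))
    reg_default_kout = math.log(2) / 24.0

    # unpack constants for the flat RHS
    sp_keys = ("cdca_am", "ca_am")
    H0 = np.stack([consts["species"][s]["h0"] for s in sp_keys])
    VMAX = np.stack([consts["species"][s]["vmax_bil"] for s in sp_keys])
    KM = np.stack([consts["species"][s]["km_bil"] for s in sp_keys])
    KBL = np.stack([consts["species"][s]["k_basol"] for s in sp_keys])
    KREN = np.array([consts["species"][s]["k_renal"] for s in sp_keys])
    AMFR = np.array([consts["species"][s]["amid_frac"] for s in sp_keys])
    BLOOD0 = np.array([consts["species"][s]["blood0"] for s in sp_keys])
    CLU0 = consts["uptake_cl0"]
    Q = consts["Q"]
    SYN_U = consts["synthesis_unam"]
    K_AM, K_UE = consts["k_amid"], consts["k_unam_efflux"]
    K_GUT = consts["k_gut"]
    K_REN_U = consts["k_renal_unam"]
    mf = np.array(phys.zone_mass)
    ilp = phys.il6
    blood0_tot = BLOOD0.sum()
    sl_sp = (StateIndex.CDCA, StateIndex.CA)

    tcz_fns = fns.get(tcz.drug_id) if tcz else None
    ggf2_fns = fns.get(ggf2.drug_id) if ggf2 else None
    apap_fns = fns.get(apap.drug_id) if apap else None
    intr_fns = {d.drug_id: fns[d.drug_id] for d in intrinsic}

    def rhs(t, y):
        viable = y[0:3]
        atp = y[3:6]
        ros, gsh, tg, alt = y[6], y[7], y[8], y[9]
        cyp3a4, cyp2e1 = y[10], y[11]
        regs = y[12:18]
        mac = y[18]
        bili = y[19:23]
        napqi, adduct = y[37], y[38]
        dy = np.zeros(N_STATES)

        # --- IL-6 axis ---
        if tcz is not None and tcz.il6_effects:
            s_eff = il6.effective_il6(s_ctx, max(tcz_fns[0](t), 0.0), ilp)
        else:
            s_eff = s_ctx
        cyp_tgt = il6.cyp_target(s_eff, ilp)
        dy[10] = ilp.cyp_kout * (cyp_tgt - cyp3a4)
        dy[11] = ilp.cyp_kout * (cyp_tgt - cyp2e1)
        regen_mult = il6.regen_multiplier(s_eff, ilp)

        # --- intrinsic (steatosis / ROS) drug effects ---
        inhib = 0.0
        p_drug = 0.0
        for d in intrinsic:
            c_int = max(intr_fns[d.drug_id][1](t), 0.0)
            if d.steatosis is not None:
                inhib = 1.0 - (1.0 - inhib) * (1.0 - vldl_inhibition(c_int, d.steatosis))
            if d.ros is not None:
                p_drug += drug_ros_production(c_int, d.ros)
        k_tg = (intrinsic[0].steatosis.k_tg if intrinsic and
                intrinsic[0].steatosis is not None else math.log(2) / 12.0)
        dy[8] = k_tg * (1.0 - (1.0 - inhib) * tg)

        # --- regulation multipliers ---
        c_ggf2 = max(ggf2_fns[1](t), 0.0) if ggf2 is not None else 0.0
        tgt = np.ones(6)
        kouts = np.full(6, reg_default_kout)
        for i, e in reg_effects:
            tgt[i] = e.target(c_ggf2)
            kouts[i] = e.kout
        dy[12:18] = kouts * (tgt - regs)
        m_ntcp, m_mrp4, m_bsep, m_amid, m_oatp, m_mrp3 = regs

        # --- bile acids (vectorized over the two amidated species) ---
        blood = y[[23, 28]]
        hep = np.stack([y[24:27], y[29:32]])
        gut = y[[27, 32]]
        unam = y[33:36]
        cl = CLU0 * m_ntcp * viable
        e_z = cl / (Q + cl)
        remain = np.concatenate([[1.0], np.cumprod(1.0 - e_z)[:2]])
        uptake = Q * blood[:, None] * (e_z * remain)[None, :]
        c_rel = hep / H0
        biliary = m_bsep * viable * VMAX * c_rel / (KM + c_rel)
        basolat = m_mrp4 * viable * KBL * c_rel
        amid = K_AM * m_amid * unam[None, :] * AMFR[:, None]
        gut_out = K_GUT * gut
        synth = 0.0 if closed_bile else 1.0
        if invitro:
            d_blood = np.zeros(2)
            ehc = np.zeros(2)
            renal = np.zeros(2)
        else:
            ehc = (gut_out if closed_bile else f_ehc * gut_out)
            renal = np.zeros(2) if closed_bile else KREN * blood
            d_blood = basolat.sum(axis=1) + ehc - uptake.sum(axis=1) - renal
        d_hep = uptake + amid - biliary - basolat
        d_gut = biliary.sum(axis=1) - gut_out
        for i, sl in enumerate(sl_sp):
            dy[sl.start] = d_blood[i]
            dy[sl.start + 1:sl.start + 4] = d_hep[i]
            dy[sl.start + 4] = d_gut[i]
        unam_efflux = K_UE * unam * viable
        dy[33:36] = synth * SYN_U - K_AM * m_amid * unam - unam_efflux
        if invitro:
            dy[36] = 0.0
        else:
            dy[36] = unam_efflux.sum() - (0.0 if closed_bile
                                          else K_REN_U * y[36])

        # --- NAPQI ---
        conj = 0.0
        if apap is not None:
            ap = apap.apap
            c_liver = max(apap_fns[1](t), 0.0)
            form = napqi_formation(c_liver, max(cyp2e1, 0.0),
                                   max(cyp3a4, 0.0), ap)
            fx = napqi_disposition(max(napqi, 0.0), max(gsh, 0.0), ap)
            conj = fx["conjugation"]
            dy[37] = form - conj - fx["other"] - fx["adduct_formation"]
            dy[38] = fx["adduct_formation"] - ap.k_adduct_clear * adduct
            p_napqi = fx["ros_production"]
            adduct_x = ap.adduct_atp_gain * adduct
        else:
            p_napqi = 0.0
            adduct_x = 0.0

        # --- ROS / GSH (intensive pools) ---
        p_tot = 1.0 + p_drug + lipotox_ros(max(tg, 0.0), intrinsic[0].ros) \
            if (intrinsic and intrinsic[0].ros is not None) else 1.0 + p_drug
        p_tot += p_napqi
        phi = min(max(gsh / phys.gsh_clear_knee, phys.gsh_clear_floor), 1.0)
        dy[6] = phys.k_ros_clear * (p_tot - phi * ros)
        dy[7] = (phys.k_gsh_syn * (phys.gsh_baseline - gsh)
                 - phys.k_gsh_ros * max(0.0, ros - phys.ros_gsh_threshold) * gsh
                 - (apap.apap.gsh_per_conj if apap is not None else 0.0) * conj)

        # --- ATP ---
        ba_sig = bb.bile_acid_toxicity(c_rel[0, 2], phys)
        blood_excess = max(0.0, blood.sum() / blood0_tot - 1.0)
        x_common = (phys.ros_damage_gain * max(0.0, ros - phys.ros_atp_threshold)
                    + adduct_x + phys.blood_ba_gain * blood_excess)
        x = np.full(3, x_common)
        x[2] += phys.ba_tox_gain * ba_sig
        f_syn = 1.0 / (1.0 + phys.mito_sensitivity * x)
        dy[3:6] = phys.k_atp * (f_syn - atp)

        # --- necrosis / regeneration / ALT ---
        mac_amp = 1.0 + ilp.mac_injury_gain * max(0.0, mac - mac0)
        nec = necrosis_rate(atp, viable, phys, mac_amp)
        reg = regeneration_rate(viable, phys, regen_mult)
        dy[0:3] = reg - nec
        nec_flux = float(mf @ nec)
        # sub-lethal ALT leak: membrane permeability grows with ATP deficit
        leak = phys.alt_leak_gain * viable * np.maximum(0.0, 1.0 - atp) ** 2
        release_flux = nec_flux + float(mf @ leak)
        dy[9] = (phys.alt_kin + phys.alt_release * release_flux
                 - phys.alt_kout * alt)
        dy[18] = ilp.mac_kout * (il6.macrophage_target(s_eff, nec_flux, ilp)
                                 - mac)

        # --- bilirubin ---
        viable_tot = float(mf @ viable)
        mult = {"oatp1b3_bilirubin_uptake": m_oatp,
                "mrp3_bilirubin_basolateral": m_mrp3}
        d_bili, _ = bb.bilirubin_derivs(bili, mult, viable_tot, bconsts)
        dy[19:23] = d_bili
        return dy

    t_eval = np.arange(0.0, duration_h + 0.5 * grid_dt, grid_dt)
    sol = solve_ivp(rhs, (0.0, duration_h), y_init, t_eval=t_eval,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(
            f"liver integration failed at t={sol.t[-1] if sol.t.size else 0:.1f} h: "
            f"{sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("non-finite state encountered during integration")
    return SimResult(times=sol.t, states=sol.y.T, phys=phys, baseline=y_base,
                     context=str(context), mode=mode, consts=consts,
                     bconsts=bconsts)
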