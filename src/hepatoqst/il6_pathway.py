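"""IL-6 / soluble-IL-6-receptor / tocilizumab interactions and downstream effects.

Tocilizumab binds both soluble and membrane-bound IL-6 receptor.  Competitive
binding of IL-6 and tocilizumab to the soluble receptor is solved as a
mass-action equilibrium.  Signaling through the membrane-bound receptor is
summarized by an "effective" IL-6 pool — the free IL-6 concentration scaled
by the fraction of membrane receptor not occupied by drug — which drives
three indirect responses relevant to hepatocyte health: suppression of
CYP3A4/CYP2E1 expression, stimulation of hepatocyte regeneration, and
macrophage recruitment.  The tocilizumab–sIL-6R complex is assumed
signaling-incapable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Il6Params",
    "equilibrium_binding",
    "effective_il6",
    "cyp_target",
    "regen_multiplier",
    "macrophage_target",
    "ug_per_ml_to_nm",
    "nm_to_ug_per_ml",
]

TCZ_MOLAR_MASS = 145_000.0  # g/mol (1.6 µM = 232 µg/mL, 5 µM = 725 µg/mL)
IL6_MOLAR_MASS = 21_000.0  # g/mol


def ug_per_ml_to_nm(conc_ug_ml: float, molar_mass: float = TCZ_MOLAR_MASS) -> float:
    """µg/mL → nM.  (µg/mL = mg/L; /(g/mol) = mmol/L·1e-3 = µM → ×1e3 nM.)"""
    return conc_ug_ml / molar_mass * 1e6


def nm_to_ug_per_ml(conc_nm: float, molar_mass: float = TCZ_MOLAR_MASS) -> float:
    return conc_nm * molar_mass / 1e6


@dataclass(frozen=True)
class Il6Params:
    """IL-6 axis parameters.

    ``il6_healthy`` (0.005 ng/mL) and ``il6_elevated`` (10 ng/mL, a proxy for
    the pro-inflammatory rheumatoid-arthritis setting) are design values.
    ``ic50_memb_ug_ml`` is the tocilizumab concentration half-blocking
    membrane-receptor signaling, derived from the default drug–receptor Kd
    (2.9 nM ≈ 0.42 µg/mL).
    """

    kd_il6_sil6r: float = 0.5  # nM
    kd_tcz_il6r: float = 2.9  # nM
    il6_healthy: float = 0.005  # ng/mL
    il6_elevated: float = 10.0  # ng/mL
    ic50_memb_ug_ml: float = nm_to_ug_per_ml(2.9)  # ≈ 0.42 µg/mL
    cyp_imax: float = 0.6
    cyp_sc50: float = 1.0  # ng/mL effective IL-6
    cyp_kout: float = np.log(2) / 36.0  # 1/h, enzyme turnover
    regen_emax: float = 1.0
    regen_ec50: float = 1.0  # ng/mL
    mac_emax: float = 1.0
    mac_ec50: float = 2.0  # ng/mL
    mac_kout: float = np.log(2) / 48.0  # 1/h
    mac_injury_gain: float = 0.1  # ≤10% modulation of injury

    def __post_init__(self) -> None:
        if self.kd_il6_sil6r <= 0 or self.kd_tcz_il6r <= 0:
            raise ValueError("Kd values must be positive")
        if not 0 <= self.cyp_imax < 1:
            raise ValueError("cyp_imax must be in [0, 1)")


def equilibrium_binding(il6_nm: float, sil6r_total_nm: float, tcz_nm: float,
                        params: Il6Params, tol: float = 1e-12):
    """Competitive two-ligand binding equilibrium on the soluble receptor.

    IL-6 and tocilizumab compete for sIL-6R.  Solves the free-receptor
    concentration R from
    ``R_t = R + L1_t·R/(Kd1+R) + L2_t·R/(Kd2+R)`` (monotone in R, bracketed
    bisection via brentq), then back-substitutes the free ligands.

    Returns a dict with free/complex species (nM); ``complex`` is the
    signaling-relevant IL-6·sIL-6R complex.
    """
    if min(il6_nm, sil6r_total_nm, tcz_nm) < 0:
        raise ValueError("binding inputs must be >= 0")
    kd1, kd2 = params.kd_il6_sil6r, params.kd_tcz_il6r
    rt = sil6r_total_nm
    if rt == 0:
        return {"complex": 0.0, "free_il6": il6_nm, "free_tcz": tcz_nm,
                "free_sil6r": 0.0, "tcz_complex": 0.0}

    def excess(r):
        return r + il6_nm * r / (kd1 + r) + tcz_nm * r / (kd2 + r) - rt

    r = brentq(excess, 0.0, rt, xtol=tol * max(rt, 1.0), rtol=8.9e-16,
               maxiter=500)
    c_il6 = il6_nm * r / (kd1 + r)
    c_tcz = tcz_nm * r / (kd2 + r)
    return {
        "complex": c_il6,
        "tcz_complex": c_tcz,
        "free_sil6r": r,
        "free_il6": il6_nm - c_il6,
        "free_tcz": tcz_nm - c_tcz,
    }


def effective_il6(il6_ng_ml, tcz_ug_ml, params: Il6Params):
    """Effective IL-6 (ng/mL): free IL-6 scaled by unblocked membrane receptor.

    effective = IL-6 · (1 − C_tcz/(C_tcz + IC50)); tocilizumab occupancy of
    the membrane-bound receptor mimics loss of classic IL-6 signaling.
    """
    il6 = np.asarray(il6_ng_ml, dtype=float)
    tcz = np.asarray(tcz_ug_ml, dtype=float)
    if np.any(il6 < 0) or np.any(tcz < 0):
        raise ValueError("concentrations must be >= 0")
    out = il6 * (1.0 - tcz / (tcz + params.ic50_memb_ug_ml))
    return float(out) if out.ndim == 0 else out


def cyp_target(eff_il6, params: Il6Params):
    """Indirect-response target for CYP3A4/2E1 activity multipliers.

    target = 1 − Imax·S/(SC50+S); the activity state relaxes toward it with
    rate ``cyp_kout``.
    """
    s = np.asarray(eff_il6, dtype=float)
    out = 1.0 - params.cyp_imax * s / (params.cyp_sc50 + s)
    return float(out) if out.ndim == 0 else out


def _regen_raw(s, params: Il6Params):
    return 1.0 + params.regen_emax * s / (params.regen_ec50 + s)


def regen_multiplier(eff_il6, params: Il6Params):
    """Hepatocyte-regeneration multiplier, normalized to 1 at healthy IL-6.

    Below-baseline effective IL-6 (receptor blockade) slows regeneration;
    elevated IL-6 accelerates it.
    """
    s = np.asarray(eff_il6, dtype=float)
    out = _regen_raw(s, params) / _regen_raw(params.il6_healthy, params)
    return float(out) if out.ndim == 0 else out


def macrophage_target(eff_il6, injury_signal, params: Il6Params):
    """Indirect-response target for the hepatic macrophage pool.

    Stimulated by effective IL-6 and by ongoing injury (fractional necrosis
    rate); the pool feeds a small (≤ ``mac_injury_gain``) amplification of
    injury back into the liver model.
    """
    s = np.asarray(eff_il6, dtype=float)
    inj = np.asarray(injury_signal, dtype=float)
    out = 1.0 + params.mac_emax * s / (params.mac_ec50 + s) + np.minimum(
        10.0 * np.maximum(inj, 0.0), 1.0)
    return float(out) if out.ndim == 0 else out
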