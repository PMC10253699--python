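"""Zonated bile acid homeostasis, transporter regulation, and bilirubin disposition.

Two amidated bile acid species (CDCA-amidated ↔ measured GCDCA, CA-amidated
↔ TCA) circulate between blood, three hepatocyte zones in sinusoidal series
(PP→MZ→CL), and a gut pool that recirculates enterohepatically in clinical
mode or washes out in the in-vitro-like (perfused chip) mode.  A lumped
unamidated pool is synthesized in hepatocytes and either amidated or
exported basolaterally.  Biliary (BSEP) export is saturable and runs close
to capacity — deepest in the centrilobular zone — so basolateral (MRP4)
export acts as the overflow valve; when it is down-regulated, centrilobular
CDCA-amidated concentrations rise steeply and inhibit ATP synthesis there.

Bilirubin is handled whole-liver: production → plasma unconjugated →
OATP1B3 uptake → conjugation → MRP2 biliary export (fixed) or MRP3
basolateral export to plasma conjugated bilirubin, which is cleared and
partially re-taken up.  Drug effects enter as indirect-response multipliers
on the named transport/enzyme steps.
"""

from __future__ import annotations

import numpy as np

from .params import (PATHWAYS, PhysiologyParams, RegulationEffect,
                     derive_bilirubin_constants)

__all__ = [
    "regulation_multiplier",
    "bile_acid_fluxes",
    "bile_acid_derivs",
    "bilirubin_fluxes",
    "bile_acid_toxicity",
    "ba_secretion_readout",
]

AMIDATED = ("cdca_am", "ca_am")


def regulation_multiplier(c_int_fn, effect: RegulationEffect, t_grid):
    """Indirect-response multiplier time course under an interstitial profile.

    Integrates dm/dt = kout·(m_target(C(t)) − m) from m(0)=1 on ``t_grid``
    (closed-form exponential update per step, exact for piecewise-constant
    C).  Standalone utility; inside full simulations the same states are
    carried by the composed ODE system.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    m = np.empty_like(t_grid)
    m[0] = 1.0
    for i in range(1, t_grid.size):
        dt = t_grid[i] - t_grid[i - 1]
        c = max(0.0, float(c_int_fn(0.5 * (t_grid[i] + t_grid[i - 1]))))
        tgt = effect.target(c)
        m[i] = tgt + (m[i - 1] - tgt) * np.exp(-effect.kout * dt)
    return m


def bile_acid_fluxes(ba, mult, viable, consts, f_ehc, invitro=False):
    """Compute all bile acid fluxes for one state.

    ``ba`` is a dict: per amidated species {"blood", "hep" (3,), "gut"},
    plus {"unam" (3,), "unam_blood"}.  ``mult`` maps pathway → multiplier.
    Returns a nested flux dict (amounts/h); uptake follows the serial
    sinusoidal extraction cascade, so downstream zones see what upstream
    zones leave behind.
    """
    Q = consts["Q"]
    m_ntcp = mult.get("ntcp_uptake", 1.0)
    m_bsep = mult.get("bsep_biliary", 1.0)
    m_mrp4 = mult.get("mrp4_basolateral", 1.0)
    m_amid = mult.get("amidation", 1.0)
    out = {}
    for sp in AMIDATED:
        k = consts["species"][sp]
        blood = ba[sp]["blood"]
        hep = ba[sp]["hep"]
        gut = ba[sp]["gut"]
        # serial extraction: per-zone clearance scaled by NTCP and viability
        cl = consts["uptake_cl0"] * m_ntcp * viable
        c_in = blood  # blood volume 1 -> conc = amount
        uptake = np.empty(3)
        for z in range(3):
            e = cl[z] / (Q + cl[z])
            uptake[z] = Q * c_in * e
            c_in = c_in * (1 - e)
        c_rel = hep / k["h0"]  # relative hepatic concentration
        biliary = (m_bsep * viable * k["vmax_bil"] * c_rel
                   / (k["km_bil"] + c_rel))
        basolat = m_mrp4 * viable * k["k_basol"] * c_rel
        amid = consts["k_amid"] * m_amid * ba["unam"] * k["amid_frac"]
        gut_out = consts["k_gut"] * gut
        out[sp] = {
            "uptake": uptake, "biliary": biliary, "basolat": basolat,
            "amidation": amid, "gut_out": gut_out,
            "ehc_return": (0.0 if invitro else f_ehc * gut_out),
            "renal": 0.0 if invitro else k["k_renal"] * blood,
        }
    out["unam"] = {
        "synthesis": consts["synthesis_unam"],
        "amidation_total": consts["k_amid"] * m_amid * ba["unam"],
        "efflux": consts["k_unam_efflux"] * ba["unam"] * viable,
        "blood_renal": 0.0 if invitro else consts["k_renal_unam"] * ba["unam_blood"],
    }
    return out


def bile_acid_derivs(ba, mult, viable, consts, f_ehc, invitro=False,
                     closed=False):
    """Time derivatives of the bile acid pools (same layout as ``ba``).

    ``closed`` freezes synthesis and all loss routes (renal, fecal) for
    mass-conservation analyses.  In in-vitro mode blood pools are clamped
    (fresh media at constant composition) and effluxes leave the system.
    """
    fx = bile_acid_fluxes(ba, mult, viable, consts, f_ehc, invitro)
    d = {}
    for sp in AMIDATED:
        f = fx[sp]
        up_tot = f["uptake"].sum()
        if invitro:
            d_blood = 0.0
        else:
            d_blood = f["basolat"].sum() + f["ehc_return"] - up_tot - f["renal"]
            if closed:
                d_blood = f["basolat"].sum() + f["gut_out"] - up_tot
        d_hep = f["uptake"] + f["amidation"] - f["biliary"] - f["basolat"]
        d_gut = f["biliary"].sum() - f["gut_out"]
        d[sp] = {"blood": d_blood, "hep": d_hep, "gut": d_gut}
    u = fx["unam"]
    synth = 0.0 if closed else u["synthesis"]
    d["unam"] = synth - u["amidation_total"] - u["efflux"]
    if invitro:
        d["unam_blood"] = 0.0
    else:
        d["unam_blood"] = u["efflux"].sum() - (0.0 if closed else u["blood_renal"])
    return d, fx


def bile_acid_toxicity(c_rel_cl_cdca, phys: PhysiologyParams):
    """ATP-synthesis inhibition signal from centrilobular CDCA-amidated load.

    Hill response on the CL-zone concentration relative to baseline; near
    zero at baseline, saturating toward 1 at severalfold accumulation.
    """
    c = np.maximum(np.asarray(c_rel_cl_cdca, dtype=float), 0.0)
    x = (c / phys.ba_tox_ec50) ** phys.ba_tox_n
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def bilirubin_fluxes(pools, mult, viable_total, consts):
    """Bilirubin fluxes. ``pools`` = (plasma_ub, plasma_cb, hep_ub, hep_cb)."""
    p_ub, p_cb, h_ub, h_cb = pools
    m_oatp = mult.get("oatp1b3_bilirubin_uptake", 1.0)
    m_mrp3 = mult.get("mrp3_bilirubin_basolateral", 1.0)
    up_ub = consts["k_up_ub"] * m_oatp * viable_total * p_ub
    up_cb = consts["k_up_cb"] * m_oatp * viable_total * p_cb
    conj = consts["k_conj"] * viable_total * h_ub
    biliary = consts["k_mrp2"] * viable_total * h_cb
    basolat = consts["k_mrp3"] * m_mrp3 * viable_total * h_cb
    clear = consts["k_clear_cb"] * p_cb
    return {"production": consts["production"], "uptake_ub": up_ub,
            "uptake_cb": up_cb, "conjugation": conj, "biliary": biliary,
            "basolateral": basolat, "clearance": clear}


def bilirubin_derivs(pools, mult, viable_total, consts):
    f = bilirubin_fluxes(pools, mult, viable_total, consts)
    d_pub = f["production"] - f["uptake_ub"]
    d_pcb = f["basolateral"] - f["uptake_cb"] - f["clearance"]
    d_hub = f["uptake_ub"] - f["conjugation"]
    d_hcb = f["conjugation"] + f["uptake_cb"] - f["biliary"] - f["basolateral"]
    return np.array([d_pub, d_pcb, d_hub, d_hcb]), f


def ba_secretion_readout(result, control, days, species=None):
    """Combined basolateral + biliary secretion as % of a control run.

    ``result``/``control`` are :class:`~hepatoqst.liver_core.SimResult`
    objects on identical time grids; ``days`` = (start, stop) of the
    integration window.  Returns a dict per amidated species (trapezoidal
    integral of the summed efflux fluxes, treated/control × 100).
    """
    t1, t2 = (float(d) * 24.0 for d in days)
    if result.times.shape != control.times.shape or np.any(
            result.times != control.times):
        raise ValueError("treated and control runs must share a time grid")
    mask = (result.times >= t1) & (result.times <= t2)
    if mask.sum() < 2:
        raise ValueError("readout window contains fewer than two grid points")
    out = {}
    for sp in (species or AMIDATED):
        num = np.trapezoid(result.secretion_flux[sp][mask],
                           result.times[mask])
        den = np.trapezoid(control.secretion_flux[sp][mask],
                           control.times[mask])
        out[sp] = 100.0 * num / den
    return out
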