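"""Reduced acetaminophen → NAPQI hepatotoxicity submodel.

NAPQI, the reactive metabolite of acetaminophen, is formed by CYP2E1 and
CYP3A4 (activity multipliers are supplied by the IL-6 pathway, which is how
tocilizumab's de-suppression of CYP expression feeds back on acetaminophen
toxicity).  NAPQI is detoxified by second-order conjugation with GSH; the
residue produces ROS and a slowly repaired protein adduct that inhibits ATP
synthesis.  Only this interaction logic — not a full multi-pathway
acetaminophen model — is represented.
"""

from __future__ import annotations

from .params import ApapParams

__all__ = ["napqi_formation", "napqi_disposition", "napqi_steady_state"]


def napqi_formation(apap_liver: float, cyp2e1_mult: float, cyp3a4_mult: float,
                    p: ApapParams) -> float:
    """NAPQI formation rate (AU/h) from liver APAP and CYP activities.

    rate = k_met · C_liver · (f_2E1·m_2E1 + f_3A4·m_3A4); strictly
    increasing in each activity multiplier.
    """
    if min(apap_liver, cyp2e1_mult, cyp3a4_mult) < 0:
        raise ValueError("formation inputs must be >= 0")
    return p.k_met * apap_liver * (p.f_cyp2e1 * cyp2e1_mult
                                   + p.f_cyp3a4 * cyp3a4_mult)


def napqi_disposition(napqi: float, gsh: float, p: ApapParams) -> dict:
    """Partition free NAPQI into conjugation and injury fluxes (AU/h).

    Conjugation consumes GSH (``gsh_consumption`` =
    gsh_per_conj × conjugation); the unconjugated residue drives ROS
    production and adduct formation.
    """
    if napqi < 0 or gsh < 0:
        raise ValueError("disposition inputs must be >= 0")
    conj = p.k_gsh_conj * gsh * napqi
    return {
        "conjugation": conj,
        "gsh_consumption": p.gsh_per_conj * conj,
        "other": p.k_other * napqi,
        "adduct_formation": p.k_adduct * napqi,
        "ros_production": p.k_napqi_ros * napqi,
    }


def napqi_steady_state(apap_liver: float, cyp2e1: float, cyp3a4: float,
                       gsh: float, p: ApapParams) -> float:
    """Quasi-steady free NAPQI level (formation / total first-order loss)."""
    form = napqi_formation(apap_liver, cyp2e1, cyp3a4, p)
    return form / (p.k_gsh_conj * gsh + p.k_other + p.k_adduct)
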