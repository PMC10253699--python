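"""Tocilizumab intrinsic-toxicity mechanisms: steatosis and oxidative stress.

Steatosis is modeled as saturable inhibition of VLDL-triglyceride export:
with inhibition fraction I(C) = Imax·C/(IC50 + C), hepatic triglyceride
(relative to its drug-free baseline TG0) approaches the steady state
TG/TG0 = 1/(1 − I(C)).  Oxidative stress combines a saturable
drug-concentration-dependent ROS production term with a lipotoxicity ramp
that only engages above a steatosis threshold — encoding the conclusion that
the observed ~2× steatosis is itself insufficient to explain the observed
ROS accumulation.

Both mechanisms are calibrated by an exact two-point fit through the day-10
endpoint pairs measured on liver chips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SteatosisParams",
    "RosParams",
    "vldl_inhibition",
    "drug_ros_production",
    "lipotox_ros",
    "fit_two_point_saturable",
    "fit_steatosis_from_endpoints",
    "fit_ros_from_endpoints",
    "TCZ_STEATOSIS_ENDPOINTS",
    "TCZ_ROS_ENDPOINTS",
]


class FitError(ValueError):
    """Raised when anchor responses are inconsistent with a saturable curve."""


# Day-10 (% of control) endpoints at the two hepatic interstitial
# tocilizumab concentrations.
TCZ_STEATOSIS_ENDPOINTS = [(52.4, 203.0), (166.3, 204.0)]
TCZ_ROS_ENDPOINTS = [(52.4, 220.0), (166.3, 230.0)]


@dataclass(frozen=True)
class SteatosisParams:
    """VLDL-export inhibition parameters.

    ``k_tg`` is the triglyceride turnover rate constant; its default half-life
    (12 h) makes the 10-day chip readout an effective steady state.
    """

    imax: float = 0.0  # dimensionless, in [0, 1)
    ic50: float = 1.0  # µg/mL
    k_tg: float = np.log(2) / 12.0  # 1/h

    def __post_init__(self) -> None:
        if not (0.0 <= self.imax < 1.0):
            raise FitError("Imax must lie in [0, 1)")
        if self.ic50 <= 0 or self.k_tg <= 0:
            raise FitError("IC50 and k_tg must be positive")


@dataclass(frozen=True)
class RosParams:
    """Drug-driven and lipotoxic ROS production parameters.

    Production is expressed in multiples of the baseline production rate
    (p_base ≡ 1); ``k_clear`` is the first-order ROS clearance whose short
    half-life (1 h) slaves ROS to its production rate.
    """

    vmax_ros: float = 0.0  # multiples of p_base
    ec50_ros: float = 1.0  # µg/mL
    k_clear: float = np.log(2) / 1.0  # 1/h
    lipotox_gain: float = 0.5  # added production per unit TG excess
    lipotox_threshold: float = 2.5  # TG/TG0 units; > observed tocilizumab steatosis

    def __post_init__(self) -> None:
        if min(self.vmax_ros, self.lipotox_gain) < 0 or self.ec50_ros <= 0:
            raise FitError("ROS parameters must be non-negative (EC50 > 0)")


def vldl_inhibition(conc, p: SteatosisParams):
    """Fractional inhibition of VLDL-triglyceride export at drug concentration C."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = p.imax * conc / (p.ic50 + conc)
    return float(out) if out.ndim == 0 else out


def drug_ros_production(conc, p: RosParams):
    """Added ROS production (multiples of baseline) at drug concentration C."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = p.vmax_ros * conc / (p.ec50_ros + conc)
    return float(out) if out.ndim == 0 else out


def lipotox_ros(tg_rel, p: RosParams):
    """Lipotoxic ROS production: linear ramp above the steatosis threshold."""
    tg_rel = np.asarray(tg_rel, dtype=float)
    if np.any(tg_rel < 0):
        raise ValueError("relative TG must be >= 0")
    out = p.lipotox_gain * np.maximum(0.0, tg_rel - p.lipotox_threshold)
    return float(out) if out.ndim == 0 else out


def fit_two_point_saturable(anchors):
    """Exact two-point fit of y = Vmax·C/(K + C).

    Uses the double-reciprocal linearization 1/y = 1/Vmax + (K/Vmax)/C, which
    is exact for two points.  Returns (Vmax, K).  Raises :class:`FitError`
    when the anchors imply a non-positive Vmax or K (e.g. equal responses at
    different concentrations, which degenerate to K = 0).
    """
    (c1, y1), (c2, y2) = anchors
    if min(c1, c2, y1, y2) <= 0 or c1 == c2:
        raise FitError("anchors must have distinct positive concentrations "
                       "and positive responses")
    slope = (1.0 / y1 - 1.0 / y2) / (1.0 / c1 - 1.0 / c2)  # K/Vmax
    intercept = 1.0 / y1 - slope / c1  # 1/Vmax
    if slope <= 0 or intercept <= 0:
        raise FitError(
            "anchors infeasible for a saturable monotone curve "
            f"(implied K/Vmax={slope:.3g}, 1/Vmax={intercept:.3g})")
    vmax = 1.0 / intercept
    km = slope * vmax
    for c, y in anchors:
        resid = abs(vmax * c / (km + c) - y)
        if resid > 1e-10 * abs(y):
            raise FitError(f"fit residual {resid:g} at anchor ({c}, {y})")
    return vmax, km


def fit_steatosis_from_endpoints(endpoints=TCZ_STEATOSIS_ENDPOINTS,
                                 **extra) -> SteatosisParams:
    """Calibrate (Imax, IC50) from two (conc, steatosis % of control) endpoints.

    Inverts the steady state TG/TG0 = 1/(1−I) to inhibition anchors
    I = 1 − 100/pct and fits the saturable curve through them.
    """
    anchors = []
    for conc, pct in endpoints:
        if pct <= 100.0:
            raise FitError("steatosis endpoints must exceed 100% of control")
        anchors.append((conc, 1.0 - 100.0 / pct))
    imax, ic50 = fit_two_point_saturable(anchors)
    if imax >= 1.0:
        raise FitError(f"implied Imax {imax:.4f} >= 1: no finite steady state")
    return SteatosisParams(imax=imax, ic50=ic50, **extra)


def fit_ros_from_endpoints(endpoints=TCZ_ROS_ENDPOINTS, **extra) -> RosParams:
    """Calibrate (Vmax, EC50) from two (conc, ROS % of control) endpoints.

    At steady state ROS/ROS0 = (p_base + p_drug)/p_base, so the added
    production anchors are pct/100 − 1 (lipotoxicity contributes nothing at
    the calibrated steatosis levels, below the lipotoxic threshold).
    """
    anchors = []
    for conc, pct in endpoints:
        if pct <= 100.0:
            raise FitError("ROS endpoints must exceed 100% of control")
        anchors.append((conc, pct / 100.0 - 1.0))
    vmax, ec50 = fit_two_point_saturable(anchors)
    return RosParams(vmax_ros=vmax, ec50_ros=ec50, **extra)
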