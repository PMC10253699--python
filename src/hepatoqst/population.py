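"""Virtual cohorts, susceptibility parameterization, and sensitivity scans.

Individuals are parameter-override maps (multipliers on susceptibility
parameters such as the ROS damage gain, baseline GSH, mitochondrial
sensitivity, or the bile acid toxicity EC50), not structural variants.
Two cohorts ship with the package:

* a four-individual cohort with elevated IL-6 (a proxy for the
  pro-inflammatory rheumatoid arthritis setting) containing two
  acetaminophen hepatotoxicity responders (high ROS susceptibility, reduced
  GSH) and two non-responders;
* a sixteen-individual healthy-volunteer cohort — the baseline human, 12
  subjects sensitized to bile acid transport inhibition, oxidative stress
  and mitochondrial dysfunction on a small factorial grid, and 3 subjects
  desensitized in the same areas.

Cohort simulations are deterministic; no randomness is consumed outside the
tuning utility (whose seed is part of its report).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exposure import DoseProtocol
from .liver_core import simulate, summarize
from .params import (PATHWAYS, DrugModel, PhysiologyParams, RegulationEffect,
                     default_apap, default_ggf2, default_tocilizumab)

__all__ = [
    "Individual",
    "SimCohort",
    "build_cohort_n4",
    "build_cohort_n16",
    "run_cohort",
    "sensitivity_scan",
    "tune",
    "TCZ_CLINICAL_PROTOCOL",
    "APAP_CLINICAL_PROTOCOL",
    "GGF2_CLINICAL_PROTOCOL",
]

# Clinical protocols: 8 mg/kg IV q4wk x12wk; 1 g q6h (4 g/day) x12wk;
# single 1.5 mg/kg IV observed for 12 weeks.
TCZ_CLINICAL_PROTOCOL = DoseProtocol("iv_bolus", 8.0, interval=672.0,
                                     n_doses=3, duration=84.0)
APAP_CLINICAL_PROTOCOL = DoseProtocol("oral", 1.0, interval=6.0,
                                      n_doses=336, duration=84.0)
GGF2_CLINICAL_PROTOCOL = DoseProtocol("iv_bolus", 1.5, n_doses=1,
                                      duration=84.0)
GGF2_LOW_PROTOCOL = DoseProtocol("iv_bolus", 0.38, n_doses=1, duration=84.0)


@dataclass(frozen=True)
class Individual:
    """One simulated subject: an id, a susceptibility descriptor, overrides."""

    id: str
    overrides: dict = field(default_factory=dict)
    descriptor: str = "baseline"

    def __post_init__(self) -> None:
        # validate override keys/values eagerly
        PhysiologyParams().with_overrides(self.overrides)


@dataclass(frozen=True)
class SimCohort:
    name: str
    individuals: tuple
    context: str = "healthy"  # shared IL-6 context

    def __post_init__(self) -> None:
        ids = [i.id for i in self.individuals]
        if len(ids) != len(set(ids)):
            raise ValueError("individual ids must be unique")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "context": self.context,
                       "individuals": [asdict(i) for i in self.individuals]},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimCohort":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["name"],
                   tuple(Individual(**i) for i in d["individuals"]),
                   d.get("context", "healthy"))


def build_cohort_n4() -> SimCohort:
    """Four-individual elevated-IL-6 cohort (tuned shipped defaults).

    Two acetaminophen responders carry elevated ROS damage gain and reduced
    GSH; two non-responders sit near baseline susceptibility.
    """
    inds = (
        Individual("nr1", {"ros_damage_gain": 1.28}, "baseline"),
        Individual("nr2", {"ros_damage_gain": 1.31}, "baseline"),
        Individual("r1", {"ros_damage_gain": 1.34, "gsh_synthesis": 0.25},
                   "high_ros_susceptibility"),
        Individual("r2", {"ros_damage_gain": 1.75, "gsh_synthesis": 0.22},
                   "high_ros_susceptibility"),
    )
    return SimCohort("simcohort_n4_elevated_il6", inds, context="elevated")


def build_cohort_n16() -> SimCohort:
    """Sixteen-individual healthy-volunteer cohort (tuned shipped defaults)."""
    inds = [Individual("baseline", {}, "baseline")]
    grid = itertools.product((0.70, 0.78, 0.88), (1.15, 1.40), (1.10, 1.30))
    for i, (ec50, mito, ros) in enumerate(grid, start=1):
        inds.append(Individual(
            f"sens{i:02d}",
            {"bile_acid_tox_ec50": ec50, "mito_sensitivity": mito,
             "ros_damage_gain": ros},
            "bile_acid_sensitive"))
    for i, (ec50, mito, ros) in enumerate(
            ((1.5, 0.85, 0.85), (1.8, 0.80, 0.80), (2.0, 0.75, 0.75)),
            start=1):
        inds.append(Individual(
            f"low{i}",
            {"bile_acid_tox_ec50": ec50, "mito_sensitivity": mito,
             "ros_damage_gain": ros},
            "low_sensitivity"))
    return SimCohort("simcohort_n16_healthy", tuple(inds))


def run_cohort(cohort: SimCohort, drugs=(), exposures=None,
               duration_days=84.0, phys: PhysiologyParams | None = None,
               **sim_kw) -> pd.DataFrame:
    """Simulate every individual; return one biomarker-summary row each."""
    rows = []
    for ind in cohort.individuals:
        try:
            res = simulate(drugs=drugs, exposures=exposures, phys=phys,
                           context=cohort.context, overrides=ind.overrides,
                           duration_days=duration_days, **sim_kw)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed for individual {ind.id!r}: {exc}") from exc
        s = summarize(res)
        rows.append({"id": ind.id, "descriptor": ind.descriptor,
                     **asdict(s)})
    return pd.DataFrame(rows)


def sensitivity_scan(pathway: str, emax_multipliers, phys=None,
                     protocol: DoseProtocol = GGF2_CLINICAL_PROTOCOL,
                     duration_days=42.0, overrides=None,
                     **sim_kw) -> pd.DataFrame:
    """One-at-a-time scan of a single regulation pathway in the baseline human.

    For each multiplier, the GGF2 drug model is reduced to the one named
    pathway with its default Emax scaled by the multiplier (a multiplier of
    0 reproduces the drug-free run); records peak ALT, peak total bilirubin,
    minimum hepatic ATP, and peak centrilobular CDCA-amidated concentration.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; known: {PATHWAYS}")
    base = default_ggf2()
    effect = next(e for e in base.regulation if e.pathway == pathway)
    rows = []
    for mult in emax_multipliers:
        if mult < 0:
            raise ValueError("Emax multipliers must be >= 0")
        if mult == 0:
            drug = DrugModel(drug_id=base.drug_id, pk=base.pk,
                             partition=base.partition, regulation=())
        else:
            emax = effect.emax * mult
            if effect.direction == "down":
                emax = min(emax, 0.95)  # transport cannot be fully abolished
            scaled = RegulationEffect(effect.pathway, effect.direction,
                                      emax, effect.ec50, effect.kout)
            drug = DrugModel(drug_id=base.drug_id, pk=base.pk,
                             partition=base.partition, regulation=(scaled,))
        res = simulate(drugs=[drug], exposures={drug.drug_id: protocol},
                       phys=phys, overrides=overrides,
                       duration_days=duration_days, **sim_kw)
        cl_cdca_rel = (res["cdca_cl"]
                       / res.consts["species"]["cdca_am"]["h0"][2])
        rows.append({
            "pathway": pathway, "emax_multiplier": mult,
            "peak_alt": float(res.alt.max()),
            "peak_tb": float(res.total_bilirubin.max()),
            "min_atp": float(res.atp_min_zone.min()),
            "peak_cl_cdca": float(cl_cdca_rel.max()),
        })
    return pd.DataFrame(rows)


def tune(constraints, free_params, evaluate=None, budget=60, seed=0):
    """Derivative-free categorical tuning of free gains.

    ``free_params`` maps name -> (default, lo, hi).  ``evaluate`` maps a
    parameter dict to an arbitrary result object; each constraint is
    (label, callable(result) -> slack) where slack <= 0 means satisfied.
    A seeded random search (log-uniform within bounds, including the
    defaults as the first candidate) minimizes total positive slack and
    returns ``(best_params, report)``; the report lists per-constraint slack
    and whether every constraint was met.  With no constraints the defaults
    are returned unchanged.
    """
    defaults = {k: v[0] for k, v in free_params.items()}
    if not constraints:
        return defaults, {"feasible": True, "evaluations": 0, "seed": seed,
                          "slacks": {}}
    if evaluate is None:
        raise ValueError("evaluate callable required when constraints given")
    rng = np.random.default_rng(seed)

    def total_slack(params):
        result = evaluate(params)
        slacks = {label: float(fn(result)) for label, fn in constraints}
        return sum(max(0.0, s) for s in slacks.values()), slacks

    best_params, (best_pen, best_slacks) = dict(defaults), total_slack(defaults)
    n_eval = 1
    while n_eval < budget and best_pen > 0:
        cand = {}
        for k, (d, lo, hi) in free_params.items():
            if lo > 0 and hi / lo > 10:
                cand[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                cand[k] = float(rng.uniform(lo, hi))
        pen, slacks = total_slack(cand)
        n_eval += 1
        if pen < best_pen:
            best_params, best_pen, best_slacks = cand, pen, slacks
    report = {"feasible": best_pen <= 0, "evaluations": n_eval, "seed": seed,
              "slacks": best_slacks, "total_violation": best_pen}
    return best_params, report
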