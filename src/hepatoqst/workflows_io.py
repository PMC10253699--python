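"""Configuration, file I/O, synthetic chip-data fixtures, and fixture statistics.

The fixture generator emulates the structure of per-chip liver-chip
(LAMPS-style) effluent datasets: daily endpoint measurements per chip with
multiplicative lognormal noise around a model-derived truth, with group
sizes matching the published chip counts.  It exists so that calibration
and parameter-recovery workflows can be exercised end-to-end without any
wet-lab data; it makes no attempt to reproduce assay-specific artifacts
(plate effects, censoring, drift).

Group comparisons on fixture data use Welch's unequal-variance t test.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "RunConfig",
    "ChipDataset",
    "generate_lamps_fixture",
    "welch_compare",
    "TCZ_CHIP_COUNTS",
    "GGF2_CHIP_COUNTS",
    "log_event",
]

# Published per-group chip counts for the two figure-style layouts
TCZ_CHIP_COUNTS = {"control": 15, "tcz_232": 14, "tcz_725": 6,
                   "il6": 6, "tcz_il6": 5}
GGF2_CHIP_COUNTS = {"control": 15, "ggf2_10": 11, "ggf2_100": 6, "ggf2_382": 5}

ENDPOINTS = ("LDH", "HMGB1", "albumin", "urea", "GCDCA", "TCA",
             "steatosis_pct", "ROS_pct")


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation run configuration (YAML/JSON serializable)."""

    mode: str = "clinical"  # "clinical" | "invitro"
    context: str = "healthy"
    duration_days: float = 84.0
    drugs: tuple = ()  # drug file paths or builtin names
    protocols: dict = field(default_factory=dict)
    cohort: str | None = None
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_dt: float = 1.0
    output: str = "results.csv"

    _KNOWN = {"mode", "context", "duration_days", "drugs", "protocols",
              "cohort", "seed", "rtol", "atol", "grid_dt", "output"}

    def __post_init__(self) -> None:
        if self.mode not in ("clinical", "invitro"):
            raise ValueError(f"mode must be clinical|invitro, got {self.mode!r}")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drugs" in d:
            d = {**d, "drugs": tuple(d["drugs"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["drugs"] = list(d["drugs"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ChipDataset:
    """Tidy per-chip measurements: one row per chip × day × endpoint."""

    data: pd.DataFrame  # columns: chip_id, group, drug, media_conc, day,
    #                              endpoint, value
    seed: int | None = None

    COLUMNS = ("chip_id", "group", "drug", "media_conc", "day", "endpoint",
               "value")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"chip dataset missing columns: {sorted(missing)}")
        if (self.data["value"] < 0).any():
            raise ValueError("chip measurements must be non-negative")

    def group_values(self, group: str, endpoint: str, day=None) -> np.ndarray:
        df = self.data
        m = (df["group"] == group) & (df["endpoint"] == endpoint)
        if day is not None:
            m &= df["day"] == day
        return df.loc[m, "value"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ChipDataset":
        return cls(pd.read_csv(path))


def generate_lamps_fixture(truth: dict, noise_cv: float, chip_counts: dict,
                           seed: int, days=(10,)) -> ChipDataset:
    """Generate a synthetic per-chip endpoint table around model truth values.

    ``truth`` maps group -> {endpoint: value} (optionally
    {endpoint: {day: value}}); each chip measurement is
    truth × LogNormal(mean 1, CV ``noise_cv``), reproducible for a given
    ``seed``.  Group metadata (drug, media_conc) is parsed from group names
    of the form ``drug_conc`` when possible.
    """
    if noise_cv <= 0:
        raise ValueError("noise_cv must be > 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    mu = -0.5 * sigma ** 2  # multiplicative noise with mean exactly 1
    rows = []
    for group, n_chips in chip_counts.items():
        endpoints = truth.get(group, {})
        if "_" in group:
            drug, _, conc = group.rpartition("_")
            try:
                media_conc = float(conc)
            except ValueError:
                drug, media_conc = group, 0.0
        else:
            drug, media_conc = group, 0.0
        for chip in range(n_chips):
            chip_id = f"{group}_chip{chip + 1:02d}"
            for endpoint, val in endpoints.items():
                per_day = val if isinstance(val, dict) else {d: val for d in days}
                for day, v in per_day.items():
                    noise = np.exp(rng.normal(mu, sigma))
                    rows.append((chip_id, group, drug, media_conc, day,
                                 endpoint, float(v) * noise))
    df = pd.DataFrame(rows, columns=list(ChipDataset.COLUMNS))
    return ChipDataset(df, seed=seed)


def welch_compare(group_a, group_b):
    """Welch's unequal-variance t test (two-sided).

    Returns (t statistic, p value) with Welch–Satterthwaite degrees of
    freedom; raises on degenerate input (n < 2 or zero variance in both
    groups).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups: t test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def log_event(fh, event: str, **fields) -> None:
    """Append one timestamped JSON line to an open log stream."""
    rec = {"ts": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event, **fields}
    fh.write(json.dumps(rec) + "\n")
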