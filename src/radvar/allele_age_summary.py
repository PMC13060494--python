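"""Quality filtering and group comparison of externally estimated allele ages.

Age tables carry one row per variant with a point estimate and CI bounds in
generations, plus a group label. Filtering keeps records whose CI bound ratio
(upper/lower) and point estimate fall under configurable caps; comparisons
are two-sided Wilcoxon rank-sum tests on per-group age distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InsufficientDataError


@dataclass(frozen=True)
class AgeRecord:
    vid: str
    group: str
    age: float  # generations
    lower: float
    upper: float


@dataclass(frozen=True)
class AgeFilterConfig:
    max_ci_ratio: float = 10.0
    max_age: float = 500_000.0
    # "bounds": ratio = upper/lower; "estimate": ratio = upper/estimate.
    ratio_mode: str = "bounds"

    def __post_init__(self):
        if self.max_ci_ratio <= 0 or self.max_age <= 0:
            raise ConfigurationError("age filter caps must be positive")
        if self.ratio_mode not in ("bounds", "estimate"):
            raise ConfigurationError(f"unknown ratio mode {self.ratio_mode!r}")


def read_age_table(path: str | Path, group_column: str = "group") -> tuple[list[AgeRecord], int]:
    """Parse a TSV of (variant_id, [group,] age, lower, upper).

    Records violating 0 < lower <= age <= upper are dropped; the second
    return value counts them.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "age", "lower", "upper"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"age table missing columns: {sorted(missing)}")
    records, rejected = [], 0
    for row in df.itertuples(index=False):
        age, lo, hi = float(row.age), float(row.lower), float(row.upper)
        if not (0 < lo <= age <= hi):
            rejected += 1
            continue
        group = str(getattr(row, group_column)) if group_column in df.columns else "all"
        records.append(AgeRecord(str(row.variant_id), group, age, lo, hi))
    return records, rejected


def filter_ages(
    records: Sequence[AgeRecord], config: AgeFilterConfig = AgeFilterConfig()
) -> tuple[list[AgeRecord], dict[str, int]]:
    """Apply the CI-ratio and age-cap filters.

    Each rejected record is tallied under the first failing rule
    (zero_lower, then ci_ratio, then age_cap), so retained + tallies sum to
    the input count. Idempotent.
    """
    retained: list[AgeRecord] = []
    tally = {"zero_lower": 0, "ci_ratio": 0, "age_cap": 0}
    for r in records:
        denom = r.lower if config.ratio_mode == "bounds" else r.age
        if denom <= 0:
            tally["zero_lower"] += 1
            continue
        if r.upper / denom > config.max_ci_ratio:
            tally["ci_ratio"] += 1
            continue
        if r.age > config.max_age:
            tally["age_cap"] += 1
            continue
        retained.append(r)
    return retained, tally


def group_summary(records: Sequence[AgeRecord]) -> pd.DataFrame:
    """Per-group n and median age."""
    rows = []
    for group in sorted({r.group for r in records}):
        ages = np.array([r.age for r in records if r.group == group])
        rows.append({"group": group, "n": len(ages), "median_age": float(np.median(ages))})
    return pd.DataFrame(rows, columns=["group", "n", "median_age"])


def compare_age_groups(
    records: Sequence[AgeRecord],
    group_a: str,
    group_b: str,
    freq_bins: Optional[Sequence[tuple[float, float]]] = None,
    freqs: Optional[dict[str, float]] = None,
) -> dict:
    """Median ages and two-sided Wilcoxon rank-sum p between two groups.

    Optional stratification: supply allele-frequency bins plus a
    variant-id -> frequency map to get one comparison per bin.
    """
    a = np.array([r.age for r in records if r.group == group_a])
    b = np.array([r.age for r in records if r.group == group_b])
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError(
            f"empty group in comparison ({group_a}: {a.size}, {group_b}: {b.size})"
        )
    out = {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "wilcoxon_p": _rank_sum_p(a, b),
    }
    if freq_bins is not None:
        if freqs is None:
            raise ConfigurationError("freq_bins given without a variant frequency map")
        strata = []
        for lo, hi in freq_bins:
            sel = [r for r in records if lo <= freqs.get(r.vid, np.nan) < hi]
            sa = np.array([r.age for r in sel if r.group == group_a])
            sb = np.array([r.age for r in sel if r.group == group_b])
            entry = {"bin": (lo, hi), "n_a": int(sa.size), "n_b": int(sb.size)}
            if sa.size and sb.size:
                entry.update(
                    median_a=float(np.median(sa)),
                    median_b=float(np.median(sb)),
                    wilcoxon_p=_rank_sum_p(sa, sb),
                )
            else:
                entry["skipped"] = "empty group in bin"
            strata.append(entry)
        out["strata"] = strata
    return out


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.unique(np.concatenate([a, b])).size < 2:
        return 1.0
    if a.size <= 25 and b.size <= 25 and np.unique(np.concatenate([a, b])).size == a.size + b.size:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
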