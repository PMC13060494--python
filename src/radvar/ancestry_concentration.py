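"""Ancestry concentration of rare-variant carriers.

Per-variant carrier profiles split by case/control status and ancestry,
enrichment classification (case-enriched / case-skew / other), dominant
ancestry, single-ancestry-like calls, Gini-Simpson diversity, and group
comparisons of concentration metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consequence_masks import QualifyingVariantSet
from .exceptions import ConfigurationError, InputError, InsufficientDataError


@dataclass
class EnrichmentThresholds:
    """Rules separating case-enriched and case-skew variants.

    ``baseline_ratio`` is the cohort's overall case/control ratio; the
    enrichment ratio rule (>= 1) is meaningful because it exceeds it.
    """

    min_ad_enriched: int = 2
    ratio_enriched: float = 1.0
    min_ad_skew: int = 5
    ratio_skew: float = 5.0
    dominance: float = 0.75
    baseline_ratio: Optional[float] = None

    def __post_init__(self):
        if self.min_ad_skew < self.min_ad_enriched or self.ratio_skew < self.ratio_enriched:
            raise ConfigurationError("skew thresholds must be >= enriched thresholds")
        if not 0 < self.dominance <= 1:
            raise ConfigurationError("dominance threshold must be in (0, 1]")

    @classmethod
    def from_counts(cls, n_cases: int, n_controls: int, **kwargs) -> "EnrichmentThresholds":
        if n_controls <= 0:
            raise ConfigurationError("control count must be positive")
        return cls(baseline_ratio=n_cases / n_controls, **kwargs)

    @classmethod
    def from_cohort(cls, case_status: np.ndarray, **kwargs) -> "EnrichmentThresholds":
        case = np.asarray(case_status, dtype=float)
        known = np.isfinite(case) & (case >= 0)
        return cls.from_counts(int((case[known] == 1).sum()), int((case[known] == 0).sum()),
                               **kwargs)


@dataclass
class VariantCarrierProfile:
    vid: str
    total_carriers: int
    ad_carriers: int
    control_carriers: int
    ancestry_counts: dict[str, int] = field(default_factory=dict)
    enrichment: str = "other"

    @property
    def proportions(self) -> dict[str, float]:
        tot = sum(self.ancestry_counts.values())
        return {k: v / tot for k, v in self.ancestry_counts.items()} if tot else {}

    @property
    def dominant(self) -> tuple[str, float]:
        return dominant_ancestry(self)

    @property
    def simpson(self) -> float:
        return simpson_diversity(self)


def build_profiles(
    variant_ids: Sequence[str],
    genotypes: np.ndarray,
    case_status: np.ndarray,
    ancestry: Sequence[str],
    min_carriers: int = 2,
) -> list[VariantCarrierProfile]:
    """One profile per variant with at least ``min_carriers`` carriers.

    A carrier has dosage >= 1 (missing genotypes do not count). Samples with
    unknown case status are excluded from the case/control split but still
    contribute to ancestry counts.
    """
    if min_carriers < 1:
        raise ConfigurationError("min_carriers must be >= 1")
    G = np.asarray(genotypes)
    if G.shape[1] != len(variant_ids):
        raise InputError("variant ids do not match genotype columns")
    case = np.asarray(case_status, dtype=float)
    ancestry = np.asarray(ancestry)
    if G.shape[0] != len(case) or G.shape[0] != len(ancestry):
        raise InputError("phenotype/genotype sample mismatch")
    known = np.isfinite(case) & (case >= 0)
    profiles = []
    carrier_mat = G >= 1
    for j, vid in enumerate(variant_ids):
        carriers = carrier_mat[:, j]
        total = int(carriers.sum())
        if total < min_carriers:
            continue
        counts: dict[str, int] = {}
        for lab in ancestry[carriers]:
            counts[lab] = counts.get(lab, 0) + 1
        profiles.append(
            VariantCarrierProfile(
                vid=str(vid),
                total_carriers=total,
                ad_carriers=int((carriers & known & (case == 1)).sum()),
                control_carriers=int((carriers & known & (case == 0)).sum()),
                ancestry_counts=counts,
            )
        )
    return profiles


def classify_enrichment(
    profile: VariantCarrierProfile, thresholds: EnrichmentThresholds = EnrichmentThresholds()
) -> str:
    """'AD-skew' / 'AD-enriched' / 'other'; skew is the more specific label."""
    ad, ctl = profile.ad_carriers, profile.control_carriers
    if ad >= thresholds.min_ad_skew and (ctl == 0 or ad / ctl >= thresholds.ratio_skew):
        return "AD-skew"
    if ad >= thresholds.min_ad_enriched and (ctl == 0 or ad / ctl >= thresholds.ratio_enriched):
        return "AD-enriched"
    return "other"


def dominant_ancestry(profile: VariantCarrierProfile) -> tuple[str, float]:
    """Ancestry with the largest carrier count; lexicographic tie-break."""
    if not profile.ancestry_counts or sum(profile.ancestry_counts.values()) == 0:
        raise InsufficientDataError(f"variant {profile.vid} has no carriers")
    label = min(profile.ancestry_counts, key=lambda k: (-profile.ancestry_counts[k], k))
    total = sum(profile.ancestry_counts.values())
    return label, profile.ancestry_counts[label] / total


def is_single_ancestry_like(profile: VariantCarrierProfile, threshold: float = 0.75) -> bool:
    """Dominant-ancestry proportion at or above the threshold (inclusive)."""
    return dominant_ancestry(profile)[1] >= threshold


def simpson_diversity(profile: VariantCarrierProfile) -> float:
    """Gini-Simpson index 1 - sum(p_i^2); 0 = all carriers share one ancestry."""
    props = np.array(list(profile.proportions.values()))
    if props.size == 0:
        raise InsufficientDataError(f"variant {profile.vid} has no carriers")
    return float(1.0 - np.sum(props**2))


def classify_profiles(
    profiles: Sequence[VariantCarrierProfile],
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> None:
    for p in profiles:
        p.enrichment = classify_enrichment(p, thresholds)


def profiles_table(profiles: Sequence[VariantCarrierProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        label, prop = dominant_ancestry(p)
        rows.append(
            {
                "variant_id": p.vid,
                "total_carriers": p.total_carriers,
                "ad_carriers": p.ad_carriers,
                "control_carriers": p.control_carriers,
                "ancestry_counts": ";".join(
                    f"{k}:{v}" for k, v in sorted(p.ancestry_counts.items())
                ),
                "enrichment": p.enrichment,
                "dominant_ancestry": label,
                "dominant_proportion": prop,
                "simpson": simpson_diversity(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "total_carriers", "ad_carriers", "control_carriers",
            "ancestry_counts", "enrichment", "dominant_ancestry",
            "dominant_proportion", "simpson",
        ],
    )


def compare_concentration(
    profiles: Sequence[VariantCarrierProfile],
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> dict:
    """Two-group comparison of concentration metrics.

    The enriched group pools 'AD-enriched' and 'AD-skew' (skew is a subset of
    enriched by construction); 'other' is the background. Also reports the
    three-group (display) medians.
    """
    classify_profiles(profiles, thresholds)
    dom = np.array([dominant_ancestry(p)[1] for p in profiles])
    div = np.array([simpson_diversity(p) for p in profiles])
    cls = np.array([p.enrichment for p in profiles])
    enriched = (cls == "AD-enriched") | (cls == "AD-skew")
    other = cls == "other"
    out: dict = {
        "n_enriched": int(enriched.sum()),
        "n_other": int(other.sum()),
        "three_group_median_dominant": {
            g: float(np.median(dom[cls == g])) if (cls == g).any() else None
            for g in ("AD-enriched", "AD-skew", "other")
        },
    }
    if not enriched.any() or not other.any():
        out["skipped"] = "a group is empty; comparison skipped"
        return out
    for metric, vals in (("dominant_proportion", dom), ("simpson", div)):
        a, b = vals[enriched], vals[other]
        if np.unique(np.concatenate([a, b])).size < 2:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out[metric] = {
            "median_enriched": float(np.median(a)),
            "median_other": float(np.median(b)),
            "wilcoxon_p": p,
        }
    thr = thresholds.dominance
    out["single_ancestry_like_fraction"] = {
        "enriched": float(np.mean(dom[enriched] >= thr)),
        "other": float(np.mean(dom[other] >= thr)),
        "all": float(np.mean(dom >= thr)),
    }
    return out
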