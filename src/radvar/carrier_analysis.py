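"""Carrier-versus-non-carrier statistics.

Ancestry-stratified and pooled carrier odds ratios (Wald CIs on the log
scale, Haldane-Anscombe continuity correction on zero cells), and per-trait
carrier comparisons: Wilcoxon rank-sum with Hodges-Lehmann location shifts
for quantitative/ordinal traits, Fisher's exact test for binary traits, with
direction-standardized signed -log10(p) scores for heatmap rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consequence_masks import QualifyingVariantSet
from .exceptions import ConfigurationError, EmptyStratumError, InputError, InsufficientDataError


def carrier_status(qset: QualifyingVariantSet) -> np.ndarray:
    """True iff the sample carries >=1 qualifying allele in the set.

    Missing genotypes were imputed to 0 at set construction and therefore
    count as non-carrier.
    """
    return qset.carrier_flags


@dataclass
class CarrierTable:
    """2x2 carrier-by-phenotype table. a/b: case carriers/non-carriers."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    @classmethod
    def from_flags(cls, carrier: np.ndarray, case: np.ndarray) -> "CarrierTable":
        """Build from boolean carrier flags and 0/1 case status.

        ``case`` entries that are negative or NaN are treated as unknown and
        excluded.
        """
        carrier = np.asarray(carrier, dtype=bool)
        case = np.asarray(case, dtype=float)
        if carrier.shape != case.shape:
            raise InputError("carrier and case vectors differ in length")
        known = np.isfinite(case) & (case >= 0)
        is_case = case == 1
        a = int(np.sum(carrier & is_case & known))
        b = int(np.sum(~carrier & is_case & known))
        c = int(np.sum(carrier & (case == 0) & known))
        d = int(np.sum(~carrier & (case == 0) & known))
        return cls(a, b, c, d)

    def continuity_corrected(self) -> "CarrierTable":
        """Add 0.5 to every cell iff any cell is zero."""
        cells = (self.a, self.b, self.c, self.d)
        if min(cells) > 0:
            return self
        return CarrierTable(*(x + 0.5 for x in cells), corrected=True)


@dataclass
class OddsRatioEstimate:
    odds_ratio: float
    log_se: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    corrected: bool = False


def odds_ratio_wald(table: CarrierTable, level: float = 0.95) -> OddsRatioEstimate:
    """Wald OR and CI on the log scale, after continuity correction if needed."""
    if table.a + table.b <= 0 or table.c + table.d <= 0:
        raise EmptyStratumError("stratum lacks cases or controls")
    t = table.continuity_corrected()
    orr = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = stats.norm.isf((1 - level) / 2)
    return OddsRatioEstimate(
        odds_ratio=orr,
        log_se=se,
        ci_lower=math.exp(math.log(orr) - z * se),
        ci_upper=math.exp(math.log(orr) + z * se),
        level=level,
        corrected=t.corrected,
    )


def stratified_or(
    carrier: np.ndarray,
    case: np.ndarray,
    ancestry: Sequence[str],
    level: float = 0.95,
) -> tuple[dict[str, OddsRatioEstimate], OddsRatioEstimate, list[str]]:
    """Per-ancestry ORs plus a pooled OR over all samples jointly.

    Strata without cases or without controls are skipped and their labels
    returned in the third element.
    """
    ancestry = np.asarray(ancestry)
    if len(ancestry) != len(carrier):
        raise InputError("ancestry labels do not match sample count")
    per: dict[str, OddsRatioEstimate] = {}
    skipped: list[str] = []
    for label in sorted(set(ancestry)):
        sel = ancestry == label
        try:
            per[label] = odds_ratio_wald(
                CarrierTable.from_flags(np.asarray(carrier)[sel], np.asarray(case)[sel]), level
            )
        except EmptyStratumError:
            skipped.append(label)
    pooled = odds_ratio_wald(CarrierTable.from_flags(carrier, case), level)
    return per, pooled, skipped


def hodges_lehmann(x: np.ndarray, y: np.ndarray) -> float:
    """Median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    # Chunk over x to bound memory when y is large.
    diffs = [xi - y for xi in x]
    return float(np.median(np.concatenate(diffs)))


@dataclass(frozen=True)
class TraitSpec:
    name: str
    kind: str  # binary | quantitative | ordinal
    direction: str  # lower-is-worse | higher-is-worse

    def __post_init__(self):
        if self.kind not in ("binary", "quantitative", "ordinal"):
            raise ConfigurationError(f"unknown trait kind {self.kind!r}")
        if self.direction not in ("lower-is-worse", "higher-is-worse"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


#: Study trait registry: worsening direction and test family per trait.
DEFAULT_TRAITS: dict[str, TraitSpec] = {
    **{
        name: TraitSpec(name, "quantitative", "lower-is-worse")
        for name in ("Age", "Age_AmongCase", "MEM", "EXF", "LAN", "VSP", "Abeta42")
    },
    **{
        name: TraitSpec(name, "binary", "higher-is-worse")
        for name in ("AD", "HS_S", "TDP43", "CVD_S")
    },
    **{
        name: TraitSpec(name, "quantitative", "higher-is-worse")
        for name in ("tTau", "pTau181")
    },
    **{
        name: TraitSpec(name, "ordinal", "higher-is-worse")
        for name in ("Braak", "CERAD", "LEWY_full", "CVD_ART", "CVD_ATH")
    },
}


@dataclass
class GeneTraitCell:
    gene: str
    trait: str
    n_carrier: int
    n_noncarrier: int
    p: Optional[float]
    effect: Optional[float]  # Hodges-Lehmann shift, or OR for binary traits
    signed_score: Optional[float]
    flags: list[str] = field(default_factory=list)


def standardize_direction(p: float, effect: float, spec: TraitSpec) -> float:
    """Signed -log10(p): positive = carriers shifted toward adverse values."""
    if not 0 < p <= 1:
        raise InputError("p must be in (0, 1]")
    if not np.isfinite(effect):
        raise InputError("effect must be finite")
    sign = float(np.sign(effect))
    adversity = sign if spec.direction == "higher-is-worse" else -sign
    return adversity * (-math.log10(p))


def _wilcoxon(x: np.ndarray, y: np.ndarray, exact_max: int = 25) -> float:
    """Two-sided rank-sum p: exact when both groups small and tie-free,
    otherwise normal approximation with tie correction."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= exact_max and len(y) <= exact_max and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def trait_test(
    carrier: np.ndarray,
    values: np.ndarray,
    spec: TraitSpec,
    gene: str = "",
    low_carrier_flag: int = 5,
) -> GeneTraitCell:
    """Compare carriers to non-carriers on one trait.

    Quantitative/ordinal traits: Wilcoxon rank-sum + Hodges-Lehmann shift.
    Binary traits: Fisher's exact test + (continuity-corrected) odds ratio.
    NaN trait values are dropped. Cells with fewer than ``low_carrier_flag``
    carriers are computed but flagged; constant traits are marked untestable.
    """
    carrier = np.asarray(carrier, dtype=bool)
    values = np.asarray(values, dtype=float)
    if carrier.shape != values.shape:
        raise InputError("carrier flags and trait values differ in length")
    ok = np.isfinite(values)
    x = values[carrier & ok]
    y = values[~carrier & ok]
    flags = []
    if x.size < low_carrier_flag:
        flags.append("low_carrier")
    if x.size == 0 or y.size == 0:
        return GeneTraitCell(gene, spec.name, int(x.size), int(y.size), None, None, None,
                             flags + ["insufficient_data"])
    if np.unique(np.concatenate([x, y])).size < 2:
        return GeneTraitCell(gene, spec.name, int(x.size), int(y.size), None, None, None,
                             flags + ["constant_trait"])

    if spec.kind == "binary":
        if not np.isin(np.concatenate([x, y]), (0.0, 1.0)).all():
            raise InputError(f"trait {spec.name} is binary but has non-0/1 values")
        a, b = int(x.sum()), int((1 - x).sum())
        c, d = int(y.sum()), int((1 - y).sum())
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        t = CarrierTable(a, b, c, d).continuity_corrected()
        orr = (t.a * t.d) / (t.b * t.c)
        effect = orr
        direction_effect = math.log(orr)
    else:
        p = _wilcoxon(x, y)
        effect = hodges_lehmann(x, y)
        direction_effect = effect
    p = max(p, 1e-300)
    score = standardize_direction(p, direction_effect, spec) if direction_effect != 0 else 0.0
    return GeneTraitCell(gene, spec.name, int(x.size), int(y.size), p, effect, score, flags)


def gene_trait_table(
    qsets: Mapping[tuple[str, str], QualifyingVariantSet],
    phenotypes: pd.DataFrame,
    traits: Mapping[str, TraitSpec],
    case_column: str = "AD",
) -> pd.DataFrame:
    """Long-format gene x trait cells over all qualifying sets.

    The Age_AmongCase convention: any trait named ``<T>_AmongCase`` is the
    ``<T>`` comparison restricted to case samples (``case_column`` == 1).
    """
    rows = []
    for (gene, mask), qset in sorted(qsets.items()):
        if qset.n_samples != len(phenotypes):
            raise InputError("phenotype table does not match genotype sample count")
        flags = carrier_status(qset)
        for name, spec in traits.items():
            source = name
            restrict = None
            if name.endswith("_AmongCase"):
                source = name[: -len("_AmongCase")]
                restrict = phenotypes[case_column].to_numpy(dtype=float) == 1
            if source not in phenotypes.columns:
                continue
            vals = phenotypes[source].to_numpy(dtype=float)
            sel_flags = flags
            if restrict is not None:
                vals = np.where(restrict, vals, np.nan)
            cell = trait_test(sel_flags, vals, spec, gene=gene)
            rows.append(
                {
                    "gene": gene,
                    "mask": mask,
                    "trait": name,
                    "n_carrier": cell.n_carrier,
                    "n_noncarrier": cell.n_noncarrier,
                    "p": cell.p,
                    "effect": cell.effect,
                    "signed_score": cell.signed_score,
                    "flags": ";".join(cell.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "mask", "trait", "n_carrier", "n_noncarrier",
            "p", "effect", "signed_score", "flags",
        ],
    )
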