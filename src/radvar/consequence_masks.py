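"""Consequence severity ranking, mask assignment and qualifying-set construction.

Variants carry one or more Sequence Ontology (SO) consequence terms; the most
severe term (under a fixed severity order) determines which annotation mask --
M1 (loss-of-function-like), M2 (protein-altering) or M3 (splice-region) -- the
variant belongs to. Qualifying sets are the per-(gene, mask) dosage matrices,
restricted to rare variants, that feed every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError, VocabularyError
from .vcfio import MISSING, VcfRecord

# Severity order, most severe first. Rank = index + 1.
SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "splice_donor_5th_base_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "start_retained_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "feature_elongation",
    "regulatory_region_variant",
    "feature_truncation",
    "intergenic_variant",
)


class SeverityOrder:
    """Total order over the SO consequence vocabulary (rank 1 = most severe)."""

    def __init__(self, terms: Sequence[str] = SEVERITY_ORDER):
        if len(set(terms)) != len(terms):
            raise ConfigurationError("severity order contains duplicate terms")
        self._rank = {t: i + 1 for i, t in enumerate(terms)}
        self.terms = tuple(terms)

    def rank(self, term: str) -> int:
        try:
            return self._rank[term]
        except KeyError:
            raise VocabularyError(f"unknown consequence term: {term!r}") from None

    def __contains__(self, term: str) -> bool:
        return term in self._rank

    def __len__(self) -> int:
        return len(self.terms)


DEFAULT_ORDER = SeverityOrder()


@dataclass(frozen=True)
class MaskDefinition:
    mask_id: str
    terms: frozenset[str]

    def __contains__(self, term: str) -> bool:
        return term in self.terms


def default_masks(include_transcript_amplification: bool = True) -> dict[str, MaskDefinition]:
    """The three annotation masks.

    ``include_transcript_amplification`` toggles the one term whose M1
    membership is ambiguous in the source material; the inclusive definition
    is the default.
    """
    m1 = {
        "transcript_ablation",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
    }
    if include_transcript_amplification:
        m1.add("transcript_amplification")
    masks = {
        "M1": MaskDefinition("M1", frozenset(m1)),
        "M2": MaskDefinition(
            "M2",
            frozenset(
                {
                    "inframe_insertion",
                    "inframe_deletion",
                    "missense_variant",
                    "protein_altering_variant",
                }
            ),
        ),
        "M3": MaskDefinition(
            "M3",
            frozenset(
                {
                    "splice_acceptor_variant",
                    "splice_donor_variant",
                    "splice_donor_5th_base_variant",
                    "splice_region_variant",
                    "splice_donor_region_variant",
                    "splice_polypyrimidine_tract_variant",
                }
            ),
        ),
    }
    return masks


DEFAULT_MASKS = default_masks()
MASK_IDS = ("M1", "M2", "M3")


def most_severe(terms: Iterable[str], order: SeverityOrder = DEFAULT_ORDER) -> str:
    """Pick the most severe term (minimal rank) from a non-empty term set."""
    terms = list(terms)
    if not terms:
        raise InputError("most_severe requires a non-empty term set")
    return min(terms, key=order.rank)


def assign_mask(
    term: str,
    masks: Mapping[str, MaskDefinition] = DEFAULT_MASKS,
    order: SeverityOrder = DEFAULT_ORDER,
) -> Optional[str]:
    """Return the id of the unique mask containing ``term``, or ``None``."""
    order.rank(term)  # vocabulary check
    hits = [mid for mid, m in masks.items() if term in m]
    if len(hits) > 1:
        raise ConfigurationError(f"term {term!r} belongs to multiple masks: {hits}")
    return hits[0] if hits else None


def decompose_multiallelic(record: VcfRecord) -> list[VcfRecord]:
    """Split a multi-allelic record into one bi-allelic record per ALT allele.

    Per-sample allele counts are conserved: in the record for ALT k, each
    original allele equal to k maps to allele 1, every other non-missing
    allele maps to 0, and missing alleles stay missing.
    """
    if record.n_alts < 1:
        raise InputError(f"record {record.vid} has no alternate allele")
    if record.n_alts == 1:
        return [record]
    out = []
    for k in range(record.n_alts):
        allele = k + 1
        gts: list[tuple[Optional[int], Optional[int]]] = []
        for i, (a1, a2) in enumerate(record.genotypes):
            for a in (a1, a2):
                if a is not None and not (0 <= a <= record.n_alts):
                    raise VocabularyError(
                        f"record {record.vid}, sample index {i}: allele index {a} out of range"
                    )
            b1 = None if a1 is None else int(a1 == allele)
            b2 = None if a2 is None else int(a2 == allele)
            gts.append((b1, b2))
        out.append(
            VcfRecord(
                chrom=record.chrom,
                pos=record.pos,
                vid=f"{record.vid}_alt{allele}",
                ref=record.ref,
                alts=(record.alts[k],),
                genotypes=gts,
            )
        )
    return out


@dataclass
class AnnotatedVariant:
    """A bi-allelic variant with its gene, consequence terms and mask call."""

    vid: str
    gene: str
    terms: frozenset[str]
    most_severe_term: str
    mask: Optional[str]
    alt_count: int = 0
    af: float = 0.0
    maf: float = 0.0


def annotate_variants(
    annotations: pd.DataFrame,
    order: SeverityOrder = DEFAULT_ORDER,
    masks: Mapping[str, MaskDefinition] = DEFAULT_MASKS,
    most_severe_only: bool = True,
) -> list[AnnotatedVariant]:
    """Turn an annotation table into mask-assigned variants.

    ``annotations`` needs columns ``variant_id``, ``gene`` and
    ``consequence_terms`` (comma-separated). One output per row, so a variant
    annotated to several genes contributes once per gene.

    With ``most_severe_only`` (default) the mask is determined solely by the
    most severe term; otherwise the variant takes the mask of the most severe
    term that belongs to any mask.
    """
    required = {"variant_id", "gene", "consequence_terms"}
    if not required.issubset(annotations.columns):
        raise InputError(f"annotation table needs columns {sorted(required)}")
    out = []
    for row in annotations.itertuples(index=False):
        terms = frozenset(t.strip() for t in str(row.consequence_terms).split(",") if t.strip())
        top = most_severe(terms, order)
        if most_severe_only:
            mask = assign_mask(top, masks, order)
        else:
            masked = [t for t in sorted(terms, key=order.rank) if assign_mask(t, masks, order)]
            mask = assign_mask(masked[0], masks, order) if masked else None
        out.append(
            AnnotatedVariant(
                vid=str(row.variant_id),
                gene=str(row.gene),
                terms=terms,
                most_severe_term=top,
                mask=mask,
            )
        )
    return out


def allele_frequencies(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alt-allele counts, frequencies and MAFs from a dosage matrix.

    Missing entries (:data:`MISSING`) are excluded from both numerator and
    denominator. MAF folds frequencies above 0.5.
    """
    d = np.asarray(dosages)
    obs = d != MISSING
    ac = np.where(obs, d, 0).sum(axis=0).astype(float)
    an = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / an, 0.0)
    maf = np.minimum(af, 1.0 - af)
    return ac.astype(int), af, maf


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density evaluated at MAF -- the standard rare-upweighting."""
    from scipy.stats import beta as beta_dist

    maf = np.asarray(maf, dtype=float)
    # Guard the density at MAF=0 (finite for a>=1).
    return beta_dist.pdf(np.clip(maf, 1e-12, 1 - 1e-12), a, b)


@dataclass
class QualifyingVariantSet:
    """Gene x mask dosage matrix with weights and MAFs for aggregation tests.

    ``genotypes`` holds clean 0/1/2 dosages: missing entries were imputed to
    0 at construction and their count is kept in ``n_missing_imputed``.
    """

    gene: str
    mask: str
    genotypes: np.ndarray  # samples x variants, int8, values 0/1/2
    variant_ids: list[str]
    maf: np.ndarray
    weights: np.ndarray
    n_missing_imputed: int = 0

    def __post_init__(self):
        if self.genotypes.ndim != 2:
            raise InputError("genotype matrix must be 2-D (samples x variants)")
        if self.genotypes.shape[1] != len(self.variant_ids):
            raise InputError("variant id count does not match genotype columns")
        if np.any(self.weights <= 0):
            raise InputError("weights must be positive")
        if np.any(self.genotypes.sum(axis=0) == 0):
            raise InputError("qualifying set contains an all-zero dosage column")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def carrier_flags(self) -> np.ndarray:
        return (self.genotypes >= 1).any(axis=1)

    @property
    def n_carriers(self) -> int:
        return int(self.carrier_flags.sum())


def build_qualifying_sets(
    variants: Sequence[AnnotatedVariant],
    genotypes: np.ndarray,
    maf_threshold: float = 0.01,
    weight_params: tuple[float, float] = (1.0, 25.0),
) -> dict[tuple[str, str], QualifyingVariantSet]:
    """Group rare, mask-assigned variants into per-(gene, mask) sets.

    ``genotypes`` columns align with ``variants`` (one column per entry; a
    variant annotated to several genes must be repeated with its column).
    A variant enters set (g, m) iff gene == g, mask == m and MAF strictly
    below ``maf_threshold``. Empty sets are omitted.
    """
    if not 0 < maf_threshold <= 0.5:
        raise ConfigurationError("maf_threshold must be in (0, 0.5]")
    genotypes = np.asarray(genotypes)
    if genotypes.shape[1] != len(variants):
        raise InputError(
            f"{len(variants)} variants but {genotypes.shape[1]} genotype columns"
        )
    ac, af, maf = allele_frequencies(genotypes)

    groups: dict[tuple[str, str], list[int]] = {}
    for j, v in enumerate(variants):
        v.alt_count = int(ac[j])
        v.af = float(af[j])
        v.maf = float(maf[j])
        if v.mask is None or not (v.maf < maf_threshold) or ac[j] == 0:
            continue
        groups.setdefault((v.gene, v.mask), []).append(j)

    out: dict[tuple[str, str], QualifyingVariantSet] = {}
    for (gene, mask), idx in groups.items():
        sub = genotypes[:, idx]
        n_missing = int((sub == MISSING).sum())
        if n_missing:
            sub = np.where(sub == MISSING, 0, sub)
        keep = sub.sum(axis=0) > 0
        if not keep.any():
            continue
        sub = np.ascontiguousarray(sub[:, keep], dtype=np.int8)
        kept_idx = [i for i, k in zip(idx, keep) if k]
        m = maf[kept_idx]
        out[(gene, mask)] = QualifyingVariantSet(
            gene=gene,
            mask=mask,
            genotypes=sub,
            variant_ids=[variants[i].vid for i in kept_idx],
            maf=m,
            weights=beta_maf_weights(m, *weight_params),
            n_missing_imputed=n_missing,
        )
    return out


def sets_summary(qsets: Mapping[tuple[str, str], QualifyingVariantSet]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "mask": s.mask,
            "n_variants": s.n_variants,
            "n_carriers": s.n_carriers,
            "variant_ids": ",".join(s.variant_ids),
        }
        for s in qsets.values()
    ]
    return pd.DataFrame(rows, columns=["gene", "mask", "n_variants", "n_carriers", "variant_ids"])
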