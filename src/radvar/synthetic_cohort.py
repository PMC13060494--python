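"""Seeded synthetic multi-ancestry cohort generator.

Produces genotypes, annotations, phenotypes (with covariates and harmonized
traits) and allele-age tables with the statistical structure the downstream
analyses assume: a heavy rare tail with a controlled singleton fraction,
ancestry-concentrated carrier draws, planted risk/protective genes acting
through a per-allele logistic model, and case/carrier-shifted traits.

All randomness flows from one seed through named sub-streams, so identical
config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import vcfio
from .consequence_masks import MASK_IDS
from .exceptions import ConfigurationError, InputError

_EXTRA_TERMS = ("synonymous_variant", "intron_variant", "non_coding_transcript_variant")
_MASK_TERMS = {
    "M1": ("stop_gained", "frameshift_variant", "stop_lost", "start_lost"),
    "M2": ("missense_variant", "inframe_insertion", "inframe_deletion",
           "protein_altering_variant"),
    "M3": ("splice_acceptor_variant", "splice_donor_variant", "splice_region_variant",
           "splice_donor_5th_base_variant"),
    "none": ("synonymous_variant", "intron_variant"),
}


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    mask: str
    effect: float  # per-allele log-odds magnitude
    direction: str = "risk"  # risk | protective
    concentration: Optional[float] = None  # overrides the global ancestry_concentration

    @property
    def beta(self) -> float:
        return abs(self.effect) * (1.0 if self.direction == "risk" else -1.0)


@dataclass(frozen=True)
class SimTraitSpec:
    name: str
    kind: str  # binary | quantitative | ordinal
    carrier_shift: float = 0.0
    case_shift: float = 0.0


@dataclass
class CohortConfig:
    n_per_ancestry: dict[str, int]
    case_fraction_per_ancestry: dict[str, float]
    n_genes: int = 50
    variants_per_gene_mean: float = 6.0
    planted_genes: list[PlantedGene] = field(default_factory=list)
    ancestry_concentration: float = 0.5
    singleton_fraction_target: float = 0.5139
    trait_specs: list[SimTraitSpec] = field(default_factory=list)
    seed: int = 0
    max_carriers: int = 50
    hom_fraction: float = 0.02
    missing_rate: float = 0.0
    trait_missing_rate: float = 0.0
    mask_probs: dict[str, float] = field(
        default_factory=lambda: {"M1": 0.15, "M2": 0.45, "M3": 0.25, "none": 0.15}
    )

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_ancestry.values()):
            raise ConfigurationError("ancestry sample counts must be >= 0")
        for label, frac in self.case_fraction_per_ancestry.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"case fraction for {label} outside [0, 1]")
            if frac > 0 and self.n_per_ancestry.get(label, 0) == 0:
                raise ConfigurationError(
                    f"ancestry {label!r} has zero samples but nonzero case fraction"
                )
        if self.n_genes < 0 or self.variants_per_gene_mean < 1:
            raise ConfigurationError("need n_genes >= 0 and variants_per_gene_mean >= 1")
        for frac_name in ("ancestry_concentration", "singleton_fraction_target",
                          "hom_fraction", "missing_rate", "trait_missing_rate"):
            if not 0 <= getattr(self, frac_name) <= 1:
                raise ConfigurationError(f"{frac_name} outside [0, 1]")
        genes = set(self.gene_ids())
        for pg in self.planted_genes:
            if pg.gene not in genes:
                raise ConfigurationError(f"planted gene {pg.gene!r} is not a generated gene id")
            if pg.mask not in MASK_IDS:
                raise ConfigurationError(f"planted gene {pg.gene!r} references unknown mask "
                                         f"{pg.mask!r}")
            if pg.direction not in ("risk", "protective"):
                raise ConfigurationError(f"unknown planted direction {pg.direction!r}")
            if pg.concentration is not None and not 0 <= pg.concentration <= 1:
                raise ConfigurationError(
                    f"planted gene {pg.gene!r} concentration outside [0, 1]"
                )
        for ts in self.trait_specs:
            if ts.kind not in ("binary", "quantitative", "ordinal"):
                raise ConfigurationError(f"unknown trait kind {ts.kind!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["planted_genes"] = [PlantedGene(**pg) for pg in d.get("planted_genes", [])]
        d["trait_specs"] = [SimTraitSpec(**ts) for ts in d.get("trait_specs", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    samples: pd.DataFrame  # sample_id, ancestry, AD, covariates, traits
    genotypes: np.ndarray  # samples x variants, int8; -1 = missing
    variant_ids: list[str]
    annotations: pd.DataFrame  # variant_id, gene, consequence_terms
    ages: pd.DataFrame  # variant_id, age, lower, upper
    config: Optional[CohortConfig] = None

    def __post_init__(self):
        if self.samples["sample_id"].duplicated().any():
            raise InputError("duplicate sample ids")
        if self.genotypes.shape != (len(self.samples), len(self.variant_ids)):
            raise InputError("genotype matrix shape mismatch")
        vals = np.unique(self.genotypes)
        if not np.isin(vals, (-1, 0, 1, 2)).all():
            raise InputError("dosages must be in {0, 1, 2, missing}")
        anno_ids = self.annotations["variant_id"]
        if sorted(anno_ids) != sorted(self.variant_ids):
            raise InputError("annotation variant ids do not match genotype columns")

    @property
    def case_status(self) -> np.ndarray:
        return self.samples["AD"].to_numpy(dtype=float)

    @property
    def ancestry(self) -> np.ndarray:
        return self.samples["ancestry"].to_numpy()

    def covariate_matrix(self) -> np.ndarray:
        cols = ["age", "sex", "platform", "pcr"] + [f"PC{i}" for i in range(1, 21)]
        return self.samples[cols].to_numpy(dtype=float)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a cohort according to the config; fully seed-deterministic."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_anno, rng_pheno, rng_trait, rng_age = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    ancestries = list(config.n_per_ancestry)
    counts = np.array([config.n_per_ancestry[a] for a in ancestries])
    n = int(counts.sum())
    labels = np.repeat(ancestries, counts)
    sample_ids = [f"S{i:06d}" for i in range(n)]
    anc_index = {a: np.where(labels == a)[0] for a in ancestries}
    anc_weights = counts / counts.sum() if n else counts

    # --- genotypes + annotations -------------------------------------------
    gene_ids = config.gene_ids()
    planted_by_gene = {pg.gene: pg for pg in config.planted_genes}
    mask_names = list(config.mask_probs)
    mask_p = np.array([config.mask_probs[m] for m in mask_names], dtype=float)
    mask_p = mask_p / mask_p.sum()

    variant_ids: list[str] = []
    anno_rows: list[dict] = []
    geno_cols: list[np.ndarray] = []
    positions: list[tuple[str, int]] = []
    planted_variant_idx: dict[str, list[int]] = {pg.gene: [] for pg in config.planted_genes}

    p_single = max(config.singleton_fraction_target, 1e-9)
    vidx = 0
    for gi, gene in enumerate(gene_ids):
        m_g = 1 + rng_geno.poisson(max(config.variants_per_gene_mean - 1.0, 0.0))
        for j in range(m_g):
            planted = planted_by_gene.get(gene)
            if planted is not None:
                mask = planted.mask
            else:
                mask = mask_names[rng_geno.choice(len(mask_names), p=mask_p)]
            top = _MASK_TERMS[mask][rng_anno.choice(len(_MASK_TERMS[mask]))]
            terms = [top]
            if rng_anno.random() < 0.4:
                extra = _EXTRA_TERMS[rng_anno.choice(len(_EXTRA_TERMS))]
                if extra != top:
                    terms.append(extra)

            k = int(min(rng_geno.geometric(p_single), config.max_carriers, n))
            col = np.zeros(n, dtype=np.int8)
            conc = config.ancestry_concentration
            if planted is not None and planted.concentration is not None:
                conc = planted.concentration
            if rng_geno.random() < conc:
                a = ancestries[rng_geno.choice(len(ancestries), p=anc_weights)]
                pool = anc_index[a]
                kk = min(k, len(pool))
                carriers = rng_geno.choice(pool, size=kk, replace=False)
            else:
                kk = min(k, n)
                carriers = rng_geno.choice(n, size=kk, replace=False)
            col[carriers] = 1
            if kk >= 2 and config.hom_fraction > 0:
                hom = carriers[rng_geno.random(kk) < config.hom_fraction]
                col[hom] = 2
            if config.missing_rate > 0:
                miss = rng_geno.random(n) < config.missing_rate
                miss[carriers] = False
                col[miss] = vcfio.MISSING

            vid = f"v{vidx:06d}"
            vidx += 1
            variant_ids.append(vid)
            geno_cols.append(col)
            anno_rows.append(
                {"variant_id": vid, "gene": gene, "consequence_terms": ",".join(terms)}
            )
            positions.append(("1", gi * 10_000 + j + 1))
            if planted is not None:
                planted_variant_idx[gene].append(len(geno_cols) - 1)

    genotypes = (
        np.stack(geno_cols, axis=1) if geno_cols else np.zeros((n, 0), dtype=np.int8)
    )
    annotations = pd.DataFrame(anno_rows, columns=["variant_id", "gene", "consequence_terms"])
    annotations["chrom"] = [p[0] for p in positions]
    annotations["pos"] = [p[1] for p in positions]

    # --- phenotypes --------------------------------------------------------
    eta = np.zeros(n)
    for a in ancestries:
        frac = config.case_fraction_per_ancestry.get(a, 0.0)
        frac = min(max(frac, 1e-9), 1 - 1e-9)
        eta[anc_index[a]] = math.log(frac / (1 - frac))
    clean = np.where(genotypes == vcfio.MISSING, 0, genotypes)
    for pg in config.planted_genes:
        idx = planted_variant_idx[pg.gene]
        if idx:
            eta = eta + pg.beta * clean[:, idx].sum(axis=1)
    case = (rng_pheno.random(n) < _logistic(eta)).astype(np.int8)

    samples = pd.DataFrame({"sample_id": sample_ids, "ancestry": labels, "AD": case})
    samples["age"] = np.round(rng_pheno.normal(75.0, 8.0, n), 4)
    samples["sex"] = rng_pheno.integers(0, 2, n).astype(np.int8)
    samples["platform"] = rng_pheno.integers(0, 2, n).astype(np.int8)
    samples["pcr"] = rng_pheno.integers(0, 2, n).astype(np.int8)
    # Ancestry-shifted PCs so null-model adjustment has something to absorb.
    anc_pos = {a: i for i, a in enumerate(ancestries)}
    for k in range(1, 21):
        shift = np.array([3.0 if (anc_pos[a] % 20) == (k - 1) else 0.0 for a in labels])
        samples[f"PC{k}"] = np.round(shift + rng_pheno.normal(0.0, 1.0, n), 4)

    # --- traits ------------------------------------------------------------
    planted_carrier = np.zeros(n, dtype=bool)
    for pg in config.planted_genes:
        idx = planted_variant_idx[pg.gene]
        if idx:
            planted_carrier |= (clean[:, idx] >= 1).any(axis=1)
    for ts in config.trait_specs:
        shift = ts.case_shift * case + ts.carrier_shift * planted_carrier.astype(float)
        if ts.kind == "quantitative":
            vals = np.round(rng_trait.normal(0.0, 1.0, n) + shift, 4)
        elif ts.kind == "binary":
            vals = (rng_trait.random(n) < _logistic(-1.0 + shift)).astype(float)
        else:  # ordinal: threshold a latent Gaussian into 5 levels
            latent = rng_trait.normal(0.0, 1.0, n) + shift
            vals = np.digitize(latent, [-1.5, -0.5, 0.5, 1.5]).astype(float)
        if config.trait_missing_rate > 0:
            vals = np.where(rng_trait.random(n) < config.trait_missing_rate, np.nan, vals)
        samples[ts.name] = vals

    # --- allele ages -------------------------------------------------------
    ac = np.where(genotypes == vcfio.MISSING, 0, genotypes).sum(axis=0).astype(float)
    age = np.exp(rng_age.normal(np.log(30.0 * np.maximum(ac, 1) + 5.0), 0.6))
    r_lo = np.exp(np.abs(rng_age.normal(0.0, 0.5, len(ac)))) + 1e-6
    r_hi = np.exp(np.abs(rng_age.normal(0.0, 0.5, len(ac)))) + 1e-6
    ages = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "age": np.round(age, 4),
            "lower": np.round(age / r_lo, 4),
            "upper": np.round(age * r_hi, 4),
        }
    )

    return SimulatedCohort(
        samples=samples,
        genotypes=genotypes,
        variant_ids=variant_ids,
        annotations=annotations,
        ages=ages,
        config=config,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

VCF_NAME = "genotypes.vcf"
ANNO_NAME = "annotations.tsv"
PHENO_NAME = "phenotypes.tsv"
AGES_NAME = "ages.tsv"


def write_cohort(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + TSVs; round-trips through read_cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample_ids = list(cohort.samples["sample_id"])

    has_pos = {"chrom", "pos"}.issubset(cohort.annotations.columns)
    records = []
    for j, vid in enumerate(cohort.variant_ids):
        row = cohort.annotations.iloc[j]
        chrom = str(row["chrom"]) if has_pos else "1"
        pos = int(row["pos"]) if has_pos else j + 1
        gts = []
        for d in cohort.genotypes[:, j]:
            if d == vcfio.MISSING:
                gts.append((None, None))
            elif d == 0:
                gts.append((0, 0))
            elif d == 1:
                gts.append((0, 1))
            else:
                gts.append((1, 1))
        records.append(
            vcfio.VcfRecord(chrom=chrom, pos=pos, vid=vid, ref="A", alts=("G",), genotypes=gts)
        )
    paths = {
        "vcf": directory / VCF_NAME,
        "annotations": directory / ANNO_NAME,
        "phenotypes": directory / PHENO_NAME,
        "ages": directory / AGES_NAME,
    }
    vcfio.write_vcf(paths["vcf"], sample_ids, records)
    cohort.annotations.drop(columns=["chrom", "pos"], errors="ignore").to_csv(
        paths["annotations"], sep="\t", index=False
    )
    cohort.samples.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6g")
    cohort.ages.to_csv(paths["ages"], sep="\t", index=False, float_format="%.6g")
    return paths


def read_cohort(directory: str | Path) -> SimulatedCohort:
    """Read a written cohort back (config is not reconstructed)."""
    directory = Path(directory)
    sample_ids, records = vcfio.read_vcf(directory / VCF_NAME)
    genotypes = vcfio.dosage_matrix(records)
    variant_ids = [r.vid for r in records]
    annotations = pd.read_csv(directory / ANNO_NAME, sep="\t")
    samples = pd.read_csv(directory / PHENO_NAME, sep="\t")
    ages = pd.read_csv(directory / AGES_NAME, sep="\t")
    if list(samples["sample_id"]) != sample_ids:
        raise InputError("phenotype sample order does not match VCF")
    return SimulatedCohort(
        samples=samples,
        genotypes=genotypes,
        variant_ids=variant_ids,
        annotations=annotations,
        ages=ages,
    )
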