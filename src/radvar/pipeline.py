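"""End-to-end orchestration: cohort -> masks -> tests -> carriers -> ages.

Runs the stages in dependency order under one configuration, writes one TSV
per stage plus a JSON manifest (config hash, seed, per-stage row counts and
the cohort summary), and computes the significant-gene list against the
Bonferroni threshold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import allele_age_summary as ages_mod
from . import ancestry_concentration as conc_mod
from . import carrier_analysis as carrier_mod
from .aggregation_tests import (
    DEFAULT_RHO_GRID,
    TEST_NAMES,
    bonferroni_threshold,
    fit_null,
    run_gene_tests,
)
from .consequence_masks import annotate_variants, build_qualifying_sets, sets_summary
from .exceptions import ConfigurationError, PipelineError
from .synthetic_cohort import CohortConfig, SimulatedCohort, read_cohort, simulate_cohort, \
    write_cohort

log = logging.getLogger("radvar.pipeline")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | files
    cohort: Optional[dict] = None  # CohortConfig fields (simulate mode)
    input_dir: Optional[str] = None  # cohort directory (files mode)
    out_dir: str = "radvar_out"
    maf_threshold: float = 0.01
    masks: Sequence[str] = ("M1", "M2", "M3")
    tests: Sequence[str] = TEST_NAMES
    traits: Optional[Sequence[str]] = None  # None = all registered traits found
    alpha: float = 0.05
    n_genes_override: Optional[int] = None  # Bonferroni denominator override
    min_carriers: int = 2
    dominance_threshold: float = 0.75
    max_ci_ratio: float = 10.0
    max_age: float = 500_000.0
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if not self.input_dir or not Path(self.input_dir).is_dir():
                raise ConfigurationError("files mode needs an existing input_dir")
        elif self.cohort is None:
            raise ConfigurationError("simulate mode needs a cohort section")
        if not 0 < self.maf_threshold <= 0.5:
            raise ConfigurationError("maf_threshold outside (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def cohort_summary(case_status: np.ndarray, ancestry: Sequence[str]) -> dict:
    """Sample-composition percentages used in run manifests."""
    case = np.asarray(case_status, dtype=float)
    known = np.isfinite(case) & (case >= 0)
    n = len(case)
    anc = pd.Series(ancestry).value_counts().to_dict()
    return summarize_cohort_counts(
        n_cases=int((case[known] == 1).sum()),
        n_controls=int((case[known] == 0).sum()),
        n_total=n,
        ancestry_counts={str(k): int(v) for k, v in anc.items()},
    )


def summarize_cohort_counts(
    n_cases: int, n_controls: int, n_total: int, ancestry_counts: Optional[dict] = None
) -> dict:
    """Percentages and ratios from raw cohort counts."""
    if n_total <= 0:
        raise ConfigurationError("total sample count must be positive")
    out = {
        "n_total": n_total,
        "n_cases": n_cases,
        "n_controls": n_controls,
        "case_pct": 100.0 * n_cases / n_total,
        "control_pct": 100.0 * n_controls / n_total,
        "case_control_ratio": (n_cases / n_controls) if n_controls else float("inf"),
    }
    if ancestry_counts:
        out["ancestry_pct"] = {
            k: 100.0 * v / n_total for k, v in sorted(ancestry_counts.items())
        }
    return out


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    d.pop("out_dir", None)  # output location must not change the run identity
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                try:
                    res = fn(*a, **kw)
                except Exception as exc:  # noqa: BLE001 - abort with stage name
                    _suffix_partials(out_dir)
                    raise PipelineError(name, exc) from exc
                return res

            return run

        return deco

    # ---- stage: cohort ----
    @stage("cohort")
    def _cohort() -> SimulatedCohort:
        if config.mode == "simulate":
            cc = dict(config.cohort)
            cc.setdefault("seed", config.seed)
            cohort = simulate_cohort(CohortConfig.from_dict(cc))
            write_cohort(cohort, out_dir / "cohort")
            return cohort
        return read_cohort(config.input_dir)

    cohort = _cohort()
    manifest["cohort_summary"] = cohort_summary(cohort.case_status, cohort.ancestry)
    manifest["stages"]["cohort"] = {
        "n_samples": int(len(cohort.samples)),
        "n_variants": int(len(cohort.variant_ids)),
    }
    log.info("cohort: %d samples, %d variants", len(cohort.samples), len(cohort.variant_ids))

    # ---- stage: masks ----
    @stage("mask")
    def _mask():
        variants = annotate_variants(cohort.annotations)
        qsets = build_qualifying_sets(variants, cohort.genotypes, config.maf_threshold)
        qsets = {k: v for k, v in qsets.items() if k[1] in set(config.masks)}
        sets_summary(qsets).to_csv(out_dir / "qualifying_sets.tsv", sep="\t", index=False)
        return variants, qsets

    variants, qsets = _mask()
    n_qualifying = sum(s.n_variants for s in qsets.values())
    manifest["stages"]["mask"] = {
        "n_annotated": len(variants),
        "n_sets": len(qsets),
        "n_qualifying_variants": n_qualifying,
    }
    log.info("mask: %d sets, %d qualifying variants", len(qsets), n_qualifying)

    # ---- stage: tests ----
    @stage("test")
    def _test():
        null = fit_null(cohort.case_status, cohort.covariate_matrix(), kind="binary")
        rows = []
        for key in sorted(qsets):
            for r in run_gene_tests(qsets[key], null, config.tests, config.rho_grid):
                rows.append(
                    {
                        "gene": r.gene, "mask": r.mask, "n_variants": r.n_variants,
                        "n_carriers": r.n_carriers, "test": r.test,
                        "statistic": r.statistic, "p": r.p,
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=["gene", "mask", "n_variants", "n_carriers", "test", "statistic", "p"],
        ).sort_values("p", kind="mergesort", ignore_index=True)
        df.to_csv(out_dir / "association_results.tsv", sep="\t", index=False,
                  float_format="%.6g")
        return null, df

    null, results = _test()
    n_genes_tested = results["gene"].nunique() if len(results) else 0
    denom = config.n_genes_override or max(n_genes_tested, 1)
    threshold = bonferroni_threshold(config.alpha, denom)
    sig = (
        results[results["p"] < threshold]["gene"].drop_duplicates().sort_values()
        if len(results)
        else pd.Series([], dtype=str)
    )
    sig.to_frame(name="gene").to_csv(out_dir / "significant_genes.tsv", sep="\t", index=False)
    manifest["stages"]["test"] = {
        "n_results": int(len(results)),
        "n_genes_tested": int(n_genes_tested),
        "bonferroni_threshold": threshold,
        "n_significant_genes": int(len(sig)),
    }
    log.info("test: %d results, threshold %.3g, %d significant genes",
             len(results), threshold, len(sig))

    # ---- stage: traits ----
    @stage("traits")
    def _traits():
        registry = carrier_mod.DEFAULT_TRAITS
        if config.traits is not None:
            registry = {k: v for k, v in registry.items() if k in set(config.traits)}
        cells = carrier_mod.gene_trait_table(qsets, cohort.samples, registry)
        cells.to_csv(out_dir / "trait_cells.tsv", sep="\t", index=False, float_format="%.6g")
        return cells

    cells = _traits()
    manifest["stages"]["traits"] = {"n_cells": int(len(cells))}

    # ---- stage: concentration ----
    @stage("concentration")
    def _concentration():
        qual_idx = [j for j, v in enumerate(variants)
                    if v.mask in set(config.masks) and v.maf < config.maf_threshold
                    and v.alt_count > 0]
        thr = conc_mod.EnrichmentThresholds.from_cohort(
            cohort.case_status, dominance=config.dominance_threshold
        )
        profiles = conc_mod.build_profiles(
            [variants[j].vid for j in qual_idx],
            np.where(cohort.genotypes[:, qual_idx] < 0, 0, cohort.genotypes[:, qual_idx]),
            cohort.case_status,
            cohort.ancestry,
            min_carriers=config.min_carriers,
        )
        summary = conc_mod.compare_concentration(profiles, thr)
        conc_mod.profiles_table(profiles).to_csv(
            out_dir / "carrier_profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(out_dir / "concentration_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return profiles, summary

    profiles, conc_summary = _concentration()
    manifest["stages"]["concentration"] = {
        "n_profiles": len(profiles),
        "n_enriched": conc_summary.get("n_enriched", 0),
    }

    # ---- stage: ages ----
    @stage("ages")
    def _ages():
        recs = [
            ages_mod.AgeRecord(str(r.variant_id), "all", float(r.age), float(r.lower),
                               float(r.upper))
            for r in cohort.ages.itertuples(index=False)
            if 0 < float(r.lower) <= float(r.age) <= float(r.upper)
        ]
        kept, tally = ages_mod.filter_ages(
            recs, ages_mod.AgeFilterConfig(config.max_ci_ratio, config.max_age)
        )
        ages_mod.group_summary(kept).to_csv(
            out_dir / "age_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        return kept, tally

    kept_ages, age_tally = _ages()
    manifest["stages"]["ages"] = {"n_retained": len(kept_ages), "rejections": age_tally}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _suffix_partials(out_dir: Path) -> None:
    """Rename stage outputs of an aborted run to *.partial."""
    for p in out_dir.glob("*.tsv"):
        p.rename(p.with_suffix(p.suffix + ".partial"))
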