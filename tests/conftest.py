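import numpy as np
import pytest

from radvar.aggregation_tests import fit_null
from radvar.consequence_masks import QualifyingVariantSet, beta_maf_weights
from radvar.synthetic_cohort import CohortConfig, simulate_cohort


def make_qset(genotypes, gene="G0000", mask="M2", weights=None):
    """Wrap a dosage matrix as a qualifying set with Beta(1,25) weights."""
    G = np.asarray(genotypes, dtype=np.int8)
    n = G.shape[0]
    ac = G.sum(axis=0)
    maf = np.minimum(ac / (2 * n), 1 - ac / (2 * n))
    if weights is None:
        weights = beta_maf_weights(maf)
    return QualifyingVariantSet(
        gene=gene,
        mask=mask,
        genotypes=G,
        variant_ids=[f"v{j}" for j in range(G.shape[1])],
        maf=np.asarray(maf, dtype=float),
        weights=np.asarray(weights, dtype=float),
    )


def random_rare_genotypes(rng, n, m, mac_range=(5, 25)):
    """Dosage matrix with per-variant MAC uniform in mac_range (het carriers)."""
    G = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        k = int(rng.integers(mac_range[0], mac_range[1] + 1))
        G[rng.choice(n, size=k, replace=False), j] = 1
    return G


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_per_ancestry={"EUR": 400, "AFR": 300, "EAS": 100},
        case_fraction_per_ancestry={"EUR": 0.3, "AFR": 0.25, "EAS": 0.3},
        n_genes=30,
        variants_per_gene_mean=6.0,
        ancestry_concentration=0.6,
        trait_specs=[],
        seed=11,
        missing_rate=0.002,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def balanced_null():
    """Null model on a balanced binary outcome with a few covariates."""
    rng = np.random.default_rng(5)
    n = 600
    X = rng.normal(size=(n, 3))
    y = rng.integers(0, 2, n).astype(float)
    return fit_null(y, X, kind="binary"), X, y, n
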