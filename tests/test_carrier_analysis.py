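import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from radvar.carrier_analysis import (
    CarrierTable,
    DEFAULT_TRAITS,
    TraitSpec,
    carrier_status,
    gene_trait_table,
    hodges_lehmann,
    odds_ratio_wald,
    standardize_direction,
    stratified_or,
    trait_test,
)
from radvar.exceptions import EmptyStratumError, InputError, InsufficientDataError

from conftest import make_qset


class TestCarrierStatus:
    def test_het_hom_and_reference(self):
        G = np.array([[1, 0], [2, 1], [0, 0]], dtype=np.int8)
        flags = carrier_status(make_qset(G))
        assert list(flags) == [True, True, False]


class TestCarrierTable:
    def test_from_flags_with_unknown_status(self):
        carrier = np.array([True, True, False, False, True])
        case = np.array([1.0, 0.0, 1.0, 0.0, np.nan])
        t = CarrierTable.from_flags(carrier, case)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_correction_only_on_zero_cell(self):
        t = CarrierTable(3, 4, 5, 6)
        assert t.continuity_corrected() is t
        t0 = CarrierTable(0, 4, 5, 6).continuity_corrected()
        assert t0.corrected
        assert (t0.a, t0.b, t0.c, t0.d) == (0.5, 4.5, 5.5, 6.5)


class TestOddsRatio:
    def test_hand_arithmetic(self):
        est = odds_ratio_wald(CarrierTable(20, 80, 10, 90))
        assert est.odds_ratio == pytest.approx(2.25)
        assert not est.corrected

    def test_zero_cell_corrected(self):
        est = odds_ratio_wald(CarrierTable(0, 100, 5, 95))
        assert est.corrected
        assert est.odds_ratio == pytest.approx(47.75 / 552.75, rel=1e-12)

    def test_symmetric_table(self):
        est = odds_ratio_wald(CarrierTable(10, 10, 10, 10))
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.ci_lower * est.ci_upper == pytest.approx(1.0, rel=1e-10)

    def test_ci_contains_or(self):
        est = odds_ratio_wald(CarrierTable(7, 43, 3, 47))
        assert est.ci_lower <= est.odds_ratio <= est.ci_upper

    def test_empty_stratum(self):
        with pytest.raises(EmptyStratumError):
            odds_ratio_wald(CarrierTable(0, 0, 5, 95))


class TestStratifiedOR:
    def test_single_ancestry_degenerate(self):
        rng = np.random.default_rng(0)
        carrier = rng.random(200) < 0.1
        case = (rng.random(200) < 0.4).astype(float)
        per, pooled, skipped = stratified_or(carrier, case, ["EUR"] * 200)
        assert per["EUR"].odds_ratio == pytest.approx(pooled.odds_ratio)
        assert skipped == []

    def test_identical_strata_match_pooled(self):
        carrier = np.array([True] * 20 + [False] * 80 + [True] * 10 + [False] * 90)
        case = np.array([1.0] * 100 + [0.0] * 100)
        both = np.concatenate([carrier, carrier])
        cases = np.concatenate([case, case])
        anc = ["A"] * 200 + ["B"] * 200
        per, pooled, _ = stratified_or(both, cases, anc)
        assert per["A"].odds_ratio == pytest.approx(per["B"].odds_ratio)
        assert pooled.odds_ratio == pytest.approx(per["A"].odds_ratio)

    def test_carrier_count_conservation(self):
        rng = np.random.default_rng(1)
        carrier = rng.random(300) < 0.15
        case = (rng.random(300) < 0.3).astype(float)
        anc = rng.choice(["A", "B", "C"], 300)
        per_counts = sum(int(np.sum(carrier[anc == a])) for a in "ABC")
        assert per_counts == int(carrier.sum())

    def test_planted_single_stratum_effect(self):
        rng = np.random.default_rng(2)
        n = 8000
        anc = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        carrier = rng.random(n) < 0.05
        p_case = np.where((anc == "A") & carrier, 0.75, 0.5)  # OR 3 in stratum A
        case = (rng.random(n) < p_case).astype(float)
        per, pooled, _ = stratified_or(carrier, case, anc)
        assert per["A"].ci_lower > 1.0
        assert per["B"].ci_lower < 1.0 < per["B"].ci_upper

    def test_empty_stratum_skipped_with_label(self):
        carrier = np.array([True, False, True, False])
        case = np.array([1.0, 1.0, 1.0, 0.0])  # stratum A: no controls
        anc = ["A", "A", "B", "B"]
        per, pooled, skipped = stratified_or(carrier, case, anc)
        assert skipped == ["A"] and "B" in per


class TestHodgesLehmann:
    def test_enumeration_example(self):
        assert hodges_lehmann([1, 2], [0, 1]) == 1.0

    def test_single_pair(self):
        assert hodges_lehmann([5], [3]) == 2.0

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=12),
        st.floats(-10, 10),
    )
    @settings(max_examples=60)
    def test_translation_equivariance(self, y, c):
        x = [v + c for v in y]
        assert hodges_lehmann(x, y) == pytest.approx(c, abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(size=14)
        brute = np.median([xi - yj for xi in x for yj in y])
        assert hodges_lehmann(x, y) == pytest.approx(brute)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            hodges_lehmann([], [1.0])

    def test_recovers_planted_shift(self):
        rng = np.random.default_rng(4)
        delta = 1.3
        x = rng.normal(delta, 1.0, 60)
        y = rng.normal(0.0, 1.0, 500)
        est = hodges_lehmann(x, y)
        boots = [
            hodges_lehmann(rng.choice(x, len(x)), rng.choice(y, len(y)))
            for _ in range(200)
        ]
        assert abs(est - delta) < 3 * np.std(boots)


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by conditional hypergeometric enumeration."""
    n1, n2, m1 = a + b, c + d, a + c
    denom = comb(n1 + n2, m1, exact=True)
    probs = {}
    for x in range(max(0, m1 - n2), min(m1, n1) + 1):
        probs[x] = comb(n1, x, exact=True) * comb(n2, m1 - x, exact=True) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def _wilcoxon_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs = stats.rankdata(pooled)[:nx].sum()
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        stats_all.append(stats.rankdata(pooled)[list(idx)].sum())
    stats_all = np.array(stats_all)
    mean = stats_all.mean()
    return float(np.mean(np.abs(stats_all - mean) >= abs(obs - mean) - 1e-12))


class TestTraitTest:
    def test_wilcoxon_exact_example(self):
        carrier = np.array([True] * 3 + [False] * 3)
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        spec = TraitSpec("Q", "quantitative", "higher-is-worse")
        cell = trait_test(carrier, vals, spec)
        assert cell.p == pytest.approx(0.1)
        assert cell.effect == pytest.approx(-3.0)

    def test_wilcoxon_matches_enumeration(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=4), rng.normal(size=5)
        carrier = np.array([True] * 4 + [False] * 5)
        spec = TraitSpec("Q", "quantitative", "higher-is-worse")
        cell = trait_test(carrier, np.concatenate([x, y]), spec)
        assert cell.p == pytest.approx(_wilcoxon_enumeration(x, y), abs=1e-9)

    def test_fisher_example(self):
        carrier = np.array([True] * 10 + [False] * 10)
        vals = np.array([1.0] * 3 + [0.0] * 7 + [1.0] * 7 + [0.0] * 3)
        spec = TraitSpec("B", "binary", "higher-is-worse")
        cell = trait_test(carrier, vals, spec)
        assert cell.p == pytest.approx(_fisher_enumeration(3, 7, 7, 3), rel=1e-6)
        assert cell.p == pytest.approx(0.179, abs=2e-3)

    def test_permutation_null_uniform(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=120)
        spec = TraitSpec("Q", "quantitative", "higher-is-worse")
        ps = []
        for _ in range(500):
            carrier = np.zeros(120, dtype=bool)
            carrier[rng.choice(120, 30, replace=False)] = True
            ps.append(trait_test(carrier, vals, spec).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_trait_untestable(self):
        carrier = np.array([True, True, False, False])
        cell = trait_test(carrier, np.ones(4), TraitSpec("Q", "quantitative",
                                                         "higher-is-worse"))
        assert cell.p is None
        assert "constant_trait" in cell.flags

    def test_low_carrier_flagged(self):
        rng = np.random.default_rng(7)
        carrier = np.zeros(50, dtype=bool)
        carrier[:3] = True
        cell = trait_test(carrier, rng.normal(size=50),
                          TraitSpec("Q", "quantitative", "higher-is-worse"))
        assert "low_carrier" in cell.flags
        assert cell.p is not None  # computed, not suppressed

    def test_missing_values_dropped(self):
        carrier = np.array([True, True, False, False, False])
        vals = np.array([1.0, np.nan, 0.0, 2.0, np.nan])
        cell = trait_test(carrier, vals, TraitSpec("Q", "quantitative",
                                                   "higher-is-worse"))
        assert cell.n_carrier == 1 and cell.n_noncarrier == 2


class TestStandardizeDirection:
    def test_lower_is_worse_downshift_adverse(self):
        spec = TraitSpec("Abeta42", "quantitative", "lower-is-worse")
        assert standardize_direction(0.01, -0.5, spec) == pytest.approx(2.0)

    def test_higher_is_worse_upshift_adverse(self):
        spec = TraitSpec("Braak", "ordinal", "higher-is-worse")
        assert standardize_direction(0.001, 0.7, spec) == pytest.approx(3.0)

    def test_p_one_zero_score(self):
        spec = TraitSpec("Q", "quantitative", "higher-is-worse")
        assert standardize_direction(1.0, 5.0, spec) == 0.0

    @given(st.floats(1e-10, 1.0, exclude_min=False), st.floats(-5, 5))
    @settings(max_examples=50)
    def test_direction_flip_antisymmetry(self, p, effect):
        if effect == 0:
            return
        hi = TraitSpec("Q", "quantitative", "higher-is-worse")
        lo = TraitSpec("Q", "quantitative", "lower-is-worse")
        assert standardize_direction(p, effect, hi) == pytest.approx(
            -standardize_direction(p, effect, lo)
        )


class TestTraitRegistry:
    def test_lower_is_worse_members(self):
        lows = {n for n, s in DEFAULT_TRAITS.items() if s.direction == "lower-is-worse"}
        assert lows == {"Age", "Age_AmongCase", "MEM", "EXF", "LAN", "VSP", "Abeta42"}

    def test_binary_members(self):
        bins = {n for n, s in DEFAULT_TRAITS.items() if s.kind == "binary"}
        assert bins == {"AD", "HS_S", "TDP43", "CVD_S"}


class TestGeneTraitTable:
    def test_long_format_and_among_case(self, small_cohort):
        import pandas as pd
        from radvar.consequence_masks import annotate_variants, build_qualifying_sets

        cohort = small_cohort
        variants = annotate_variants(cohort.annotations)
        qsets = build_qualifying_sets(variants, cohort.genotypes, 0.01)
        key = sorted(qsets)[0]
        rng = np.random.default_rng(8)
        pheno = cohort.samples.copy()
        pheno["Age"] = rng.normal(75, 8, len(pheno))
        traits = {
            "AD": DEFAULT_TRAITS["AD"],
            "Age": DEFAULT_TRAITS["Age"],
            "Age_AmongCase": DEFAULT_TRAITS["Age_AmongCase"],
        }
        cells = gene_trait_table({key: qsets[key]}, pheno, traits)
        assert set(cells.trait) == {"AD", "Age", "Age_AmongCase"}
        row = cells[cells.trait == "Age_AmongCase"].iloc[0]
        n_cases_carrying = int(
            (carrier_status(qsets[key]) & (pheno["AD"].to_numpy() == 1)).sum()
        )
        assert row.n_carrier == n_cases_carrying
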