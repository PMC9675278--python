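"""Diagnostics layer vs brute-force and independent library oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from methmark.stats import (
    ContingencyTable2x2,
    association_table,
    auc_mann_whitney,
    clopper_pearson,
    fisher_exact,
    kruskal_wallis,
    optimal_cutoff,
    performance_at_cutoff,
    roc_curve,
)


def auc_brute_force(scores, labels):
    cases = [s for s, l in zip(scores, labels) if l]
    controls = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def random_instance(rng, n_max=30):
    n1 = int(rng.integers(2, n_max))
    n0 = int(rng.integers(2, n_max))
    # integer-ish scores force ties
    scores = np.concatenate(
        [rng.normal(1.0, 1.0, n1), rng.normal(0.0, 1.0, n0)]
    ).round(1)
    labels = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
    return scores, labels


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([3.0, 4.0, 1.0, 2.0], [True, True, False, False])
        assert roc.auc == 1.0
        assert optimal_cutoff(roc) == pytest.approx(2.5)
        j = roc.sens + roc.spec - 1.0
        assert j.max() == pytest.approx(1.0)

    def test_all_tied_scores(self):
        roc = roc_curve([5.0] * 6, [True, True, True, False, False, False])
        assert roc.auc == 0.5
        assert optimal_cutoff(roc) == np.inf  # highest-specificity sentinel

    def test_pair_enumeration_example(self):
        # cases (3,5,7) vs controls (2,4,6): 6 winning pairs, no ties
        scores = [3, 5, 7, 2, 4, 6]
        labels = [True] * 3 + [False] * 3
        assert auc_brute_force(scores, labels) == pytest.approx(6.0 / 9)
        assert auc_mann_whitney(scores, labels) == pytest.approx(6.0 / 9)

    def test_pair_enumeration_with_ties(self):
        # cases (3,5,7) vs controls (3,4,6): 5 wins + one tie -> 5.5/9
        scores = [3, 5, 7, 3, 4, 6]
        labels = [True] * 3 + [False] * 3
        assert auc_brute_force(scores, labels) == pytest.approx(5.5 / 9)
        assert auc_mann_whitney(scores, labels) == pytest.approx(5.5 / 9)

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(25):
            scores, labels = random_instance(rng)
            auc = auc_mann_whitney(scores, labels)
            assert auc == pytest.approx(auc_brute_force(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_pair_counting_equals_trapezoid(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            scores, labels = random_instance(rng)
            roc = roc_curve(scores, labels)
            fpr = 1.0 - roc.spec
            trap = np.trapezoid(roc.sens[::-1], fpr[::-1])
            assert roc.auc == pytest.approx(trap, abs=1e-9)

    def test_sens_non_increasing_and_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        scores, labels = random_instance(rng, n_max=50)
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sens) <= 1e-12)
        lo, hi = roc.auc_ci
        assert 0.0 <= lo <= roc.auc <= hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])


def youden_exhaustive(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    distinct = np.unique(scores)
    cands = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    j = np.array(
        [
            (scores[labels] > t).mean() + (scores[~labels] <= t).mean() - 1.0
            for t in cands
        ]
    )
    ties = np.flatnonzero(j >= j.max() - 1e-12)
    return cands[ties[-1]]  # highest threshold = highest specificity


def test_optimal_cutoff_matches_exhaustive_search():
    rng = np.random.default_rng(3)
    for _ in range(50):
        scores, labels = random_instance(rng)
        roc = roc_curve(scores, labels)
        assert optimal_cutoff(roc) == youden_exhaustive(scores, labels)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (32, 37, (71.2, 95.5)),
            (98, 106, (85.7, 96.7)),
            (42, 55, (63.0, 86.8)),
        ],
    )
    def test_printed_interval_reproduction(self, k, n, expected):
        lo, hi = clopper_pearson(k, n, 0.95)
        assert (round(lo, 1), round(hi, 1)) == expected

    def test_boundaries(self):
        lo, hi = clopper_pearson(0, 10, 0.95)
        assert lo == 0.0 and hi < 100.0
        lo, hi = clopper_pearson(10, 10, 0.95)
        assert lo > 0.0 and hi == 100.0

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (50, 50), (0, 4), (12, 100)]:
            lo, hi = clopper_pearson(k, n, 0.95)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(100 * slo, abs=1e-9)
            assert hi == pytest.approx(100 * shi, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(1, 4, level=1.5)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((16, 10, 26, 2), 0.008),   # grade low/high x positive/negative
            ((37, 13, 5, 0), 0.324),    # stage Ta,T1 / T2-T4
            ((32, 11, 10, 2), 0.709),   # sex
            ((12, 7, 30, 6), 0.109),    # age < 65 / >= 65
        ],
    )
    def test_clinical_association_tables(self, table, expected):
        assert round(fisher_exact(ContingencyTable2x2(*table)), 3) == expected

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            cells = rng.integers(0, 25, 4)
            if cells.sum() == 0:
                continue
            ours = fisher_exact(ContingencyTable2x2(*map(int, cells)))
            theirs = sps.fisher_exact(cells.reshape(2, 2))[1]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b, c, d = map(int, rng.integers(0, 20, 4))
            p1 = fisher_exact(ContingencyTable2x2(a, b, c, d))
            p2 = fisher_exact(ContingencyTable2x2(d, c, b, a))
            assert p1 == pytest.approx(p2, abs=1e-12)
            assert 0.0 < p1 <= 1.0

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 5, 7)) == 1.0
        assert fisher_exact(ContingencyTable2x2(5, 0, 7, 0)) == 1.0


class TestKruskalWallis:
    def test_identical_groups_carry_no_signal(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_ranking_oracle_no_ties(self):
        # ranks 1..6; H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27.0 / 7.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [rng.integers(0, 6, rng.integers(3, 10)).astype(float)
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                continue
            h, p = kruskal_wallis(groups)
            sh, sp = sps.kruskal(*groups)
            assert h == pytest.approx(sh, abs=1e-10)
            assert p == pytest.approx(sp, abs=1e-10)

    def test_chi_square_p_close_to_permutation_null(self):
        groups = [[1.2, 3.4, 2.2, 4.1], [2.0, 5.5, 4.8, 6.1], [0.5, 1.1, 2.9, 1.8]]
        h_obs, p_chi = kruskal_wallis(groups)
        sizes = [len(g) for g in groups]
        pooled = np.concatenate([np.asarray(g) for g in groups])
        ranks = sps.rankdata(pooled)
        n = ranks.size
        rng = np.random.default_rng(11)
        n_perm = 100_000
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        permuted = ranks[perm]
        h = np.zeros(n_perm)
        start = 0
        for sz in sizes:
            h += permuted[:, start:start + sz].sum(axis=1) ** 2 / sz
            start += sz
        h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
        p_perm = (h >= h_obs - 1e-12).mean()
        assert p_chi == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestAssociationTable:
    def test_grade_strata_positivity(self, validation_cohort):
        records, calls = validation_cohort
        bca = [r for r in records if r.group == "BCa"]
        res = association_table(bca, calls, "grade")
        assert res.positivity == (61.5, 92.9)
        assert res.n == (26, 28)  # unknown-grade sample excluded
        assert res.p == 0.008

    def test_overall_positivity_from_column_sums(self, validation_cohort):
        records, calls = validation_cohort
        bca = [r for r in records if r.group == "BCa"]
        res = association_table(bca, calls, "sex")
        assert sum(res.positives) == 42
        assert round(100 * sum(res.positives) / sum(res.n), 1) == 76.4

    def test_all_negative_cohort(self, validation_cohort):
        records, _ = validation_cohort
        bca = [r for r in records if r.group == "BCa"]
        calls = {r.sample_id: False for r in bca}
        res = association_table(bca, calls, "sex")
        assert res.positivity == (0.0, 0.0) and res.p == 1.0

    def test_unknown_parameter_rejected(self, validation_cohort):
        records, calls = validation_cohort
        with pytest.raises(ValueError):
            association_table(records, calls, "height")


def test_performance_at_cutoff_counts_and_cis():
    scores = [35.0] * 10 + [25.0] * 8 + [25.0] * 90 + [33.0] * 10
    labels = [True] * 18 + [False] * 100
    perf = performance_at_cutoff(scores, labels, 31.35)
    assert (perf.tp, perf.fn, perf.fp, perf.tn) == (10, 8, 10, 90)
    assert perf.sensitivity == pytest.approx(100 * 10 / 18)
    assert round(perf.sensitivity, 1) == 55.6
    lo, hi = perf.sensitivity_ci
    assert lo < perf.sensitivity < hi


def test_empty_stratum_reported_as_undefined():
    perf = performance_at_cutoff([35.0, 25.0], [True, True], 31.35)
    assert perf.specificity is None and perf.specificity_ci is None
    assert perf.sensitivity == pytest.approx(50.0)
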