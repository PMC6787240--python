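"""Diagnostic statistics: t-tests, ROC/DeLong, Youden, OR-rule envelope."""

import numpy as np
import pytest
from scipy import stats as sps

from fetadc import (
    ClassifierRule,
    bivariate_roc,
    classify_biparametric,
    compare_roc,
    diagnostic_measures,
    empirical_roc,
    independent_t_test,
    youden_cutoff,
)
from fetadc.stats import _envelope_auc, _or_rule_points


# ---------------------------------------------------------------------------
# oracles


def auc_by_pair_counting(pos, neg):
    """Brute force: concordant pairs + half ties over all (pos, neg) pairs."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def jackknife_auc_variance(pos, neg):
    """Delete-one jackknife of the AUC, grouped by class."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    m, n = len(pos), len(neg)
    a_del_pos = [auc_by_pair_counting(np.delete(pos, i), neg) for i in range(m)]
    a_del_neg = [auc_by_pair_counting(pos, np.delete(neg, j)) for j in range(n)]
    var_pos = (m - 1) / m * np.sum((np.asarray(a_del_pos) - np.mean(a_del_pos)) ** 2)
    var_neg = (n - 1) / n * np.sum((np.asarray(a_del_neg) - np.mean(a_del_neg)) ** 2)
    return var_pos + var_neg


def youden_by_exhaustive_scan(pos, neg):
    scores = np.unique(np.concatenate([pos, neg]))
    cuts = np.concatenate([[scores[0] - 1], (scores[:-1] + scores[1:]) / 2, [scores[-1] + 1]])
    best = max(
        ((np.mean(pos > c) + np.mean(neg <= c) - 1, np.mean(neg <= c), c) for c in cuts),
    )
    return best[0]


def random_instance(rng, max_n=12):
    m = int(rng.integers(2, max_n))
    n = int(rng.integers(2, max_n))
    # integer scores force plenty of ties
    return rng.integers(0, 6, m).astype(float), rng.integers(0, 6, n).astype(float)


def scores_labels(pos, neg):
    return np.concatenate([pos, neg]), np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)]


# ---------------------------------------------------------------------------
# t-test


class TestIndependentTTest:
    def test_identical_samples(self):
        r = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.md == 0 and r.p_value == pytest.approx(1.0)

    def test_pure_shift(self):
        r = independent_t_test([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert r.md == pytest.approx(10.0)

    def test_matches_textbook_pooled_formula(self):
        # REC {5,7,9,11}, PTRE {1,3}: sp^2 = (3*20/3 + 1*2)/4 = 5.5,
        # se = sqrt(5.5 * (1/4 + 1/2)), t = 6/se, df = 4
        r = independent_t_test([5.0, 7.0, 9.0, 11.0], [1.0, 3.0])
        se = np.sqrt(5.5 * (1 / 4 + 1 / 2))
        assert r.md == pytest.approx(6.0)
        assert r.se == pytest.approx(se, rel=1e-12)
        assert r.t == pytest.approx(6.0 / se, rel=1e-12)
        assert r.p_value == pytest.approx(2 * sps.t.sf(6.0 / se, 4), rel=1e-12)

    def test_agrees_with_scipy_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.normal(1, 2, 8), rng.normal(0, 2, 5)
            ours = independent_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert ours.t == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            independent_t_test([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# ROC


class TestEmpiricalROC:
    def test_perfect_separation(self):
        s, y = scores_labels([3.0, 4.0], [1.0, 2.0])
        r = empirical_roc(s, y)
        assert r.auc == 1.0 and r.ci95 == (1.0, 1.0)

    def test_hand_counted_ties(self):
        # REC {3, 1}, PTRE {2}: one concordant, one discordant -> 0.5
        s, y = scores_labels([3.0, 1.0], [2.0])
        assert empirical_roc(s, y).auc == 0.5

    def test_all_scores_equal(self):
        s, y = scores_labels([1.0, 1.0], [1.0, 1.0])
        r = empirical_roc(s, y)
        assert r.auc == 0.5 and r.p_value == 1.0

    def test_auc_equals_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            pos, neg = random_instance(rng)
            r = empirical_roc(*scores_labels(pos, neg))
            assert abs(r.auc - auc_by_pair_counting(pos, neg)) < 1e-12

    def test_delong_variance_equals_jackknife_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pos, neg = random_instance(rng, max_n=9)
            r = empirical_roc(*scores_labels(pos, neg))
            assert r.auc_se**2 == pytest.approx(
                jackknife_auc_variance(pos, neg), abs=1e-10
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 10), rng.normal(0, 1, 7)
        s, y = scores_labels(pos, neg)
        base = empirical_roc(s, y)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert empirical_roc(f(s), y).auc == pytest.approx(base.auc, abs=1e-12)

    def test_smaller_direction_flips(self):
        s, y = scores_labels([1.0, 2.0], [3.0, 4.0])
        assert empirical_roc(s, y).auc == 0.0
        assert empirical_roc(s, y, direction="smaller").auc == 1.0

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(4)
        pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 10)
        r = empirical_roc(*scores_labels(pos, neg))
        assert r.ci95[0] <= r.auc <= r.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1.0, 2.0], [1, 1])


class TestCompareROC:
    def test_identical_scores_give_p_one(self):
        s, y = scores_labels([3.0, 4.0, 2.0], [1.0, 2.5])
        a = empirical_roc(s, y)
        diff, se, p = compare_roc(a, a, paired=True)
        assert diff == 0.0 and p == 1.0

    def test_paired_variance_matches_jackknife_oracle(self):
        # delete-one jackknife of the AUC *difference* (5 pos + 3 neg)
        rng = np.random.default_rng(5)
        pos_a, neg_a = rng.normal(1, 1, 5), rng.normal(0, 1, 3)
        pos_b, neg_b = pos_a + rng.normal(0, 0.5, 5), neg_a + rng.normal(0, 0.5, 3)
        a = empirical_roc(*scores_labels(pos_a, neg_a))
        b = empirical_roc(*scores_labels(pos_b, neg_b))
        diff, se, _ = compare_roc(a, b, paired=True)

        def delta(pa, na, pb, nb):
            return auc_by_pair_counting(pa, na) - auc_by_pair_counting(pb, nb)

        d_pos = [
            delta(np.delete(pos_a, i), neg_a, np.delete(pos_b, i), neg_b) for i in range(5)
        ]
        d_neg = [
            delta(pos_a, np.delete(neg_a, j), pos_b, np.delete(neg_b, j)) for j in range(3)
        ]
        var = (4 / 5) * np.sum((np.asarray(d_pos) - np.mean(d_pos)) ** 2) + (
            2 / 3
        ) * np.sum((np.asarray(d_neg) - np.mean(d_neg)) ** 2)
        assert diff == pytest.approx(delta(pos_a, neg_a, pos_b, neg_b), abs=1e-12)
        assert se**2 == pytest.approx(var, abs=1e-10)

    def test_unpaired_adds_variances(self):
        rng = np.random.default_rng(6)
        a = empirical_roc(*scores_labels(rng.normal(1, 1, 8), rng.normal(0, 1, 6)))
        b = empirical_roc(*scores_labels(rng.normal(1, 1, 9), rng.normal(0, 1, 5)))
        _, se, _ = compare_roc(a, b, paired=False)
        assert se == pytest.approx(np.sqrt(a.auc_se**2 + b.auc_se**2), rel=1e-12)

    def test_paired_size_mismatch_rejected(self):
        a = empirical_roc(*scores_labels([1.0, 2.0], [0.0, 0.5]))
        b = empirical_roc(*scores_labels([1.0, 2.0, 3.0], [0.0, 0.5]))
        with pytest.raises(ValueError):
            compare_roc(a, b, paired=True)


class TestYouden:
    def test_perfect_separation(self):
        r = empirical_roc(*scores_labels([3.0, 4.0], [1.0, 2.0]))
        cutoff, sens, spec, j = youden_cutoff(r)
        assert j == 1.0 and 2.0 < cutoff < 3.0

    def test_overlapping_samples_tie_break_to_specificity(self):
        # REC {3,4,5}, PTRE {1,2,3}: J = 2/3 at either cutoff 2.5 (sens 1,
        # spec 2/3) or 3.5 (sens 2/3, spec 1); tie goes to higher specificity
        r = empirical_roc(*scores_labels([3.0, 4.0, 5.0], [1.0, 2.0, 3.0]))
        cutoff, sens, spec, j = youden_cutoff(r)
        assert j == pytest.approx(2 / 3)
        assert spec == 1.0 and sens == pytest.approx(2 / 3)
        assert cutoff == pytest.approx(3.5)

    def test_all_equal_scores(self):
        r = empirical_roc(*scores_labels([2.0, 2.0], [2.0, 2.0]))
        assert youden_cutoff(r)[3] == 0.0

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            pos, neg = random_instance(rng)
            r = empirical_roc(*scores_labels(pos, neg))
            assert youden_cutoff(r)[3] == pytest.approx(
                youden_by_exhaustive_scan(pos, neg), abs=1e-12
            )

    def test_j_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        pos, neg = rng.normal(1, 1, 9), rng.normal(0, 1, 6)
        r1 = empirical_roc(*scores_labels(pos, neg))
        r2 = empirical_roc(*scores_labels(np.exp(pos), np.exp(neg)))
        assert youden_cutoff(r1)[3] == pytest.approx(youden_cutoff(r2)[3], abs=1e-12)


# ---------------------------------------------------------------------------
# classifier and diagnostics


class TestClassifyBiparametric:
    @pytest.mark.parametrize(
        "tbr,adc,expected",
        [
            (1.82, 1133.0, "PTRE"),  # neither marker above threshold
            (1.99, 1757.0, "REC"),   # ADC fires despite borderline TBR
            (2.57, 1815.0, "REC"),   # both fire
            (1.73, 1362.0, "REC"),   # ADC alone fires
            (2.50, 850.0, "REC"),    # TBR alone fires (restricted diffusion)
        ],
    )
    def test_worked_cases(self, tbr, adc, expected):
        assert classify_biparametric(tbr, adc) == expected

    def test_thresholds_are_strict(self):
        assert classify_biparametric(2.0, 1254.0) == "PTRE"

    def test_single_marker_modes(self):
        rule_t = ClassifierRule(combination="tbr_only")
        rule_a = ClassifierRule(combination="adc_only")
        assert classify_biparametric(2.5, 900.0, rule_t) == "REC"
        assert classify_biparametric(2.5, 900.0, rule_a) == "PTRE"

    def test_or_rule_dominance(self):
        # OR-rule sensitivity >= each marker's; specificity <= each marker's
        rng = np.random.default_rng(9)
        tbr = np.r_[rng.normal(3.2, 1.0, 32), rng.normal(2.1, 1.0, 10)]
        adc = np.r_[rng.normal(1313, 250, 32), rng.normal(1029, 250, 10)]
        y = np.r_[np.ones(32, int), np.zeros(10, int)]
        results = {}
        for comb in ("or_rule", "tbr_only", "adc_only"):
            rule = ClassifierRule(combination=comb)
            pred = [classify_biparametric(t, a, rule) for t, a in zip(tbr, adc)]
            results[comb] = diagnostic_measures(pred, y)
        assert results["or_rule"].sensitivity >= max(
            results["tbr_only"].sensitivity, results["adc_only"].sensitivity
        )
        assert results["or_rule"].specificity <= min(
            results["tbr_only"].specificity, results["adc_only"].specificity
        )


class TestDiagnosticMeasures:
    def test_perfect_predictions(self):
        y = [1, 1, 0, 0]
        d = diagnostic_measures(y, y)
        assert (d.sensitivity, d.specificity, d.ppv, d.npv) == (1, 1, 1, 1)

    def test_cohort_sized_counts(self):
        # tp=26, fn=6, tn=6, fp=4 at 32/10 -> sens 81.25%, spec 60%
        pred = [1] * 26 + [0] * 6 + [0] * 6 + [1] * 4
        true = [1] * 32 + [0] * 10
        d = diagnostic_measures(pred, true)
        assert (d.tp, d.fp, d.tn, d.fn) == (26, 4, 6, 6)
        assert d.sensitivity == pytest.approx(0.8125)
        assert d.specificity == pytest.approx(0.60)

    def test_undefined_npv_is_nan(self):
        pred = [1] * 12
        true = [1] * 2 + [0] * 10
        d = diagnostic_measures(pred, true)
        assert d.specificity == 0.0 and np.isnan(d.npv)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_measures([1, 0], [1, 0, 1])


# ---------------------------------------------------------------------------
# bivariate envelope


def envelope_auc_by_enumeration(tbr, adc, y):
    """Oracle: enumerate every threshold pair over the raw score values."""
    pts = []
    cand_t = np.r_[-np.inf, np.unique(tbr), np.inf]
    cand_a = np.r_[-np.inf, np.unique(adc), np.inf]
    y = np.asarray(y)
    for ct in cand_t:
        for ca in cand_a:
            pred = (tbr > ct) | (adc > ca)
            tpr = pred[y == 1].mean()
            fpr = pred[y == 0].mean()
            pts.append((fpr, tpr))
    pts = np.array(pts + [(0, 0), (1, 1)])
    fpr_u = np.unique(pts[:, 0])
    tpr_u = np.maximum.accumulate([pts[pts[:, 0] == f, 1].max() for f in fpr_u])
    return float(np.sum(np.asarray(tpr_u)[:-1] * np.diff(fpr_u)))


class TestBivariateROC:
    def test_constant_second_marker_reduces_to_univariate(self):
        rng = np.random.default_rng(10)
        tbr = np.r_[rng.normal(3, 1, 8), rng.normal(2, 1, 6)]
        y = np.r_[np.ones(8, int), np.zeros(6, int)]
        bi = bivariate_roc(tbr, np.full(14, 5.0), y, n_boot=10)
        uni = empirical_roc(tbr, y)
        assert bi.auc == pytest.approx(uni.auc, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            m, n = int(rng.integers(2, 6)), int(rng.integers(2, 5))
            tbr = rng.integers(0, 5, m + n).astype(float)
            adc = rng.integers(0, 5, m + n).astype(float)
            y = np.r_[np.ones(m, int), np.zeros(n, int)]
            bi = bivariate_roc(tbr, adc, y, n_boot=2)
            assert bi.auc == pytest.approx(envelope_auc_by_enumeration(tbr, adc, y), abs=1e-12)

    def test_perfect_markers(self):
        y = np.r_[np.ones(4, int), np.zeros(3, int)]
        tbr = np.r_[np.full(4, 3.0), np.full(3, 1.0)]
        bi = bivariate_roc(tbr, tbr * 100, y, n_boot=5)
        assert bi.auc == 1.0

    def test_envelope_dominates_univariate(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            m, n = 8, 6
            tbr = rng.normal(0.5, 1, m + n)
            adc = rng.normal(0.5, 1, m + n)
            y = np.r_[np.ones(m, int), np.zeros(n, int)]
            bi = bivariate_roc(tbr, adc, y, n_boot=2)
            assert bi.auc >= empirical_roc(tbr, y).auc - 1e-12
            assert bi.auc >= empirical_roc(adc, y).auc - 1e-12

    def test_bootstrap_se_is_seeded(self):
        rng = np.random.default_rng(13)
        tbr = np.r_[rng.normal(3, 1, 8), rng.normal(2, 1, 6)]
        adc = np.r_[rng.normal(1300, 200, 8), rng.normal(1000, 200, 6)]
        y = np.r_[np.ones(8, int), np.zeros(6, int)]
        a = bivariate_roc(tbr, adc, y, n_boot=50, seed=99)
        b = bivariate_roc(tbr, adc, y, n_boot=50, seed=99)
        assert a.auc_se == b.auc_se > 0
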