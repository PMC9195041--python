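"""Mann-Whitney, ROC/AUC, DeLong and cohort summaries."""

from itertools import combinations

import numpy as np
import pytest
import scipy.stats

from dcekinetics import (
    ParamDist,
    CohortSpec,
    auc_ci_delong,
    auc_of_scores,
    compare_auc_delong,
    fit_cohort,
    mann_whitney_u,
    roc_points,
    simulate_cohort,
    summarize_cohort,
    youden_threshold,
)


def brute_force_u(x, y):
    """Independent pair-counting oracle."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


def brute_force_exact_p(x, y):
    """Full enumeration of group labelings."""
    pooled = list(x) + list(y)
    n = len(x)
    mu = len(x) * len(y) / 2.0
    u_obs = brute_force_u(x, y)
    total = extreme = 0
    for comb in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(brute_force_u(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_complete_ties(self):
        x = [2.0, 2.0, 2.0, 2.0]
        res = mann_whitney_u(x, x)
        assert res.u_statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, size=5).astype(float)  # ties likely
        y = rng.integers(0, 8, size=6).astype(float)
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.u_statistic == brute_force_u(x, y)
        assert res.p_value == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_normal_approx_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 20)
        res = mann_whitney_u(x, y)
        assert res.method == "normal-approx"
        ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic",
                                       use_continuity=True)
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_vs_approx_agreement_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0, 1, 6)
        pe = mann_whitney_u(x, y, mode="exact").p_value
        pa = mann_whitney_u(x, y, mode="normal-approx").p_value
        assert abs(pe - pa) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAuc:
    def test_perfect_separation(self):
        scores = [10, 20, 1, 2]
        labels = ["pos", "pos", "neg", "neg"]
        assert auc_of_scores(scores, labels, "pos") == 1.0
        assert auc_of_scores(scores, labels, "pos", direction="smaller") == 0.0

    def test_all_tied_scores(self):
        assert auc_of_scores([5, 5, 5, 5], ["p", "p", "n", "n"], "p") == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_and_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 10, 8).astype(float)
        neg = rng.integers(0, 10, 11).astype(float)
        scores = np.concatenate([pos, neg])
        labels = np.array(["p"] * 8 + ["n"] * 11)
        auc = auc_of_scores(scores, labels, "p")
        assert auc == pytest.approx(brute_force_u(pos, neg) / (8 * 11), abs=1e-12)
        u = mann_whitney_u(pos, neg).u_statistic
        assert auc * 8 * 11 == pytest.approx(u, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_of_scores([1, 2], ["p", "p"], "p")


class TestRocPoints:
    def test_separating_gap_has_perfect_operating_point(self):
        scores = [10, 20, 30, 40]
        labels = ["IDC", "IDC", "benign", "benign"]
        roc = roc_points(scores, labels, "IDC", direction="smaller")
        j = roc.sensitivity + roc.specificity - 1
        best = np.argmax(j)
        assert j[best] == pytest.approx(1.0)
        assert 20 < roc.thresholds[best] < 30

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_area_equals_pair_count_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 25).astype(float)
        labels = np.where(rng.random(25) < 0.4, "p", "n")
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        for direction in ("larger", "smaller"):
            roc = roc_points(scores, labels, "p", direction)
            fpr = 1 - roc.specificity
            order = np.lexsort((roc.sensitivity, fpr))
            area = np.trapezoid(roc.sensitivity[order], fpr[order])
            assert area == pytest.approx(
                auc_of_scores(scores, labels, "p", direction), abs=1e-12)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        aucs = []
        for _ in range(1000):
            labels = np.where(rng.permutation(40) < 20, "p", "n")
            aucs.append(auc_of_scores(scores, labels, "p"))
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-6

    def test_direction_coherence(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.5, "p", "n")
        r1 = roc_points(scores, labels, "p", "larger")
        r2 = roc_points(-scores, labels, "p", "smaller")
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        a1, ci1, _ = auc_ci_delong(scores, labels, "p", "larger")
        a2, ci2, _ = auc_ci_delong(-scores, labels, "p", "smaller")
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert ci1 == pytest.approx(ci2, abs=1e-12)


class TestYouden:
    def test_separating_cutoff_in_gap(self):
        scores = [1, 2, 3, 8, 9, 10]
        labels = ["n"] * 3 + ["p"] * 3
        roc = roc_points(scores, labels, "p")
        thr = youden_threshold(roc)
        assert 3 < thr < 8

    def test_all_tied_returns_a_threshold_with_zero_j(self):
        roc = roc_points([5.0] * 6, ["p"] * 3 + ["n"] * 3, "p")
        thr = youden_threshold(roc)
        idx = int(np.argmin(np.abs(roc.thresholds - thr)))
        assert roc.sensitivity[idx] + roc.specificity[idx] - 1 == pytest.approx(0)

    def test_binormal_threshold_near_analytic_crossing(self):
        """Equal-variance binormal scores: the Youden cutoff converges
        on the equal-likelihood point midway between the means."""
        rng = np.random.default_rng(8)
        pos = rng.normal(1.0, 1.0, 4000)
        neg = rng.normal(-1.0, 1.0, 4000)
        scores = np.concatenate([pos, neg])
        labels = np.array(["p"] * 4000 + ["n"] * 4000)
        thr = youden_threshold(roc_points(scores, labels, "p"))
        assert abs(thr - 0.0) < 0.15


class TestDeLong:
    def test_degenerate_interval_for_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["n"] * 3 + ["p"] * 3
        auc, ci, degenerate = auc_ci_delong(scores, labels, "p")
        assert auc == 1.0 and ci == (1.0, 1.0) and degenerate

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        from sklearn.metrics import roc_auc_score
        auc, _, _ = auc_ci_delong(scores, np.where(labels, "p", "n"), "p")
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_coverage_of_true_auc(self):
        """Binormal simulation: the 95% interval covers the true AUC at
        a rate inside [90%, 99%] over 500 replicates."""
        delta = 1.0
        true_auc = scipy.stats.norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(500):
            pos = rng.normal(delta, 1, 50)
            neg = rng.normal(0, 1, 50)
            scores = np.concatenate([pos, neg])
            labels = np.array(["p"] * 50 + ["n"] * 50)
            _, (lo, hi), _ = auc_ci_delong(scores, labels, "p")
            hits += lo <= true_auc <= hi
        assert 0.90 <= hits / 500 <= 0.99

    def test_duplicated_subjects_halve_variance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=40)
        labels = np.array(["p"] * 15 + ["n"] * 25)
        _, (lo, hi), _ = auc_ci_delong(scores, labels, "p")
        _, (lo2, hi2), _ = auc_ci_delong(np.tile(scores, 2), np.tile(labels, 2), "p")
        ratio = ((hi2 - lo2) / (hi - lo)) ** 2
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_compare_marker_with_itself(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.5, "p", "n")
        assert compare_auc_delong(scores, scores, labels, "p") == 1.0

    def test_compare_with_negated_marker(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.5, "p", "n")
        p = compare_auc_delong(scores, -scores, labels, "p",
                               direction_a="larger", direction_b="smaller")
        assert p == 1.0

    def test_power_for_large_auc_gap(self):
        """AUC gap ~0.3 at n=150: the paired test detects it at the 5%
        level in at least 95% of 200 replicates."""
        rng = np.random.default_rng(23)
        wins = 0
        for _ in range(200):
            labels = np.array(["p"] * 75 + ["n"] * 75)
            latent = np.concatenate([rng.normal(1.8, 1, 75), rng.normal(0, 1, 75)])
            good = latent + rng.normal(0, 0.3, 150)
            poor = 0.1 * latent + rng.normal(0, 1.5, 150)
            wins += compare_auc_delong(good, poor, labels, "p") < 0.05
        assert wins / 200 >= 0.95

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_delong([1, 2], [1, 2, 3], ["p", "n", "p"], "p")


class TestSummarizeCohort:
    @staticmethod
    def _tiny_cohort():
        spec = CohortSpec(
            groups={
                "IDC": {"a": ParamDist(1.5, 0), "b": ParamDist(19.6, 0),
                        "c": ParamDist(0.3, 0), "d": ParamDist(-3.7e-4, 0)},
                "benign": {"a": ParamDist(1.4, 0), "b": ParamDist(31.5, 0),
                           "c": ParamDist(0.1, 0), "d": ParamDist(2.2e-4, 0)},
            },
            n_per_group={"IDC": 3, "benign": 3}, noise_sigma=0.0,
        )
        recs = simulate_cohort(spec)
        fits = fit_cohort(recs)
        return [r.with_fit(f) for r, f in zip(recs, fits)]

    def test_degenerate_cohort_reports_generating_means(self):
        fitted = self._tiny_cohort()
        report = summarize_cohort(fitted, ("IDC", "benign"), markers=("b",))
        row = report.iloc[0]
        assert row["mean_IDC"] == pytest.approx(19.6, rel=1e-3)
        assert row["mean_benign"] == pytest.approx(31.5, rel=1e-3)
        # 3 vs 3 fully separated, exact two-sided permutation p
        assert row["p_value"] == pytest.approx(0.1, abs=1e-12)
        assert row["auc"] == 1.0

    def test_single_marker_single_row(self):
        report = summarize_cohort(self._tiny_cohort(), ("IDC", "benign"),
                                  markers=("b",))
        assert len(report) == 1 and report.iloc[0]["marker"] == "b"

    def test_late_slope_reported_on_printed_scale(self):
        report = summarize_cohort(self._tiny_cohort(), ("IDC", "benign"),
                                  markers=("d",))
        assert report.iloc[0]["mean_IDC"] == pytest.approx(-3.7, rel=1e-2)
        assert report.iloc[0]["mean_benign"] == pytest.approx(2.2, rel=1e-2)

    def test_determinism(self):
        r1 = summarize_cohort(self._tiny_cohort(), ("IDC", "benign"))
        r2 = summarize_cohort(self._tiny_cohort(), ("IDC", "benign"))
        assert r1.equals(r2)

    def test_small_group_rejected_by_name(self):
        fitted = self._tiny_cohort()
        with pytest.raises(ValueError, match="benign"):
            summarize_cohort([f for f in fitted if f.group == "IDC"]
                             + [f for f in fitted if f.group == "benign"][:1],
                             ("IDC", "benign"))
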