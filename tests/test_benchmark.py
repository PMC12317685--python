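"""Assessment statistics: ROC/AUC, PR, MCC curve, Welch t, surveys."""

import math

import numpy as np
import pytest
from scipy import stats

import pepmat as pm
from conftest import pair_count_auc


class TestRocAuc:
    def test_perfect_and_tied_pairs(self):
        _, auc = pm.roc_auc([0.9, 0.1], [True, False])
        assert auc == 1.0
        _, auc = pm.roc_auc([0.5, 0.5], [True, False])
        assert auc == 0.5

    def test_three_by_three_pair_enumeration(self):
        # concordant pairs: 0.9 and 0.8 each beat all three negatives,
        # 0.4 beats two of them -> 8 of 9
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [True, True, True, False, False, False]
        _, auc = pm.roc_auc(scores, labels)
        assert auc == pytest.approx(8 / 9)
        assert auc == pytest.approx(pair_count_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pm.roc_auc([0.1, 0.2], [True, True])

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(40)
        labels = rng.random(40) > 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        points, _ = pm.roc_auc(scores, labels)
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)
        fprs, tprs = zip(*points)
        assert all(b >= a for a, b in zip(fprs, fprs[1:]))
        assert all(b >= a for a, b in zip(tprs, tprs[1:]))

    def test_trapezoid_equals_rank_formulation(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.random(n) > 0.4
            if labels.all() or not labels.any():
                labels[0] = not labels[0]
            points, auc = pm.roc_auc(scores, labels)
            trapezoid = np.trapezoid([p[1] for p in points], [p[0] for p in points])
            assert abs(trapezoid - auc) < 1e-9
            assert abs(auc - pair_count_auc(scores, labels)) < 1e-9

    def test_score_negation_complements_auc(self, rng):
        scores = rng.permutation(np.arange(20) / 19)  # tie-free
        labels = np.arange(20) % 3 == 0
        _, auc = pm.roc_auc(scores, labels)
        _, flipped = pm.roc_auc(-scores, labels)
        assert auc + flipped == pytest.approx(1.0)


class TestMcc:
    def test_hand_computed_counts(self):
        assert pm.mcc(tp=2, fp=1, fn=1, tn=2) == pytest.approx(1 / 3)

    def test_zero_marginal_convention(self):
        assert pm.mcc(tp=3, fp=3, fn=0, tn=0) == 0.0

    def test_curve_has_101_thresholds(self):
        curve = pm.mcc_curve([0.2, 0.8], [False, True])
        assert len(curve) == 101
        assert curve[0][0] == 0.0 and curve[-1][0] == 1.0

    def test_perfect_separation_inside_gap(self):
        curve = pm.mcc_curve([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        for threshold, value in curve:
            if 0.3 <= threshold <= 0.7:
                assert value == pytest.approx(1.0)
        # at threshold 0 everything is predicted positive: a zero marginal
        assert curve[0][1] == 0.0

    def test_max_invariant_under_monotone_transform(self):
        scores = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        labels = [False, False, True, True, True]
        best = pm.best_mcc_threshold(pm.mcc_curve(scores, labels))[1]
        best_t = pm.best_mcc_threshold(pm.mcc_curve(np.sqrt(scores), labels))[1]
        assert best_t >= best - 1e-12


class TestWelch:
    def test_identical_samples(self):
        t, p = pm.welch_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 0.5)

    def test_textbook_formula_oracle(self):
        a, b = [2.0, 4.0], [1.0, 3.0]
        t, p = pm.welch_one_tailed(a, b)
        # closed-form Welch statistic and Welch-Satterthwaite df
        va, vb = np.var(a, ddof=1) / 2, np.var(b, ddof=1) / 2
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 1 + vb**2 / 1)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(stats.t.sf(t_expected, df))

    def test_swap_negates_t_and_complements_p(self, rng):
        a = rng.normal(1.0, 1.0, size=8)
        b = rng.normal(0.0, 2.0, size=6)
        t_ab, p_ab = pm.welch_one_tailed(a, b)
        t_ba, p_ba = pm.welch_one_tailed(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(1 - p_ba)

    def test_degenerate_zero_variance(self):
        assert pm.welch_one_tailed([1.0, 1.0], [1.0, 1.0]) == (0.0, 0.5)
        t, p = pm.welch_one_tailed([2.0, 2.0], [1.0, 1.0])
        assert t == math.inf and p == 0.0


class TestLooBenchmark:
    def test_separable_fixture_is_perfect(self, toy_sets, gaps21):
        functional, control = toy_sets
        matrix = pm.identity_matrix(match=5, mismatch=-2)
        result = pm.loo_benchmark(functional, control, matrix, gaps21)
        assert result.auc == 1.0
        assert result.best_mcc == pytest.approx(1.0)
        assert result.p_value < 0.05

    def test_constant_scores_are_uninformative(self, toy_sets, gaps21):
        functional, control = toy_sets
        zero = pm.SubstitutionMatrix(np.zeros((20, 20), dtype=int))
        result = pm.loo_benchmark(functional, control, zero, gaps21)
        assert result.auc == pytest.approx(0.5, abs=0.25)

    def test_content_scorer_runs_without_alignment(self, toy_sets):
        functional, control = toy_sets
        result = pm.loo_benchmark(functional, control, None, None, scorer="content")
        # toy functional peptides are Q/P-rich, controls hydrophobic:
        # composition alone separates them
        assert result.auc == 1.0

    def test_label_shuffle_null_centers_on_half(self, rng):
        aucs = []
        scores = rng.random(30)
        for _ in range(200):
            labels = np.zeros(30, dtype=bool)
            labels[rng.choice(30, size=15, replace=False)] = True
            _, auc = pm.roc_auc(scores, labels)
            aucs.append(auc)
        assert 0.45 <= np.mean(aucs) <= 0.55


class TestSurvey:
    def test_identity_outranks_its_negation(self, toy_sets):
        functional, control = toy_sets
        good = pm.identity_matrix(match=5, mismatch=-2, id="identity")
        bad = pm.SubstitutionMatrix(-np.asarray(good.scores), id="negated")
        board = pm.matrix_survey(functional, control, [bad, good])
        assert len(board) == 2
        assert board.entries[0].matrix.id == "identity"
        assert board.entries[0].result.auc >= board.entries[1].result.auc

    def test_leaderboard_tsv_rows(self, toy_sets, tmp_path):
        functional, control = toy_sets
        board = pm.matrix_survey(
            functional, control, [pm.identity_matrix(id="only")]
        )
        path = tmp_path / "board.tsv"
        board.to_tsv(path)
        assert len(path.read_text().splitlines()) == 2  # header + one matrix


class TestImprovementCorrelation:
    @staticmethod
    def _entry(matrix, auc):
        result = pm.BenchmarkResult(
            score_table=None, roc_points=[], auc=auc, pr_points=[], mcc_points=[],
            best_threshold=0.5, best_mcc=0.0, t_statistic=0.0, p_value=0.5,
        )
        return pm.SurveyEntry(matrix=matrix, gaps=pm.GapPenalties(-2, -1), result=result)

    def _pair(self, delta_cells, auc_before, auc_after):
        before = pm.SubstitutionMatrix(np.zeros((20, 20), dtype=int))
        scores = np.zeros((20, 20), dtype=int)
        for k in range(delta_cells):
            scores[k // 20, k % 20] = 1
        after = pm.SubstitutionMatrix(scores)
        return self._entry(before, auc_before), self._entry(after, auc_after)

    def test_perfectly_linear_pairs(self):
        pairs = [self._pair(d, 0.5, 0.5 + 0.01 * d) for d in (1, 2, 3, 4)]
        before, after = zip(*pairs)
        assert pm.improvement_correlation(before, after) == pytest.approx(1.0)

    def test_hand_example_matches_closed_form(self):
        distances = [1, 2, 3, 5]
        gains = [0.02, 0.01, 0.05, 0.06]
        pairs = [self._pair(d, 0.5, 0.5 + g) for d, g in zip(distances, gains)]
        before, after = zip(*pairs)
        x, y = np.array(distances), np.array(gains)
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert pm.improvement_correlation(before, after) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        pairs = [self._pair(2, 0.5, 0.6) for _ in range(4)]
        before, after = zip(*pairs)
        with pytest.raises(ValueError, match="variance"):
            pm.improvement_correlation(before, after)
        with pytest.raises(ValueError, match="3"):
            pm.improvement_correlation(before[:2], after[:2])
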