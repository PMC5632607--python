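import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from admkit.errors import ParameterError, SamplingError
from admkit.evaluation import (
    ConfusionMatrix,
    ThresholdReport,
    binarize,
    evaluate_at_threshold,
    metric_curve,
    sample_pseudoabsences,
    select_kappa_threshold,
    select_roc_threshold,
    wilcoxon_signed_rank,
)
from admkit.grids import CONTINUOUS, BinaryModel, GridGeometry, SuitabilityModel
from admkit.occurrences import OccurrenceSet


def make_binary(grid, geometry=None, species="sp"):
    grid = np.asarray(grid)
    geometry = geometry or GridGeometry(*grid.shape, 0.0, grid.shape[0] * 1000.0, 1000.0)
    return BinaryModel(species, "PDM", grid, geometry, np.ones(grid.shape, bool), 50.0, "kappa")


def make_suit(grid, species="sp"):
    grid = np.asarray(grid, dtype=float)
    geometry = GridGeometry(*grid.shape, 0.0, grid.shape[0] * 1000.0, 1000.0)
    return SuitabilityModel(species, "enfa", grid, CONTINUOUS, geometry,
                            np.ones(grid.shape, bool))


class TestConfusionMatrix:
    def test_symmetric_matrix_hand_values(self):
        cm = ConfusionMatrix(TP=40, FP=10, FN=10, TN=40)
        assert cm.kappa == pytest.approx(0.6)
        assert cm.sensitivity == pytest.approx(0.8)
        assert cm.specificity == pytest.approx(0.8)
        assert cm.omission == pytest.approx(0.2)
        assert cm.commission == pytest.approx(0.2)
        assert cm.overall == pytest.approx(0.8)

    def test_perfect_agreement_gives_kappa_one(self):
        assert ConfusionMatrix(10, 0, 0, 15).kappa == pytest.approx(1.0)

    def test_prediction_independent_of_truth_gives_kappa_zero(self):
        # proportional rows: prediction says presence with fixed probability
        assert ConfusionMatrix(TP=30, FN=10, FP=30, TN=10).kappa == pytest.approx(0.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(deadline=None, max_examples=200)
    def test_kappa_bounded(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp, fp, fn, tn)
        if cm.N and np.isfinite(cm.kappa):
            assert -1.0 - 1e-12 <= cm.kappa <= 1.0 + 1e-12


class TestEvaluateAtThreshold:
    @pytest.fixture()
    def setup(self, occ_from_cells):
        rng = np.random.default_rng(0)
        suit = make_suit(rng.uniform(0, 100, (20, 20)))
        pres = occ_from_cells(suit.geometry, np.column_stack(
            [rng.integers(0, 20, 30), rng.integers(0, 20, 30)]), source="museum")
        abse = occ_from_cells(suit.geometry, np.column_stack(
            [rng.integers(0, 20, 30), rng.integers(0, 20, 30)]), source="museum")
        return suit, pres, abse

    def test_threshold_zero_predicts_everything_present(self, setup):
        suit, pres, abse = setup
        cm = evaluate_at_threshold(suit, 0.0, pres, abse)
        assert cm.FN == 0 and cm.TN == 0 and cm.TP == 30 and cm.FP == 30

    def test_threshold_above_max_predicts_everything_absent(self, setup):
        suit, pres, abse = setup
        cm = evaluate_at_threshold(suit, 100.5, pres, abse)
        assert cm.TP == 0 and cm.FP == 0


class TestPseudoabsences:
    def test_all_absence_model_yields_distinct_cells(self):
        model = make_binary(np.zeros((5, 5)))
        occ = sample_pseudoabsences(model, 10, seed=1)
        assert len(np.unique(occ.cells(model.geometry), axis=0)) == 10

    def test_all_presence_model_is_sampling_error(self):
        with pytest.raises(SamplingError):
            sample_pseudoabsences(make_binary(np.ones((5, 5))), 1, seed=1)

    def test_exclusion_cells_never_drawn(self, occ_from_cells):
        model = make_binary(np.zeros((4, 4)))
        excl = occ_from_cells(model.geometry, [[r, c] for r in range(4) for c in range(2)])
        occ = sample_pseudoabsences(model, 8, seed=2, exclusion=excl)
        assert np.all(occ.cells(model.geometry)[:, 1] >= 2)

    def test_empirical_distribution_uniform_over_absence_cells(self):
        model = make_binary(np.zeros((6, 6)))
        counts = np.zeros(36)
        for seed in range(400):
            occ = sample_pseudoabsences(model, 9, seed=seed)
            cells = occ.cells(model.geometry)
            np.add.at(counts, cells[:, 0] * 6 + cells[:, 1], 1)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_same_engine_warns(self):
        model = make_binary(np.zeros((5, 5)))
        model.metadata["engine"] = "enfa"
        with pytest.warns(UserWarning, match="cross-engine"):
            sample_pseudoabsences(model, 3, seed=0, engine_under_test="enfa")


class TestMetricCurve:
    def test_perfect_separation_gives_auc_one(self, occ_from_cells):
        grid = np.zeros((10, 10))
        grid[:5] = 90.0
        suit = make_suit(grid)
        pres = occ_from_cells(suit.geometry, [[r, c] for r in range(3) for c in range(5)])
        abse = occ_from_cells(suit.geometry, [[r, c] for r in range(7, 10) for c in range(5)])
        rep = metric_curve(suit, pres, abse)
        assert rep.auc == pytest.approx(1.0)

    def test_identical_scores_give_auc_half(self, occ_from_cells):
        suit = make_suit(np.full((10, 10), 50.0))
        pres = occ_from_cells(suit.geometry, [[0, 0], [1, 1]])
        abse = occ_from_cells(suit.geometry, [[2, 2], [3, 3]])
        assert metric_curve(suit, pres, abse).auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_oracle(self, occ_from_cells):
        rng = np.random.default_rng(7)
        suit = make_suit(rng.uniform(0, 100, (15, 15)))
        p_cells = np.column_stack([rng.integers(0, 15, 25), rng.integers(0, 15, 25)])
        a_cells = np.column_stack([rng.integers(0, 15, 25), rng.integers(0, 15, 25)])
        pres = occ_from_cells(suit.geometry, p_cells)
        abse = occ_from_cells(suit.geometry, a_cells)
        ps = suit.grid[p_cells[:, 0], p_cells[:, 1]]
        as_ = suit.grid[a_cells[:, 0], a_cells[:, 1]]
        # candidate thresholds at every distinct score -> trapezoid AUC is exact
        thresholds = sorted(np.unique(np.concatenate([ps, as_])))
        rep = metric_curve(suit, pres, abse, thresholds)
        wins = sum((p > a) + 0.5 * (p == a) for p in ps for a in as_)
        assert rep.auc == pytest.approx(wins / (len(ps) * len(as_)), abs=1e-12)

    def test_empty_threshold_list_rejected(self, occ_from_cells):
        suit = make_suit(np.zeros((5, 5)))
        occ = occ_from_cells(suit.geometry, [[0, 0]])
        with pytest.raises(ParameterError):
            metric_curve(suit, occ, occ, [])


def report_from(matrices, thresholds):
    return ThresholdReport("sp", "enfa", list(thresholds),
                           [ConfusionMatrix(*m) for m in matrices], auc=0.5)


class TestThresholdSelection:
    def test_kappa_argmax(self):
        rep = report_from([(10, 40, 0, 10), (40, 10, 10, 40), (20, 2, 30, 48)], [20, 60, 80])
        assert select_kappa_threshold(rep) == 60

    def test_kappa_tie_goes_to_lowest_threshold(self):
        rep = report_from([(40, 10, 10, 40), (40, 10, 10, 40)], [60, 80])
        assert select_kappa_threshold(rep) == 60

    def test_roc_distance_hand_example(self):
        # (sens, spec) = (1.0, 0.6), (0.8, 0.9), (0.5, 1.0): distances 0.4, ~0.224, 0.5
        rep = report_from([(50, 20, 0, 30), (40, 5, 10, 45), (25, 0, 25, 50)], [20, 60, 80])
        assert select_roc_threshold(rep) == 60

    def test_perfect_point_selected_with_zero_distance(self):
        rep = report_from([(50, 50, 0, 0), (50, 0, 0, 50)], [20, 60])
        assert select_roc_threshold(rep) == 60

    def test_selection_invariant_to_duplicated_candidates(self):
        mats = [(10, 40, 0, 10), (40, 10, 10, 40)]
        rep1 = report_from(mats, [20, 60])
        rep2 = report_from(mats + mats, [20, 60, 20, 60])
        assert select_kappa_threshold(rep1) == select_kappa_threshold(rep2)
        assert select_roc_threshold(rep1) == select_roc_threshold(rep2)

    def test_exhaustive_scan_oracle(self, occ_from_cells):
        rng = np.random.default_rng(11)
        suit = make_suit(rng.uniform(0, 100, (15, 15)))
        pres = occ_from_cells(suit.geometry, np.column_stack(
            [rng.integers(0, 15, 40), rng.integers(0, 15, 40)]))
        abse = occ_from_cells(suit.geometry, np.column_stack(
            [rng.integers(0, 15, 40), rng.integers(0, 15, 40)]))
        rep = metric_curve(suit, pres, abse)
        kappas = [cm.kappa for cm in rep.matrices]
        dists = [np.hypot(1 - cm.sensitivity, 1 - cm.specificity) for cm in rep.matrices]
        assert select_kappa_threshold(rep) == rep.thresholds[int(np.argmax(kappas))]
        assert select_roc_threshold(rep) == rep.thresholds[int(np.argmin(dists))]


class TestBinarize:
    def test_zero_threshold_keeps_all_valid_cells(self):
        suit = make_suit(np.random.default_rng(1).uniform(0, 100, (8, 8)))
        pdm = binarize(suit, 0.0, "kappa")
        assert pdm.presence.all()

    def test_above_max_threshold_empties_model(self):
        suit = make_suit(np.full((8, 8), 40.0))
        assert binarize(suit, 99.0, "roc").presence.sum() == 0

    def test_presence_sets_nested_in_threshold(self):
        suit = make_suit(np.random.default_rng(2).uniform(0, 100, (12, 12)))
        prev = binarize(suit, 0.0, "kappa").presence
        for t in (10, 30, 50, 70, 90):
            cur = binarize(suit, float(t), "kappa").presence
            assert not np.any(cur & ~prev)  # nested
            prev = cur


def brute_force_wilcoxon_p(diffs):
    """Literal enumeration over all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(diffs))
    n = len(diffs)
    w_plus = ranks[diffs > 0].sum()
    total = ranks.sum()
    W = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= W + 1e-12 or wp >= total - W - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_rank_sum_hand_example(self):
        W, _ = wilcoxon_signed_rank([(d, 0) for d in (1, 2, 3, 4, 5, -6)])
        assert W == 6  # W+ = 15, W- = 6

    def test_all_positive_n5_exact_p(self):
        _, p = wilcoxon_signed_rank([(d, 0) for d in (1, 2, 3, 4, 5)])
        assert p == pytest.approx(2 / 2**5)

    def test_exact_p_matches_full_enumeration_n12(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.4, 1.0, 12).round(1)
        diffs = diffs[diffs != 0][:12]
        W, p = wilcoxon_signed_rank([(d, 0) for d in diffs])
        assert p == pytest.approx(brute_force_wilcoxon_p(diffs), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.5, 1.0, 14)
        _, p = wilcoxon_signed_rank([(d, 0) for d in diffs])
        sp = stats.wilcoxon(diffs, mode="exact").pvalue
        assert p == pytest.approx(sp, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            W, p = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert (W, p) == (0.0, 1.0)

    def test_large_sample_normal_approximation_close_to_exact_tail(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.8, 1.0, 30)
        _, p = wilcoxon_signed_rank([(d, 0) for d in diffs])
        sp = stats.wilcoxon(diffs, mode="approx", correction=True).pvalue
        assert p == pytest.approx(sp, rel=0.05)
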