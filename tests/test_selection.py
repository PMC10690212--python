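import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canonet.datatypes import CanonetError, PenaltySpec, ScalingScheme
from canonet.selection import (
    auto_scaling_factors,
    build_penalty_grid,
    candidate_scaling_schemes,
    classification_metrics,
    cv_binary,
    cv_quantitative,
    cv_scaling_search,
    kfold_split,
    pairwise_preliminary_cc,
    scaled_prediction_error,
)
from canonet.synthetic import SyntheticSpec, generate
from conftest import make_dataset, standardized


class TestScaledPredictionError:
    def test_zero_discrepancy(self):
        assert scaled_prediction_error(0.7, 0.7) == 0.0

    def test_direct_arithmetic(self):
        assert scaled_prediction_error(0.9, 0.45) == pytest.approx(1.0)

    def test_zero_test_cc_gives_infinity(self):
        assert math.isinf(scaled_prediction_error(0.5, 0.0))


class TestPenaltyGrid:
    def test_three_blocks_five_candidates_gives_125(self):
        cands = [0.1, 0.2, 0.3, 0.4, 0.5]
        grid = build_penalty_grid([cands] * 3)
        assert grid.n_combinations == 125
        assert len(grid.combinations()) == 125

    def test_with_classifier_candidates_gives_625(self):
        cands = [round(0.1 * i, 1) for i in range(5, 10)]
        grid = build_penalty_grid([cands] * 3, cands)
        assert grid.n_combinations == 625

    def test_single_combination(self):
        assert build_penalty_grid([[0.3]]).combinations() == [(0.3,)]

    def test_row_major_order(self):
        grid = build_penalty_grid([[0.1, 0.2], [0.3, 0.4]])
        assert grid.combinations() == list(itertools.product([0.1, 0.2], [0.3, 0.4]))

    def test_empty_list_errors(self):
        with pytest.raises(CanonetError, match="nonempty"):
            build_penalty_grid([[]])


class TestKfoldSplit:
    def test_exact_division(self):
        folds = kfold_split(10, 5, seed=0)
        _, counts = np.unique(folds, return_counts=True)
        assert list(counts) == [2] * 5

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(kfold_split(23, 4, seed=9),
                                      kfold_split(23, 4, seed=9))

    def test_stratified_fold_class_counts(self):
        labels = np.array([1, 0] * 6)
        folds = kfold_split(12, 3, seed=1, stratify_labels=labels)
        for k in range(3):
            test = labels[folds == k]
            assert (test == 0).sum() == 2 and (test == 1).sum() == 2

    @given(st.integers(min_value=4, max_value=40), st.integers(min_value=2, max_value=6),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_partition_property(self, n, K, seed):
        if K > n:
            K = n
        folds = kfold_split(n, K, seed)
        assert folds.shape == (n,)
        vals, counts = np.unique(folds, return_counts=True)
        assert set(vals) == set(range(K))
        assert counts.max() - counts.min() <= 1

    def test_k_larger_than_n_errors(self):
        with pytest.raises(CanonetError):
            kfold_split(3, 5, seed=0)


class TestClassificationMetrics:
    def test_perfect_ranking_auc_one(self):
        m = classification_metrics(np.array([0, 0, 1, 1]),
                                   np.array([0.1, 0.2, 0.8, 0.9]))
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0

    def test_all_ties_auc_half(self):
        m = classification_metrics(np.array([0, 1, 0, 1]), np.full(4, 0.5))
        assert m["auc"] == 0.5

    def test_pairwise_enumeration_example(self):
        m = classification_metrics(np.array([1, 1, 0, 0]),
                                   np.array([0.9, 0.4, 0.6, 0.1]))
        # pairs: (0.9,0.6)+, (0.9,0.1)+, (0.4,0.6)-, (0.4,0.1)+ -> 3/4
        assert m["auc"] == pytest.approx(3.0 / 4)

    def test_single_class_errors(self):
        with pytest.raises(CanonetError):
            classification_metrics(np.ones(4), np.arange(4.0))

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=4, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_auc_equals_exhaustive_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n).astype(float)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 1)  # rounding induces ties
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        got = classification_metrics(labels, scores)["auc"]
        assert got == pytest.approx(oracle, abs=1e-12)


@pytest.fixture(scope="module")
def small_quant():
    spec = SyntheticSpec(n_subjects=120, block_sizes=(15, 15),
                         planted_sizes=(4, 4), noise_sd=0.3, seed=11)
    data, truth = generate(spec)
    return standardized(data), truth


class TestCvQuantitative:
    def test_single_combination_returned_as_best(self, small_quant):
        data, _ = small_quant
        grid = build_penalty_grid([[0.3], [0.3]])
        res = cv_quantitative(data, grid, ScalingScheme.unweighted(2), K=3, seed=0)
        assert res.best.penalties == (0.3, 0.3)

    def test_degenerate_penalty_not_selected(self, small_quant):
        data, _ = small_quant
        # l = 1/sqrt(p) keeps only one feature: weaker held-out correlation
        tiny = 1.0 / np.sqrt(15)
        grid = build_penalty_grid([[tiny, 0.5], [tiny, 0.5]])
        res = cv_quantitative(data, grid, ScalingScheme.unweighted(2), K=3, seed=0)
        assert res.best.penalties == (0.5, 0.5)

    def test_loss_consistent_with_stored_ccs_and_minimal(self, small_quant):
        data, _ = small_quant
        grid = build_penalty_grid([[0.2, 0.4], [0.2, 0.4]])
        res = cv_quantitative(data, grid, ScalingScheme.unweighted(2), K=3, seed=1)
        for rec in res.records:
            assert rec.loss == pytest.approx(
                scaled_prediction_error(rec.train_cc, rec.test_cc))
            assert res.best.loss <= rec.loss


@pytest.fixture(scope="module")
def binary_data():
    spec = SyntheticSpec(n_subjects=100, block_sizes=(15, 15),
                         planted_sizes=(4, 4), noise_sd=0.3,
                         phenotype_effect=2.0, binary=True, seed=13)
    data, _ = generate(spec)
    return standardized(data)


class TestCvBinary:
    def test_single_combination_returned_as_best(self, binary_data):
        grid = build_penalty_grid([[0.5], [0.5]], [0.9])
        res = cv_binary(binary_data, grid, K=3, seed=0)
        assert res.best.penalties == (0.5, 0.5, 0.9)
        assert res.metric_name == "auc"

    def test_permuted_phenotype_auc_near_chance(self):
        spec = SyntheticSpec(n_subjects=100, block_sizes=(15, 15),
                             planted_sizes=(4, 4), noise_sd=0.3,
                             phenotype_effect=0.0, binary=True, seed=14)
        data, _ = generate(spec)
        data = standardized(data)
        grid = build_penalty_grid([[0.5], [0.5]], [0.9])
        res = cv_binary(data, grid, K=4, seed=2)
        assert 0.35 <= res.best.loss <= 0.65

    def test_unknown_metric_lists_valid_names(self, binary_data):
        grid = build_penalty_grid([[0.5], [0.5]], [0.9])
        with pytest.raises(CanonetError, match="accuracy.*auc.*precision.*recall.*f1"):
            cv_binary(binary_data, grid, K=3, seed=0, eval_method="brier")


class TestAutoScalingFactors:
    def test_two_block_printed_example(self):
        cc = np.array([[0.0, 0.8], [0.8, 0.0]])
        scheme = auto_scaling_factors(cc, shrinkage=2.0)
        assert scheme.between[0, 1] == pytest.approx(0.4)
        np.testing.assert_allclose(scheme.pheno, [1.0, 1.0])

    def test_three_block_printed_example_rounded(self):
        cc = np.zeros((3, 3))
        cc[0, 1] = cc[1, 0] = 0.960
        cc[0, 2] = cc[2, 0] = 0.689
        cc[1, 2] = cc[2, 1] = 0.632
        scheme = auto_scaling_factors(cc, shrinkage=5.0)
        assert round(scheme.between[0, 1], 3) == 0.192
        assert round(scheme.between[0, 2], 3) == 0.138
        assert round(scheme.between[1, 2], 3) == 0.126

    def test_identity_shrinkage(self):
        cc = np.array([[0.0, -0.55], [-0.55, 0.0]])
        scheme = auto_scaling_factors(cc, shrinkage=1.0)
        assert scheme.between[0, 1] == pytest.approx(0.55)

    def test_nonpositive_shrinkage_errors(self):
        with pytest.raises(CanonetError):
            auto_scaling_factors(np.zeros((2, 2)), 0.0)


class TestPairwisePreliminaryCC:
    def test_duplicate_blocks_give_near_one(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 10))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        data = make_dataset([X, X.copy()], rng.normal(size=60))
        cc = pairwise_preliminary_cc(data)
        assert cc[0, 1] >= 0.999
        assert cc[0, 1] == cc[1, 0]

    def test_independent_noise_blocks_low_cc(self):
        rng = np.random.default_rng(16)
        A = rng.normal(size=(200, 20))
        B = rng.normal(size=(200, 20))
        A = (A - A.mean(0)) / A.std(0, ddof=1)
        B = (B - B.mean(0)) / B.std(0, ddof=1)
        data = make_dataset([A, B], rng.normal(size=200))
        assert pairwise_preliminary_cc(data)[0, 1] < 0.5


class TestCvScalingSearch:
    def test_single_candidate_returned(self, small_quant):
        data, _ = small_quant
        scheme = ScalingScheme.unweighted(2)
        grid = build_penalty_grid([[0.3], [0.3]])
        best_scheme, best, _ = cv_scaling_search(data, [scheme], grid, K=3, seed=0)
        assert best_scheme is scheme

    def test_candidate_pheno_weights_sum_to_one(self):
        for scheme in candidate_scaling_schemes(3, step=0.1):
            assert scheme.pheno.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(scheme.between[np.triu_indices(3, 1)] == 1.0)

    def test_signal_block_receives_larger_pheno_weight(self):
        # only block 1 carries phenotype signal
        rng = np.random.default_rng(17)
        z = rng.normal(size=150)
        X1 = np.column_stack([z + 0.3 * rng.normal(size=150) for _ in range(8)])
        X2 = rng.normal(size=(150, 8))
        X1 = (X1 - X1.mean(0)) / X1.std(0, ddof=1)
        X2 = (X2 - X2.mean(0)) / X2.std(0, ddof=1)
        y = z + 0.3 * rng.normal(size=150)
        data = make_dataset([X1, X2], y)
        candidates = [s for s in candidate_scaling_schemes(2, step=0.5)]
        grid = build_penalty_grid([[0.4], [0.4]])
        best_scheme, _, _ = cv_scaling_search(data, candidates, grid, K=3, seed=3)
        assert best_scheme.pheno[0] >= best_scheme.pheno[1]
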