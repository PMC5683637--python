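import numpy as np
import pytest

from oracles import auc_pairs, occc_direct, schoeners_d_direct, tss_exhaustive
from virtualsdm import (
    EnvStack,
    GridSpec,
    Raster,
    auc,
    evaluate_scores,
    independent_evaluation,
    occc,
    schoeners_d,
    tss,
)
from virtualsdm.errors import GridError, UndefinedMetricError


def random_instance(seed, max_n=12):
    """Small random scores/labels with both classes and some ties."""
    rng = np.random.default_rng(seed)
    n = rng.integers(3, max_n + 1)
    scores = rng.choice(np.round(rng.random(6), 2), size=n)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_complete_tie_scores_half(self):
        assert auc([0.6, 0.6], [1, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_pair_oracle(self, seed):
        scores, labels = random_instance(seed)
        assert auc(scores, labels) == pytest.approx(auc_pairs(scores, labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_score_negation_complements_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.linspace(0.1, 0.9, 10))  # tie-free
        labels = np.array([1] * 4 + [0] * 6)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [1, 1])


class TestTss:
    def test_perfect_separation_scores_one(self):
        stat, cut, sens, spec = tss([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert stat == 1.0
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < cut <= 0.8

    def test_known_confusion_arithmetic(self):
        # at the optimal cut (0.6): 8/10 presences at or above it, 7/10
        # absences below it -> TSS = 0.8 + 0.7 - 1
        scores = np.array([0.6] * 8 + [0.1] * 2 + [0.3] * 7 + [0.6] * 3)
        labels = np.array([1] * 10 + [0] * 10)
        stat, cut, sens, spec = tss(scores, labels)
        assert cut == pytest.approx(0.6)
        assert sens == pytest.approx(0.8) and spec == pytest.approx(0.7)
        assert stat == pytest.approx(sens + spec - 1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        scores, labels = random_instance(seed)
        stat, *_ = tss(scores, labels)
        assert stat == pytest.approx(tss_exhaustive(scores, labels))

    def test_tied_maxima_take_the_lower_threshold(self):
        # cuts 0.6 and 0.9 both reach TSS 0.5; the lower one is reported
        stat, cut, _, _ = tss([0.9, 0.6, 0.6, 0.1], [1, 1, 0, 0])
        assert stat == pytest.approx(0.5)
        assert cut == pytest.approx(0.6)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            tss([0.1, 0.2], [0, 0])


class TestSchoenersD:
    def test_identity_overlap_is_one(self, generalist):
        assert schoeners_d(generalist.suitability, generalist.suitability) == 1.0

    def test_disjoint_supports_score_zero(self):
        assert schoeners_d([1.0, 0.0, 2.0], [0.0, 5.0, 0.0]) == pytest.approx(0.0)

    def test_two_cell_worked_example(self):
        assert schoeners_d([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.5)

    def test_invariant_to_positive_rescaling_and_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(50), rng.random(50)
        assert schoeners_d(a, b) == pytest.approx(schoeners_d(7.3 * a, b))
        assert schoeners_d(a, b) == pytest.approx(schoeners_d(b, a))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(12), rng.random(12)
        assert schoeners_d(a, b) == pytest.approx(schoeners_d_direct(a, b))

    def test_zero_mass_rejected(self):
        with pytest.raises(UndefinedMetricError):
            schoeners_d([0.0, 0.0], [1.0, 1.0])

    def test_mismatched_grids_rejected(self):
        r1 = Raster(GridSpec(3, 3), np.ones((3, 3)))
        r2 = Raster(GridSpec(3, 4), np.ones((3, 4)))
        with pytest.raises(GridError):
            schoeners_d(r1, r2)


class TestOccc:
    def test_identity_agreement_is_one(self, generalist):
        assert occc(generalist.suitability, generalist.suitability) == pytest.approx(
            1.0
        )

    def test_shifted_pair_worked_example(self):
        # x=[0,1], y=[1,2]: 2*0.25 / (0.25 + 0.25 + 1) = 1/3
        assert occc([0.0, 1.0], [1.0, 2.0]) == pytest.approx(1.0 / 3.0)

    def test_independent_noise_concordance_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.random(10_000)
        b = rng.random(10_000)
        assert abs(occc(a, b)) < 0.03

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(12), rng.random(12)
        assert occc(a, b) == pytest.approx(occc_direct(a, b))
        assert occc(a, b) == pytest.approx(occc(b, a))

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_pearson_correlation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=40)
        b = 0.6 * a + rng.normal(size=40) + 0.5
        assert abs(occc(a, b)) <= abs(np.corrcoef(a, b)[0, 1]) + 1e-12

    def test_constant_pair_rejected(self):
        with pytest.raises(UndefinedMetricError):
            occc([1.0, 1.0], [1.0, 1.0])


class _IdentityModel:
    """Scores each point by its single feature (used to plug the truth in)."""

    feature_names = ["suit"]

    def predict(self, X):
        return np.asarray(X)[:, 0]


class _SeededRandomModel:
    feature_names = ["suit"]

    def __init__(self, seed):
        self.seed = seed

    def predict(self, X):
        return np.random.default_rng(self.seed).random(len(X))


class TestIndependentEvaluation:
    @pytest.fixture()
    def truth_stack(self, generalist):
        return EnvStack([("suit", generalist.suitability)])

    def test_truth_scorer_beats_random_scorer(self, generalist, truth_stack):
        rec = independent_evaluation(
            _IdentityModel(), generalist, truth_stack, n_eval=300, seed=5
        )
        rnd = independent_evaluation(
            _SeededRandomModel(9), generalist, truth_stack, n_eval=300, seed=5
        )
        assert rec.auc > 0.5
        assert rec.auc > rnd.auc
        assert rec.mode == "independent"

    def test_repeatable_given_seed(self, generalist, truth_stack):
        a = independent_evaluation(
            _IdentityModel(), generalist, truth_stack, n_eval=100, seed=3
        )
        b = independent_evaluation(
            _IdentityModel(), generalist, truth_stack, n_eval=100, seed=3
        )
        assert a == b

    def test_evaluate_scores_bundles_consistently(self):
        scores = [0.9, 0.7, 0.3, 0.2]
        labels = [1, 1, 0, 0]
        rec = evaluate_scores(scores, labels, replicate=2, fold=4)
        assert rec.auc == auc(scores, labels)
        assert rec.tss == tss(scores, labels)[0]
        assert (rec.mode, rec.replicate, rec.fold) == ("standard", 2, 4)
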