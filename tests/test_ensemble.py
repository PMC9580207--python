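"""Bootstrap ensemble training, voting, floored cross-entropy, seed search."""

import numpy as np
import pytest

from mirsel import (
    PenaltyConfig,
    SimulationConfig,
    cross_entropy,
    generate_cohort,
    seed_search,
    stratified_split,
    train_ensemble,
    vote_predict,
)
from mirsel.ensemble import EnsembleError, EnsembleResult, _evaluate_split
from mirsel.penalized_mlr import fit_mlr_en, predict_class, select_params
from mirsel.sampling import bootstrap_per_subtype, derived_seed

FAST_CV = PenaltyConfig(
    alpha_grid=(0.2, 0.8),
    lambda_path_length=5,
    cv_folds=3,
    convergence_tol=1e-6,
)


@pytest.fixture(scope="module")
def trained(small_cohort):
    cohort, truth = small_cohort
    split = stratified_split(cohort.labels, seed=2)
    ensemble = train_ensemble(cohort, split, M=5, config=FAST_CV, seed=3)
    return cohort, truth, split, ensemble


class TestTrainEnsemble:
    def test_single_model_ensemble_equals_seeded_fit(self, small_cohort):
        cohort, _ = small_cohort
        split = stratified_split(cohort.labels, seed=1)
        ensemble = train_ensemble(cohort, split, M=1, config=FAST_CV, seed=7)
        idx = bootstrap_per_subtype(split, cohort.labels, derived_seed(7, 0, 0))
        Xb, yb = cohort.values[idx], cohort.labels[idx]
        a0, l0 = select_params(Xb, yb, FAST_CV, seed=derived_seed(7, 0, 1))
        direct = fit_mlr_en(Xb, yb, a0, l0, FAST_CV)
        assert np.array_equal(
            ensemble.models[0].coefficients, direct.coefficients
        )

    def test_deterministic_given_seed(self, small_cohort):
        cohort, _ = small_cohort
        split = stratified_split(cohort.labels, seed=1)
        a = train_ensemble(cohort, split, M=2, config=FAST_CV, seed=4)
        b = train_ensemble(cohort, split, M=2, config=FAST_CV, seed=4)
        for ma, mb in zip(a.models, b.models):
            assert np.array_equal(ma.coefficients, mb.coefficients)

    def test_vote_rows_sum_to_M(self, trained):
        _, _, _, ensemble = trained
        assert (ensemble.vote_matrix.sum(axis=1) == ensemble.M).all()

    def test_signal_recovery_beats_prior_accuracy(self, trained):
        cohort, _, split, ensemble = trained
        y_test = cohort.labels[split.test_indices]
        labels, _ = vote_predict(ensemble, cohort.values[split.test_indices])
        accuracy = np.mean(labels == y_test)
        _, counts = np.unique(cohort.labels, return_counts=True)
        prior_accuracy = counts.max() / counts.sum()
        assert accuracy > prior_accuracy


class TestVotePredict:
    def test_unanimous_vote(self, trained):
        cohort, _, split, ensemble = trained
        X = cohort.values[split.test_indices][:1]
        per_model = [predict_class(m, X)[0] for m in ensemble.models]
        labels, fractions = vote_predict(ensemble, X)
        if len(set(per_model)) == 1:
            assert labels[0] == per_model[0]
        assert np.isclose(fractions.sum(), 1.0)

    def test_tie_breaks_to_smallest_class(self):
        # two constant models voting for classes 2 and 1 respectively
        from mirsel.penalized_mlr import MlrModel

        def constant_model(code):
            b = np.full(5, -10.0)
            b[code - 1] = 10.0
            return MlrModel(
                coefficients=np.zeros((2, 5)),
                intercepts=b,
                alpha0=0.5,
                lambda0=0.1,
                objective_value=0.0,
                classes=np.arange(1, 6),
            )

        from mirsel.sampling import SplitResult

        split = SplitResult(
            train_indices=np.array([0]),
            test_indices=np.array([1]),
            seed=0,
            per_subtype_train_counts={1: 1},
        )
        ensemble = EnsembleResult(
            models=[constant_model(2), constant_model(1)],
            split=split,
            vote_matrix=np.array([[1, 1, 0, 0, 0]]),
            M=2,
        )
        labels, fractions = vote_predict(ensemble, np.zeros((1, 2)))
        assert labels[0] == 1  # (1 vote, 1 vote) -> smallest class wins
        assert np.allclose(fractions, [[0.5, 0.5, 0, 0, 0]])

    def test_empty_ensemble_rejected(self):
        from mirsel.sampling import SplitResult

        split = SplitResult(
            train_indices=np.array([0]),
            test_indices=np.array([], dtype=int),
            seed=0,
            per_subtype_train_counts={1: 1},
        )
        ensemble = EnsembleResult(
            models=[], split=split, vote_matrix=np.zeros((0, 5)), M=0
        )
        with pytest.raises(EnsembleError):
            vote_predict(ensemble, np.zeros((1, 2)))


class TestCrossEntropy:
    def test_perfect_votes_give_zero(self):
        fractions = np.eye(5)[[0, 2, 4]]
        assert cross_entropy(fractions, np.array([1, 3, 5])) == 0.0

    def test_zero_vote_sample_contributes_floor(self):
        fractions = np.array([[0.0, 1.0, 0.0, 0.0, 0.0]])
        value = cross_entropy(fractions, np.array([1]))
        assert np.isclose(value, -np.log(0.001))
        assert np.isclose(value, 6.9078, atol=5e-5)

    def test_hand_computed_two_sample_case(self):
        fractions = np.array(
            [[0.5, 0.5, 0.0, 0.0, 0.0], [0.25, 0.25, 0.25, 0.25, 0.0]]
        )
        value = cross_entropy(fractions, np.array([1, 2]))
        assert np.isclose(value, (-np.log(0.5) - np.log(0.25)) / 2)
        assert np.isclose(value, 1.0397, atol=5e-5)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.full((1, 5), 0.2), np.array([6]))

    def test_nonnegative_with_equality_iff_perfect(self):
        rng = np.random.default_rng(0)
        fractions = rng.dirichlet(np.ones(5), size=20)
        y = rng.integers(1, 6, size=20)
        assert cross_entropy(fractions, y) > 0.0


class TestSeedSearch:
    @staticmethod
    def stub(table):
        def evaluate(cohort, split, M, config, seed):
            return table[seed]

        return evaluate

    def test_single_repeat_returns_seed_one(self, small_cohort):
        cohort, _ = small_cohort
        result = seed_search(
            cohort, n_repeats=1, M=1, config=FAST_CV,
            evaluate=self.stub({1: (0.5, 1.0)}),
        )
        assert result.best_seed == 1

    def test_argmax_accuracy_wins(self, small_cohort):
        cohort, _ = small_cohort
        table = {1: (0.5, 1.0), 2: (0.9, 1.0), 3: (0.7, 1.0)}
        result = seed_search(
            cohort, n_repeats=3, M=1, config=FAST_CV, evaluate=self.stub(table)
        )
        assert result.best_seed == 2

    def test_accuracy_tie_breaks_to_lower_cross_entropy(self, small_cohort):
        cohort, _ = small_cohort
        table = {1: (0.9, 0.6), 2: (0.9, 0.4)}
        result = seed_search(
            cohort, n_repeats=2, M=1, config=FAST_CV, evaluate=self.stub(table)
        )
        assert result.best_seed == 2

    def test_failed_repeat_recorded_not_dropped(self, small_cohort):
        cohort, _ = small_cohort

        def flaky(cohort, split, M, config, seed):
            if seed == 1:
                raise RuntimeError("boom")
            return 0.8, 0.5

        with pytest.warns(UserWarning, match="seed 1 failed"):
            result = seed_search(
                cohort, n_repeats=2, M=1, config=FAST_CV, evaluate=flaky
            )
        assert len(result.per_seed) == 2
        assert np.isnan(result.per_seed[0][1])
        assert result.best_seed == 2

    def test_real_search_is_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        a = seed_search(cohort, n_repeats=2, M=2, config=FAST_CV)
        b = seed_search(cohort, n_repeats=2, M=2, config=FAST_CV)
        assert a.per_seed == b.per_seed


class TestEnsembleVersusWeakLearner:
    def test_vote_accuracy_at_least_median_single_model(self, small_config):
        """Over 10 replicate cohorts, the vote beats the median member ≥80%."""
        import dataclasses

        wins = 0
        reps = 10
        for seed in range(reps):
            cohort, _ = generate_cohort(
                dataclasses.replace(small_config, seed=100 + seed)
            )
            split = stratified_split(cohort.labels, seed=1)
            ensemble = train_ensemble(
                cohort, split, M=5, config=FAST_CV, seed=seed
            )
            X = cohort.values[split.test_indices]
            y = cohort.labels[split.test_indices]
            vote_labels, _ = vote_predict(ensemble, X)
            vote_acc = np.mean(vote_labels == y)
            single = np.median(
                [np.mean(predict_class(m, X) == y) for m in ensemble.models]
            )
            wins += vote_acc >= single
        assert wins >= 0.8 * reps
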