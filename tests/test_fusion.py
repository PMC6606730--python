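"""Choquet integral, fuzzy measures, QP measure learning and fused
classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emofuse.containers import ValidationError
from emofuse.fusion import (
    ConfidenceProfile,
    FuzzyMeasure,
    ModalityClassifier,
    build_measure_qp,
    choquet_integral,
    classify_fused,
    global_confidence,
    learn_fuzzy_measures,
    margin_objective,
    profiles_from_confidences,
    proper_subsets,
    train_modality_classifier,
)


def choquet_by_level_sets(f, mu):
    """Independent oracle: integrate mu({f >= t}) over t via the sorted
    breakpoints (layer-cake representation of the Choquet integral)."""
    f = np.asarray(f, dtype=float)
    levels = np.concatenate([[0.0], np.sort(np.unique(f))])
    total = 0.0
    for lo, hi in zip(levels[:-1], levels[1:]):
        level_set = frozenset(np.flatnonzero(f >= hi))
        total += (hi - lo) * mu.mu(level_set)
    return total


def random_measure(n, rng):
    """Random monotone normalized measure built by a max-cascade over the
    subset lattice."""
    coeffs = {}
    for s in proper_subsets(n):
        lower = max((coeffs[s - {e}] for e in s if len(s) > 1), default=0.0)
        coeffs[s] = float(rng.uniform(lower, 1.0))
    return FuzzyMeasure(n, coeffs)


class TestFuzzyMeasure:
    def test_boundary_values_implicit(self):
        mu = FuzzyMeasure.uniform(3)
        assert mu.mu(set()) == 0.0
        assert mu.mu({0, 1, 2}) == 1.0

    def test_monotonicity_violation_rejected(self):
        coeffs = {s: len(s) / 3 for s in proper_subsets(3)}
        coeffs[frozenset({0, 1})] = 0.1  # below its subset {0} at 1/3
        with pytest.raises(ValidationError):
            FuzzyMeasure(3, coeffs)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            FuzzyMeasure(2, {frozenset({0}): 1.5, frozenset({1}): 0.5})

    def test_dict_roundtrip(self, rng):
        mu = random_measure(3, rng)
        again = FuzzyMeasure.from_dict(3, mu.to_dict())
        assert again.coefficients == mu.coefficients


class TestChoquetIntegral:
    def test_hand_worked_two_classifier_case(self):
        mu = FuzzyMeasure(2, {frozenset({0}): 1.0, frozenset({1}): 0.5})
        # 0.2 * mu(X) + (0.8 - 0.2) * mu({x2}) = 0.2 + 0.6 * 0.5
        assert choquet_integral([0.2, 0.8], mu) == pytest.approx(0.5)

    def test_idempotent_on_constant_input(self, rng):
        mu = random_measure(3, rng)
        assert choquet_integral([0.4, 0.4, 0.4], mu) == pytest.approx(0.4)

    def test_extreme_measures_give_max_and_min(self):
        n = 3
        top = FuzzyMeasure(n, {s: 1.0 for s in proper_subsets(n)})
        bottom = FuzzyMeasure(n, {s: 0.0 for s in proper_subsets(n)})
        f = [0.2, 0.9, 0.5]
        assert choquet_integral(f, top) == pytest.approx(0.9)
        assert choquet_integral(f, bottom) == pytest.approx(0.2)

    def test_additive_measure_reduces_to_weighted_mean(self, rng):
        w = np.array([0.5, 0.2, 0.3])
        mu = FuzzyMeasure.additive(w)
        f = rng.uniform(0, 1, 3)
        assert choquet_integral(f, mu) == pytest.approx(float(w @ f))

    def test_out_of_range_confidences_rejected(self):
        mu = FuzzyMeasure.uniform(2)
        with pytest.raises(ValidationError):
            choquet_integral([0.5, 1.5], mu)

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(2, 4),
        f_seed=st.integers(0, 10_000),
        mu_seed=st.integers(0, 10_000),
    )
    def test_matches_level_set_oracle(self, n, f_seed, mu_seed):
        f = np.random.default_rng(f_seed).uniform(0, 1, n)
        mu = random_measure(n, np.random.default_rng(mu_seed))
        assert choquet_integral(f, mu) == pytest.approx(
            choquet_by_level_sets(f, mu), abs=1e-12
        )
        assert min(f) - 1e-12 <= choquet_integral(f, mu) <= max(f) + 1e-12

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(2, 4),
        seed=st.integers(0, 10_000),
        coord=st.integers(0, 3),
        bump=st.floats(0.0, 0.3),
    )
    def test_monotone_in_each_coordinate(self, n, seed, coord, bump):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0, 0.7, n)
        mu = random_measure(n, rng)
        g = f.copy()
        g[coord % n] += bump
        assert choquet_integral(g, mu) >= choquet_integral(f, mu) - 1e-12


class TestGlobalConfidence:
    def test_identical_classifiers_give_shared_value(self):
        prof = ConfidenceProfile(
            np.array([[0.7, 0.2], [0.7, 0.2]]), ("a", "b"), (1, 2)
        )
        measures = {1: FuzzyMeasure.uniform(2), 2: FuzzyMeasure.uniform(2)}
        g = global_confidence(prof, measures)
        assert np.allclose(g, [0.7, 0.2])

    def test_uniform_measure_is_arithmetic_mean(self, rng):
        mat = rng.uniform(0, 1, (3, 4))
        prof = ConfidenceProfile(mat, ("a", "b", "c"), (1, 2, 3, 4))
        measures = {c: FuzzyMeasure.uniform(3) for c in (1, 2, 3, 4)}
        assert np.allclose(global_confidence(prof, measures), mat.mean(axis=0))

    def test_measure_count_mismatch_rejected(self):
        prof = ConfidenceProfile(np.zeros((2, 3)), ("a", "b"), (1, 2, 3))
        with pytest.raises(ValidationError):
            global_confidence(prof, {1: FuzzyMeasure.uniform(2)})


class TestClassifyFused:
    def test_dominant_class_wins(self):
        prof = ConfidenceProfile(
            np.array([[0.9, 0.1], [0.8, 0.2]]), ("a", "b"), (1, 2)
        )
        measures = {1: FuzzyMeasure.uniform(2), 2: FuzzyMeasure.uniform(2)}
        assert classify_fused(prof, measures) == 1

    def test_tie_breaks_to_lowest_class_id(self):
        prof = ConfidenceProfile(
            np.array([[0.5, 0.5], [0.5, 0.5]]), ("a", "b"), (3, 4)
        )
        measures = {3: FuzzyMeasure.uniform(2), 4: FuzzyMeasure.uniform(2)}
        assert classify_fused(prof, measures) == 3


def synthetic_profiles(rng, n_samples=60, good_acc=1.0, m=2):
    """Profiles where classifier 0 is accurate with prob good_acc and
    classifier 1 emits random confidences."""
    profiles, labels = [], []
    cids = tuple(range(1, m + 1))
    for k in range(n_samples):
        y = cids[k % m]
        good = np.full(m, 0.1 / (m - 1))
        target = y if rng.uniform() < good_acc else cids[(k + 1) % m]
        good[cids.index(target)] = 0.9
        rand = rng.uniform(0, 1, m)
        rand /= rand.sum()
        profiles.append(
            ConfidenceProfile(np.vstack([good, rand]), ("good", "rand"), cids)
        )
        labels.append(y)
    return profiles, labels


class TestMeasureQP:
    def test_variable_count_is_m_times_2n_minus_2(self, rng):
        profiles, labels = synthetic_profiles(rng)
        qp = build_measure_qp(profiles, labels)
        assert qp.n_variables == 2 * (2**2 - 2) == 4

    def test_quadratic_form_matches_direct_objective(self, rng):
        """The expanded QP evaluated at random feasible measures equals the
        brute-force evaluation of the margin objective."""
        profiles, labels = synthetic_profiles(rng, n_samples=30)
        qp = build_measure_qp(profiles, labels)
        p = 2**2 - 2
        for _ in range(50):
            measures = {c: random_measure(2, rng) for c in (1, 2)}
            vec = np.concatenate([measures[c].to_vector() for c in qp.class_ids])
            direct = margin_objective(profiles, labels, measures)
            assert qp.objective(vec) == pytest.approx(direct, abs=1e-8)

    def test_constraints_reject_nonmonotone_accept_uniform(self, rng):
        # three classifiers so the lattice has genuine cover relations
        profiles, labels = [], []
        for k in range(12):
            y = k % 2 + 1
            profiles.append(ConfidenceProfile(
                rng.uniform(0, 1, (3, 2)), ("a", "b", "c"), (1, 2)
            ))
            labels.append(y)
        qp = build_measure_qp(profiles, labels)
        uni = np.tile(FuzzyMeasure.uniform(3).to_vector(), 2)
        assert np.all(qp.A_ineq @ uni + qp.b_ineq >= -1e-12)
        bad = uni.copy()
        bad[3] = 0.01  # pair {0,1} below singleton {0} (= 1/3)
        assert np.any(qp.A_ineq @ bad + qp.b_ineq < 0)

    def test_perfect_classifier_outweighs_random_one(self, rng):
        profiles, labels = synthetic_profiles(rng)
        measures = learn_fuzzy_measures(profiles, labels)
        for c, mu in measures.items():
            assert mu.mu({0}) > mu.mu({1})

    def test_learned_objective_beats_any_known_measure(self, rng):
        profiles, labels = synthetic_profiles(rng, n_samples=40)
        learned = learn_fuzzy_measures(profiles, labels, ridge=0.0)
        J_learned = margin_objective(profiles, labels, learned)
        true = {c: random_measure(2, rng) for c in (1, 2)}
        uniform = {c: FuzzyMeasure.uniform(2) for c in (1, 2)}
        assert J_learned <= margin_objective(profiles, labels, true) + 1e-6
        assert J_learned <= margin_objective(profiles, labels, uniform) + 1e-6

    def test_regularized_solution_never_worse_than_uniform(self, rng):
        profiles, labels = synthetic_profiles(rng, n_samples=40, good_acc=0.6)
        learned = learn_fuzzy_measures(profiles, labels)  # default ridge
        uniform = {c: FuzzyMeasure.uniform(2) for c in (1, 2)}
        assert margin_objective(profiles, labels, learned) <= margin_objective(
            profiles, labels, uniform
        ) + 1e-9

    def test_symmetric_classifiers_get_equal_coefficients(self, rng):
        profiles, labels = [], []
        for k in range(40):
            y = k % 2 + 1
            conf = np.array([0.8, 0.2]) if y == 1 else np.array([0.2, 0.8])
            profiles.append(
                ConfidenceProfile(np.vstack([conf, conf]), ("a", "b"), (1, 2))
            )
            labels.append(y)
        measures = learn_fuzzy_measures(profiles, labels)
        for c, mu in measures.items():
            assert mu.mu({0}) == pytest.approx(mu.mu({1}), abs=1e-3)

    def test_learned_measures_satisfy_invariants(self, rng):
        profiles, labels = synthetic_profiles(rng, n_samples=50, good_acc=0.7)
        for mu in learn_fuzzy_measures(profiles, labels).values():
            mu.validate()  # raises on violation


class TestModalityClassifier:
    def test_separable_toy_set_fits_perfectly(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2))])
        y = np.array([1] * 10 + [2] * 10)
        clf = train_modality_classifier(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_confidence_rows_sum_to_one(self, rng):
        X = rng.uniform(0, 1, (30, 4))
        y = rng.integers(1, 6, 30)
        while len(np.unique(y)) < 2:
            y = rng.integers(1, 6, 30)
        clf = train_modality_classifier(X, y)
        conf = clf.confidences(X)
        assert np.allclose(conf.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((conf >= 0) & (conf <= 1))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValidationError):
            train_modality_classifier(np.zeros((5, 2)), [1] * 5)

    def test_absent_classes_get_zero_confidence(self, rng):
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2))])
        y = np.array([1] * 10 + [4] * 10)
        conf = train_modality_classifier(X, y).confidences(X)
        assert np.allclose(conf[:, [1, 2, 4]], 0.0)

    def test_profiles_stacking(self, rng):
        conf = {"a": rng.uniform(0, 1, (5, 3)), "b": rng.uniform(0, 1, (5, 3))}
        profs = profiles_from_confidences(conf, (1, 2, 3))
        assert len(profs) == 5
        assert np.allclose(profs[2].matrix[0], conf["a"][2])
        assert np.allclose(profs[2].matrix[1], conf["b"][2])
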