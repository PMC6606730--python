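"""Decision-level fusion by the discrete Choquet integral.

Each modality classifier emits per-class confidence factors in [0,1]; a
per-class fuzzy measure over classifier coalitions weights them through the
Choquet integral into a global confidence, and the predicted class is the
argmax. The measures are learned from training confidences by minimizing a
squared margin deficit, a convex quadratic program under the fuzzy-measure
monotonicity and bound constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from sklearn.svm import SVC

from .containers import ValidationError

logger = logging.getLogger(__name__)

_EPS = 1e-9


def proper_subsets(n: int) -> list[frozenset[int]]:
    """Nonempty proper subsets of {0..n-1}: singletons first, then pairs, ...
    (the coefficient ordering of the stacked measure vector)."""
    subsets: list[frozenset[int]] = []
    for size in range(1, n):
        for combo in combinations(range(n), size):
            subsets.append(frozenset(combo))
    return subsets


class FuzzyMeasure:
    """Normalized monotone set function on subsets of n classifier indices.

    mu(empty) = 0 and mu(X) = 1 are implicit; coefficients holds the values
    on every nonempty proper subset.
    """

    def __init__(self, n: int, coefficients: Mapping[frozenset[int], float]):
        self.n = int(n)
        if self.n < 1:
            raise ValidationError("need at least one classifier")
        expected = set(proper_subsets(self.n))
        given = {frozenset(k) for k in coefficients}
        if given != expected:
            raise ValidationError(
                "coefficients must cover exactly the nonempty proper subsets"
            )
        self.coefficients = {frozenset(k): float(v) for k, v in coefficients.items()}
        self.validate()

    def mu(self, subset) -> float:
        s = frozenset(subset)
        if not s:
            return 0.0
        if s == frozenset(range(self.n)):
            return 1.0
        try:
            return self.coefficients[s]
        except KeyError:
            raise ValidationError(f"subset {sorted(s)} outside index set") from None

    def validate(self, tol: float = 1e-8) -> None:
        """Bounds and monotonicity over every cover pair of the lattice."""
        for s, v in self.coefficients.items():
            if not (-tol <= v <= 1 + tol):
                raise ValidationError(f"mu({sorted(s)}) = {v} outside [0,1]")
        full = frozenset(range(self.n))
        for s in self.coefficients:
            for e in full - s:
                if self.mu(s | {e}) < self.mu(s) - tol:
                    raise ValidationError(
                        f"monotonicity violated: mu({sorted(s | {e})}) < mu({sorted(s)})"
                    )

    @classmethod
    def uniform(cls, n: int) -> "FuzzyMeasure":
        """Additive symmetric measure: mu(A) = |A|/n (Choquet = arithmetic mean)."""
        return cls(n, {s: len(s) / n for s in proper_subsets(n)})

    @classmethod
    def additive(cls, weights: Sequence[float]) -> "FuzzyMeasure":
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("additive weights must be nonnegative and sum to 1")
        n = len(w)
        return cls(n, {s: float(sum(w[i] for i in s)) for s in proper_subsets(n)})

    def to_vector(self, order: Sequence[frozenset[int]] | None = None) -> np.ndarray:
        order = list(order) if order is not None else proper_subsets(self.n)
        return np.array([self.coefficients[s] for s in order])

    @classmethod
    def from_vector(cls, n: int, vec: np.ndarray) -> "FuzzyMeasure":
        order = proper_subsets(n)
        return cls(n, dict(zip(order, np.asarray(vec, dtype=float))))

    def to_dict(self) -> dict[str, float]:
        return {
            ",".join(map(str, sorted(s))): v for s, v in self.coefficients.items()
        }

    @classmethod
    def from_dict(cls, n: int, d: Mapping[str, float]) -> "FuzzyMeasure":
        return cls(
            n, {frozenset(map(int, k.split(","))): v for k, v in d.items()}
        )


def _check_confidences(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < -_EPS) or np.any(f > 1 + _EPS):
        raise ValidationError("confidence factors must lie in [0,1]")
    return np.clip(f, 0.0, 1.0)


def choquet_linear_coeffs(f: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """The Choquet integral as an affine function of the proper-subset
    coefficient vector: integral = coeffs . mu_vec + const (the constant is
    the contribution of mu(X) = 1)."""
    f = _check_confidences(f)
    order = np.argsort(f, kind="stable")
    subsets = proper_subsets(n)
    index = {s: i for i, s in enumerate(subsets)}
    coeffs = np.zeros(len(subsets))
    const = 0.0
    prev = 0.0
    remaining = list(order)
    for i in range(n):
        diff = f[order[i]] - prev
        prev = f[order[i]]
        A = frozenset(remaining)
        if A == frozenset(range(n)):
            const += diff  # mu(X) = 1
        elif A:
            coeffs[index[A]] += diff
        remaining = remaining[1:]
    return coeffs, const


def choquet_integral(f: Sequence[float], mu: FuzzyMeasure) -> float:
    """Discrete Choquet integral of confidences f with respect to mu.

    Sorts f ascending with f(x_(0)) = 0 and accumulates
    sum_i [f(x_(i)) - f(x_(i-1))] * mu(A_(i)) where A_(i) holds the indices
    of the n-i+1 largest values. Lies in [min f, max f].
    """
    f = _check_confidences(np.asarray(f, dtype=float))
    if len(f) != mu.n:
        raise ValidationError("confidence vector length != measure index-set size")
    coeffs, const = choquet_linear_coeffs(f, mu.n)
    return float(const + coeffs @ mu.to_vector())


@dataclass
class ConfidenceProfile:
    """Per-classifier, per-class confidence factors in [0,1]."""

    matrix: np.ndarray  # (n_classifiers, m_classes)
    classifier_ids: tuple[str, ...]
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.classifier_ids), len(self.class_ids)):
            raise ValidationError("profile shape mismatch")
        self.matrix = _check_confidences(self.matrix)

    @property
    def n_classifiers(self) -> int:
        return self.matrix.shape[0]

    @property
    def m_classes(self) -> int:
        return self.matrix.shape[1]


def global_confidence(
    profile: ConfidenceProfile, measures: Mapping[int, FuzzyMeasure]
) -> np.ndarray:
    """Per-class fused confidence: Choquet integral of each class's column
    with that class's measure."""
    if set(measures) != set(profile.class_ids):
        raise ValidationError("need exactly one measure per class")
    return np.array(
        [
            choquet_integral(profile.matrix[:, j], measures[cid])
            for j, cid in enumerate(profile.class_ids)
        ]
    )


def classify_fused(
    profile: ConfidenceProfile, measures: Mapping[int, FuzzyMeasure]
) -> int:
    """Class with the highest global confidence; ties break to the lowest id."""
    g = global_confidence(profile, measures)
    best = np.flatnonzero(g == g.max())
    if len(best) > 1:
        logger.info("fused-confidence tie among %s; lowest class id chosen",
                    [profile.class_ids[i] for i in best])
    return int(profile.class_ids[best[0]])


# ---------------------------------------------------------------------------
# measure learning
# ---------------------------------------------------------------------------


@dataclass
class QPProblem:
    """minimize 0.5 mu^T D mu + Gamma^T mu  s.t.  A_ineq mu + b_ineq >= 0,
    over the stacked per-class measure coefficient vector."""

    D: np.ndarray
    Gamma: np.ndarray
    A_ineq: np.ndarray
    b_ineq: np.ndarray
    constant: float
    n_classifiers: int
    m_classes: int
    class_ids: tuple[int, ...]

    @property
    def n_variables(self) -> int:
        return self.D.shape[0]

    def objective(self, mu: np.ndarray) -> float:
        """J evaluated at a stacked coefficient vector (up to nothing: the
        additive constant is included, so this equals the margin objective)."""
        mu = np.asarray(mu, dtype=float)
        return float(0.5 * mu @ self.D @ mu + self.Gamma @ mu + self.constant)


def _competitor(profile: ConfidenceProfile, true_class: int) -> int:
    """Strongest competing class under the uniform additive measure
    (column means), fixed before optimization so the QP stays quadratic."""
    means = profile.matrix.mean(axis=0)
    best, best_v = None, -np.inf
    for j, cid in enumerate(profile.class_ids):
        if cid == true_class:
            continue
        if means[j] > best_v:
            best, best_v = cid, means[j]
    return best


def build_measure_qp(
    profiles: Sequence[ConfidenceProfile],
    labels: Sequence[int],
    class_ids: Sequence[int] | None = None,
) -> QPProblem:
    """Quadratic expansion of the squared margin-deficit objective

        J = sum_k (Phi^y_k(true) - Phi^c_k(competitor) - 1)^2

    over the stacked measure vector (per class: singletons, then pairs, ...).
    Constraints encode the [0,1] bounds and every monotonicity cover relation
    of the subset lattice, per class.
    """
    if len(profiles) != len(labels):
        raise ValidationError("profiles and labels differ in length")
    if not profiles:
        raise ValidationError("no training profiles")
    cids = tuple(class_ids) if class_ids is not None else profiles[0].class_ids
    if not set(labels) <= set(cids):
        raise ValidationError("labels outside the class-id set")
    if set(labels) != set(cids):
        raise ValidationError("every class must be represented in training")
    n = profiles[0].n_classifiers
    m = len(cids)
    subsets = proper_subsets(n)
    p = len(subsets)  # 2^n - 2
    nvar = m * p
    pos = {cid: k for k, cid in enumerate(cids)}

    D = np.zeros((nvar, nvar))
    Gamma = np.zeros(nvar)
    constant = 0.0
    for profile, y in zip(profiles, labels):
        c = _competitor(profile, y)
        jy = profile.class_ids.index(y)
        jc = profile.class_ids.index(c)
        cy, ky = choquet_linear_coeffs(profile.matrix[:, jy], n)
        cc, kc = choquet_linear_coeffs(profile.matrix[:, jc], n)
        a = np.zeros(nvar)
        a[pos[y] * p : (pos[y] + 1) * p] = cy
        a[pos[c] * p : (pos[c] + 1) * p] -= cc
        b = ky - kc - 1.0
        D += 2.0 * np.outer(a, a)
        Gamma += 2.0 * b * a
        constant += b * b

    rows, offs = [], []
    full = frozenset(range(n))
    sub_index = {s: i for i, s in enumerate(subsets)}
    for k in range(m):
        base = k * p
        for s in subsets:
            # bounds 0 <= mu(A) <= 1
            r = np.zeros(nvar)
            r[base + sub_index[s]] = 1.0
            rows.append(r)
            offs.append(0.0)
            r = np.zeros(nvar)
            r[base + sub_index[s]] = -1.0
            rows.append(r)
            offs.append(1.0)
            # cover relations mu(A + e) >= mu(A)
            for e in full - s:
                bigger = s | {e}
                r = np.zeros(nvar)
                r[base + sub_index[s]] = -1.0
                if bigger != full:
                    r[base + sub_index[bigger]] = 1.0
                    rows.append(r)
                    offs.append(0.0)
                # mu(X) = 1 >= mu(A) already enforced by the upper bound
    return QPProblem(
        D=D,
        Gamma=Gamma,
        A_ineq=np.array(rows),
        b_ineq=np.array(offs),
        constant=constant,
        n_classifiers=n,
        m_classes=m,
        class_ids=cids,
    )


def _repair(vec: np.ndarray, n: int) -> np.ndarray:
    """Clip into [0,1] and enforce monotonicity bottom-up (tiny solver slack)."""
    subsets = proper_subsets(n)
    idx = {s: i for i, s in enumerate(subsets)}
    out = np.clip(np.asarray(vec, dtype=float), 0.0, 1.0)
    for s in subsets:  # ordered by size: subsets of smaller size come first
        if len(s) == 1:
            continue
        lower = max(out[idx[s - {e}]] for e in s if len(s) > 1)
        out[idx[s]] = max(out[idx[s]], lower)
    return out


def margin_objective(
    profiles: Sequence[ConfidenceProfile],
    labels: Sequence[int],
    measures: Mapping[int, FuzzyMeasure],
) -> float:
    """Direct (non-expanded) evaluation of J for given measures."""
    total = 0.0
    for profile, y in zip(profiles, labels):
        c = _competitor(profile, y)
        jy = profile.class_ids.index(y)
        jc = profile.class_ids.index(c)
        phi_y = choquet_integral(profile.matrix[:, jy], measures[y])
        phi_c = choquet_integral(profile.matrix[:, jc], measures[c])
        total += (phi_y - phi_c - 1.0) ** 2
    return total


def learn_fuzzy_measures(
    profiles: Sequence[ConfidenceProfile],
    labels: Sequence[int],
    class_ids: Sequence[int] | None = None,
    maxiter: int = 200,
    ridge: float = 0.1,
) -> dict[int, FuzzyMeasure]:
    """Solve the measure-learning QP; fall back to the uniform measure if the
    solver fails or does not improve on it.

    ridge shrinks the solution toward the uniform (mean-fusion) measure by
    adding ridge * n_samples * ||mu - mu_uniform||^2 to the objective. The
    margin target of 1 is usually unreachable, which makes the unregularized
    problem reward whichever classifier happens to emit the sharper training
    confidences; the shrinkage keeps coalition importances from flipping on
    that noise while leaving a genuinely better classifier upweighted. The
    regularized optimum still satisfies J(learned) <= J(uniform).
    """
    qp = build_measure_qp(profiles, labels, class_ids=class_ids)
    n, m, p = qp.n_classifiers, qp.m_classes, 2**qp.n_classifiers - 2
    uniform_vec = np.tile(FuzzyMeasure.uniform(n).to_vector(), m)
    lam = ridge * len(labels)
    D_reg = qp.D + 2.0 * lam * np.eye(qp.n_variables)
    G_reg = qp.Gamma - 2.0 * lam * uniform_vec

    def fun(x: np.ndarray) -> float:
        return float(0.5 * x @ D_reg @ x + G_reg @ x)

    def jac(x: np.ndarray) -> np.ndarray:
        return D_reg @ x + G_reg

    cons = [
        {
            "type": "ineq",
            "fun": lambda x: qp.A_ineq @ x + qp.b_ineq,
            "jac": lambda x: qp.A_ineq,
        }
    ]
    res = optimize.minimize(
        fun,
        uniform_vec,
        jac=jac,
        method="SLSQP",
        constraints=cons,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    x = res.x if res.success else uniform_vec
    if not res.success:
        logger.warning("measure QP solver failed (%s); uniform measure used",
                       res.message)
    if fun(x) > fun(uniform_vec) + 1e-12:
        x = uniform_vec
    measures: dict[int, FuzzyMeasure] = {}
    for k, cid in enumerate(qp.class_ids):
        vec = _repair(x[k * p : (k + 1) * p], n)
        measures[cid] = FuzzyMeasure.from_vector(n, vec)
    return measures


# ---------------------------------------------------------------------------
# modality classifiers
# ---------------------------------------------------------------------------


class ModalityClassifier:
    """Multiclass SVM (RBF kernel, C = 1) with calibrated per-class
    confidence factors in [0,1] summing to 1."""

    def __init__(
        self,
        modality: str = "",
        C: float = 1.0,
        gamma: str | float = "scale",
        random_state: int = 0,
        class_ids: Sequence[int] = (1, 2, 3, 4, 5),
    ):
        self.modality = modality
        self.class_ids = tuple(int(c) for c in class_ids)
        self.svm = SVC(
            kernel="rbf", C=C, gamma=gamma, probability=True, random_state=random_state
        )

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "ModalityClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValidationError("training set must contain at least 2 classes")
        if not set(y) <= set(self.class_ids):
            raise ValidationError("labels outside the declared class-id set")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self.svm.fit(np.asarray(X, dtype=float), y)
        return self

    def confidences(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, m_classes) confidence factors aligned to class_ids;
        classes absent from training get confidence 0."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            proba = self.svm.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((proba.shape[0], len(self.class_ids)))
        for j, cls in enumerate(self.svm.classes_):
            out[:, self.class_ids.index(int(cls))] = proba[:, j]
        return np.clip(out, 0.0, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(np.asarray(X, dtype=float))


def train_modality_classifier(
    X: np.ndarray,
    y: Sequence[int],
    modality: str = "",
    svm_params: Mapping | None = None,
    class_ids: Sequence[int] = (1, 2, 3, 4, 5),
) -> ModalityClassifier:
    clf = ModalityClassifier(modality=modality, class_ids=class_ids,
                             **(dict(svm_params) if svm_params else {}))
    return clf.fit(X, y)


def profiles_from_confidences(
    conf_by_classifier: Mapping[str, np.ndarray],
    class_ids: Sequence[int],
) -> list[ConfidenceProfile]:
    """Stack per-classifier confidence matrices (n_samples x m) into one
    ConfidenceProfile per sample."""
    names = tuple(conf_by_classifier)
    mats = [np.asarray(conf_by_classifier[k]) for k in names]
    n_samples = mats[0].shape[0]
    for m in mats:
        if m.shape != mats[0].shape:
            raise ValidationError("classifier confidence shapes differ")
    return [
        ConfidenceProfile(
            matrix=np.vstack([m[i] for m in mats]),
            classifier_ids=names,
            class_ids=tuple(int(c) for c in class_ids),
        )
        for i in range(n_samples)
    ]
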