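"""ICA spatial-filter bank and SVD spatial features.

Per-trial unmixing matrices are estimated by natural-gradient Infomax ICA
(logistic nonlinearity, whitened input, annealed learning rate). A filter is
*valid* when the per-column argmax indices of |A| (A = W^-1, the mixing
matrix) form a permutation of all channels — i.e. every independent
component has a distinct dominant electrode. Valid filters are aligned so
component i sits on channel i and averaged into a mean spatial filter; the
projection of a trial through the mean filter is summarized by its singular
value decomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import EEGTrial, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ICAResult:
    W: np.ndarray  # unmixing (components x channels), including whitening
    A: np.ndarray  # mixing = pinv(W)
    converged: bool
    n_iter: int


def fit_ica(
    trial_matrix: np.ndarray,
    max_iter: int = 600,
    tol: float = 1e-5,
    rng: np.random.Generator | None = None,
    l_rate: float | None = None,
    anneal_start: int = 250,
    anneal_step: float = 0.98,
) -> ICAResult:
    """Natural-gradient Infomax ICA on a channels x samples matrix.

    The data are centred and PCA-whitened; the square unmixing matrix of the
    whitened data is optimized by the logistic-Infomax natural-gradient rule
    with learning-rate annealing. Deterministic given rng.
    """
    X = np.asarray(trial_matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D channels x samples matrix")
    n_ch, n_samp = X.shape
    if n_samp < 10 * n_ch:
        raise ValidationError(f"need >= {10 * n_ch} samples for {n_ch} channels")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite data")
    rng = rng or np.random.default_rng(0)

    X = X - X.mean(axis=1, keepdims=True)
    cov = X @ X.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    whiten = (evecs / np.sqrt(evals)).T  # PCA whitening (rows: wh. components)
    Z = whiten @ X

    W = np.eye(n_ch)
    if l_rate is None:
        l_rate = 0.01 / np.log(n_ch + 2.0)
    block = max(8, int(np.sqrt(n_samp / 3.0)))
    eye = np.eye(n_ch)
    prev_delta: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        perm = rng.permutation(n_samp)
        W_old = W.copy()
        for start in range(0, n_samp - block + 1, block):
            xb = Z[:, perm[start : start + block]]
            u = W @ xb
            y = 1.0 / (1.0 + np.exp(-u))
            grad = (block * eye + (1.0 - 2.0 * y) @ u.T) @ W
            W = W + (l_rate / block) * grad
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                # blow-up: restart with a smaller step
                W = np.eye(n_ch)
                l_rate *= 0.5
                break
        delta = (W - W_old).ravel()
        # scale-invariant criterion: component directions matter, row scale
        # keeps adapting to the logistic density long after they settle
        Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
        Wn_old = W_old / np.linalg.norm(W_old, axis=1, keepdims=True)
        change = np.linalg.norm(Wn - Wn_old) / n_ch
        # anneal when the update direction turns by more than 60 degrees:
        # near the optimum successive stochastic updates decorrelate, so the
        # step size decays and the iteration settles
        if prev_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
            if denom > 0 and delta @ prev_delta / denom < 0.5:
                l_rate *= 0.9
        prev_delta = delta
        if it >= anneal_start:
            # geometric decay: once the directions have stopped drifting the
            # stochastic fluctuation shrinks with the step size
            l_rate *= anneal_step
        if change < tol:
            converged = True
            break

    W_total = W @ whiten
    A = np.linalg.pinv(W_total)
    if not converged:
        logger.warning("Infomax did not converge within %d iterations", max_iter)
    return ICAResult(W=W_total, A=A, converged=converged, n_iter=it)


def validity_judgment(A: np.ndarray) -> tuple[bool, np.ndarray]:
    """Per-column argmax of |A| and the permutation test.

    D[h] is the channel where component h loads most strongly; the filter is
    valid iff D contains every channel index exactly once. Ties resolve to
    the lowest row index (logged).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("mixing matrix must be square")
    absA = np.abs(A)
    D = absA.argmax(axis=0)
    for h in range(A.shape[1]):
        col = absA[:, h]
        if np.sum(col == col[D[h]]) > 1:
            logger.warning("column %d argmax tie resolved to lowest row index", h)
    is_valid = len(np.unique(D)) == A.shape[0]
    return bool(is_valid), D


@dataclass
class SpatialFilterBank:
    """Valid, channel-aligned per-trial unmixing matrices and their mean."""

    valid_filters: list[np.ndarray]
    mean_filter: np.ndarray
    validity_flags: list[bool]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "filters.npz",
            mean_filter=self.mean_filter,
            **{f"filter_{i}": f for i, f in enumerate(self.valid_filters)},
        )
        (d / "bank.json").write_text(
            json.dumps(
                {
                    "n_valid": len(self.valid_filters),
                    "validity_flags": self.validity_flags,
                    "n_channels": int(self.mean_filter.shape[0]),
                }
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "SpatialFilterBank":
        d = Path(directory)
        meta = json.loads((d / "bank.json").read_text())
        data = np.load(d / "filters.npz")
        return cls(
            valid_filters=[data[f"filter_{i}"] for i in range(meta["n_valid"])],
            mean_filter=data["mean_filter"],
            validity_flags=list(meta["validity_flags"]),
        )


def _align_filter(W: np.ndarray, A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Reorder rows of W so component h sits at row D[h]; fix scale and sign
    (unit row norm, dominant mixing coefficient positive) so filters from
    different trials are commensurable before averaging."""
    n = W.shape[0]
    aligned = np.empty_like(W)
    for h in range(n):
        row = W[h].copy()
        if A[D[h], h] < 0:
            row = -row
        norm = np.linalg.norm(row)
        aligned[D[h]] = row / (norm if norm > 0 else 1.0)
    return aligned


def build_filter_bank(
    trials: Sequence[np.ndarray] | Sequence[EEGTrial],
    max_iter: int = 600,
    tol: float = 1e-5,
    seed: int = 0,
) -> SpatialFilterBank:
    """Fit ICA per trial, keep valid converged filters (aligned by D), and
    average them into the mean spatial filter."""
    if len(trials) == 0:
        raise ValidationError("need at least one trial")
    mats = [t.data if isinstance(t, EEGTrial) else np.asarray(t) for t in trials]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(mats))
    valid: list[np.ndarray] = []
    flags: list[bool] = []
    for mat, child in zip(mats, children):
        res = fit_ica(mat, max_iter=max_iter, tol=tol, rng=np.random.default_rng(child))
        ok = False
        if res.converged:
            is_valid, D = validity_judgment(res.A)
            if is_valid:
                valid.append(_align_filter(res.W, res.A, D))
                ok = True
        flags.append(ok)
    if not valid:
        raise ValidationError(
            "no valid spatial filter was obtained; increase max_iter, relax tol, "
            "or provide longer/cleaner trials"
        )
    mean_filter = np.mean(np.stack(valid, axis=0), axis=0)
    return SpatialFilterBank(
        valid_filters=valid, mean_filter=mean_filter, validity_flags=flags
    )


@dataclass
class SpatialFeatures:
    """SVD summary of a trial projected through the mean spatial filter.

    ES columns are lambda_i * v_i (v_i the unit right-singular vectors), so
    column i's norm equals the i-th singular value.
    """

    ES: np.ndarray
    singular_values: np.ndarray

    def summary_vector(self, mode: str = "lambda_only") -> np.ndarray:
        """Fixed-length vector for classification: the singular values,
        optionally followed by the leading ES column."""
        if mode == "lambda_only":
            return self.singular_values.copy()
        if mode == "lambda_plus_leading":
            return np.concatenate([self.singular_values, self.ES[:, 0]])
        raise ValidationError(f"unknown summary mode {mode!r}")


def extract_spatial_features(
    trial_matrix: np.ndarray | EEGTrial, bank: SpatialFilterBank
) -> SpatialFeatures:
    """Project a trial through the mean filter and decompose: S = U Sigma V^T,
    ES = [lambda_1 v_1, ..., lambda_n v_n]."""
    X = trial_matrix.data if isinstance(trial_matrix, EEGTrial) else np.asarray(trial_matrix)
    if bank.mean_filter.shape[1] != X.shape[0]:
        raise ValidationError("bank/channel-count mismatch")
    S = bank.mean_filter @ X
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    ES = Vt.T * s[None, :]
    return SpatialFeatures(ES=ES, singular_values=s)
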