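"""Orthogonal PLS discriminant analysis (OPLS-DA) with four cross-validation
schemes and label-permutation testing.

For a binary class vector ``y`` (coded -1/+1) and an autoscaled matrix ``X``,
OPLS-DA splits the modelled variation into one *predictive* component (the
direction covarying with class) and ``n_ortho`` *orthogonal* components that
carry systematic variation uncorrelated with class.  With ``n_ortho = 0`` the
model reduces exactly to one-component PLS-DA.

Predictive ability is summarized by ``R2Y`` (fitted explained class variance)
and ``Q2 = 1 - PRESS/TSS`` over held-out class codes under a chosen
cross-validation scheme: leave-one-out, venetian blinds (cyclic interleaved
assignment), contiguous blocks, or repeated random subsets.  Permutation
testing refits the model under randomized class labels and reports the
add-one empirical p-value of the observed Q2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .runtable import SampleMatrix

__all__ = ["OplsModel", "CvScheme", "fit_oplsda", "cross_validate",
           "permutation_test", "choose_n_ortho"]


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (single predictive component)."""

    w_pred: np.ndarray        # predictive weights (unit norm)
    p_pred: np.ndarray        # predictive loadings
    q: float                  # inner relation y = q * t
    t_pred: np.ndarray        # predictive scores (training)
    W_ortho: np.ndarray       # (n_ortho, J) orthogonal weights
    P_ortho: np.ndarray       # (n_ortho, J) orthogonal loadings
    T_ortho: np.ndarray       # (n, n_ortho) orthogonal scores
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    r2y: float
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_ortho(self) -> int:
        return self.W_ortho.shape[0]

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predicted class code (continuous) for raw-scale samples."""
        X = np.atleast_2d(np.asarray(X_raw, dtype=float))
        Xs = (X - self.x_mean) / self.x_sd
        for w_o, p_o in zip(self.W_ortho, self.P_ortho):
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, p_o)
        return self.q * (Xs @ self.w_pred) + self.y_mean

    def classify(self, X_raw: np.ndarray) -> np.ndarray:
        """'C' where the predicted code exceeds 0, else 'N'."""
        return np.where(self.predict(X_raw) > 0, "C", "N")


def _fit_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """OPLS on already-scaled X and centred y; returns component blocks."""
    cov = Xs.T @ yc
    norm = np.linalg.norm(cov)
    if norm == 0:
        raise ValueError("class vector is orthogonal to the data (no covariance)")
    w = cov / norm
    W_o, P_o, T_o = [], [], []
    Xf = Xs
    for k in range(n_ortho):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-10:
            raise ValueError(
                f"n_ortho={n_ortho} meets or exceeds the informative rank "
                f"(no orthogonal variation left at component {k + 1})")
        w_o = w_o / nrm
        t_o = Xf @ w_o
        denom = t_o @ t_o
        if denom < 1e-12:
            raise ValueError(
                f"n_ortho={n_ortho} meets or exceeds the informative rank")
        p_o = Xf.T @ t_o / denom
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    J = Xs.shape[1]
    W_o = np.array(W_o).reshape(n_ortho, J) if n_ortho else np.empty((0, J))
    P_o = np.array(P_o).reshape(n_ortho, J) if n_ortho else np.empty((0, J))
    T_o = np.array(T_o).T if n_ortho else np.empty((Xs.shape[0], 0))
    return w, p, q, t, W_o, P_o, T_o


def fit_oplsda(matrix: SampleMatrix, n_ortho: int = 0) -> OplsModel:
    """Autoscale and fit a 1+``n_ortho``-component OPLS-DA model."""
    if n_ortho < 0:
        raise ValueError(f"n_ortho must be >= 0, got {n_ortho}")
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("OPLS-DA needs both classes present")
    X = matrix.X
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    if n_ortho >= min(Xs.shape[0] - 1, Xs.shape[1]):
        raise ValueError(
            f"n_ortho={n_ortho} meets or exceeds the matrix rank bound "
            f"{min(Xs.shape[0] - 1, Xs.shape[1])}")
    y_mean = float(y.mean())
    yc = y - y_mean
    w, p, q, t, W_o, P_o, T_o = _fit_core(Xs, yc, n_ortho)
    yhat = q * t + y_mean
    ss = float(((y - yhat) ** 2).sum())
    tss = float((yc ** 2).sum())
    return OplsModel(w, p, q, t, W_o, P_o, T_o, x_mean, x_sd, y_mean,
                     1.0 - ss / tss, matrix.feature_ids)


@dataclass
class CvScheme:
    """Cross-validation split scheme.

    ``kind`` is one of ``loo``, ``venetian_blinds``, ``contiguous_blocks`` or
    ``random_subsets``.  Defaults follow the usual chemometrics conventions:
    10 splits, 10 samples per blind, 10 random-subset iterations.
    """

    kind: str = "loo"
    n_splits: int = 10
    blind_size: int = 10
    n_iterations: int = 10
    seed: int = 0

    def splits(self, n: int, rng: np.random.Generator | None = None
               ) -> list[list[np.ndarray]]:
        """Held-out index sets; outer list = iterations (one, except for
        random subsets)."""
        idx = np.arange(n)
        if self.kind == "loo":
            return [[np.array([i]) for i in idx]]
        if self.n_splits > n:
            raise ValueError(
                f"{self.n_splits} splits exceed the {n} available samples")
        if self.kind == "venetian_blinds":
            return [[idx[idx % self.n_splits == k] for k in range(self.n_splits)]]
        if self.kind == "contiguous_blocks":
            return [np.array_split(idx, self.n_splits)]
        if self.kind == "random_subsets":
            rng = rng or np.random.default_rng(self.seed)
            out = []
            for _ in range(self.n_iterations):
                perm = rng.permutation(n)
                out.append([np.sort(chunk) for chunk in
                            np.array_split(perm, self.n_splits)])
            return out
        raise ValueError(f"unknown CV scheme kind: {self.kind!r}")


def _q2_one_partition(matrix: SampleMatrix, folds, n_ortho: int) -> float:
    y = matrix.y
    press = 0.0
    for held in folds:
        tr = np.setdiff1d(np.arange(len(y)), held)
        sub = SampleMatrix(matrix.data.iloc[tr].copy(),
                           matrix.classes.iloc[tr].copy())
        model = fit_oplsda(sub, n_ortho)
        pred = model.predict(matrix.X[held])
        press += float(((y[held] - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def cross_validate(matrix: SampleMatrix, scheme: CvScheme,
                   n_ortho: int = 0) -> float:
    """Q2 = 1 - PRESS/TSS over held-out class codes under ``scheme``
    (averaged over iterations for random subsets)."""
    rng = np.random.default_rng(scheme.seed)
    partitions = scheme.splits(matrix.n_samples, rng)
    q2s = [_q2_one_partition(matrix, folds, n_ortho) for folds in partitions]
    return float(np.mean(q2s))


def permutation_test(matrix: SampleMatrix, scheme: CvScheme, n_ortho: int,
                     n_perm: int, seed: int = 0
                     ) -> tuple[float, np.ndarray, float]:
    """Label-permutation test of the cross-validated Q2.

    Returns (observed Q2, permuted Q2 values, empirical p) with the add-one
    rule ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    observed = cross_validate(matrix, scheme, n_ortho)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    labels = matrix.classes.to_numpy()
    for k in range(n_perm):
        shuffled = matrix.classes.copy()
        shuffled[:] = rng.permutation(labels)
        pm = SampleMatrix(matrix.data.copy(), shuffled)
        perms[k] = cross_validate(pm, scheme, n_ortho)
    p = (1.0 + float((perms >= observed).sum())) / (n_perm + 1.0)
    return observed, perms, p


def choose_n_ortho(matrix: SampleMatrix, max_ortho: int = 3,
                   scheme: CvScheme | None = None) -> int:
    """Pick the orthogonal-component count (0..max) maximizing CV Q2."""
    scheme = scheme or CvScheme(kind="loo")
    best, best_q2 = 0, -np.inf
    cap = min(max_ortho, matrix.n_samples - 2, len(matrix.feature_ids) - 1)
    for k in range(cap + 1):
        try:
            q2 = cross_validate(matrix, scheme, k)
        except ValueError:
            break
        if q2 > best_q2:
            best, best_q2 = k, q2
    return best
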