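"""Linear SVM "metabolic score" classification, leave-one-out evaluation, and
nested-LOOCV recursive feature elimination.

The classifier is the standard soft-margin linear SVM: samples ``x`` with
class code ``c`` (+1 = cancer ``C``, -1 = control ``N``) are separated by the
hyperplane ``w . x' + b = 0`` maximizing the margin; the decision value
``w . x' + b`` is the *metabolic score* — positive predicts cancer, negative
control.

Recursive feature elimination (RFE) repeats, from the full feature set down
to a single feature: run full LOOCV (n models, each trained on n-1 samples),
average each feature's weight across the n fold models, record the LOOCV
accuracy/sensitivity/specificity, and discard the feature with the smallest
importance ``|mean fold weight|``.  The optimal panel is the smallest feature
set whose (accuracy, sensitivity, specificity) triple is lexicographically
maximal over the whole trace.

Autoscaling modes
-----------------
``global`` (default) autoscales the full matrix once before RFE — this is
the conventional metabolomics workflow, but the held-out sample contributes
to the scaling statistics, so LOOCV estimates are optimistically biased.
``per_fold`` recomputes scaling from each training fold only (no leakage,
slower).  Both are exposed; the default matches common practice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .runtable import CLASS_CODING, SampleMatrix

__all__ = [
    "Scaling", "SvmModel", "RfeStep", "RfeTrace", "PanelSelection",
    "LoocvResult", "autoscale", "train_linear_svm", "fit_metabolic_model",
    "metabolic_score", "loocv_evaluate", "rfe", "select_optimal_panel",
]


@dataclass
class Scaling:
    """Per-feature centre/spread used for autoscaling (mean 0, SD 1)."""

    mean: np.ndarray
    sd: np.ndarray
    feature_ids: list[str]

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    @classmethod
    def identity(cls, feature_ids: list[str]) -> "Scaling":
        J = len(feature_ids)
        return cls(np.zeros(J), np.ones(J), list(feature_ids))


def autoscale(matrix: SampleMatrix) -> tuple[SampleMatrix, Scaling]:
    """Centre each feature to mean 0 and scale to unit sample SD (ddof=1).

    Returns the transformed matrix and the scaling parameters for reuse on
    held-out samples.  A zero-variance feature is an error (it cannot be
    scaled) and is named in the message.
    """
    X = matrix.X
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [matrix.feature_ids[k] for k in dead[:5]]
        raise ValueError(f"zero-variance feature(s): {names}")
    scaling = Scaling(mean, sd, matrix.feature_ids)
    data = pd.DataFrame(scaling.apply(X), index=matrix.data.index,
                        columns=matrix.data.columns)
    return SampleMatrix(data, matrix.classes.copy(),
                        None if matrix.meta is None else matrix.meta.copy()), scaling


@dataclass
class SvmModel:
    """Trained linear SVM: weights ``w``, bias ``b``, the feature order they
    refer to, the autoscaling applied before scoring, and the cost used."""

    w: np.ndarray
    b: float
    feature_ids: list[str]
    scaling: Scaling
    cost: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "w": self.w.tolist(), "b": self.b, "feature_ids": self.feature_ids,
            "scaling_mean": self.scaling.mean.tolist(),
            "scaling_sd": self.scaling.sd.tolist(), "cost": self.cost,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "SvmModel":
        d = json.loads(Path(path).read_text())
        scaling = Scaling(np.asarray(d["scaling_mean"]),
                          np.asarray(d["scaling_sd"]), d["feature_ids"])
        return cls(np.asarray(d["w"]), d["b"], d["feature_ids"], scaling,
                   d["cost"])


def _fit_svc(X: np.ndarray, y: np.ndarray, cost: float) -> tuple[np.ndarray, float]:
    m = SVC(kernel="linear", C=cost)
    m.fit(X, y)
    return m.coef_[0].copy(), float(m.intercept_[0])


def train_linear_svm(matrix: SampleMatrix, cost: float = 1.0,
                     scaling: Scaling | None = None) -> SvmModel:
    """Fit a soft-margin linear SVM on the matrix *as given* (no internal
    rescaling; pass the scaling used upstream so scoring can reapply it)."""
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if not matrix.feature_ids:
        raise ValueError("training data has no features")
    w, b = _fit_svc(matrix.X, y, cost)
    return SvmModel(w, b, matrix.feature_ids,
                    scaling or Scaling.identity(matrix.feature_ids), cost)


def fit_metabolic_model(matrix: SampleMatrix, cost: float = 1.0) -> SvmModel:
    """Autoscale then train; the returned model scores raw-scale samples."""
    scaled, scaling = autoscale(matrix)
    return train_linear_svm(scaled, cost, scaling)


def metabolic_score(model: SvmModel, x: np.ndarray) -> tuple[float, str]:
    """Score one raw-scale sample: ``w . x~' + b`` with ``x~`` the autoscaled
    vector; positive -> cancer ``C``, negative -> control ``N``.

    A score of exactly 0 is on the hyperplane; it is classified ``N``
    (conservative for a screening score) with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.feature_ids),):
        raise ValueError(
            f"sample has {x.size} features, model expects {len(model.feature_ids)}"
        )
    score = float(model.w @ model.scaling.apply(x) + model.b)
    if score == 0.0:
        warnings.warn("metabolic score is exactly 0 (on the hyperplane); "
                      "classifying as N")
        return score, "N"
    return score, "C" if score > 0 else "N"


# -- leave-one-out cross-validation ----------------------------------------


@dataclass
class LoocvResult:
    accuracy: float       # percent
    sensitivity: float    # percent, correct C / total C
    specificity: float    # percent, correct N / total N
    scores: pd.DataFrame  # sample_id, score, predicted, true


def _check_two_per_class(y: np.ndarray) -> None:
    for cls, code in CLASS_CODING.items():
        if (y == code).sum() < 2:
            raise ValueError(f"LOOCV needs >= 2 samples of class {cls}")


def _metrics(correct: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    acc = 100.0 * correct.mean()
    sens = 100.0 * correct[y == +1].mean()
    spec = 100.0 * correct[y == -1].mean()
    return acc, sens, spec


def loocv_evaluate(matrix: SampleMatrix, cost: float = 1.0,
                   scaling_mode: str = "global") -> LoocvResult:
    """Leave-one-out evaluation: n linear SVMs each trained on n-1 samples,
    the held-out sample scored by the fold model."""
    if scaling_mode not in ("global", "per_fold"):
        raise ValueError(f"unknown scaling_mode: {scaling_mode!r}")
    y = matrix.y
    _check_two_per_class(y)
    n = matrix.n_samples
    X = matrix.X
    if scaling_mode == "global":
        Xs, _ = _global_scaled(matrix)
    scores = np.empty(n)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        if scaling_mode == "global":
            Ztr, zte = Xs[tr], Xs[i]
        else:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Ztr, zte = (X[tr] - mu) / sd, (X[i] - mu) / sd
        w, b = _fit_svc(Ztr, y[tr], cost)
        scores[i] = w @ zte + b
    predicted = np.where(scores > 0, 1, -1)
    correct = predicted == y
    acc, sens, spec = _metrics(correct, y)
    df = pd.DataFrame({
        "sample_id": matrix.data.index,
        "score": scores,
        "predicted": ["C" if p > 0 else "N" for p in predicted],
        "true": matrix.classes.to_numpy(),
    })
    return LoocvResult(acc, sens, spec, df)


def _global_scaled(matrix: SampleMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [matrix.feature_ids[k] for k in dead[:5]]
        raise ValueError(f"zero-variance feature(s): {names}")
    return (X - mu) / sd, matrix.y


# -- recursive feature elimination -----------------------------------------


@dataclass
class RfeStep:
    feature_ids: list[str]
    avg_weights: np.ndarray   # fold-averaged signed weights, matching feature_ids
    accuracy: float
    sensitivity: float
    specificity: float
    eliminated: str | None    # feature discarded after this step (None at size 1)


@dataclass
class RfeTrace:
    steps: list[RfeStep] = field(default_factory=list)
    cost: float = 1.0
    scaling_mode: str = "global"

    def metrics_table(self) -> pd.DataFrame:
        """Panel size vs LOOCV metrics (accuracy-evolution curve)."""
        return pd.DataFrame({
            "panel_size": [len(s.feature_ids) for s in self.steps],
            "accuracy": [s.accuracy for s in self.steps],
            "sensitivity": [s.sensitivity for s in self.steps],
            "specificity": [s.specificity for s in self.steps],
            "eliminated": [s.eliminated for s in self.steps],
        })

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "cost": self.cost, "scaling_mode": self.scaling_mode,
            "steps": [{
                "feature_ids": s.feature_ids,
                "avg_weights": s.avg_weights.tolist(),
                "accuracy": s.accuracy, "sensitivity": s.sensitivity,
                "specificity": s.specificity, "eliminated": s.eliminated,
            } for s in self.steps],
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "RfeTrace":
        d = json.loads(Path(path).read_text())
        steps = [RfeStep(s["feature_ids"], np.asarray(s["avg_weights"]),
                         s["accuracy"], s["sensitivity"], s["specificity"],
                         s["eliminated"]) for s in d["steps"]]
        return cls(steps, d["cost"], d["scaling_mode"])


def _importance(W_mean: np.ndarray, W_abs_mean: np.ndarray, rule: str) -> np.ndarray:
    if rule == "signed_mean":
        return np.abs(W_mean)
    if rule == "mean_abs":
        return W_abs_mean
    raise ValueError(f"unknown importance rule: {rule!r}")


def rfe(matrix: SampleMatrix, cost: float = 1.0, scaling_mode: str = "global",
        importance: str = "signed_mean") -> RfeTrace:
    """Nested-LOOCV recursive feature elimination.

    At each panel size, a full LOOCV is run; each feature's weight is averaged
    over the n fold models, the LOOCV metrics are recorded, and the feature
    with the smallest importance (``|fold-mean weight|`` by default, mean
    ``|weight|`` with ``importance='mean_abs'``) is eliminated.  Ties break to
    the earliest feature in column order.  The trace has one step per panel
    size from J down to 1.

    With global scaling the LOOCV inner loop runs on a precomputed linear
    Gram matrix that is rank-1-downdated after each elimination, which is
    algebraically identical to refitting on the reduced matrix.
    """
    if len(matrix.feature_ids) < 2:
        raise ValueError("RFE needs at least 2 features")
    y = matrix.y
    _check_two_per_class(y)
    if scaling_mode == "global":
        return _rfe_gram(matrix, y, cost, importance)
    if scaling_mode != "per_fold":
        raise ValueError(f"unknown scaling_mode: {scaling_mode!r}")
    return _rfe_per_fold(matrix, y, cost, importance)


def _rfe_gram(matrix: SampleMatrix, y: np.ndarray, cost: float,
              importance: str) -> RfeTrace:
    Xs, _ = _global_scaled(matrix)
    n = len(y)
    ids = matrix.feature_ids
    active = list(range(Xs.shape[1]))
    G = Xs @ Xs.T
    trace = RfeTrace(cost=cost, scaling_mode="global")
    while active:
        Z = Xs[:, active]
        W_sum = np.zeros(len(active))
        W_abs_sum = np.zeros(len(active))
        correct = np.zeros(n, bool)
        for i in range(n):
            tr = np.ones(n, bool)
            tr[i] = False
            m = SVC(kernel="precomputed", C=cost)
            m.fit(G[np.ix_(tr, tr)], y[tr])
            dec = float(m.decision_function(G[i, tr][None, :])[0])
            correct[i] = (1 if dec > 0 else -1) == y[i]
            w = m.dual_coef_[0] @ Z[tr][m.support_]
            W_sum += w
            W_abs_sum += np.abs(w)
        acc, sens, spec = _metrics(correct, y)
        imp = _importance(W_sum / n, W_abs_sum / n, importance)
        if len(active) > 1:
            k = int(np.argmin(imp))
            elim = ids[active[k]]
        else:
            k, elim = None, None
        trace.steps.append(RfeStep([ids[a] for a in active], W_sum / n,
                                   acc, sens, spec, elim))
        if k is None:
            break
        z = Xs[:, active[k]]
        G -= np.outer(z, z)
        del active[k]
    return trace


def _rfe_per_fold(matrix: SampleMatrix, y: np.ndarray, cost: float,
                  importance: str) -> RfeTrace:
    X = matrix.X
    n = len(y)
    ids = matrix.feature_ids
    active = list(range(X.shape[1]))
    trace = RfeTrace(cost=cost, scaling_mode="per_fold")
    while active:
        Z = X[:, active]
        W_sum = np.zeros(len(active))
        W_abs_sum = np.zeros(len(active))
        correct = np.zeros(n, bool)
        for i in range(n):
            tr = np.ones(n, bool)
            tr[i] = False
            mu = Z[tr].mean(axis=0)
            sd = Z[tr].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            w, b = _fit_svc((Z[tr] - mu) / sd, y[tr], cost)
            dec = w @ ((Z[i] - mu) / sd) + b
            correct[i] = (1 if dec > 0 else -1) == y[i]
            W_sum += w
            W_abs_sum += np.abs(w)
        acc, sens, spec = _metrics(correct, y)
        imp = _importance(W_sum / n, W_abs_sum / n, importance)
        if len(active) > 1:
            k = int(np.argmin(imp))
            elim = ids[active[k]]
        else:
            k, elim = None, None
        trace.steps.append(RfeStep([ids[a] for a in active], W_sum / n,
                                   acc, sens, spec, elim))
        if k is None:
            break
        del active[k]
    return trace


@dataclass
class PanelSelection:
    feature_ids: list[str]
    size: int
    accuracy: float
    sensitivity: float
    specificity: float


def select_optimal_panel(trace: RfeTrace) -> PanelSelection:
    """Smallest panel whose (accuracy, sensitivity, specificity) triple is
    lexicographically maximal over the trace — the "minimum of N features
    reaching the best metrics" rule."""
    if not trace.steps:
        raise ValueError("empty RFE trace")
    best = max((s.accuracy, s.sensitivity, s.specificity) for s in trace.steps)
    winners = [s for s in trace.steps
               if (s.accuracy, s.sensitivity, s.specificity) == best]
    chosen = min(winners, key=lambda s: len(s.feature_ids))
    return PanelSelection(chosen.feature_ids, len(chosen.feature_ids),
                          chosen.accuracy, chosen.sensitivity,
                          chosen.specificity)
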