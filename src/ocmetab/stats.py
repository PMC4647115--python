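"""Univariate per-feature summaries and PCA-based experimental-bias checks.

Each curated feature is summarized by its class means, a signed fold change
(ratio of class means, negated when the control mean is larger, magnitude
always >= 1), and a two-sided Mann-Whitney U test.  The bias check projects
autoscaled samples onto PC1/PC2 and quantifies clustering by batch, site or
collection day as a between/within variance ratio of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .runtable import SampleMatrix

__all__ = ["signed_fold_change", "mann_whitney", "feature_summaries",
           "pca_bias_check", "FeatureSummary"]


@dataclass
class FeatureSummary:
    feature_id: str
    mean_C: float
    mean_N: float
    fold_change: float      # signed, |fc| >= 1
    U: float                # min(U_C, U_N)
    p_value: float          # two-sided
    tier: str               # 'p<0.05' | 'p<0.10' | 'ns'


def signed_fold_change(mean_C: float, mean_N: float) -> float:
    """Ratio of class means with sign: positive (= mean_C/mean_N) when the
    cancer mean is at least the control mean, else -mean_N/mean_C."""
    if mean_C <= 0 or mean_N <= 0:
        raise ValueError(
            f"class means must be positive, got C={mean_C}, N={mean_N}")
    if mean_C >= mean_N:
        return mean_C / mean_N
    return -mean_N / mean_C


def mann_whitney(group_c, group_n) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have <= 8 observations and no
    ties; tie-corrected normal approximation otherwise.  The reported U is
    ``min(U_C, U_N)`` (the classical table statistic).
    """
    c = np.asarray(group_c, dtype=float)
    n = np.asarray(group_n, dtype=float)
    if c.size == 0 or n.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.mannwhitneyu(c, n, alternative="two-sided", method="auto")
    u_c = float(res.statistic)
    u = min(u_c, c.size * n.size - u_c)
    return u, float(res.pvalue)


def _tier(p: float) -> str:
    if p < 0.05:
        return "p<0.05"
    if p < 0.10:
        return "p<0.10"
    return "ns"


def feature_summaries(matrix: SampleMatrix) -> pd.DataFrame:
    """Per-feature class means, signed fold change, U and p (one row per
    feature, sorted by p)."""
    is_c = (matrix.classes == "C").to_numpy()
    rows = []
    for f in matrix.feature_ids:
        a = matrix.data[f].to_numpy(dtype=float)
        mc, mn = float(a[is_c].mean()), float(a[~is_c].mean())
        u, p = mann_whitney(a[is_c], a[~is_c])
        fc = signed_fold_change(mc, mn) if mc > 0 and mn > 0 else np.nan
        rows.append(FeatureSummary(f, mc, mn, fc, u, p, _tier(p)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def pca_bias_check(matrix: SampleMatrix, labels) -> tuple[pd.DataFrame, float]:
    """Project autoscaled samples onto PC1/PC2 and score label clustering.

    ``labels`` is a per-sample grouping (batch, site or collection day).
    The association score is a pseudo-F: the between-group mean square of the
    PC1-PC2 scores divided by the within-group mean square; values near 1
    indicate no grouping structure, large values indicate clustering.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.data.index)
    n = matrix.n_samples
    if n < 3:
        raise ValueError(f"PCA bias check needs >= 3 samples, got {n}")
    X = matrix.X
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Xs)
    df = pd.DataFrame(scores, columns=["PC1", "PC2"], index=matrix.data.index)
    df["label"] = labels

    groups = labels.unique()
    k = len(groups)
    grand = scores.mean(axis=0)
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        sub = scores[(labels == g).to_numpy()]
        centre = sub.mean(axis=0)
        ss_between += len(sub) * float(((centre - grand) ** 2).sum())
        ss_within += float(((sub - centre) ** 2).sum())
    if k < 2 or n - k < 1 or ss_within == 0:
        score = np.inf if ss_between > 0 else 0.0
    else:
        score = (ss_between / (k - 1)) / (ss_within / (n - k))
    return df, float(score)


def pca_component_suggestion(matrix: SampleMatrix, max_components: int = 10
                             ) -> int:
    """Leave-one-out PRESS-based suggestion for the PCA component count
    (eigenvalue-one style fallback when PRESS keeps decreasing)."""
    X = matrix.X
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    n, J = Xs.shape
    cap = min(max_components, n - 2, J)
    best_k, best_press = 1, np.inf
    for k in range(1, cap + 1):
        press = 0.0
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            pca = PCA(n_components=k).fit(Xs[tr])
            comp = pca.components_
            xi = Xs[i] - pca.mean_
            press += float(((xi - (xi @ comp.T) @ comp) ** 2).sum())
        if press < best_press:
            best_k, best_press = k, press
    return best_k
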