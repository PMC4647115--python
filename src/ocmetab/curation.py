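"""Peak-list curation: presence filter, total-area normalization, pooled-QC
drift filter, blank-baseline filter, and duplicate averaging.

The composed :func:`curate` turns a run-level :class:`~ocmetab.runtable.RunTable`
into a sample-level :class:`~ocmetab.runtable.SampleMatrix`:

1. drop features detected in fewer than ``min_runs`` runs;
2. divide every run by its total peak area (each run then sums to 1);
3. drop features whose pooled-QC peak area trends with acquisition order;
4. drop features that never clear a multiple of the blank baseline in at
   least half of any sample group (all / cancer / control);
5. average duplicate injections per sample, excluding QC and blank runs.

Baseline thresholding in step 4 is performed on the *pre-normalization* area
scale: blank runs have tiny raw totals, so after total-area normalization a
blank's entries are rescaled to the same magnitude as sample entries and the
detection-limit comparison would be meaningless.  ``curate`` snapshots the raw
areas for that decision and applies the removals to the normalized table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .runtable import RunTable, SampleMatrix

__all__ = [
    "CurationParams",
    "CurationReport",
    "presence_filter",
    "tic_normalize",
    "qc_drift_filter",
    "baseline_filter",
    "average_duplicates",
    "curate",
]


@dataclass
class CurationParams:
    """Tunable thresholds of the curation pipeline."""

    min_runs: int = 40                 # presence filter
    group_fraction: float = 0.5        # baseline filter: share of a group
    baseline_multiple: float = 10.0    # baseline filter: multiple of baseline
    qc_rule: str = "slope_se"          # 'slope_se' or 'span_sd'
    qc_time_axis: str = "run_index"    # or 'acquisition_time'
    baseline_mode: str = "per_feature"  # or 'global'


@dataclass
class CurationReport:
    """Audit trail: per-stage removals and counts."""

    removed: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    baseline: dict[str, float] | float | None = None

    def record(self, stage: str, before: list[str], after: list[str]) -> None:
        gone = [f for f in before if f not in set(after)]
        self.removed[stage] = gone
        self.counts[stage] = (len(before), len(after))

    def stage_of(self, feature_id: str) -> str | None:
        for stage, ids in self.removed.items():
            if feature_id in ids:
                return stage
        return None


def presence_filter(table: RunTable, min_runs: int = 40,
                    total_runs: int | None = None) -> RunTable:
    """Remove features not present (non-missing, area > 0) in at least
    ``min_runs`` of the table's runs.

    ``total_runs`` is informational (defaults to the actual run count); the
    decision depends only on ``min_runs``.
    """
    if min_runs < 0:
        raise ValueError(f"min_runs must be >= 0, got {min_runs}")
    if total_runs is None:
        total_runs = table.n_runs
    present = (table.areas > 0).sum(axis=0)
    keep = present[present >= min_runs].index.tolist()
    return table.select_features(keep)


def tic_normalize(table: RunTable) -> RunTable:
    """Divide each run's areas by that run's total peak area (missing peaks
    excluded from the total); every run then sums to 1."""
    totals = table.areas.sum(axis=1, skipna=True)
    zero = totals <= 0
    if zero.any():
        bad = table.meta.loc[zero.to_numpy(), "run_index"].tolist()
        raise ValueError(f"run(s) with non-positive total area: {bad}")
    out = table.copy()
    out.areas = table.areas.div(totals, axis=0)
    return out


def _qc_slopes(table: RunTable, time_axis: str):
    qc = table.subset_runs(table.mask("qc_pool"))
    if qc.n_runs < 3:
        raise ValueError(
            f"QC drift filter needs >= 3 pooled-QC runs, found {qc.n_runs}"
        )
    x = qc.meta[time_axis].to_numpy(dtype=float)
    return qc, x


def qc_drift_filter(table: RunTable, rule: str = "slope_se",
                    time_axis: str = "run_index",
                    min_relative_drift: float = 1e-9,
                    ) -> tuple[RunTable, list[str]]:
    """Remove features whose pooled-QC areas trend with acquisition order.

    For each feature an ordinary-least-squares line of QC area versus
    ``time_axis`` is fit.  Under the default ``slope_se`` rule a feature is
    removed iff ``|slope| > SE(slope)`` — the slope estimate more than one of
    its own standard deviations away from zero.  The alternative ``span_sd``
    rule removes iff ``|slope| * span > SD(QC areas)``, i.e. the fitted drift
    across the whole acquisition exceeds one SD of the QC areas themselves.

    Features observed in fewer than 3 QC runs cannot be assessed and are
    removed (no evidence of QC stability).  A fitted drift smaller than
    ``min_relative_drift`` of the mean QC area over the whole acquisition is
    floating-point noise on an exactly stable feature and is treated as zero
    slope (kept).
    """
    if rule not in ("slope_se", "span_sd"):
        raise ValueError(f"unknown QC drift rule: {rule!r}")
    qc, x = _qc_slopes(table, time_axis)
    span = x.max() - x.min()
    keep: list[str] = []
    removed: list[str] = []
    for f in table.feature_ids:
        y = qc.areas[f].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            removed.append(f)
            continue
        if np.ptp(y[ok]) == 0.0:
            keep.append(f)  # exactly constant: zero slope by definition
            continue
        res = stats.linregress(x[ok], y[ok])
        scale = np.abs(y[ok]).mean()
        if scale > 0 and abs(res.slope) * span < min_relative_drift * scale:
            keep.append(f)
            continue
        if rule == "slope_se":
            drifting = abs(res.slope) > res.stderr
        else:
            drifting = abs(res.slope) * span > np.std(y[ok], ddof=1)
        (removed if drifting else keep).append(f)
    return table.select_features(keep), removed


def baseline_filter(table: RunTable, fraction: float = 0.5,
                    multiple: float = 10.0, mode: str = "per_feature",
                    ) -> tuple[RunTable, dict[str, float] | float]:
    """Purge features that never rise above ``multiple`` times the blank
    baseline in at least ``fraction`` of any sample group.

    The baseline is the maximum area observed across blank runs — per feature
    by default, or a single global scalar (max over all blanks and features)
    with ``mode='global'``.  A feature is kept iff, in at least one of the
    groups {all study samples, cancer, control}, the share of samples whose
    area is >= ``multiple * baseline`` reaches ``fraction``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if multiple < 0:
        raise ValueError(f"multiple must be >= 0, got {multiple}")
    blanks = table.subset_runs(table.mask("blank"))
    if blanks.n_runs == 0:
        raise ValueError("baseline filter needs at least one blank run")
    per_feature = blanks.areas.max(axis=0).fillna(0.0)
    if mode == "global":
        baseline = pd.Series(float(per_feature.max()), index=per_feature.index)
    elif mode == "per_feature":
        baseline = per_feature
    else:
        raise ValueError(f"unknown baseline mode: {mode!r}")

    study = table.subset_runs(table.mask("study"))
    cls = study.meta["class_label"].to_numpy()
    groups = {"all": np.ones(len(cls), bool), "C": cls == "C", "N": cls == "N"}
    keep: list[str] = []
    for f in table.feature_ids:
        a = study.areas[f].to_numpy(dtype=float)
        thresh = multiple * baseline[f]
        above = np.nan_to_num(a, nan=-np.inf) >= thresh
        if any(above[g].mean() >= fraction for g in groups.values() if g.any()):
            keep.append(f)
    out = table.select_features(keep)
    bl = float(baseline.iloc[0]) if mode == "global" else \
        {f: float(v) for f, v in per_feature.items()}
    return out, bl


def average_duplicates(table: RunTable) -> SampleMatrix:
    """Average replicate injections per study sample (missing peaks count as
    0); QC and blank runs are excluded from the output."""
    study = table.subset_runs(table.mask("study"))
    if study.n_runs == 0:
        raise ValueError("no study runs to average")
    areas = study.areas.fillna(0.0)
    areas.index = study.meta["sample_id"].to_numpy()
    data = areas.groupby(level=0, sort=False).mean()
    cls = study.meta.drop_duplicates("sample_id").set_index("sample_id")
    order = cls.index.tolist()
    data = data.loc[order]
    meta = cls[["batch_id", "site_id"]].copy()
    return SampleMatrix(data, cls["class_label"].rename("class"), meta)


def curate(table: RunTable, params: CurationParams | None = None,
           ) -> tuple[SampleMatrix, CurationReport]:
    """Run the full curation chain and return the sample matrix plus an
    audit report of what each stage removed."""
    params = params or CurationParams()
    table.validate()
    report = CurationReport()
    raw = table  # snapshot for raw-scale baseline thresholding

    before = table.feature_ids
    t1 = presence_filter(table, params.min_runs)
    report.record("presence", before, t1.feature_ids)

    t2 = tic_normalize(t1)

    t3, _ = qc_drift_filter(t2, rule=params.qc_rule, time_axis=params.qc_time_axis)
    report.record("qc_drift", t1.feature_ids, t3.feature_ids)

    raw3 = raw.select_features(t3.feature_ids)
    kept_raw, baseline = baseline_filter(
        raw3, fraction=params.group_fraction,
        multiple=params.baseline_multiple, mode=params.baseline_mode)
    t4 = t3.select_features(kept_raw.feature_ids)
    report.record("baseline", t3.feature_ids, t4.feature_ids)
    report.baseline = baseline

    if not t4.feature_ids:
        raise ValueError("no features survive curation")

    matrix = average_duplicates(t4)
    if (matrix.classes.value_counts().reindex(["C", "N"]).fillna(0) < 1).any():
        warnings.warn("curated matrix is missing one of the classes")
    return matrix, report
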