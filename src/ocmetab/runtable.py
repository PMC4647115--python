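"""Run-level and sample-level data containers for LC-MS peak-area tables.

A :class:`RunTable` is the object a peak-picking tool exports: one row per
instrument run (study sample injection, pooled-QC injection, or blank), with
acquisition metadata and one non-negative peak area per detected feature
(``NaN`` encodes a peak absent in that run).  A :class:`SampleMatrix` is the
modelling substrate produced by curation: one row per study sample with
duplicate-averaged, normalized areas and a binary class label (``C`` = cancer,
``N`` = normal control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Metadata columns of a run table, in serialization order.
META_COLUMNS = [
    "run_index",
    "sample_id",
    "replicate_index",
    "role",
    "batch_id",
    "site_id",
    "class_label",
    "acquisition_time",
]

ROLES = {"study", "qc_pool", "blank"}
CLASS_LABELS = {"C", "N", "none"}

#: Class coding used throughout: control/normal -> -1, cancer -> +1.
CLASS_CODING = {"N": -1, "C": +1}


class RunTableError(ValueError):
    """Raised when a run table violates a structural invariant."""


@dataclass
class RunTable:
    """Runs x features peak-area table with acquisition metadata.

    Parameters
    ----------
    meta : pandas.DataFrame
        One row per run with the columns in :data:`META_COLUMNS`.
    areas : pandas.DataFrame
        Same row order as ``meta``; columns are feature ids (strings), values
        are peak areas (>= 0) with ``NaN`` for absent peaks.
    """

    meta: pd.DataFrame
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.areas = self.areas.reset_index(drop=True)
        self.areas.columns = [str(c) for c in self.areas.columns]

    # -- accessors ---------------------------------------------------------

    @property
    def n_runs(self) -> int:
        return len(self.meta)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.columns)

    def mask(self, role: str) -> np.ndarray:
        return (self.meta["role"] == role).to_numpy()

    @property
    def study(self) -> "RunTable":
        return self.subset_runs(self.mask("study"))

    def subset_runs(self, mask: np.ndarray) -> "RunTable":
        return RunTable(self.meta.loc[mask].copy(), self.areas.loc[mask].copy())

    def select_features(self, feature_ids) -> "RunTable":
        """Return a new table restricted to ``feature_ids`` (order preserved)."""
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return RunTable(self.meta.copy(), self.areas[keep].copy())

    def copy(self) -> "RunTable":
        return RunTable(self.meta.copy(), self.areas.copy())

    # -- validation --------------------------------------------------------

    def validate(self) -> "RunTable":
        """Check structural invariants; raise :class:`RunTableError` naming
        the offending run/feature."""
        if len(self.meta) != len(self.areas):
            raise RunTableError(
                f"metadata has {len(self.meta)} runs but areas has {len(self.areas)}"
            )
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise RunTableError(f"missing metadata columns: {missing_cols}")
        idx = self.meta["run_index"]
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique().tolist())
            raise RunTableError(f"duplicated run_index values: {dupes}")
        bad_roles = set(self.meta["role"]) - ROLES
        if bad_roles:
            raise RunTableError(f"unknown run roles: {sorted(bad_roles)}")
        bad_cls = set(self.meta["class_label"]) - CLASS_LABELS
        if bad_cls:
            raise RunTableError(f"unknown class labels: {sorted(bad_cls)}")
        study = self.meta["role"] == "study"
        if (self.meta.loc[study, "class_label"] == "none").any():
            bad = self.meta.loc[study & (self.meta["class_label"] == "none"), "run_index"]
            raise RunTableError(f"study runs without class label: {bad.tolist()}")
        if (self.meta.loc[~study, "class_label"] != "none").any():
            bad = self.meta.loc[~study & (self.meta["class_label"] != "none"), "run_index"]
            raise RunTableError(f"non-study runs with a class label: {bad.tolist()}")
        neg = self.areas.lt(0)
        if neg.any().any():
            rows, cols = np.nonzero(neg.to_numpy())
            run = self.meta["run_index"].iloc[rows[0]]
            feat = self.areas.columns[cols[0]]
            raise RunTableError(
                f"negative peak area at run_index={run}, feature={feat!r}"
            )
        return self


@dataclass
class SampleMatrix:
    """Samples x features matrix of averaged, normalized peak areas.

    ``data`` is indexed by sample id; ``classes`` maps sample id to ``C``/``N``;
    ``meta`` optionally carries age/batch/site per sample.
    """

    data: pd.DataFrame
    classes: pd.Series
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.data.columns = [str(c) for c in self.data.columns]
        self.classes = self.classes.reindex(self.data.index)
        bad = set(self.classes.unique()) - {"C", "N"}
        if bad:
            raise ValueError(f"sample classes must be 'C' or 'N', got {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def y(self) -> np.ndarray:
        """Class coding vector: C -> +1, N -> -1."""
        return self.classes.map(CLASS_CODING).to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_features(self, feature_ids) -> "SampleMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        meta = None if self.meta is None else self.meta.copy()
        return SampleMatrix(self.data[keep].copy(), self.classes.copy(), meta)

    #: per-sample metadata columns carried through CSV round trips
    _META_COLS = ("batch_id", "site_id", "age")

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.meta is not None:
            for col in reversed([c for c in self._META_COLS
                                 if c in self.meta.columns]):
                out.insert(0, col, self.meta[col])
        out.insert(0, "class_label", self.classes)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "SampleMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        classes = df.pop("class_label")
        meta_cols = [c for c in cls._META_COLS if c in df.columns]
        meta = df[meta_cols].copy() if meta_cols else None
        return cls(df.drop(columns=meta_cols), classes, meta)


# -- run-table CSV round trip ----------------------------------------------


def write_run_table(table: RunTable, path) -> None:
    """Serialize a run table to CSV (metadata columns, then feature columns).

    Missing peaks are written as empty cells, preserving the missing/zero
    distinction on round trip.
    """
    table.validate()
    flat = pd.concat(
        [table.meta[META_COLUMNS].reset_index(drop=True),
         table.areas.reset_index(drop=True)],
        axis=1,
    )
    flat.to_csv(path, index=False)


def read_run_table(path) -> RunTable:
    """Read and validate a run table written by :func:`write_run_table`."""
    path = Path(path)
    flat = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in flat.columns]
    if missing:
        raise RunTableError(
            f"malformed header in {path.name}: missing columns {missing}"
        )
    meta = flat[META_COLUMNS].copy()
    areas = flat.drop(columns=META_COLUMNS).astype(float)
    table = RunTable(meta, areas)
    table.validate()
    return table
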