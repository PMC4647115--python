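import numpy as np
import pandas as pd
import pytest

from ocmetab import RunTable, SampleMatrix, SyntheticConfig, simulate_run_table


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Scaled-down study profile for fast unit tests."""
    base = dict(
        n_case=10, n_control=10, n_features=30, planted_panel_size=4,
        qc_interval=5, n_batches=2, n_blanks=3, n_sites=2, seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def small_study():
    return simulate_run_table(small_config(seed=11))


def separable_matrix(n_per_class: int = 5, n_features: int = 3, gap: float = 6.0,
                     noise: float = 0.3, seed: int = 0) -> SampleMatrix:
    """Two well-separated Gaussian classes (first feature carries the gap)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(scale=noise, size=(n, n_features))
    X[:n_per_class, 0] += gap / 2
    X[n_per_class:, 0] -= gap / 2
    ids = [f"S{i + 1}" for i in range(n)]
    classes = pd.Series(["C"] * n_per_class + ["N"] * n_per_class, index=ids)
    data = pd.DataFrame(X, index=ids,
                        columns=[f"f{j + 1}" for j in range(n_features)])
    return SampleMatrix(data, classes)


def noise_matrix(n: int = 16, n_features: int = 8, seed: int = 0) -> SampleMatrix:
    """Isotropic noise with arbitrary balanced labels (null data)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    ids = [f"S{i + 1}" for i in range(n)]
    classes = pd.Series(["C"] * (n // 2) + ["N"] * (n - n // 2), index=ids)
    return SampleMatrix(
        pd.DataFrame(X, index=ids, columns=[f"f{j + 1}" for j in range(n_features)]),
        classes)


def toy_curation_table() -> RunTable:
    """Six-feature run table where exactly one feature fails each filter.

    F2 is present in only 3 of 14 runs (presence casualty at min_runs=4);
    F3 drifts linearly across the five QC runs (drift casualty); F5 has a
    high blank level relative to its study areas (baseline casualty);
    F1, F4, F6 survive.  QC-run totals are constant by construction so that
    total-area normalization does not leak F3's drift into stable features;
    F4's QC wiggle has |slope| < SE (hand-checked OLS: slope -8.4/3 per run
    index against SE 10.5/3) and F5's has |slope| << SE.
    """
    qc_rows = {
        "F1": [20.0] * 5,
        "F3": [10.0, 15.0, 20.0, 25.0, 30.0],
        "F4": [135.0, 72.0, 100.0, 128.0, 65.0],
        "F5": [25.0, 83.0, 50.0, 17.0, 75.0],
        "F6": [30.0] * 5,
    }
    # run layout: QC at 1,4,7,10,13 (even spacing), duplicates non-adjacent
    roles = ["qc_pool", "study", "study", "qc_pool", "study", "study",
             "qc_pool", "study", "study", "qc_pool", "study", "study",
             "qc_pool", "blank"]
    samples = ["QC-POOL", "S1", "S2", "QC-POOL", "S3", "S4", "QC-POOL",
               "S1", "S2", "QC-POOL", "S3", "S4", "QC-POOL", "BLANK"]
    reps = [1, 1, 1, 2, 1, 1, 3, 2, 2, 4, 2, 2, 5, 1]
    classes = ["none", "C", "C", "none", "N", "N", "none", "C", "C", "none",
               "N", "N", "none", "none"]
    study_level = {"F1": 20.0, "F2": 10.0, "F3": 20.0, "F4": 100.0,
                   "F5": 30.0, "F6": 30.0}
    blank_level = {"F1": 0.01, "F2": np.nan, "F3": 0.01, "F4": 0.01,
                   "F5": 5.0, "F6": 0.01}
    f2_present_runs = {2, 3, 5}  # 1-based run_index; only 3 runs -> purged

    rows = []
    qc_seen = 0
    for r, role in enumerate(roles, start=1):
        if role == "qc_pool":
            vals = {f: qc_rows[f][qc_seen] for f in qc_rows}
            vals["F2"] = np.nan
            qc_seen += 1
        elif role == "blank":
            vals = dict(blank_level)
        else:
            vals = dict(study_level)
            if r not in f2_present_runs:
                vals["F2"] = np.nan
        rows.append([vals[f] for f in ["F1", "F2", "F3", "F4", "F5", "F6"]])

    meta = pd.DataFrame({
        "run_index": range(1, 15), "sample_id": samples,
        "replicate_index": reps, "role": roles, "batch_id": "B1",
        "site_id": "S", "class_label": classes,
        "acquisition_time": [30.0 * r for r in range(14)],
    })
    meta.loc[meta.role != "study", ["batch_id", "site_id"]] = "none"
    areas = pd.DataFrame(rows, columns=["F1", "F2", "F3", "F4", "F5", "F6"])
    return RunTable(meta, areas).validate()
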