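"""Synthetic run-table generator emulating a duplicate-injection serum
metabolomics case/control study.

The generator emits the object a peak-picking tool would export: a run-level
peak-area table for ``n_case + n_control`` sera analysed in duplicate, with
pooled-QC injections at a fixed cadence, blank runs, batch structure, a
per-run total-intensity scalar, detection-limit censoring of low peaks, and a
small planted panel of discriminative features whose ground truth is returned
alongside the table.

Statistical model
-----------------
Peak areas are lognormal: feature ``f`` has base log-mean ``mu_f`` and
biological log-SD ``sigma_f``; a planted feature shifts the cancer-class
log-mean by ``d_f * sigma_f`` (standardized effect ``d_f``, mixed signs).
Each run multiplies the sample's true areas by a batch factor, a technical
replicate error, a per-run intensity scalar, and (for drift features) a
linear differential-drift trend in acquisition order.

Pooled-QC runs are the mean composition of all study samples (mirroring
physical pooling) times the per-run intensity scalar and the drift trend;
they carry no per-feature technical noise, so the QC drift filter sees the
drift trend itself rather than injection noise.  Differential drift slopes
are recentred to zero intensity-weighted sum: the common (whole-signal) drift
component is already represented by the per-run scalar that total-area
normalization removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .runtable import META_COLUMNS, RunTable

__all__ = ["SyntheticConfig", "GroundTruth", "simulate_run_table"]


@dataclass
class SyntheticConfig:
    """Study-emulation profile; defaults reproduce the target design:
    46 cancer + 49 control sera in duplicate, ~255 features, 8 batches,
    pooled QC every 8 study runs."""

    n_case: int = 46
    n_control: int = 49
    n_features: int = 255
    planted_panel_size: int = 16
    #: standardized log-scale effect magnitudes drawn uniformly, mixed signs
    effect_size_range: tuple[float, float] = (1.5, 2.5)
    #: base log-mean abundance drawn uniformly over this range
    log_area_mu: tuple[float, float] = (float(np.log(1e3)), float(np.log(1e6)))
    #: per-feature biological log-SD drawn uniformly over this range
    log_area_sigma: tuple[float, float] = (0.4, 0.8)
    #: fractional technical variation between duplicate injections
    replicate_cv: float = 0.12
    #: log-SD of the per-run total-intensity multiplier
    tic_scale_sigma: float = 0.2
    qc_interval: int = 8
    n_batches: int = 8
    #: log-SD of multiplicative per-(batch, feature) shifts
    batch_effect_sigma: float = 0.05
    #: fraction of features given a QC-visible monotone trend in run order
    drift_feature_fraction: float = 0.10
    #: fractional differential drift over the whole acquisition span
    drift_slope: float = 0.3
    #: blank-run level as a fraction of a feature's mean abundance
    blank_baseline: float = 0.01
    #: fraction of features with elevated blank contamination
    blank_contamination_fraction: float = 0.05
    #: contaminated-feature blank level (fraction of mean abundance)
    blank_contamination_level: float = 0.5
    #: marginal probability that a study-run peak is censored as absent
    missing_rate: float = 0.05
    n_blanks: int = 11
    n_sites: int = 5
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_features": self.n_features,
            "planted_panel_size": self.planted_panel_size,
            "n_batches": self.n_batches,
            "n_blanks": self.n_blanks,
            "n_sites": self.n_sites,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be a positive count, got {v}")
        if self.planted_panel_size > self.n_features:
            raise ValueError(
                f"planted_panel_size ({self.planted_panel_size}) exceeds "
                f"n_features ({self.n_features})"
            )
        if self.qc_interval < 1:
            raise ValueError(f"qc_interval must be >= 1, got {self.qc_interval}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        return self


@dataclass
class GroundTruth:
    """Planted structure of a simulated run table (for recovery tests)."""

    planted_feature_ids: list[str]
    #: feature id -> signed standardized effect (positive = higher in cancer)
    effects: dict[str, float]
    drift_feature_ids: list[str]
    #: feature id -> fractional drift over the acquisition span
    drift_slopes: dict[str, float]
    contaminated_feature_ids: list[str]
    #: sample id -> 'C' / 'N'
    class_labels: dict[str, str]
    #: sample id -> age at collection (years)
    sample_age: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _interleaved_order(sample_ids: list[str], rng: np.random.Generator,
                       max_tries: int = 1000) -> list[str]:
    """Shuffle two copies of each sample id so no duplicate pair is adjacent."""
    runs = np.array(sample_ids * 2)
    for _ in range(max_tries):
        rng.shuffle(runs)
        if not any(runs[i] == runs[i + 1] for i in range(len(runs) - 1)):
            return runs.tolist()
    # deterministic repair: swap offending runs with a compatible partner
    runs = runs.tolist()
    for i in range(len(runs) - 1):
        if runs[i] == runs[i + 1]:
            for j in range(len(runs)):
                if (runs[j] != runs[i]
                        and (j == 0 or runs[j - 1] != runs[i])
                        and (j == len(runs) - 1 or runs[j + 1] != runs[i])
                        and abs(j - i - 1) > 1):
                    runs[i + 1], runs[j] = runs[j], runs[i + 1]
                    break
    return runs


def simulate_run_table(config: SyntheticConfig) -> tuple[RunTable, GroundTruth]:
    """Simulate one complete acquisition and return (RunTable, GroundTruth).

    The acquisition sequence starts and ends with a pooled-QC injection,
    inserts a QC after every ``qc_interval`` study runs, places one blank at
    the start and the rest evenly through the sequence, and interleaves
    duplicate study injections so they are never consecutive.  Identical
    configs (same seed) yield bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.n_features
    feature_ids = [f"F{k + 1:04d}" for k in range(J)]

    # -- per-feature population parameters ---------------------------------
    mu = rng.uniform(*config.log_area_mu, size=J)
    sigma = rng.uniform(*config.log_area_sigma, size=J)
    mean_area = np.exp(mu + sigma**2 / 2)  # lognormal mean, used as weights

    # planted panel: reliably detected features (above the censoring-prone
    # abundance zone), disjoint from drift and blank-contaminated sets
    abundant = np.argsort(mu)[J // 5:]
    planted = np.sort(rng.choice(abundant, size=config.planted_panel_size,
                                 replace=False))
    effects = rng.uniform(*config.effect_size_range, size=planted.size)
    effects *= rng.choice([-1.0, 1.0], size=planted.size)

    rest = np.setdiff1d(np.arange(J), planted)
    n_drift = int(round(config.drift_feature_fraction * J))
    drift_idx = np.sort(rng.choice(rest, size=min(n_drift, rest.size), replace=False))
    rest2 = np.setdiff1d(rest, drift_idx)
    n_cont = int(round(config.blank_contamination_fraction * J))
    cont_idx = np.sort(rng.choice(rest2, size=min(n_cont, rest2.size), replace=False))

    # -- samples ------------------------------------------------------------
    n = config.n_case + config.n_control
    sample_ids = [f"EOC-{i + 1:02d}" for i in range(config.n_case)] + \
                 [f"CTRL-{i + 1:02d}" for i in range(config.n_control)]
    classes = np.array(["C"] * config.n_case + ["N"] * config.n_control)
    ages = np.clip(rng.normal(57.0, 8.0, size=n), 35, 85).round(1)
    sites = np.array([f"S{1 + i % config.n_sites}" for i in range(n)])
    rng.shuffle(sites)

    # batches balanced by class (round-robin within class, then shuffled ids)
    batch_of = np.empty(n, dtype=int)
    for cls in ("C", "N"):
        members = np.flatnonzero(classes == cls)
        rng.shuffle(members)
        batch_of[members] = np.arange(members.size) % config.n_batches

    true_log = mu[None, :] + rng.normal(size=(n, J)) * sigma[None, :]
    true_log[np.ix_(classes == "C", planted)] += (effects * sigma[planted])[None, :]
    true_area = np.exp(true_log)

    batch_fac = np.exp(rng.normal(0.0, config.batch_effect_sigma,
                                  size=(config.n_batches, J)))

    pool = true_area.mean(axis=0)  # physical pooling of all study sera

    log_detect = np.quantile(true_log, config.missing_rate) \
        if config.missing_rate > 0 else -np.inf

    slopes = np.zeros(J)
    if drift_idx.size:
        s = config.drift_slope * rng.uniform(0.5, 1.0, size=drift_idx.size)
        s *= rng.choice([-1.0, 1.0], size=drift_idx.size)
        # recentre against the pooled composition, counting only features
        # detectable in the pool, so QC total intensity is drift-stable:
        # the common drift component lives in the per-run scalar, which
        # TIC normalization removes
        w = pool[drift_idx] * (np.log(pool[drift_idx]) >= log_detect)
        if w.sum() > 0:
            s -= np.dot(w, s) / w.sum() * (w > 0)
        slopes[drift_idx] = s

    # -- acquisition sequence ----------------------------------------------
    id_to_row = {s: i for i, s in enumerate(sample_ids)}
    study_seq = _interleaved_order(sample_ids, rng)
    seq: list[tuple[str, str]] = [("blank", ""), ("qc_pool", "")]
    since_qc = 0
    n_study = len(study_seq)
    extra_blanks = max(config.n_blanks - 1, 0)
    blank_after = set()
    if extra_blanks:
        blank_after = set(np.linspace(1, n_study, extra_blanks + 1,
                                      dtype=int)[:-1].tolist())
    for k, sid in enumerate(study_seq, start=1):
        seq.append(("study", sid))
        since_qc += 1
        if since_qc == config.qc_interval:
            seq.append(("qc_pool", ""))
            since_qc = 0
        if k in blank_after:
            seq.append(("blank", ""))
    if seq[-1][0] != "qc_pool":
        seq.append(("qc_pool", ""))

    total_runs = len(seq)
    run_index = np.arange(1, total_runs + 1)
    span = float(total_runs - 1)
    drift_t = (run_index - run_index.mean()) / span  # in [-0.5, 0.5]

    # -- areas per run -------------------------------------------------------
    areas = np.empty((total_runs, J))
    missing = np.zeros((total_runs, J), dtype=bool)
    meta_rows = []
    rep_count: dict[str, int] = {}
    blank_level = np.where(
        np.isin(np.arange(J), cont_idx),
        config.blank_contamination_level, config.blank_baseline) * mean_area

    for r, (role, sid) in enumerate(seq):
        tic = np.exp(rng.normal(0.0, config.tic_scale_sigma))
        trend = 1.0 + slopes * drift_t[r]
        if role == "study":
            i = id_to_row[sid]
            tech = np.clip(rng.normal(0.0, config.replicate_cv, size=J), -0.9, None)
            a = true_area[i] * batch_fac[batch_of[i]] * (1.0 + tech) * trend * tic
            if config.missing_rate > 0:
                p_miss = 1.0 / (1.0 + np.exp((np.log(a / tic) - log_detect) / 0.5))
                missing[r] = rng.random(J) < p_miss
            rep_count[sid] = rep_count.get(sid, 0) + 1
            meta_rows.append((sid, rep_count[sid], role, f"B{batch_of[i] + 1}",
                              sites[i], classes[i]))
        elif role == "qc_pool":
            a = pool * trend * tic
            # detection status of the pool is a property of the pooled
            # material, constant across QC injections
            missing[r] = np.log(pool) < log_detect
            meta_rows.append(("QC-POOL", 1, role, "none", "none", "none"))
        else:  # blank
            a = blank_level * rng.lognormal(0.0, 0.3, size=J) * tic
            missing[r] = np.log(a / tic) < log_detect
            meta_rows.append(("BLANK", 1, role, "none", "none", "none"))
        areas[r] = a

    areas[missing] = np.nan
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "replicate_index",
                                            "role", "batch_id", "site_id",
                                            "class_label"])
    meta.insert(0, "run_index", run_index)
    meta["acquisition_time"] = (run_index - 1) * 34.0  # minutes (23' gradient + re-equilibration)
    meta = meta[META_COLUMNS]

    table = RunTable(meta, pd.DataFrame(areas, columns=feature_ids)).validate()
    truth = GroundTruth(
        planted_feature_ids=[feature_ids[k] for k in planted],
        effects={feature_ids[k]: float(d) for k, d in zip(planted, effects)},
        drift_feature_ids=[feature_ids[k] for k in drift_idx],
        drift_slopes={feature_ids[k]: float(slopes[k]) for k in drift_idx},
        contaminated_feature_ids=[feature_ids[k] for k in cont_idx],
        class_labels={s: c for s, c in zip(sample_ids, classes)},
        sample_age={s: float(a) for s, a in zip(sample_ids, ages)},
    )
    return table, truth
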