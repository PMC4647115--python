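"""End-to-end orchestration: simulate -> curate -> SVM-RFE -> validate ->
summarize, with every intermediate persisted and a reproducibility manifest.

A :class:`RunConfig` holds one parameter block per stage plus a single global
seed that governs every stochastic stage; :func:`run_pipeline` executes the
stages in order, writes each intermediate as CSV/JSON under the output
directory, and returns a :class:`RunManifest` with content checksums so a
re-run with the same config can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curation import CurationParams, curate
from .oplsda import CvScheme, choose_n_ortho, cross_validate, fit_oplsda, \
    permutation_test
from .runtable import SampleMatrix
from .stats import feature_summaries, pca_bias_check
from .svm import fit_metabolic_model, loocv_evaluate, rfe, select_optimal_panel
from .synthetic import SyntheticConfig, simulate_run_table
from .runtable import write_run_table

log = logging.getLogger("ocmetab.pipeline")

_TUPLE_FIELDS = {"effect_size_range", "log_area_mu", "log_area_sigma"}


@dataclass
class RunConfig:
    """Per-stage parameter blocks; ``seed`` overrides the synthetic seed so
    one number governs the whole run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    curation: CurationParams = field(default_factory=CurationParams)
    cost: float = 1.0
    scaling_mode: str = "global"
    importance: str = "signed_mean"
    n_ortho: int | None = None       # None -> choose by LOO Q2 (cap 3)
    cv_schemes: tuple[str, ...] = ("loo", "venetian_blinds",
                                   "contiguous_blocks", "random_subsets")
    n_permutations: int = 99
    permutation_scheme: str = "venetian_blinds"
    seed: int = 0

    def __post_init__(self) -> None:
        self.synthetic.seed = self.seed

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def native(x):
            if isinstance(x, dict):
                return {k: native(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [native(v) for v in x]
            if isinstance(x, np.floating):
                return float(x)
            if isinstance(x, np.integer):
                return int(x)
            return x

        return native(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        for k in _TUPLE_FIELDS:
            if k in syn:
                syn[k] = tuple(syn[k])
        cur = dict(d.pop("curation", {}))
        d["cv_schemes"] = tuple(d.get("cv_schemes",
                                      cls.__dataclass_fields__["cv_schemes"].default))
        return cls(synthetic=SyntheticConfig(**syn),
                   curation=CurationParams(**cur), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    versions: dict[str, str]
    checksums: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    selected_panel: dict | None = None
    validation: dict | None = None
    wall_time_s: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute all stages; every intermediate is written under ``outdir``.

    Raises with the failing stage named; identical configs yield identical
    output checksums.
    """
    t0 = time.monotonic()
    config.synthetic.validate()  # fail before any stage output
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import sklearn
    import scipy
    manifest = RunManifest(
        config_hash=config.content_hash(),
        versions={"ocmetab": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
                  "scipy": scipy.__version__},
    )
    config.to_yaml(outdir / "config.yaml")

    def finish_stage(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest.checksums[p.name] = _sha256(p)
        manifest.stages.append(stage)
        log.info("stage %-10s done (%s)", stage,
                 ", ".join(p.name for p in paths))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        stage = "simulate"
        try:
            table, truth = simulate_run_table(config.synthetic)
            write_run_table(table, outdir / "run_table.csv")
            truth.to_json(outdir / "ground_truth.json")
            finish_stage(stage, outdir / "run_table.csv",
                         outdir / "ground_truth.json")

            stage = "curate"
            matrix, report = curate(table, config.curation)
            matrix.to_csv(outdir / "sample_matrix.csv")
            (outdir / "curation_report.json").write_text(json.dumps({
                "removed": report.removed,
                "counts": {k: list(v) for k, v in report.counts.items()},
            }, indent=1))
            finish_stage(stage, outdir / "sample_matrix.csv",
                         outdir / "curation_report.json")

            stage = "rfe"
            trace = rfe(matrix, cost=config.cost,
                        scaling_mode=config.scaling_mode,
                        importance=config.importance)
            trace.to_json(outdir / "rfe_trace.json")
            trace.metrics_table().to_csv(outdir / "accuracy_evolution.csv",
                                         index=False)
            panel = select_optimal_panel(trace)
            panel_matrix = matrix.select_features(panel.feature_ids)
            model = fit_metabolic_model(panel_matrix, cost=config.cost)
            model.to_json(outdir / "model.json")
            loocv = loocv_evaluate(panel_matrix, cost=config.cost,
                                   scaling_mode=config.scaling_mode)
            scores = loocv.scores.copy()
            scores["age"] = scores["sample_id"].map(truth.sample_age)
            scores.to_csv(outdir / "scores.csv", index=False)
            manifest.selected_panel = {
                "feature_ids": panel.feature_ids, "size": panel.size,
                "accuracy": panel.accuracy, "sensitivity": panel.sensitivity,
                "specificity": panel.specificity,
            }
            finish_stage(stage, outdir / "rfe_trace.json",
                         outdir / "accuracy_evolution.csv",
                         outdir / "model.json", outdir / "scores.csv")

            stage = "validate"
            n_ortho = config.n_ortho
            if n_ortho is None:
                n_ortho = choose_n_ortho(panel_matrix)
            opls = fit_oplsda(panel_matrix, n_ortho)
            q2 = {kind: cross_validate(panel_matrix,
                                       CvScheme(kind=kind, seed=config.seed),
                                       n_ortho)
                  for kind in config.cv_schemes}
            perm_p = None
            if config.n_permutations > 0:
                _, _, perm_p = permutation_test(
                    panel_matrix,
                    CvScheme(kind=config.permutation_scheme, seed=config.seed),
                    n_ortho, config.n_permutations, seed=config.seed + 1)
            manifest.validation = {"n_ortho": n_ortho, "R2Y": opls.r2y,
                                   "Q2": q2, "permutation_p": perm_p}
            (outdir / "validation.json").write_text(
                json.dumps(manifest.validation, indent=1))
            finish_stage(stage, outdir / "validation.json")

            stage = "summarize"
            feature_summaries(panel_matrix).to_csv(
                outdir / "feature_summaries.csv", index=False)
            pca_scores, assoc = pca_bias_check(
                matrix, matrix.meta["batch_id"] if matrix.meta is not None
                else ["?"] * matrix.n_samples)
            pca_scores.to_csv(outdir / "pca_scores.csv", index_label="sample_id")
            manifest.validation["batch_association_pseudoF"] = assoc
            finish_stage(stage, outdir / "feature_summaries.csv",
                         outdir / "pca_scores.csv")
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest.warnings = [str(w.message) for w in caught]
    manifest.wall_time_s = round(time.monotonic() - t0, 3)
    manifest.to_json(outdir / "manifest.json")
    return manifest
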