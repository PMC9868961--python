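"""End-to-end orchestration: simulate -> featurize -> train -> evaluate -> rank.

Each stage consumes and produces plain files in a run directory, so the
``run_all`` driver and the CLI subcommands compose identically. A single
global seed fans out into per-stage seeds (see :func:`~cleavesite.splits.
stage_seed`), so any stage can be re-run in isolation and reproduce the
same bytes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .alignment import Scoring
from .features import featurize_dataset, registry_manifest
from .io import (
    read_dataset,
    read_feature_matrix,
    write_dataset,
    write_feature_matrix,
)
from .metrics import METRIC_NAMES, EvalReport, metric_suite
from .models import (
    MODEL_IDS,
    FittedModel,
    cross_validate,
    cv_mean,
    get_config,
    predict_scores,
    train_model,
)
from .simulate import default_profile, generate_dataset
from .splits import stage_seed
from .topsis import (
    Criterion,
    build_decision_matrix,
    rank_table,
    topsis_scores,
)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    guides_fasta: Optional[str] = None
    sites_table: Optional[str] = None
    train_fraction: float = 0.7
    cv_folds: int = 5
    model_ids: list = field(default_factory=lambda: list(MODEL_IDS))
    threshold: float = 0.5
    topsis_normalization: str = "vector"
    fpr_direction: str = "cost"
    seed: int = 0
    group_by_guide: bool = False
    scoring_match: float = 1.0
    scoring_mismatch: float = -1.0
    scoring_gap: float = -2.0
    out_dir: str = "run"

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise PipelineConfigError(f"train_fraction {self.train_fraction} outside (0, 1)")
        if self.cv_folds < 2:
            raise PipelineConfigError("cv_folds must be >= 2")
        unknown = [m for m in self.model_ids if m not in MODEL_IDS]
        if unknown:
            raise PipelineConfigError(f"unknown model_ids {unknown}; known: {list(MODEL_IDS)}")
        if (self.guides_fasta is None) != (self.sites_table is None):
            raise PipelineConfigError("guides_fasta and sites_table must be given together")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @property
    def scoring(self) -> Scoring:
        return Scoring(self.scoring_match, self.scoring_mismatch, self.scoring_gap)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------- stages


def stage_simulate(out_dir: str, seed: int, profile=None) -> None:
    """Generate the synthetic dataset and write guides/sites/profile files."""
    profile = profile or default_profile()
    ds = generate_dataset(profile, seed=stage_seed(seed, "simulate"))
    os.makedirs(out_dir, exist_ok=True)
    write_dataset(ds, os.path.join(out_dir, "guides.fasta"), os.path.join(out_dir, "sites.csv"))
    manifest = profile.to_manifest()
    manifest["derived_seed"] = stage_seed(seed, "simulate")
    with open(os.path.join(out_dir, "profile.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def stage_featurize(out_dir: str, guides_fasta=None, sites_table=None, scoring=Scoring()) -> None:
    guides_fasta = guides_fasta or os.path.join(out_dir, "guides.fasta")
    sites_table = sites_table or os.path.join(out_dir, "sites.csv")
    ds = read_dataset(guides_fasta, sites_table)
    featurize_dataset(ds, scoring=scoring)
    os.makedirs(out_dir, exist_ok=True)
    write_feature_matrix(ds, os.path.join(out_dir, "features.csv"))
    with open(os.path.join(out_dir, "registry.json"), "w") as fh:
        json.dump(registry_manifest(), fh, indent=1)


def stage_train(out_dir: str, config: PipelineConfig) -> None:
    """Split, fit every requested model on the training part, run CV on it."""
    X, y = read_feature_matrix(os.path.join(out_dir, "features.csv"))
    split_seed = stage_seed(config.seed, "split")
    n = len(X)
    n_train = math.floor(config.train_fraction * n)
    order = np.random.default_rng(split_seed).permutation(n)
    assignment = pd.Series("test", index=[X.index[i] for i in order], name="split", dtype=object)
    assignment.iloc[:n_train] = "train"
    assignment = assignment.reindex(X.index)
    assignment.rename_axis("site_id").to_frame().to_csv(os.path.join(out_dir, "split.csv"))

    train_idx = assignment[assignment == "train"].index
    model_dir = os.path.join(out_dir, "models")
    os.makedirs(model_dir, exist_ok=True)
    train_seed = stage_seed(config.seed, "train")
    cv_seed = stage_seed(config.seed, "cv")
    cv_rows = []
    for mid in config.model_ids:
        cfg = get_config(mid)
        fitted = train_model(cfg, X.loc[train_idx], y.loc[train_idx], seed=train_seed)
        fitted.save(os.path.join(model_dir, f"{mid}.joblib"))
        fold_reports = cross_validate(
            cfg,
            X.loc[train_idx],
            y.loc[train_idx],
            k=config.cv_folds,
            seed=cv_seed,
            threshold=config.threshold,
        )
        mean = cv_mean(fold_reports, mid)
        for rep in [*fold_reports, mean]:
            cv_rows.append({"model": mid, "surface": rep.surface, **rep.metric_dict()})
    pd.DataFrame(cv_rows).to_csv(os.path.join(out_dir, "metrics_cv.csv"), index=False)


def stage_evaluate(out_dir: str, config: PipelineConfig) -> None:
    """Score the 30% holdout with every fitted model; write the metrics table."""
    X, y = read_feature_matrix(os.path.join(out_dir, "features.csv"))
    split = pd.read_csv(os.path.join(out_dir, "split.csv"), index_col="site_id")["split"]
    test_idx = split[split == "test"].index
    rows = []
    for mid in config.model_ids:
        fitted = FittedModel.load(os.path.join(out_dir, "models", f"{mid}.joblib"))
        scores = predict_scores(fitted, X.loc[test_idx])
        rep = metric_suite(
            y.loc[test_idx].values,
            scores,
            threshold=config.threshold,
            model_id=mid,
            surface="holdout",
            seed=config.seed,
        )
        rows.append({"model": mid, "surface": rep.surface, **rep.metric_dict()})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metrics_holdout.csv"), index=False)


def stage_rank(out_dir: str, config: PipelineConfig, metrics_csv=None) -> pd.DataFrame:
    """TOPSIS-rank the models from the holdout metrics table."""
    metrics_csv = metrics_csv or os.path.join(out_dir, "metrics_holdout.csv")
    df = pd.read_csv(metrics_csv)
    if len(df) < 2:
        # degenerate ranking: closeness undefined with a single alternative
        out = pd.DataFrame(
            {"model": df["model"], "score": [float("nan")] * len(df), "rank": [1] * len(df)}
        )
    else:
        # a collapsed classifier can leave a metric undefined (e.g.
        # precision when nothing is predicted positive); for ranking it is
        # scored as the worst observed value of that criterion
        filled = df.copy()
        for m in METRIC_NAMES:
            worst = filled[m].max() if (m == "fpr" and config.fpr_direction == "cost") else filled[m].min()
            filled[m] = filled[m].fillna(worst)
        reports = [
            EvalReport(model_id=r["model"], surface="holdout", **{m: r[m] for m in METRIC_NAMES})
            for r in filled.to_dict("records")
        ]
        criteria = [
            Criterion(
                m,
                "cost" if (m == "fpr" and config.fpr_direction == "cost") else "benefit",
                1.0,
            )
            for m in METRIC_NAMES
        ]
        matrix = build_decision_matrix(reports, criteria)
        out = rank_table(topsis_scores(matrix, normalization=config.topsis_normalization))
    out.to_csv(os.path.join(out_dir, "topsis.csv"), index=False)
    return out


def run_all(config: PipelineConfig) -> str:
    """Run every stage into ``config.out_dir``; returns the directory path."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    if config.guides_fasta is None:
        stage_simulate(out, config.seed)
        guides, sites = None, None
    else:
        guides, sites = config.guides_fasta, config.sites_table
    stage_featurize(out, guides, sites, scoring=config.scoring)
    stage_train(out, config)
    stage_evaluate(out, config)
    stage_rank(out, config)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("simulate", "split", "train", "cv")
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
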