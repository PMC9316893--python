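"""End-to-end benchmark and feature-set comparison harnesses.

Orchestrates the leakage-safe protocol: stratified 80/20 split; imputation
statistics, normalization ranges, feature rankings and resampling all
fitted on the training split only and applied to the test split; the
proposed ensemble compared against plain random-forest, SVM and kNN
baselines trained on the unbalanced training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data_io import (
    LabeledDataset,
    fit_imputer,
    fit_minmax,
    impute_class_mean,
    normalize_minmax,
    stratified_split,
)
from .ensemble import fit_ensemble
from .evaluation import EvaluationReport, evaluate
from .feature_selection import (
    apply_cutoff,
    boostfs_rank,
    chi2_rank,
    degs_feature_ranking,
    rfe_svc_rank,
    select_degs,
)

logger = logging.getLogger("spiderens")

METHODS = ("proposed", "rf", "svm", "knn")
FEATURE_SETS = ("all", "chi2", "rfe", "boostfs", "degs")


@dataclass
class RunConfig:
    """Configuration of one benchmark or feature-comparison run."""

    methods: tuple[str, ...] = ("proposed", "rf", "svm", "knn")
    feature_sets: tuple[str, ...] = ("all",)
    n_keep: int = 100
    test_fraction: float = 0.2
    k: int = 3
    knn_k: int = 5
    rounds: int = 10
    seed: int = 0
    resample_baselines: bool = False

    def __post_init__(self) -> None:
        if not self.methods or not self.feature_sets:
            raise ValueError("at least one method and one feature set are required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets {sorted(unknown)}")


def preprocess_split(data: LabeledDataset, config: RunConfig):
    """Split, then impute and min-max normalize with train-fitted statistics."""
    split = stratified_split(data, config.test_fraction, config.seed)
    imp = fit_imputer(split.train)
    train = impute_class_mean(split.train, imp)
    test = impute_class_mean(split.test, imp)
    params = fit_minmax(train)
    train = normalize_minmax(train, params)
    test = normalize_minmax(test, params, clip=True)
    return train, test


def _fit_method(method: str, train: LabeledDataset, config: RunConfig):
    from .imbalance import spider_resample

    if method == "proposed":
        return fit_ensemble(train, rounds=config.rounds, resample_first=True,
                            k=config.k, seed=config.seed)
    if config.resample_baselines:
        train = spider_resample(train, k=config.k, seed=config.seed).dataset
    if method == "rf":
        model = RandomForestClassifier(n_estimators=100, random_state=config.seed, n_jobs=1)
    elif method == "svm":
        model = CalibratedClassifierCV(
            SVC(kernel="rbf", C=1.0, gamma="scale", random_state=config.seed),
            method="sigmoid", cv=3, ensemble=False)
    elif method == "knn":
        model = KNeighborsClassifier(n_neighbors=config.knn_k)
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(method)
    model.fit(train.features, train.labels)
    return model


@dataclass
class BenchmarkTable:
    """Rows of (dataset, method, feature_set) -> metric summary."""

    rows: list[dict] = field(default_factory=list)
    reports: dict[tuple, EvaluationReport] = field(default_factory=dict)

    def add(self, dataset: str, method: str, feature_set: str,
            report: EvaluationReport | None, error: str | None = None) -> None:
        key = (dataset, method, feature_set)
        if any(r["dataset"] == dataset and r["method"] == method
               and r["feature_set"] == feature_set for r in self.rows):
            raise ValueError(f"duplicate benchmark row {key}")
        row = {"dataset": dataset, "method": method, "feature_set": feature_set}
        if report is not None:
            row.update(accuracy=round(report.accuracy, 6), mcc=round(report.mcc, 6),
                       rmse=round(report.rmse, 6), f1=round(report.f_score, 6),
                       auc=round(report.auc, 6), error="")
            self.reports[key] = report
        else:
            row.update(accuracy=np.nan, mcc=np.nan, rmse=np.nan, f1=np.nan,
                       auc=np.nan, error=error or "failed")
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df = self.to_frame()
        df.to_csv(out_dir / "table.tsv", sep="\t", index=False, float_format="%.6g")
        (out_dir / "table.json").write_text(
            json.dumps(self.rows, indent=1, sort_keys=True, default=float) + "\n",
            encoding="utf-8")


def run_benchmark(
    datasets: dict[str, LabeledDataset], config: RunConfig
) -> BenchmarkTable:
    """KEEL-style benchmark: each dataset x method on one stratified split.

    The proposed method resamples and boosts; baselines train plainly on the
    unbalanced training split. A failing combination is recorded as an error
    row, not raised.
    """
    table = BenchmarkTable()
    for name, data in datasets.items():
        train, test = preprocess_split(data, config)
        for method in config.methods:
            try:
                model = _fit_method(method, train, config)
                table.add(name, method, "all", evaluate(model, test))
            except Exception as exc:  # row-level failure containment
                logger.warning("benchmark row (%s, %s) failed: %s", name, method, exc)
                table.add(name, method, "all", None, error=str(exc))
    return table


def run_feature_comparison(
    data: LabeledDataset,
    config: RunConfig,
    stages: list[LabeledDataset] | None = None,
    deg_alpha: float = 0.005,
) -> BenchmarkTable:
    """Feature-set comparison: rank on train only, cut, train, evaluate.

    The ``degs`` feature set requires three-contrast stage data sharing the
    dataset's feature names; its cut-off is the intersection size itself.
    """
    train, test = preprocess_split(data, config)
    rankings: dict[str, object] = {}
    for fs in config.feature_sets:
        if fs == "all":
            rankings[fs] = None
        elif fs == "chi2":
            rankings[fs] = chi2_rank(train)
        elif fs == "rfe":
            rankings[fs] = rfe_svc_rank(train, step=max(1, train.n_features // 10))
        elif fs == "boostfs":
            rankings[fs] = boostfs_rank(train, seed=config.seed)
        elif fs == "degs":
            if stages is None:
                raise ValueError("feature set 'degs' requires stage data")
            deg = select_degs(stages, alpha=deg_alpha)
            rankings[fs] = degs_feature_ranking(deg, train.feature_names)

    table = BenchmarkTable()
    for fs in config.feature_sets:
        ranking = rankings[fs]
        if ranking is None:
            sub_train, sub_test = train, test
        else:
            n_keep = min(config.n_keep, train.n_features)
            if fs == "degs":
                n_members = int((ranking.scores > 0).sum())
                if n_members == 0:
                    for method in config.methods:
                        table.add("data", method, fs, None, error="empty DEG intersection")
                    continue
                n_keep = n_members
            sub_train = apply_cutoff(ranking, train, n_keep)
            sub_test = apply_cutoff(ranking, test, n_keep)
        for method in config.methods:
            try:
                model = _fit_method(method, sub_train, config)
                table.add("data", method, fs, evaluate(model, sub_test))
            except Exception as exc:
                logger.warning("comparison row (%s, %s) failed: %s", method, fs, exc)
                table.add("data", method, fs, None, error=str(exc))
    return table
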