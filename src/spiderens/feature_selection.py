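"""Feature/gene ranking strategies and differential-expression selection.

Four strategies are provided: the chi-squared selection statistic on
nonnegative (min-max normalized) features, recursive feature elimination
wrapped around a linear support-vector classifier, gradient-boosted-tree
gain importance (BoostFS), and a differentially-expressed-gene selector
that intersects up-/down-regulated gene sets across three timepoint
contrasts (Welch t-test with Benjamini-Hochberg FDR control). A cut-off
sweep harness measures downstream accuracy/AUC as a function of the number
of features kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE, chi2
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests
from xgboost import XGBClassifier

from .data_io import LabeledDataset

UP = "up"
DOWN = "down"


@dataclass
class FeatureRanking:
    """Ordered per-feature scores from one selection strategy.

    ``order`` sorts ``scores`` descending, ties broken by ascending feature
    index; higher score means more relevant.
    """

    method: str
    scores: np.ndarray
    order: np.ndarray

    @classmethod
    def from_scores(cls, method: str, scores: np.ndarray) -> "FeatureRanking":
        scores = np.asarray(scores, dtype=float)
        # lexsort: primary key last — descending score, then ascending index
        order = np.lexsort((np.arange(len(scores)), -scores))
        return cls(method=method, scores=scores, order=order)


def chi2_rank(data: LabeledDataset) -> FeatureRanking:
    """Chi-squared statistic of class-conditional feature sums vs expectation.

    Requires nonnegative features (min-max normalize first). Constant and
    all-zero features score 0.
    """
    data.require_both_classes()
    if np.nanmin(data.features) < 0:
        raise ValueError("chi2 requires nonnegative features; normalize first")
    scores, _ = chi2(data.features, data.labels)
    scores = np.nan_to_num(scores, nan=0.0)
    return FeatureRanking.from_scores("chi2", scores)


def rfe_svc_rank(data: LabeledDataset, step: int = 1) -> FeatureRanking:
    """Recursive elimination with a linear SVC (C=1); later-dropped = higher.

    Each round drops the ``step`` features with smallest squared weight; the
    score is the (negated) elimination rank, so the surviving feature scores
    highest.
    """
    data.require_both_classes()
    if step < 1 or step >= data.n_features:
        raise ValueError("step must satisfy 1 <= step < n_features")
    est = SVC(kernel="linear", C=1.0)
    rfe = RFE(estimator=est, n_features_to_select=1, step=step)
    rfe.fit(data.features, data.labels)
    # ranking_ is 1 for the survivor, increasing with earlier elimination
    scores = (data.n_features - rfe.ranking_).astype(float)
    return FeatureRanking.from_scores("rfe_svc", scores)


def boostfs_rank(data: LabeledDataset, seed: int = 0) -> FeatureRanking:
    """Gain importance from a gradient-boosted tree classifier.

    100 rounds, depth 3, learning rate 0.1, seed-fixed; features never used
    in a split score 0.
    """
    data.require_both_classes()
    model = XGBClassifier(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        random_state=seed,
        n_jobs=1,
        tree_method="exact",
        eval_metric="logloss",
    )
    model.fit(data.features, data.labels)
    gain = model.get_booster().get_score(importance_type="gain")
    scores = np.zeros(data.n_features)
    for key, val in gain.items():
        scores[int(key[1:])] = val  # keys are "f<idx>"
    return FeatureRanking.from_scores("boostfs", scores)


def apply_cutoff(ranking: FeatureRanking, data: LabeledDataset, n_keep: int) -> LabeledDataset:
    """Restrict the dataset to the top-``n_keep`` ranked features.

    The kept features stay in their original column order.
    """
    if not 1 <= n_keep <= data.n_features:
        raise ValueError(f"n_keep must lie in [1, {data.n_features}]")
    keep = np.sort(ranking.order[:n_keep])
    return data.select_features(keep)


def sweep_cutoffs(
    ranking: FeatureRanking,
    train: LabeledDataset,
    test: LabeledDataset,
    grid: list[int] | None = None,
    rounds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy/AUC of the default ensemble at each feature cut-off.

    Default grid is 5, 10, ..., 1000, clipped to the feature count and
    deduplicated. Returns a DataFrame with columns cutoff, accuracy, auc.
    """
    from .ensemble import fit_ensemble  # local import avoids a cycle
    from .evaluation import evaluate

    if grid is None:
        grid = list(range(5, 1001, 5))
    grid = sorted({min(g, train.n_features) for g in grid if g >= 1})
    if not grid:
        raise ValueError("cut-off grid is empty")
    rows = []
    for cut in grid:
        sub_train = apply_cutoff(ranking, train, cut)
        sub_test = apply_cutoff(ranking, test, cut)
        model = fit_ensemble(sub_train, rounds=rounds, seed=seed, resample_first=False)
        report = evaluate(model, sub_test)
        rows.append({"cutoff": cut, "accuracy": report.accuracy, "auc": report.auc})
    return pd.DataFrame(rows)


@dataclass
class DEGResult:
    """Per-contrast differential-expression tables and their intersections.

    ``per_contrast`` maps the contrast name to a DataFrame with columns
    gene, effect (condition mean - reference mean), p, adj_p, direction;
    ``intersection_up`` / ``intersection_down`` hold the genes consistently
    up-/down-regulated (adjusted p < alpha) in all three contrasts.
    """

    per_contrast: dict[str, pd.DataFrame]
    intersection_up: set[str]
    intersection_down: set[str]
    alpha: float


#: Conventional contrast names: control-vs-patient, baseline-vs-year1,
#: year1-vs-year2. In each, group 0 is the reference, group 1 the condition.
CONTRAST_NAMES = ("C-vs-P", "B-1-fu", "1-2-fu")


def select_degs(
    stages: list[LabeledDataset],
    alpha: float = 0.005,
    log_transform: bool = False,
    names: tuple[str, str, str] = CONTRAST_NAMES,
) -> DEGResult:
    """Three-contrast DEG selection with FDR-controlled Venn intersection.

    Per contrast and gene: Welch two-sample t-test on (optionally
    log2-transformed) values, Benjamini-Hochberg adjustment across genes;
    a gene is differentially expressed if adjusted p < alpha. Direction is
    the sign of (condition mean - reference mean): positive means up.
    """
    if len(stages) != 3:
        raise ValueError("exactly three contrasts are required")
    ref_names = stages[0].feature_names
    for s in stages[1:]:
        if s.feature_names != ref_names:
            raise ValueError("feature names differ across contrasts")
    per_contrast: dict[str, pd.DataFrame] = {}
    up_sets: list[set[str]] = []
    down_sets: list[set[str]] = []
    for name, stage in zip(names, stages):
        stage.require_both_classes()
        x = stage.features
        if log_transform:
            x = np.log2(x)
        ref = x[stage.labels == 0]
        cond = x[stage.labels == 1]
        if len(ref) < 2 or len(cond) < 2:
            raise ValueError(f"contrast {name}: each group needs >= 2 samples")
        tstat, p = stats.ttest_ind(cond, ref, axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        _, adj_p, _, _ = multipletests(p, method="fdr_bh")
        effect = cond.mean(axis=0) - ref.mean(axis=0)
        direction = np.where(effect > 0, UP, DOWN)
        table = pd.DataFrame({
            "gene": ref_names,
            "effect": effect,
            "p": p,
            "adj_p": adj_p,
            "direction": direction,
        })
        per_contrast[name] = table
        sig = table[table.adj_p < alpha]
        up_sets.append(set(sig.gene[sig.direction == UP]))
        down_sets.append(set(sig.gene[sig.direction == DOWN]))
    return DEGResult(
        per_contrast=per_contrast,
        intersection_up=set.intersection(*up_sets),
        intersection_down=set.intersection(*down_sets),
        alpha=alpha,
    )


def degs_feature_ranking(result: DEGResult, feature_names: list[str]) -> FeatureRanking:
    """Binary ranking from a DEG intersection: members score 1, others 0.

    Ordering within the member/non-member groups follows feature index, so
    ``apply_cutoff`` with the intersection size returns exactly the DEG set.
    """
    members = result.intersection_up | result.intersection_down
    scores = np.array([1.0 if g in members else 0.0 for g in feature_names])
    return FeatureRanking.from_scores("degs", scores)
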