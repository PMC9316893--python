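"""Hierarchical voting + boosting ensemble over class-balanced subsets.

Two heterogeneous arms — a random-forest family and a support-vector family
— are each trained as an AdaBoost-style committee: every round draws a
class-balanced subset (sampling probability proportional to the current
boosting weights), fits one base learner on it, scores the whole training
population, and up-weights the misclassified samples. The two arms are
combined by averaging their class-probability outputs (majority vote of
class probability); an exact probability tie goes to the minority class by
default. An optional third arm of gradient-boosted trees can be enabled.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data_io import LabeledDataset
from .imbalance import spider_resample

EPS_FLOOR = 1e-6
MODEL_FORMAT = "spiderens-model"
MODEL_VERSION = 1


@dataclass
class BaseLearnerSpec:
    """Configuration of one base-learner family.

    Defaults follow the study configuration: the random forest has 100 trees
    each considering 10 randomly selected attributes (clipped to the feature
    count); the SVM uses an RBF kernel with C = 1 and a 1/(n_features * var)
    gamma.
    """

    family: str = "random_forest"  # random_forest | svm | gbt
    rf_trees: int = 100
    rf_features_per_tree: int = 10
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("random_forest", "svm", "gbt"):
            raise ValueError(f"unknown base-learner family {self.family!r}")


class CalibratedSVC:
    """SVC emitting class probabilities via a sigmoid on the decision value.

    The sigmoid is fitted on a 20% internal holdout of the training subset
    (falling back to the training decisions when the holdout cannot be
    stratified), so the committee can average probabilities across arms.
    """

    def __init__(self, spec: BaseLearnerSpec, random_state: int):
        self.svc = SVC(kernel=spec.svm_kernel, C=spec.svm_C, gamma=spec.svm_gamma,
                       random_state=random_state)
        self.random_state = random_state
        self.classes_ = np.array([0, 1])

    def fit(self, x: np.ndarray, y: np.ndarray) -> "CalibratedSVC":
        y = np.asarray(y, dtype=int)
        holdout = None
        n0, n1 = int((y == 0).sum()), int((y == 1).sum())
        if min(n0, n1) >= 5:
            xt, xh, yt, yh = train_test_split(
                x, y, test_size=0.2, random_state=self.random_state, stratify=y)
            if len(np.unique(yh)) == 2 and len(np.unique(yt)) == 2:
                holdout = (xh, yh)
                x, y = xt, yt
        self.svc.fit(x, y)
        cal_x, cal_y = holdout if holdout is not None else (x, y)
        dec = self.svc.decision_function(cal_x).reshape(-1, 1)
        self._sigmoid = LogisticRegression(C=1e6, max_iter=1000)
        self._sigmoid.fit(dec, cal_y)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        dec = self.svc.decision_function(x).reshape(-1, 1)
        return self._sigmoid.predict_proba(dec)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.svc.predict(x)


def make_base_learner(spec: BaseLearnerSpec, n_features: int, seed: int):
    """Instantiate one unfitted base learner of the spec's family."""
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.rf_trees,
            max_features=min(spec.rf_features_per_tree, n_features),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "svm":
        return CalibratedSVC(spec, random_state=seed)
    return XGBClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1,
        random_state=seed, n_jobs=1, eval_metric="logloss",
    )


def draw_balanced_subset(
    data: LabeledDataset,
    sample_weights: np.ndarray,
    per_class_size: int,
    rng_seed: int,
) -> LabeledDataset:
    """Draw ``per_class_size`` samples per class, probability ~ weight.

    Sampling is without replacement when the class holds at least
    ``per_class_size`` samples, with replacement otherwise. The selected
    rows are returned in their original order, so a full-size uniform draw
    reproduces the input exactly.
    """
    data.require_both_classes()
    w = np.asarray(sample_weights, dtype=float)
    if w.shape != (data.n_samples,) or (w < 0).any():
        raise ValueError("sample_weights must be nonnegative, one per sample")
    rng = np.random.default_rng(rng_seed)
    chosen: list[np.ndarray] = []
    for c in (0, 1):
        idx = np.flatnonzero(data.labels == c)
        wc = w[idx]
        total = wc.sum()
        if total <= 0:
            raise ValueError(f"class {c} has zero total weight")
        p = wc / total
        replacing = len(idx) < per_class_size
        chosen.append(rng.choice(idx, size=per_class_size, replace=replacing, p=p))
    sel = np.sort(np.concatenate(chosen))
    # with-replacement draws may repeat a sample; deduplicate ids on subset
    feats = data.features[sel]
    labels = data.labels[sel]
    ids = []
    seen: dict[str, int] = {}
    for i in sel:
        base = data.sample_ids[i]
        seen[base] = seen.get(base, 0)
        ids.append(base if seen[base] == 0 else f"{base}~{seen[base]}")
        seen[base] += 1
    return LabeledDataset(feats, labels, list(data.feature_names), ids)


@dataclass
class BoostedCommittee:
    """An ordered committee of base learners with AdaBoost-style weights."""

    spec: BaseLearnerSpec
    members: list = field(default_factory=list)
    member_weights: list[float] = field(default_factory=list)
    rounds: int = 0
    subset_size: int = 0

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return committee_predict_proba(self, features)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)


def committee_predict_proba(committee: BoostedCommittee, features: np.ndarray) -> np.ndarray:
    """alpha-weighted average of member class probabilities; rows sum to 1.

    When every alpha is zero the members are averaged uniformly.
    """
    features = np.asarray(features, dtype=float)
    if not committee.members:
        raise ValueError("committee has no members")
    alphas = np.asarray(committee.member_weights, dtype=float)
    if alphas.sum() <= 0:
        alphas = np.ones_like(alphas)
    alphas = alphas / alphas.sum()
    out = np.zeros((features.shape[0], 2))
    for a, member in zip(alphas, committee.members):
        proba = member.predict_proba(features)
        # align to classes (0, 1) if the member saw only a permuted order
        classes = np.asarray(getattr(member, "classes_", [0, 1]), dtype=int)
        aligned = np.zeros_like(out)
        for col, cls in enumerate(classes):
            aligned[:, cls] = proba[:, col]
        out += a * aligned
    return out / out.sum(axis=1, keepdims=True)


def boost_fit(
    spec: BaseLearnerSpec,
    data: LabeledDataset,
    rounds: int = 10,
    per_class_size: int | None = None,
    seed: int = 0,
) -> BoostedCommittee:
    """Train a boosted committee on class-balanced weighted subsets.

    Samples start equally weighted. Each round draws a balanced subset by
    the current weights, fits one learner, and computes its weighted error
    on the whole population; members with error >= 0.5 are discarded and the
    draw retried (3 retries per round, then early stop). Accepted members
    get alpha = 0.5 * ln((1 - eps) / eps) (eps clipped to [1e-6, 1 - 1e-6]),
    misclassified samples are up-weighted by exp(alpha), and an essentially
    error-free member ends the loop.
    """
    data.require_both_classes()
    if rounds < 1:
        raise ValueError("rounds must be positive")
    n0, n1 = data.class_counts()
    if per_class_size is None:
        per_class_size = min(n0, n1)
    rng = np.random.default_rng(seed)
    n = data.n_samples
    w = np.full(n, 1.0 / n)
    committee = BoostedCommittee(spec=spec, rounds=rounds, subset_size=per_class_size)
    for round_no in range(rounds):
        accepted = False
        for _ in range(4):  # first attempt + 3 retries
            subset_seed = int(rng.integers(0, 2**31 - 1))
            subset = draw_balanced_subset(data, w, per_class_size, subset_seed)
            learner = make_base_learner(spec, data.n_features, seed=spec.seed + round_no)
            learner.fit(subset.features, subset.labels)
            predicted = np.asarray(learner.predict(data.features), dtype=int)
            mis = predicted != data.labels
            eps_raw = float(w[mis].sum())
            if eps_raw >= 0.5:
                continue
            accepted = True
            break
        if not accepted:
            break  # early stop: no acceptable member this round
        eps = min(max(eps_raw, EPS_FLOOR), 1 - EPS_FLOOR)
        alpha = 0.5 * math.log((1 - eps) / eps)
        committee.members.append(learner)
        committee.member_weights.append(alpha)
        if eps_raw <= EPS_FLOOR:
            break  # essentially perfect member; further rounds are redundant
        w[mis] *= math.exp(alpha)
        w /= w.sum()
    if not committee.members:
        raise RuntimeError("boosting failed to find weak learner")
    return committee


@dataclass
class VotingEnsemble:
    """Two (optionally three) boosted committees voting by class probability."""

    arms: list[BoostedCommittee]
    tie_rule: str = "minority"  # minority | majority

    def __post_init__(self) -> None:
        families = [a.spec.family for a in self.arms]
        if len(set(families)) != len(families):
            raise ValueError("ensemble arms must have distinct families")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        probs = [committee_predict_proba(arm, features) for arm in self.arms]
        return np.mean(probs, axis=0)

    def predict(self, features: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(features)
        tie_label = 1 if self.tie_rule == "minority" else 0
        out = np.where(proba[:, 1] > proba[:, 0], 1,
                       np.where(proba[:, 1] < proba[:, 0], 0, tie_label))
        return out.astype(int)


def tune_svm_c(data: LabeledDataset, seed: int, grid: tuple[float, ...] = (0.1, 1.0, 10.0)) -> float:
    """Pick svm_C from a small deterministic grid by 3-fold CV accuracy."""
    best_c, best_acc = grid[0], -1.0
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for c in grid:
        accs = []
        for tr, te in cv.split(data.features, data.labels):
            model = SVC(kernel="rbf", C=c, gamma="scale").fit(
                data.features[tr], data.labels[tr])
            accs.append(float((model.predict(data.features[te]) == data.labels[te]).mean()))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_acc, best_c = mean_acc, c
    return best_c


def fit_ensemble(
    data: LabeledDataset,
    rounds: int = 10,
    per_class_size: int | None = None,
    resample_first: bool = True,
    k: int = 3,
    seed: int = 0,
    with_gbt_arm: bool = False,
    tune: bool = False,
    tie_rule: str = "minority",
) -> VotingEnsemble:
    """Fit the full hierarchical ensemble.

    With ``resample_first`` the training population is first balanced by
    selective over-sampling (originals + synthetics pooled); one boosted
    committee is then fitted per family with derived seeds.
    """
    data.require_both_classes()
    if resample_first:
        data = spider_resample(data, k=k, seed=seed).dataset
    svm_c = tune_svm_c(data, seed) if tune else 1.0
    specs = [
        BaseLearnerSpec(family="random_forest", seed=seed),
        BaseLearnerSpec(family="svm", svm_C=svm_c, seed=seed + 1),
    ]
    if with_gbt_arm:
        specs.append(BaseLearnerSpec(family="gbt", seed=seed + 2))
    arms = [
        boost_fit(spec, data, rounds=rounds, per_class_size=per_class_size, seed=spec.seed)
        for spec in specs
    ]
    return VotingEnsemble(arms=arms, tie_rule=tie_rule)


def save_model(ensemble: VotingEnsemble, path: str | Path) -> None:
    """Serialize with a versioned header so load can refuse mismatches."""
    payload = {"format": MODEL_FORMAT, "version": MODEL_VERSION, "model": ensemble}
    with Path(path).open("wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> VotingEnsemble:
    with Path(path).open("rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path} is not a spiderens model file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version {payload.get('version')} unsupported (expected {MODEL_VERSION})")
    return payload["model"]
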