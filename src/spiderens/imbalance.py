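"""Selective kNN-based over-sampling of the minority class (SPIDER-style).

The resampler proceeds in two steps. First, every sample is classified by the
majority vote of its k nearest neighbors; samples whose neighborhood vote
contradicts their own label are flagged *noisy* and excluded from the neighbor
pool used for generation. Second, the remaining minority samples are split
into *weak* (locally outnumbered by the majority class) and *strong* samples,
and new minority samples are synthesized by random interpolation between each
seed sample and one of its nearest non-noisy neighbors — weak seeds are
amplified proportionally to the majority presence in their neighborhood,
strong seeds once — until the classes are balanced. Original majority samples
are retained: no information is discarded through under-sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, euclidean

from .data_io import LabeledDataset

SAFE = "safe"
NOISY = "noisy"
WEAK = "weak"
STRONG = "strong"
EXCLUDED = "excluded"


def pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(euclidean(a, b))


@dataclass
class NeighborIndex:
    """Pairwise Euclidean distances with deterministic neighbor ordering."""

    k: int
    distances: np.ndarray  # symmetric, zero diagonal

    @classmethod
    def build(cls, features: np.ndarray, k: int) -> "NeighborIndex":
        if k < 1:
            raise ValueError("k must be positive")
        d = cdist(features, features, metric="euclidean")
        return cls(k=k, distances=d)

    def neighbors(self, i: int, pool: np.ndarray | None = None, k: int | None = None) -> np.ndarray:
        """Indices of the k nearest neighbors of sample ``i`` within ``pool``.

        ``pool`` is a boolean mask over samples (default: all); sample ``i``
        itself is never a neighbor. Distance ties break by lower index.
        """
        k = self.k if k is None else k
        n = self.distances.shape[0]
        mask = np.ones(n, dtype=bool) if pool is None else pool.copy()
        mask[i] = False
        cand = np.flatnonzero(mask)
        if len(cand) == 0:
            return cand
        # stable sort on distance; candidate indices are already ascending,
        # so equal distances resolve to the lower sample index
        order = np.argsort(self.distances[i, cand], kind="stable")
        return cand[order[:k]]


@dataclass
class SampleFlags:
    """Per-sample noise flags and minority strength tags.

    ``classification[i]`` is ``safe`` or ``noisy`` for every sample;
    ``minority_strength[i]`` is ``weak``/``strong``/``excluded`` for minority
    samples and ``None`` for majority samples.
    """

    classification: list[str]
    minority_strength: list[str | None]


def knn_flag(data: LabeledDataset, k: int = 3, index: NeighborIndex | None = None) -> SampleFlags:
    """Flag each sample safe/noisy by the majority vote of its k neighbors.

    A sample is *safe* iff the plurality label among its k nearest other
    samples equals its own label; vote ties count as safe.
    """
    data.require_both_classes()
    if np.isnan(data.features).any():
        raise ValueError("missing values present; impute first")
    n = data.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    n0, n1 = data.class_counts()
    if min(n0, n1) < k:
        raise ValueError(f"each class needs at least k={k} samples")
    index = index or NeighborIndex.build(data.features, k)
    classification: list[str] = []
    for i in range(n):
        nb = index.neighbors(i, k=k)
        votes_own = int((data.labels[nb] == data.labels[i]).sum())
        classification.append(SAFE if 2 * votes_own >= len(nb) else NOISY)
    return SampleFlags(classification=classification, minority_strength=[None] * n)


def partition_minority(
    data: LabeledDataset,
    flags: SampleFlags,
    k: int = 3,
    index: NeighborIndex | None = None,
) -> SampleFlags:
    """Tag non-noisy minority samples weak/strong; noisy minority → excluded.

    The neighborhood is re-evaluated in the safe-sample pool (noisy samples
    of either class removed); a minority sample is *weak* when majority-class
    samples outnumber minority ones among its k nearest pooled neighbors.
    Restricting to safe samples is what makes the weak class attainable: with
    noisy minority samples still in the pool, a sample that passed the safety
    vote could never be locally outnumbered at odd k.
    """
    index = index or NeighborIndex.build(data.features, k)
    n0, n1 = data.class_counts()
    minority_label = 1 if n1 <= n0 else 0
    noisy = np.array([c == NOISY for c in flags.classification])
    pool = ~noisy
    strength: list[str | None] = [None] * data.n_samples
    for i in range(data.n_samples):
        if data.labels[i] != minority_label:
            continue
        if noisy[i]:
            strength[i] = EXCLUDED
            continue
        nb = index.neighbors(i, pool=pool, k=k)
        maj = int((data.labels[nb] != minority_label).sum())
        mino = len(nb) - maj
        strength[i] = WEAK if maj > mino else STRONG
    return SampleFlags(classification=list(flags.classification), minority_strength=strength)


@dataclass
class ResampleResult:
    """Augmented dataset plus provenance for the resampling step.

    ``synthetic_parents`` / ``synthetic_neighbors`` give, for each synthetic
    row in order, the input-dataset indices of the seed sample and of the
    neighbor it was interpolated toward.
    """

    dataset: LabeledDataset
    flags: SampleFlags
    provenance: list[str]  # "original" / "synthetic", aligned with dataset rows
    seed: int
    synthetic_parents: list[int] = None
    synthetic_neighbors: list[int] = None


def spider_resample(
    data: LabeledDataset,
    k: int = 3,
    seed: int = 0,
    balance_target: float = 1.0,
    max_passes: int = 10,
    drop_noisy_majority: bool = False,
) -> ResampleResult:
    """Balance the classes by selective minority over-sampling.

    Weak minority seeds generate one synthetic sample per majority neighbor
    among their k nearest non-noisy neighbors; strong seeds generate one.
    Each synthetic sample is ``s + u * (nu - s)`` with ``u ~ Uniform(0, 1)``
    and ``nu`` drawn uniformly from the seed's k nearest non-noisy neighbors,
    so every coordinate lies on the parent-neighbor segment. Generation stops
    as soon as the minority count reaches ``ceil(balance_target * majority)``
    or after ``max_passes`` sweeps over the weak set.
    """
    data.require_both_classes()
    rng = np.random.default_rng(seed)
    index = NeighborIndex.build(data.features, k)
    flags = knn_flag(data, k, index=index)
    flags = partition_minority(data, flags, k, index=index)

    n0, n1 = data.class_counts()
    minority_label = 1 if n1 <= n0 else 0
    majority_label = 1 - minority_label
    noisy = np.array([c == NOISY for c in flags.classification])

    minority_idx = np.flatnonzero(data.labels == minority_label)
    if all(flags.minority_strength[i] == EXCLUDED for i in minority_idx):
        raise ValueError("no seeds for amplification: every minority sample is noisy")

    weak = [i for i in minority_idx if flags.minority_strength[i] == WEAK]
    strong = [i for i in minority_idx if flags.minority_strength[i] == STRONG]

    # generation pool: all non-noisy samples
    pool = ~noisy
    keep_mask = np.ones(data.n_samples, dtype=bool)
    if drop_noisy_majority:
        keep_mask = ~(noisy & (data.labels == majority_label))

    majority_count = int((data.labels[keep_mask] == majority_label).sum())
    minority_count = int((data.labels == minority_label).sum())
    target = math.ceil(balance_target * majority_count)

    new_rows: list[np.ndarray] = []
    new_parents: list[int] = []
    new_neighbors: list[int] = []

    def generate_from(s: int) -> bool:
        """Synthesize one sample seeded at ``s``; False if it has no neighbors."""
        nb = index.neighbors(s, pool=pool, k=k)
        if len(nb) == 0:
            return False
        nu = int(rng.choice(nb))
        u = rng.uniform()
        new_rows.append(data.features[s] + u * (data.features[nu] - data.features[s]))
        new_parents.append(s)
        new_neighbors.append(nu)
        return True

    done = minority_count >= target
    for pass_no in range(max_passes):
        if done:
            break
        progressed = False
        for s in weak:
            nb = index.neighbors(s, pool=pool, k=k)
            c = int((data.labels[nb] == majority_label).sum())
            for _ in range(c):
                if minority_count >= target:
                    done = True
                    break
                if generate_from(s):
                    minority_count += 1
                    progressed = True
            if done:
                break
        if pass_no == 0 and not done:
            for s in strong:
                if minority_count >= target:
                    done = True
                    break
                if generate_from(s):
                    minority_count += 1
                    progressed = True
        if minority_count >= target:
            done = True
        if not progressed:
            break

    keep_idx = np.flatnonzero(keep_mask)
    features = np.vstack([data.features[keep_idx]] + ([np.array(new_rows)] if new_rows else []))
    labels = np.concatenate([
        data.labels[keep_idx],
        np.full(len(new_rows), minority_label, dtype=int),
    ])
    sample_ids = [data.sample_ids[i] for i in keep_idx] + [
        f"syn{j}_{data.sample_ids[p]}" for j, p in enumerate(new_parents)
    ]
    provenance = ["original"] * len(keep_idx) + ["synthetic"] * len(new_rows)
    out = LabeledDataset(features, labels, list(data.feature_names), sample_ids)
    return ResampleResult(dataset=out, flags=flags, provenance=provenance, seed=seed,
                          synthetic_parents=new_parents, synthetic_neighbors=new_neighbors)
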