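"""Dynamic feature selection and the optimal subset of features (OSF).

The selection procedure hunts for features that are *stable* under
perturbations of the training sample, in two stages:

Dynamic selection (per held-out patient). Under leave-one-patient-out
resampling, each fold iterates: draw ``n_subsets`` class-stratified random
subsets of ``subset_fraction`` of the training patients; on each subset
apply a Wilcoxon rank-sum filter (two-sided p < ``filter_alpha``, no
multiple-testing correction) followed by an embedded criterion (a
100-tree Gini-importance forest keeping features above the mean
importance); union the per-subset selections into the iteration set; and
intersect iteration sets cumulatively. All folds advance in lockstep and
iteration stops globally once the number of features discarded between
two consecutive iterations is below ``stop_delta`` for at least
``stop_patient_fraction`` of the folds, or at ``max_iterations``.

Optimal subset (OSF). The per-fold cumulative sets are intersected
patient by patient; what survives every fold is the stable core used by
the downstream classifier.

The embedded threshold (above-mean importance vs a fixed count) is the
one genuinely unstated knob of the procedure; it is surfaced as
``importance_rule`` and recorded in traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._forest import gini_importances
from ._rng import STREAM_SELECTION, derive_int_seed, substream
from .cnn_features import FEATURES_PER_ROI
from .errors import ConfigurationError

__all__ = [
    "SelectionConfig",
    "FeatureIndexSet",
    "IterationRecord",
    "SelectionTrace",
    "wilcoxon_pvalues",
    "wilcoxon_filter",
    "forest_embedded_select",
    "dynamic_selection",
    "compute_osf",
]


@dataclass(frozen=True)
class SelectionConfig:
    n_subsets: int = 10
    subset_fraction: float = 0.90
    filter_alpha: float = 0.001
    n_trees: int = 100
    importance_rule: str = "above_mean"  # or "top_k"
    top_k: int = 30
    #: threshold scale for above_mean: keep importance > fraction * mean.
    #: Per-tree importances are normalized, so the candidate mean is the
    #: uniform share 1/K and fraction=1.0 (the strict reading) discards
    #: the lower half of a uniformly informative pool; the default 0.5
    #: keeps the whole informative cluster while features near the noise
    #: floor still fall out (see the methods note).
    mean_fraction: float = 0.5
    #: features examined per forest node. None (default) adapts to the
    #: candidate pool: max(1, K // 20). Small, uniformly informative pools
    #: get totally randomized split choice (importance measures marginal
    #: strength, so equally strong features rank comparably); large pools
    #: get greedy concentration, so the same consistently strongest
    #: features are kept across resamples and survive the intersections.
    forest_max_features: int | None = None
    #: smallest candidate pool the embedded forest will rank; an importance
    #: comparison over fewer candidates carries no ensemble evidence and
    #: the pool is rejected as unstable (returns the empty set).
    min_candidates: int = 4
    stop_delta: int = 10
    stop_patient_fraction: float = 0.95
    max_iterations: int = 20
    per_fold_stopping: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subsets < 1:
            raise ConfigurationError("n_subsets must be >= 1")
        if not 0.0 < self.subset_fraction < 1.0:
            raise ConfigurationError("subset_fraction must be in (0, 1)")
        if not 0.0 < self.filter_alpha < 1.0:
            raise ConfigurationError("filter_alpha must be in (0, 1)")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.importance_rule not in ("above_mean", "top_k"):
            raise ConfigurationError("importance_rule must be above_mean or top_k")
        if self.mean_fraction <= 0:
            raise ConfigurationError("mean_fraction must be > 0")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if not 0.0 < self.stop_patient_fraction <= 1.0:
            raise ConfigurationError("stop_patient_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FeatureIndexSet:
    """A sorted set of indices into a feature space, with provenance.

    ``provenance`` is the set of patient ids whose data influenced the
    selection; it powers the leakage guard in the evaluation stage. For
    the concatenated per-patient descriptor, indices below 43264 belong
    to the pre-treatment (T1) block, the rest to the early-treatment (T2)
    block.
    """

    indices: tuple[int, ...]
    provenance: frozenset = frozenset()

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        if idx and idx[0] < 0:
            raise ValueError("feature indices must be non-negative")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "provenance", frozenset(self.provenance))

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __contains__(self, i) -> bool:
        return int(i) in set(self.indices)

    def intersection(self, other: "FeatureIndexSet") -> "FeatureIndexSet":
        return FeatureIndexSet(
            set(self.indices) & set(other.indices),
            self.provenance | other.provenance,
        )

    def union(self, other: "FeatureIndexSet") -> "FeatureIndexSet":
        return FeatureIndexSet(
            set(self.indices) | set(other.indices),
            self.provenance | other.provenance,
        )

    def timepoint_counts(self, boundary: int = FEATURES_PER_ROI) -> dict[str, int]:
        t1 = sum(1 for i in self.indices if i < boundary)
        return {"T1": t1, "T2": len(self.indices) - t1}

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=np.int64)


def _tie_term(sorted_vals: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tied groups, per column of the trailing axes.

    ``sorted_vals`` has shape (..., m, p), sorted along the sample axis.
    """
    *lead, m, p = sorted_vals.shape
    flat = sorted_vals.reshape(-1, m, p)
    b = flat.shape[0]
    new_run = np.ones((b, m, p), dtype=np.int64)
    new_run[:, 1:, :] = flat[:, 1:, :] != flat[:, :-1, :]
    rid = np.cumsum(new_run, axis=1) - 1  # run id within each column
    offsets = (np.arange(b)[:, None, None] * p + np.arange(p)[None, None, :]) * m
    counts = np.bincount((rid + offsets).ravel(), minlength=b * p * m)
    counts = counts.reshape(b, p, m)
    T = (counts.astype(np.float64) ** 3 - counts).sum(axis=2)
    return T.reshape(*lead, p) if lead else T.reshape(p)


def _approx_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation rank-sum p-values, vectorized.

    Midranks with tie-corrected variance and a 0.5 continuity correction
    (the convention of scipy's asymptotic Mann-Whitney test). Supports a
    leading batch axis: X (..., m, p), y (..., m).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    m = X.shape[-2]
    # one sort serves both ranking and tie detection; midranks equal plain
    # ranks when a column is tie-free, so the cheap path is exact
    order = np.argsort(X, axis=-2, kind="stable")
    S = np.take_along_axis(X, order, axis=-2)
    if np.any(S[..., 1:, :] == S[..., :-1, :]):
        ranks = stats.rankdata(X, axis=-2)
        T = _tie_term(S)
    else:
        ranks = np.empty_like(X)
        np.put_along_axis(
            ranks,
            order,
            np.arange(1.0, m + 1.0).reshape((m, 1)),
            axis=-2,
        )
        T = np.zeros(X.shape[:-2] + (X.shape[-1],))
    mask1 = (y == 1)[..., None]
    n1 = mask1.sum(axis=-2)
    n2 = (~mask1).sum(axis=-2)
    R1 = np.where(mask1, ranks, 0.0).sum(axis=-2)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((m + 1) - T / (m * (m - 1)))
    num = np.maximum(np.abs(U1 - mu) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, num / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    # fully tied (constant) columns carry no information
    p = np.where(var <= 0, 1.0, p)
    return p


@lru_cache(maxsize=128)
def _exact_u_tail_tables(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """(cdf, sf) of the exact null distribution of the Mann-Whitney U
    statistic for group sizes (n1, n2), no ties.

    Built by dynamic programming over rank memberships: dp[k, s] counts
    subsets of {1..n} of size k with rank sum s.
    """
    n = n1 + n2
    max_s = n1 * n + 1
    dp = np.zeros((n1 + 1, max_s), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        dp[1:, rank:] += dp[:-1, :-rank].copy()  # each rank used once
    counts = dp[n1]  # indexed by rank sum of group 1
    offset = n1 * (n1 + 1) // 2  # U = R1 - offset
    pmf = counts[offset : offset + n1 * n2 + 1]
    pmf = pmf / pmf.sum()
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    return cdf, sf


def _exact_pvalues(ranks1_sum: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Vectorized exact two-sided p-values from group-1 rank sums."""
    cdf, sf = _exact_u_tail_tables(n1, n2)
    u = np.rint(ranks1_sum - n1 * (n1 + 1) / 2.0).astype(np.int64)
    return np.minimum(1.0, 2.0 * np.minimum(cdf[u], sf[u]))


def wilcoxon_pvalues(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per feature column.

    Exact when both class sizes are <= 12 and the column is tie-free
    (verified to equal full enumeration over rank assignments); otherwise
    the normal approximation with tie and continuity corrections.
    Constant columns get p = 1.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) with one label per row")
    n1 = int((y == 1).sum())
    n2 = int((y == 0).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    if n1 <= 12 and n2 <= 12 and X.shape[1] > 0:
        order = np.argsort(X, axis=0, kind="stable")
        S = np.take_along_axis(X, order, axis=0)
        tie_free = ~np.any(S[1:] == S[:-1], axis=0)
        p = (
            np.ones(X.shape[1])
            if tie_free.all()
            else _approx_pvalues(X, y)  # tie/continuity-corrected fallback
        )
        if tie_free.any():
            ranks = np.empty_like(X)
            np.put_along_axis(
                ranks, order, np.arange(1.0, len(y) + 1.0)[:, None], axis=0
            )
            r1 = ranks[y == 1][:, tie_free].sum(axis=0)
            p[tie_free] = _exact_pvalues(r1, n1, n2)
        return p
    return _approx_pvalues(X, y)


def wilcoxon_filter(
    X: np.ndarray, labels: np.ndarray, alpha: float = 0.001
) -> FeatureIndexSet:
    """Indices of features whose rank-sum p-value is below ``alpha``.

    The raw cutoff is applied without multiple-testing correction; the
    stability machinery downstream is what controls false selections.
    """
    p = wilcoxon_pvalues(X, labels)
    return FeatureIndexSet(np.flatnonzero(p < alpha))


def forest_embedded_select(
    X: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig,
    candidates: Iterable[int] | None = None,
    seed: int | None = None,
) -> FeatureIndexSet:
    """Embedded criterion: keep candidates with above-mean Gini importance.

    A seeded ``n_trees``-tree forest is fit on the candidate columns;
    features whose mean-decrease-in-impurity importance strictly exceeds
    the mean over candidates are kept (``importance_rule="above_mean"``),
    or the ``top_k`` most important (``importance_rule="top_k"``).
    An empty candidate set returns an empty set.
    """
    if candidates is None:
        cand = np.arange(np.asarray(X).shape[1], dtype=np.int64)
    else:
        cand = np.asarray(sorted(set(int(i) for i in candidates)), dtype=np.int64)
    if cand.size < max(1, config.min_candidates):
        return FeatureIndexSet(())
    if (
        config.importance_rule == "above_mean"
        and config.mean_fraction >= 1.0
        and cand.size == 1
    ):
        # a lone candidate's importance equals the mean; strictly-greater fails
        return FeatureIndexSet(())
    max_features = (
        config.forest_max_features
        if config.forest_max_features is not None
        else max(1, int(cand.size) // 20)
    )
    imp = gini_importances(
        np.asarray(X, dtype=np.float64)[:, cand],
        np.asarray(labels),
        n_trees=config.n_trees,
        max_features=max_features,
        seed=seed if seed is not None else config.seed,
    )
    if config.importance_rule == "above_mean":
        keep = imp > config.mean_fraction * imp.mean()
        return FeatureIndexSet(cand[keep])
    order = np.lexsort((cand, -imp))[: min(config.top_k, cand.size)]
    return FeatureIndexSet(cand[order])


@dataclass
class IterationRecord:
    iteration: int
    subset_sets: list[tuple[int, ...]]
    union: tuple[int, ...]
    cumulative: tuple[int, ...]
    discarded: int | None  # vs previous iteration; None at the first


@dataclass
class SelectionTrace:
    fold_id: str
    iterations: list[IterationRecord] = field(default_factory=list)


def _stratified_subsets(
    train_rows: np.ndarray,
    y: np.ndarray,
    fraction: float,
    n_subsets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_subsets, m) row-index array; per-class sizes round up."""
    per_class_rows = [train_rows[y[train_rows] == c] for c in (0, 1)]
    takes = [int(math.ceil(fraction * len(rows))) for rows in per_class_rows]
    for take, rows in zip(takes, per_class_rows):
        if take < 2:
            raise ConfigurationError(
                "subset_fraction yields fewer than 2 training patients per class"
            )
    out = np.empty((n_subsets, sum(takes)), dtype=np.int64)
    for s in range(n_subsets):
        parts = [
            rng.choice(rows, size=take, replace=False)
            for rows, take in zip(per_class_rows, takes)
        ]
        out[s] = np.concatenate(parts)
    return out


def dynamic_selection(
    features: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig,
    patient_ids: Sequence[str] | None = None,
) -> tuple[dict[str, FeatureIndexSet], list[SelectionTrace]]:
    """Leave-one-patient-out dynamic feature selection.

    Returns the final cumulative feature set per fold (keyed by held-out
    patient id) and the per-fold traces. Cumulative sets are verified to
    be non-increasing across iterations on every run.
    """
    config.validate()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    n = X.shape[0]
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(n)]
    if len(patient_ids) != n or y.shape != (n,):
        raise ValueError("features, labels and patient_ids must align")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 patients per class")

    all_rows = np.arange(n)
    cumulative: list[set[int] | None] = [None] * n
    last_discard: list[int | None] = [None] * n
    active = [True] * n
    traces = [SelectionTrace(fold_id=pid) for pid in patient_ids]

    for it in range(1, config.max_iterations + 1):
        for f in range(n):
            if not active[f]:
                continue
            train_rows = np.delete(all_rows, f)
            rng = substream(config.seed, STREAM_SELECTION, f, it)
            subsets = _stratified_subsets(
                train_rows, y, config.subset_fraction, config.n_subsets, rng
            )
            pvals = _approx_batch_or_exact(X, y, subsets)
            subset_sets: list[tuple[int, ...]] = []
            union: set[int] = set()
            for s in range(config.n_subsets):
                survivors = np.flatnonzero(pvals[s] < config.filter_alpha)
                kept = forest_embedded_select(
                    X[subsets[s]],
                    y[subsets[s]],
                    config,
                    candidates=survivors,
                    seed=derive_int_seed(config.seed, STREAM_SELECTION, f, it, s),
                )
                subset_sets.append(kept.indices)
                union |= set(kept.indices)
            prev = cumulative[f]
            new = set(union) if prev is None else prev & union
            if prev is not None:
                # monotone-intersection invariant, asserted on every run
                if not new <= prev:
                    raise AssertionError("cumulative set grew across iterations")
                last_discard[f] = len(prev) - len(new)
            cumulative[f] = new
            traces[f].iterations.append(
                IterationRecord(
                    iteration=it,
                    subset_sets=subset_sets,
                    union=tuple(sorted(union)),
                    cumulative=tuple(sorted(new)),
                    discarded=last_discard[f],
                )
            )
            if (
                config.per_fold_stopping
                and last_discard[f] is not None
                and last_discard[f] < config.stop_delta
            ):
                active[f] = False
        if config.per_fold_stopping:
            if not any(active):
                break
        elif it >= 2:
            settled = sum(
                1 for d in last_discard if d is not None and d < config.stop_delta
            )
            if settled >= config.stop_patient_fraction * n:
                break

    fold_sets = {
        patient_ids[f]: FeatureIndexSet(
            cumulative[f] or (),
            provenance=frozenset(
                patient_ids[i] for i in range(n) if i != f
            ),
        )
        for f in range(n)
    }
    return fold_sets, traces


def _approx_batch_or_exact(
    X: np.ndarray, y: np.ndarray, subsets: np.ndarray
) -> np.ndarray:
    """Per-subset filter p-values, batched when the approximation applies."""
    counts1 = (y[subsets] == 1).sum(axis=1)
    counts0 = (y[subsets] == 0).sum(axis=1)
    if counts1.max() <= 12 and counts0.max() <= 12:
        return np.stack([wilcoxon_pvalues(X[rows], y[rows]) for rows in subsets])
    return _approx_pvalues(X[subsets], y[subsets])


def compute_osf(
    per_fold_sets: Mapping[str, FeatureIndexSet] | Sequence[FeatureIndexSet],
) -> FeatureIndexSet:
    """Optimal subset of features: the patient-by-patient intersection.

    Any empty fold set makes the OSF empty; the result's provenance is the
    union of the fold provenances (every patient that influenced selection).
    """
    sets = (
        list(per_fold_sets.values())
        if isinstance(per_fold_sets, Mapping)
        else list(per_fold_sets)
    )
    if not sets:
        raise ValueError("need at least one fold set")
    osf = sets[0]
    for s in sets[1:]:
        osf = osf.intersection(s)
    return osf
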