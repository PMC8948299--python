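"""Partitioning Around Medoids, silhouette validation and sensitivity runs.

This is the classic Kaufman-Rousseeuw PAM: a greedy BUILD phase chooses k
initial medoids (first the point minimising total distance to all others,
then the point giving the largest additional cost reduction, repeatedly),
and a best-improvement SWAP phase repeatedly applies the single
(medoid, non-medoid) exchange with the largest strict cost decrease until
none exists.  Every tie — BUILD candidate, SWAP pair, nearest-medoid
assignment, best k — is broken toward the lowest index / smallest k, so the
whole procedure is deterministic for a given dissimilarity matrix.

The swap search is vectorised over all (medoid, candidate) pairs: with
nearest- and second-nearest-medoid distances cached per point, the cost
change of every exchange is assembled from two n x (n-k) arrays and a
per-cluster group sum, giving O(n^2) work per iteration rather than a
four-deep Python loop.  Complexity is O(k (n-k)^2) per swap step; the
pipeline targets desk-scale n (thousands), not the full-population scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import comb

from .distance import DissimilarityMatrix, dissimilarity
from .errors import ParameterError

_COST_TOL = 1e-12


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray          # k distinct row indices, ascending
    assignment: np.ndarray       # per-point group index 0..k-1
    total_cost: float
    silhouette: Optional[np.ndarray] = None
    avg_silhouette: Optional[float] = None
    n_swaps: int = 0
    ids: Optional[list] = None


@dataclass
class KSelectionTrace:
    """Silhouette-vs-k trace with the winning solution attached."""

    entries: list  # list of (k, avg_silhouette)
    chosen_k: int
    best: ClusteringResult
    results: dict = field(default_factory=dict)  # k -> ClusteringResult

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["k", "avg_silhouette"])


def _dist_values(D: Union[DissimilarityMatrix, np.ndarray]) -> tuple[np.ndarray, list]:
    """Accept a tagged DissimilarityMatrix or any raw symmetric matrix.

    Raw matrices are not forced into [0, 1]; PAM and the silhouette are
    scale-free, and the worked examples use plain absolute differences.
    """
    if isinstance(D, DissimilarityMatrix):
        return D.values, D.ids
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ParameterError("dissimilarity must be a square matrix")
    if np.abs(arr - arr.T).max(initial=0.0) > 1e-9:
        raise ParameterError("dissimilarity must be symmetric")
    return arr, list(range(arr.shape[0]))


def _nearest_two(Dm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest and second-nearest medoid distance per point.

    ``Dm`` is n x k with columns ordered by ascending medoid row index, so
    argmin's first-occurrence rule breaks ties toward the lowest medoid
    index.
    """
    nearest_pos = Dm.argmin(axis=1)
    n = Dm.shape[0]
    near = Dm[np.arange(n), nearest_pos]
    masked = Dm.copy()
    masked[np.arange(n), nearest_pos] = np.inf
    second = masked.min(axis=1)
    return nearest_pos, near, second


def pam(D: Union[DissimilarityMatrix, np.ndarray], k: int) -> ClusteringResult:
    """Cluster via PAM; deterministic BUILD + best-improvement SWAP."""
    dist, ids = _dist_values(D)
    n = dist.shape[0]
    if not (2 <= k < n):
        raise ParameterError(f"k must satisfy 2 <= k < n (k={k}, n={n})")

    # ---- BUILD ----
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    near = dist[:, medoids[0]].copy()
    for _ in range(1, k):
        gain = np.maximum(near[:, None] - dist, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        nxt = int(np.argmax(gain))
        medoids.append(nxt)
        near = np.minimum(near, dist[:, nxt])

    # ---- SWAP ----
    n_swaps = 0
    while True:
        med = np.array(sorted(medoids))
        cand = np.setdiff1d(np.arange(n), med)
        Dm = dist[:, med]
        nearest_pos, near, second = _nearest_two(Dm)
        Dc = dist[:, cand]                                   # n x m
        # if the removed medoid was j's nearest: j moves to min(d(j,h), second_j)
        A = np.minimum(Dc, second[:, None]) - near[:, None]
        # otherwise j can only improve by adopting h
        B = np.minimum(Dc - near[:, None], 0.0)
        onehot = np.zeros((k, n))
        onehot[nearest_pos, np.arange(n)] = 1.0
        A_grp = onehot @ A                                    # k x m
        B_grp = onehot @ B
        delta = (B.sum(axis=0)[None, :] - B_grp) + A_grp      # k x m
        flat = int(np.argmin(delta))                          # first occurrence:
        i, h = divmod(flat, len(cand))                        # lexicographic tie-break
        if delta[i, h] >= -_COST_TOL:
            break
        medoids = [m for m in med if m != med[i]] + [int(cand[h])]
        n_swaps += 1

    med = np.array(sorted(medoids))
    nearest_pos, near, _ = _nearest_two(dist[:, med])
    nearest_pos[med] = np.arange(k)  # a medoid always leads its own cluster
    total_cost = float(near.sum())
    return ClusteringResult(
        k=k,
        medoids=med,
        assignment=nearest_pos.astype(int),
        total_cost=total_cost,
        n_swaps=n_swaps,
        ids=ids,
    )


def silhouette(
    D: Union[DissimilarityMatrix, np.ndarray], assignment: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths and their unweighted mean.

    s(i) = (b - a)/max(a, b) with a = mean within-cluster distance and b =
    smallest mean distance to another cluster.  Singleton clusters (and the
    degenerate a = b = 0 case) score 0, following Rousseeuw.
    """
    dist, _ = _dist_values(D)
    labels = np.asarray(assignment, dtype=int)
    if labels.shape[0] != dist.shape[0]:
        raise ParameterError("assignment length must match matrix size")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ParameterError("silhouette requires at least two clusters")
    n = dist.shape[0]
    onehot = (labels[None, :] == uniq[:, None]).astype(float)   # g x n
    sums = dist @ onehot.T                                       # n x g
    sizes = onehot.sum(axis=1)                                   # g
    own = np.searchsorted(uniq, labels)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_other = sums / sizes[None, :]
        own_size = sizes[own]
        a = np.where(own_size > 1, sums[np.arange(n), own] / np.maximum(own_size - 1, 1), 0.0)
        mean_other[np.arange(n), own] = np.inf
        b = mean_other.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s = np.where(own_size == 1, 0.0, s)
    return s, float(s.mean())


def select_k(
    D: Union[DissimilarityMatrix, np.ndarray],
    k_grid: Iterable[int] = range(2, 16),
    keep_results: bool = False,
) -> KSelectionTrace:
    """Run PAM over a k grid and keep the silhouette-maximising solution.

    Ties in average silhouette go to the smallest k.  The grid is clipped to
    the feasible range [2, n-1]; an empty (clipped) grid is an error.
    """
    dist, _ = _dist_values(D)
    n = dist.shape[0]
    grid = sorted({int(k) for k in k_grid if 2 <= k < n})
    if not grid:
        raise ParameterError("k grid is empty after clipping to [2, n-1]")
    entries = []
    results: dict[int, ClusteringResult] = {}
    best_k, best_res = None, None
    for k in grid:
        res = pam(D, k)
        res.silhouette, res.avg_silhouette = silhouette(D, res.assignment)
        entries.append((k, res.avg_silhouette))
        if keep_results:
            results[k] = res
        if best_res is None or res.avg_silhouette > best_res.avg_silhouette:
            best_k, best_res = k, res
    return KSelectionTrace(entries=entries, chosen_k=best_k, best=best_res, results=results)


def adjusted_rand(a: Sequence, b: Sequence) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ParameterError("partitions must have equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial and identical in structure
    return float((sum_comb - expected) / (max_index - expected))


@dataclass
class SensitivityVariant:
    name: str
    chosen_k: int
    ari_vs_baseline: float
    crosstab: pd.DataFrame
    dropped_conditions: list
    n_rows_dropped: int
    trace: KSelectionTrace


@dataclass
class SensitivityReport:
    variants: dict  # name -> SensitivityVariant

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant": v.name,
                    "chosen_k": v.chosen_k,
                    "ari_vs_baseline": v.ari_vs_baseline,
                    "n_conditions_dropped": len(v.dropped_conditions),
                    "n_rows_dropped": v.n_rows_dropped,
                }
                for v in self.variants.values()
            ]
        )


VARIANTS = ("hamming", "drop_top_condition", "drop_rare_conditions")


def sensitivity_suite(
    M: pd.DataFrame,
    baseline: ClusteringResult,
    k_grid: Iterable[int] = range(2, 16),
    rare_threshold: float = 0.05,
    variants: Sequence[str] = VARIANTS,
) -> SensitivityReport:
    """Re-run the clustering under the three robustness variants.

    1. ``hamming``: replace the Jaccard distance with Hamming.
    2. ``drop_top_condition``: exclude the single most prevalent condition.
    3. ``drop_rare_conditions``: exclude conditions with overall prevalence
       below ``rare_threshold``.

    Patients are retained even if column removal leaves them below the
    multimorbidity threshold; rows left all-zero (Jaccard undefined) are
    necessarily excluded from that variant and counted.  Each variant
    reports its chosen k, the adjusted Rand index against the baseline
    partition (on the rows common to both) and a cross-tabulation.
    """
    if not isinstance(M, pd.DataFrame):
        M = pd.DataFrame(np.asarray(M))
    base_labels = pd.Series(baseline.assignment, index=M.index)
    prevalence = M.mean(axis=0)
    out: dict[str, SensitivityVariant] = {}
    k_grid = list(k_grid)
    for name in variants:
        if name not in VARIANTS:
            raise ParameterError(f"unknown sensitivity variant {name!r}")
        metric = "jaccard"
        sub = M
        dropped_cols: list = []
        if name == "hamming":
            metric = "hamming"
        elif name == "drop_top_condition":
            dropped_cols = [prevalence.idxmax()]
            sub = M.drop(columns=dropped_cols)
        elif name == "drop_rare_conditions":
            dropped_cols = list(prevalence.index[prevalence < rare_threshold])
            sub = M.drop(columns=dropped_cols)
        nonzero = sub.sum(axis=1) > 0
        n_rows_dropped = int((~nonzero).sum()) if metric == "jaccard" else 0
        if metric == "jaccard":
            sub = sub[nonzero]
        trace = select_k(dissimilarity(sub, metric=metric), k_grid)
        labels = pd.Series(trace.best.assignment, index=sub.index)
        common = labels.index
        ari = adjusted_rand(base_labels.loc[common], labels)
        crosstab = pd.crosstab(
            base_labels.loc[common].rename("baseline"), labels.rename(name)
        )
        out[name] = SensitivityVariant(
            name=name,
            chosen_k=trace.chosen_k,
            ari_vs_baseline=float(ari),
            crosstab=crosstab,
            dropped_conditions=dropped_cols,
            n_rows_dropped=n_rows_dropped,
            trace=trace,
        )
    return SensitivityReport(out)
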