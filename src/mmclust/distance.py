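"""Patient-patient dissimilarity and the Hopkins clusterability statistic.

On binary condition flags the Gower dissimilarity with asymmetric binary
treatment reduces to the Jaccard distance: joint absences carry no
information about similarity (two patients are not alike merely for both
lacking psoriasis).  The Hamming distance — the symmetric alternative that
counts joint absences as agreement — is provided for sensitivity analysis.

The Hopkins statistic compares nearest-neighbour distances of real rows
(w_i) with those of synthetic reference rows (u_i) via
``H = sum(w) / (sum(u) + sum(w))``.  Orientation: about 0.5 for
structureless data, toward 0 for strongly clustered data, so a value such
as 0.28 reads as "clusterable".  The complement ``1 - H`` is exposed for
users of the opposite convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import ParameterError

_SYMMETRY_TOL = 1e-12


@dataclass
class DissimilarityMatrix:
    """Symmetric patient x patient distances in [0, 1] with a metric tag."""

    ids: list
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("dissimilarity matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ParameterError("ids length must match matrix size")
        if np.abs(v - v.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ParameterError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > _SYMMETRY_TOL:
            raise ParameterError("dissimilarity matrix must have a zero diagonal")
        if v.min(initial=0.0) < -_SYMMETRY_TOL or v.max(initial=0.0) > 1 + _SYMMETRY_TOL:
            raise ParameterError("dissimilarity values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_binary(M: Union[pd.DataFrame, np.ndarray]) -> tuple[np.ndarray, list]:
    if isinstance(M, pd.DataFrame):
        ids = list(M.index)
        arr = M.to_numpy()
    else:
        arr = np.asarray(M)
        ids = list(range(arr.shape[0]))
    if not np.isin(arr, (0, 1)).all():
        raise ParameterError("condition matrix must be binary 0/1")
    return arr.astype(bool), ids


def jaccard_matrix(M: Union[pd.DataFrame, np.ndarray]) -> DissimilarityMatrix:
    """Jaccard distances ``1 - |x&y| / |x|y|`` between all row pairs.

    Undefined for an all-zero row (empty union with itself); such rows are
    rejected with the offending patient named.  For the multimorbid cohort
    every row has >= 2 positives, so this cannot trigger in the main
    pipeline.
    """
    arr, ids = _as_binary(M)
    zero = np.flatnonzero(~arr.any(axis=1))
    if zero.size:
        raise ParameterError(
            f"Jaccard undefined for all-zero condition vector(s): "
            f"{[ids[i] for i in zero[:5]]}"
        )
    d = squareform(pdist(arr, metric="jaccard"))
    return DissimilarityMatrix(ids, d, "jaccard")


def hamming_matrix(M: Union[pd.DataFrame, np.ndarray]) -> DissimilarityMatrix:
    """Proportion of differing positions between all row pairs."""
    arr, ids = _as_binary(M)
    d = squareform(pdist(arr, metric="hamming"))
    return DissimilarityMatrix(ids, d, "hamming")


def dissimilarity(M, metric: str = "jaccard") -> DissimilarityMatrix:
    if metric == "jaccard":
        return jaccard_matrix(M)
    if metric == "hamming":
        return hamming_matrix(M)
    raise ParameterError(f"unknown metric {metric!r}")


@dataclass
class HopkinsResult:
    statistic: float
    n_probes: int
    n_reps: int
    reference_scheme: str
    seed: Optional[int]
    metric: str = "jaccard"
    per_rep: list = field(default_factory=list)

    @property
    def complement(self) -> float:
        """The opposite orientation convention (clustered -> 1)."""
        return 1.0 - self.statistic


def hopkins_statistic(
    M: Union[pd.DataFrame, np.ndarray],
    probe_fraction: float = 0.1,
    n_reps: int = 25,
    reference_scheme: str = "marginal",
    seed: Optional[int] = None,
    metric: str = "jaccard",
    max_probes: int = 100,
) -> HopkinsResult:
    """Clustering tendency of a binary condition matrix.

    Per repetition, ``m = max(10, round(probe_fraction * n))`` (capped at
    ``max_probes``) real rows are sampled and compared against ``m``
    reference rows drawn per ``reference_scheme``:

    - ``marginal`` (default): per-condition Bernoulli at the observed
      prevalence — the no-association null that keeps marginals realistic;
    - ``uniform``: Bernoulli(0.5) on every condition.

    w_i is each sampled real row's distance to its nearest *other* real row;
    u_i is each reference row's distance to its nearest real row.  All-zero
    reference rows are resampled (the Jaccard distance is undefined there).
    """
    arr, _ = _as_binary(M)
    n, p = arr.shape
    if n < 20:
        raise ParameterError("Hopkins statistic needs n >= 20 rows")
    m = min(max(10, round(probe_fraction * n)), max_probes)
    if m >= n:
        raise ParameterError(f"probe count {m} must be smaller than n={n}")
    if reference_scheme not in ("marginal", "uniform"):
        raise ParameterError(f"unknown reference scheme {reference_scheme!r}")
    rng = np.random.default_rng(seed)
    prev = arr.mean(axis=0) if reference_scheme == "marginal" else np.full(p, 0.5)

    per_rep = []
    for _ in range(n_reps):
        probe = rng.choice(n, size=m, replace=False)
        dw = cdist(arr[probe], arr, metric=metric)
        dw[np.arange(m), probe] = np.inf  # exclude self-distance
        w = dw.min(axis=1)

        ref = rng.random((m, p)) < prev
        for _retry in range(100):
            zero = ~ref.any(axis=1)
            if not zero.any():
                break
            ref[zero] = rng.random((int(zero.sum()), p)) < prev
        else:
            raise ParameterError(
                "could not draw non-empty reference rows; prevalences too small"
            )
        u = cdist(ref, arr, metric=metric).min(axis=1)
        # w == 0 is the perfectly-clustered limit (duplicated rows): H = 0
        # even when degenerate marginals make the reference draws coincide
        per_rep.append(float(w.sum() / (u.sum() + w.sum())) if w.sum() > 0 else 0.0)
    return HopkinsResult(
        statistic=float(np.mean(per_rep)),
        n_probes=m,
        n_reps=n_reps,
        reference_scheme=reference_scheme,
        seed=seed,
        metric=metric,
        per_rep=per_rep,
    )
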