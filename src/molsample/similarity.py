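"""Similarity and distance kernels: Tanimoto and the Value Difference Metric.

Both kernels are exposed as scalar functions plus vectorised "one query
against a pool" helpers that the samplers use.  Neighbour search is fully
deterministic: ties break toward the lower row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from molsample.fingerprints_io import FingerprintDataset

logger = logging.getLogger(__name__)


def _as_binary(v) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("vector entries must be 0 or 1")
    return arr.astype(np.int64)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors are defined as identical (similarity 1.0) to
    avoid the 0/0 indeterminate while preserving "identical implies
    maximal similarity".
    """
    a = _as_binary(a)
    b = _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    if union == 0:
        logger.debug("tanimoto of two all-zero vectors: returning 1.0 by convention")
        return 1.0
    return inter / union


def tanimoto_to_many(query, pool: np.ndarray) -> np.ndarray:
    """Tanimoto similarity of ``query`` against every row of ``pool``."""
    q = _as_binary(query)
    M = np.asarray(pool, dtype=np.int64)
    if M.shape[1] != q.shape[0]:
        raise ValueError(f"width mismatch: query {q.shape[0]}, pool {M.shape[1]}")
    inter = M @ q
    union = int(q.sum()) + M.sum(axis=1) - inter
    sims = np.ones(M.shape[0], dtype=np.float64)
    nz = union > 0
    sims[nz] = inter[nz] / union[nz]
    return sims


def tanimoto_matrix(rows: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Tanimoto similarity matrix of ``rows``."""
    M = np.asarray(rows, dtype=np.int64)
    inter = M @ M.T
    counts = M.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    S = np.ones_like(inter, dtype=np.float64)
    nz = union > 0
    S[nz] = inter[nz] / union[nz]
    return S


@dataclass
class ClassValueStats:
    """Per-bit class-conditional value probabilities P(class | bit = v).

    ``p`` has shape ``(n_bits, 2, 2)`` indexed ``[bit, value, class]``;
    ``counts`` has shape ``(n_bits, 2)`` giving how many rows carried each
    value at each bit.  For a (bit, value) never observed and smoothing 0
    the conditionals are set to the uninformative 0.5 / 0.5.
    """

    p: np.ndarray
    counts: np.ndarray
    smoothing: float

    @property
    def n_bits(self) -> int:
        return self.p.shape[0]

    def delta_table(self, exponent: float) -> np.ndarray:
        """``D[j, va, vb]`` = VDM contribution of bit j taking values va, vb."""
        diff = np.abs(self.p[:, :, None, :] - self.p[:, None, :, :])  # (bits, va, vb, class)
        return (diff ** exponent).sum(axis=-1)


def fit_class_value_stats(
    dataset: FingerprintDataset, smoothing: float = 1.0
) -> ClassValueStats:
    """Estimate P(class | bit = v) with additive (Laplace) smoothing.

    P(c | bit_j = v) = (count(class=c, bit_j=v) + s) / (count(bit_j=v) + 2s)
    """
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    dataset.require_both_classes()
    X = dataset.X.astype(np.int64)
    y = dataset.y
    n_bits = dataset.bit_count
    counts = np.zeros((n_bits, 2), dtype=np.int64)
    joint = np.zeros((n_bits, 2, 2), dtype=np.int64)  # [bit, value, class]
    for c in (0, 1):
        Xc = X[y == c]
        ones = Xc.sum(axis=0)
        joint[:, 1, c] = ones
        joint[:, 0, c] = Xc.shape[0] - ones
    counts = joint.sum(axis=2)
    denom = counts.astype(np.float64) + 2.0 * smoothing
    num = joint.astype(np.float64) + smoothing
    p = np.full((n_bits, 2, 2), 0.5, dtype=np.float64)
    seen = denom > 0
    for c in (0, 1):
        np.divide(num[:, :, c], denom, where=seen, out=p[:, :, c])
    return ClassValueStats(p=p, counts=counts, smoothing=float(smoothing))


def vdm_distance(a, b, stats: ClassValueStats, exponent: float = 2.0) -> float:
    """Value Difference Metric between two binary vectors.

    sum_j sum_c |P(c | bit_j = a_j) - P(c | bit_j = b_j)| ** exponent
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    a = _as_binary(a)
    b = _as_binary(b)
    if a.shape != b.shape or a.shape[0] != stats.n_bits:
        raise ValueError(
            f"width mismatch: a {a.shape[0]}, b {b.shape[0]}, stats {stats.n_bits}"
        )
    D = stats.delta_table(exponent)
    return float(D[np.arange(stats.n_bits), a, b].sum())


def vdm_to_many(query, pool: np.ndarray, stats: ClassValueStats, exponent: float = 2.0) -> np.ndarray:
    """VDM distance of ``query`` against every row of ``pool``."""
    q = _as_binary(query)
    M = _as_binary(pool)
    if M.shape[1] != q.shape[0] or q.shape[0] != stats.n_bits:
        raise ValueError("width mismatch between query, pool and stats")
    D = stats.delta_table(exponent)  # (bits, 2, 2)
    bits = np.arange(stats.n_bits)
    return D[bits, q[None, :], M].sum(axis=1)


def k_nearest(
    query_index: int,
    pool: np.ndarray,
    k: int,
    metric: str = "tanimoto",
    stats: ClassValueStats | None = None,
    exponent: float = 2.0,
) -> list[int]:
    """Indices of the ``k`` nearest rows of ``pool`` to row ``query_index``.

    The query row is excluded from its own neighbour list.  "Nearest"
    means highest Tanimoto similarity or lowest VDM distance; ties break
    toward the lower row index.  Requires ``k < len(pool)``.
    """
    pool = np.asarray(pool)
    n = pool.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the pool size {n}")
    if not 0 <= query_index < n:
        raise IndexError(f"query_index {query_index} out of range for pool of {n}")
    query = pool[query_index]
    if metric == "tanimoto":
        key = -tanimoto_to_many(query, pool)
    elif metric == "vdm":
        if stats is None:
            raise ValueError("metric='vdm' requires ClassValueStats")
        key = vdm_to_many(query, pool, stats, exponent)
    else:
        raise ValueError(f"unknown metric {metric!r} (expected tanimoto or vdm)")
    order = np.lexsort((np.arange(n), key))  # stable: key first, index breaks ties
    return [int(i) for i in order if i != query_index][:k]
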