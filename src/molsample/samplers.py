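"""The nine sampling conditions behind one uniform contract.

Every sampler takes a :class:`FingerprintDataset` plus a seed and returns a
:class:`SamplingResult` whose dataset has exactly equal class counts (the
no-sampling baseline exempted).  Under-samplers keep a subset of the input
rows; over-samplers append duplicated or synthetic rows and never delete.
The minority class is simply the rarer one in the input — nothing is
hard-wired to "active".

The augmented under/over-samplers are guided by the most-common-feature
(MCF) fingerprint: a reference fingerprint whose set bits are the
highest-frequency features exceeding the reference class's average feature
frequency, rebuilt after every removal/duplication batch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np

from molsample.fingerprints_io import FingerprintDataset
from molsample.similarity import (
    ClassValueStats,
    fit_class_value_stats,
    k_nearest,
    tanimoto_matrix,
    tanimoto_to_many,
)

__all__ = [
    "MCFProfile",
    "SamplingResult",
    "build_mcf",
    "sample_none",
    "random_undersample",
    "augmented_random_undersample",
    "random_oversample",
    "augmented_random_oversample",
    "kmedoids_restart_undersample",
    "kmedoids_swap_undersample",
    "smote",
    "apply_sampler",
    "SAMPLER_NAMES",
]


@dataclass
class MCFProfile:
    """A most-common-feature fingerprint for a reference class.

    ``candidate_bits`` lists (bit index, relative frequency) pairs whose
    frequency in the frequency base strictly exceeded ``avg_frequency``,
    sorted by descending frequency (ties toward the lower bit index).
    ``fallback_used`` flags the scarcity fallback: fewer candidates than
    ``n_features``, with the remainder filled by descending frequency
    regardless of the threshold.
    """

    fingerprint: np.ndarray
    n_features: int
    candidate_bits: list[tuple[int, float]]
    avg_frequency: float
    fallback_used: bool = False


@dataclass
class SamplingResult:
    """A resampled dataset plus a machine-checkable audit trail."""

    dataset: FingerprintDataset
    method: str
    seed: int
    params: dict = field(default_factory=dict)
    removed_indices: list[int] = field(default_factory=list)
    duplicated_indices: list[int] = field(default_factory=list)
    synthetic_parents: list[tuple[int, int, int]] = field(default_factory=list)
    iterations: int = 0
    iteration_log: list[dict] = field(default_factory=list)

    def audit_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "params": self.params,
            "removed_indices": [int(i) for i in self.removed_indices],
            "duplicated_indices": [int(i) for i in self.duplicated_indices],
            "synthetic_parents": [[int(a), int(b), int(c)] for a, b, c in self.synthetic_parents],
            "iterations": self.iterations,
            "iteration_log": self.iteration_log,
        }

    def audit_json(self) -> str:
        return json.dumps(self.audit_dict(), sort_keys=True, indent=2)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_mcf(reference_rows: np.ndarray, frequency_rows: np.ndarray) -> MCFProfile:
    """Construct the MCF fingerprint.

    The threshold ``avg_frequency`` is the mean over bits of the reference
    class's per-bit relative frequency of ones; per-bit candidate
    frequencies come from ``frequency_rows`` (normally the complete
    current dataset).  The fingerprint sets the top ``n_features``
    candidate bits, where ``n_features`` is the round-half-up of the
    reference class's mean set-bit count per row.
    """
    ref = np.asarray(reference_rows, dtype=np.float64)
    freq_base = np.asarray(frequency_rows, dtype=np.float64)
    if ref.ndim != 2 or ref.shape[0] == 0 or ref.shape[1] == 0:
        raise ValueError("reference_rows must be a nonempty 2-D binary matrix")
    if freq_base.ndim != 2 or freq_base.shape[0] == 0:
        raise ValueError("frequency_rows must be a nonempty 2-D binary matrix")
    if ref.shape[1] != freq_base.shape[1]:
        raise ValueError("reference and frequency matrices must share bit width")

    ref_bit_freq = ref.mean(axis=0)
    avg_frequency = float(ref_bit_freq.mean())
    n_features = _round_half_up(float(ref.sum(axis=1).mean()))
    if n_features == 0:
        raise ValueError("reference class has no set bits: nothing to profile")

    bit_freq = freq_base.mean(axis=0)
    n_bits = ref.shape[1]
    order = np.lexsort((np.arange(n_bits), -bit_freq))  # descending freq, ties low index
    candidates = [(int(j), float(bit_freq[j])) for j in order if bit_freq[j] > avg_frequency]

    fallback = len(candidates) < n_features
    chosen = [j for j, _ in candidates[:n_features]]
    if fallback:
        extra = [int(j) for j in order if bit_freq[j] <= avg_frequency]
        chosen += extra[: n_features - len(chosen)]
    fingerprint = np.zeros(n_bits, dtype=np.uint8)
    fingerprint[chosen] = 1
    return MCFProfile(
        fingerprint=fingerprint,
        n_features=n_features,
        candidate_bits=candidates,
        avg_frequency=avg_frequency,
        fallback_used=fallback,
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _class_indices(dataset: FingerprintDataset) -> tuple[np.ndarray, np.ndarray]:
    """(minority indices, majority indices), in original row order."""
    dataset.require_both_classes()
    minority = dataset.minority_label()
    min_idx = np.flatnonzero(dataset.y == minority)
    maj_idx = np.flatnonzero(dataset.y != minority)
    return min_idx, maj_idx


def _keep_rows(dataset: FingerprintDataset, kept: np.ndarray) -> FingerprintDataset:
    return dataset.subset(np.sort(kept))


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def sample_none(dataset: FingerprintDataset, seed: int = 0) -> SamplingResult:
    """The untouched 'original dataset' baseline."""
    return SamplingResult(dataset=dataset.copy(), method="none", seed=int(seed))


def random_undersample(dataset: FingerprintDataset, seed: int = 0) -> SamplingResult:
    """Remove uniformly random majority rows until the classes are equal."""
    min_idx, maj_idx = _class_indices(dataset)
    rng = np.random.default_rng(seed)
    keep_majority = rng.choice(maj_idx, size=len(min_idx), replace=False)
    removed = sorted(set(maj_idx.tolist()) - set(int(i) for i in keep_majority))
    kept = np.concatenate([min_idx, keep_majority])
    return SamplingResult(
        dataset=_keep_rows(dataset, kept),
        method="randus",
        seed=int(seed),
        removed_indices=removed,
    )


def augmented_random_undersample(
    dataset: FingerprintDataset,
    seed: int = 0,
    batch_fraction: float = 0.1,
    removal_fraction: float = 0.5,
) -> SamplingResult:
    """MCF-guided under-sampling.

    Each iteration: build the MCF from the current majority rows
    (reference) and the complete current dataset (frequency base); list
    the majority rows most similar to the MCF; remove a random part of
    the list, capped so the majority never drops below the minority
    count; recompute and repeat until exactly balanced.
    """
    if not 0 < batch_fraction <= 1 or not 0 < removal_fraction <= 1:
        raise ValueError("batch_fraction and removal_fraction must be in (0, 1]")
    min_idx, maj_idx = _class_indices(dataset)
    rng = np.random.default_rng(seed)
    surviving = list(int(i) for i in maj_idx)  # original indices, input order
    target = len(min_idx)
    removed: list[int] = []
    log: list[dict] = []
    iterations = 0
    while len(surviving) > target:
        iterations += 1
        excess = len(surviving) - target
        maj_rows = dataset.X[surviving]
        freq_rows = np.vstack([dataset.X[min_idx], maj_rows])
        profile = build_mcf(maj_rows, freq_rows)
        sims = tanimoto_to_many(profile.fingerprint, maj_rows)
        order = np.lexsort((np.arange(len(surviving)), -sims))
        batch_size = max(1, math.ceil(batch_fraction * excess))
        batch_pos = order[:batch_size]
        n_remove = min(excess, max(1, math.ceil(removal_fraction * batch_size)))
        chosen_pos = rng.choice(batch_pos, size=n_remove, replace=False)
        chosen = sorted(surviving[p] for p in chosen_pos)
        log.append(
            {
                "mcf_bits": np.flatnonzero(profile.fingerprint).tolist(),
                "avg_frequency": profile.avg_frequency,
                "batch_indices": sorted(surviving[p] for p in batch_pos),
                "threshold_similarity": float(sims[batch_pos].min()),
                "removed": chosen,
            }
        )
        removed.extend(chosen)
        surviving = [i for i in surviving if i not in set(chosen)]
    kept = np.concatenate([min_idx, np.asarray(surviving, dtype=np.intp)])
    return SamplingResult(
        dataset=_keep_rows(dataset, kept),
        method="augrandus",
        seed=int(seed),
        params={"batch_fraction": batch_fraction, "removal_fraction": removal_fraction},
        removed_indices=sorted(removed),
        iterations=iterations,
        iteration_log=log,
    )


def _dup_id(base: str, counter: int) -> str:
    return f"{base}~dup{counter}"


def random_oversample(dataset: FingerprintDataset, seed: int = 0) -> SamplingResult:
    """Append uniformly chosen (with replacement) minority duplicates."""
    min_idx, maj_idx = _class_indices(dataset)
    deficit = len(maj_idx) - len(min_idx)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(min_idx, size=deficit, replace=True)
    new_ids = [_dup_id(dataset.ids[i], n) for n, i in enumerate(chosen)]
    minority = dataset.minority_label()
    out = dataset.with_appended(new_ids, dataset.X[chosen], [minority] * deficit)
    return SamplingResult(
        dataset=out,
        method="randos",
        seed=int(seed),
        duplicated_indices=[int(i) for i in chosen],
    )


def augmented_random_oversample(
    dataset: FingerprintDataset,
    seed: int = 0,
    batch_fraction: float = 0.1,
    duplication_fraction: float = 0.5,
) -> SamplingResult:
    """MCF-guided over-sampling: the mirror of the augmented under-sampler.

    The MCF is built with the minority class as reference; the candidate
    list holds the minority rows LEAST similar to it, and a random part
    of the list is duplicated each iteration until exact balance.
    """
    if not 0 < batch_fraction <= 1 or not 0 < duplication_fraction <= 1:
        raise ValueError("batch_fraction and duplication_fraction must be in (0, 1]")
    min_idx, maj_idx = _class_indices(dataset)
    rng = np.random.default_rng(seed)
    minority = dataset.minority_label()
    # current minority pool: (ancestor original index, row) — duplicates join it
    pool: list[tuple[int, np.ndarray]] = [(int(i), dataset.X[i]) for i in min_idx]
    duplicated: list[int] = []
    log: list[dict] = []
    iterations = 0
    target = len(maj_idx)
    while len(pool) < target:
        iterations += 1
        deficit = target - len(pool)
        min_rows = np.vstack([row for _, row in pool])
        freq_rows = np.vstack([min_rows, dataset.X[maj_idx]])
        profile = build_mcf(min_rows, freq_rows)
        sims = tanimoto_to_many(profile.fingerprint, min_rows)
        order = np.lexsort((np.arange(len(pool)), sims))  # ascending: most dissimilar first
        batch_size = max(1, math.ceil(batch_fraction * deficit))
        batch_pos = order[:batch_size]
        n_dup = min(deficit, max(1, math.ceil(duplication_fraction * batch_size)))
        chosen_pos = rng.choice(batch_pos, size=n_dup, replace=False)
        chosen_ancestors = sorted(pool[p][0] for p in chosen_pos)
        log.append(
            {
                "mcf_bits": np.flatnonzero(profile.fingerprint).tolist(),
                "avg_frequency": profile.avg_frequency,
                "batch_ancestors": sorted(pool[p][0] for p in batch_pos),
                "threshold_similarity": float(sims[batch_pos].max()),
                "duplicated": chosen_ancestors,
            }
        )
        for p in chosen_pos:
            pool.append((pool[p][0], pool[p][1]))
            duplicated.append(pool[p][0])
    n_new = len(pool) - len(min_idx)
    new_rows = np.vstack([row for _, row in pool[len(min_idx):]]) if n_new else np.empty((0, dataset.bit_count), dtype=np.uint8)
    new_ids = [
        _dup_id(dataset.ids[anc], n) for n, (anc, _) in enumerate(pool[len(min_idx):])
    ]
    out = dataset.with_appended(new_ids, new_rows, [minority] * n_new) if n_new else dataset.copy()
    return SamplingResult(
        dataset=out,
        method="augrandos",
        seed=int(seed),
        params={"batch_fraction": batch_fraction, "duplication_fraction": duplication_fraction},
        duplicated_indices=duplicated,
        iterations=iterations,
        iteration_log=log,
    )


def _assignment_cost(S: np.ndarray, medoid_pos: np.ndarray) -> float:
    """Sum over rows of the Tanimoto similarity to the most-similar medoid."""
    return float(S[:, medoid_pos].max(axis=1).sum())


def kmedoids_restart_undersample(
    dataset: FingerprintDataset,
    seed: int = 0,
    restarts: int = 100,
    exhaustive: bool = False,
) -> SamplingResult:
    """k-medoids under-sampling by repeated random restarts ("kMedoids1").

    Draws ``restarts`` independent medoid sets of size = minority count
    from the majority class, scores each by the total Tanimoto similarity
    of every majority row to its most-similar medoid, and keeps the
    highest-scoring set as the under-sampled majority class.  With
    ``exhaustive=True`` all medoid combinations are enumerated instead
    (tiny instances only).
    """
    if restarts < 1:
        raise ValueError("restarts must be positive")
    min_idx, maj_idx = _class_indices(dataset)
    n_medoids = len(min_idx)  # majority count would make under-sampling vacuous
    S = tanimoto_matrix(dataset.X[maj_idx])
    m = len(maj_idx)
    rng = np.random.default_rng(seed)

    best_cost = -np.inf
    best_pos: np.ndarray | None = None
    costs: list[float] = []
    if exhaustive:
        draws = (np.asarray(c, dtype=np.intp) for c in combinations(range(m), n_medoids))
    else:
        draws = (rng.choice(m, size=n_medoids, replace=False) for _ in range(restarts))
    n_draws = 0
    for pos in draws:
        n_draws += 1
        cost = _assignment_cost(S, pos)
        costs.append(cost)
        if cost > best_cost:
            best_cost = cost
            best_pos = np.sort(pos)
    assert best_pos is not None
    kept_majority = maj_idx[best_pos]
    removed = sorted(set(int(i) for i in maj_idx) - set(int(i) for i in kept_majority))
    kept = np.concatenate([min_idx, kept_majority])
    return SamplingResult(
        dataset=_keep_rows(dataset, kept),
        method="kmedoids1",
        seed=int(seed),
        params={"restarts": restarts, "exhaustive": exhaustive, "n_medoids": n_medoids},
        removed_indices=removed,
        iterations=n_draws,
        iteration_log=[{"costs": costs, "best_cost": best_cost}],
    )


def kmedoids_swap_undersample(
    dataset: FingerprintDataset,
    seed: int = 0,
    swaps_per_medoid: int = 30,
) -> SamplingResult:
    """k-medoids under-sampling by per-medoid random swaps ("kMedoids2").

    Starts from a random medoid set of size = minority count; each medoid
    in turn is tentatively exchanged with ``swaps_per_medoid`` random
    non-medoid majority rows, recosting the full assignment each time.
    The best configuration ever observed is retained.
    """
    if swaps_per_medoid < 1:
        raise ValueError("swaps_per_medoid must be positive")
    min_idx, maj_idx = _class_indices(dataset)
    n_medoids = len(min_idx)
    m = len(maj_idx)
    S = tanimoto_matrix(dataset.X[maj_idx])
    rng = np.random.default_rng(seed)

    current = rng.choice(m, size=n_medoids, replace=False)
    best_pos = np.sort(current.copy())
    best_cost = _assignment_cost(S, current)
    initial_cost = best_cost
    evaluated: list[float] = [best_cost]
    for mi in range(n_medoids):
        for _ in range(swaps_per_medoid):
            if m == n_medoids:
                break
            non_medoids = np.setdiff1d(np.arange(m), current)
            swap_in = int(rng.choice(non_medoids))
            candidate = current.copy()
            candidate[mi] = swap_in
            cost = _assignment_cost(S, candidate)
            evaluated.append(cost)
            if cost > best_cost:
                best_cost = cost
                best_pos = np.sort(candidate.copy())
                current = candidate
    kept_majority = maj_idx[best_pos]
    removed = sorted(set(int(i) for i in maj_idx) - set(int(i) for i in kept_majority))
    kept = np.concatenate([min_idx, kept_majority])
    return SamplingResult(
        dataset=_keep_rows(dataset, kept),
        method="kmedoids2",
        seed=int(seed),
        params={"swaps_per_medoid": swaps_per_medoid, "n_medoids": n_medoids},
        removed_indices=removed,
        iterations=n_medoids * swaps_per_medoid,
        iteration_log=[
            {
                "initial_cost": initial_cost,
                "best_cost": best_cost,
                "evaluated_costs": evaluated,
            }
        ],
    )


def smote(
    dataset: FingerprintDataset,
    seed: int = 0,
    k: int = 5,
    metric: str = "tanimoto",
    vdm_exponent: float = 2.0,
    vdm_smoothing: float = 1.0,
) -> SamplingResult:
    """Binary SMOTE: synthesise minority rows by 2-of-3 majority voting.

    Each synthetic row takes, per bit, the value shared by at least two
    of {a minority seed row, two of its k nearest same-class neighbours}.
    Neighbourhoods use Tanimoto similarity or the VDM (with
    class-conditional stats fit on the dataset handed in).  Seed rows
    cycle through a seeded shuffle of the minority class, reshuffled per
    pass, so each row is reused a near-equal number of times.
    """
    if k < 1:
        raise ValueError("k must be positive")
    min_idx, maj_idx = _class_indices(dataset)
    if len(min_idx) < k + 1:
        raise ValueError(
            f"minority class has {len(min_idx)} rows but k={k} neighbours are "
            f"required per row; lower k to at most {len(min_idx) - 1}"
        )
    if metric not in ("tanimoto", "vdm"):
        raise ValueError(f"unknown metric {metric!r} (expected tanimoto or vdm)")
    stats: ClassValueStats | None = None
    if metric == "vdm":
        stats = fit_class_value_stats(dataset, smoothing=vdm_smoothing)

    min_rows = dataset.X[min_idx]
    neighbours = [
        k_nearest(i, min_rows, k, metric=metric, stats=stats, exponent=vdm_exponent)
        for i in range(len(min_idx))
    ]

    rng = np.random.default_rng(seed)
    deficit = len(maj_idx) - len(min_idx)
    minority = dataset.minority_label()
    schedule: list[int] = []
    synthetic_rows: list[np.ndarray] = []
    parents: list[tuple[int, int, int]] = []
    for n in range(deficit):
        if not schedule:
            schedule = list(rng.permutation(len(min_idx)))
        pos = schedule.pop(0)
        nbrs = neighbours[pos]
        pick = rng.choice(len(nbrs), size=2, replace=False)
        n1, n2 = nbrs[pick[0]], nbrs[pick[1]]
        votes = min_rows[pos].astype(np.int64) + min_rows[n1] + min_rows[n2]
        synthetic_rows.append((votes >= 2).astype(np.uint8))
        parents.append((int(min_idx[pos]), int(min_idx[n1]), int(min_idx[n2])))
    method = "smotetc" if metric == "tanimoto" else "smotevdm"
    if deficit:
        new_ids = [f"synthetic~{method}~{n}" for n in range(deficit)]
        out = dataset.with_appended(new_ids, np.vstack(synthetic_rows), [minority] * deficit)
    else:
        out = dataset.copy()
    return SamplingResult(
        dataset=out,
        method=method,
        seed=int(seed),
        params={"k": k, "metric": metric, "vdm_exponent": vdm_exponent},
        synthetic_parents=parents,
        iterations=deficit,
    )


# ---------------------------------------------------------------------------
# uniform dispatch
# ---------------------------------------------------------------------------

_SAMPLERS: dict[str, Callable[..., SamplingResult]] = {
    "none": sample_none,
    "randus": random_undersample,
    "augrandus": augmented_random_undersample,
    "randos": random_oversample,
    "augrandos": augmented_random_oversample,
    "kmedoids1": kmedoids_restart_undersample,
    "kmedoids2": kmedoids_swap_undersample,
    "smotetc": lambda dataset, seed=0, **kw: smote(dataset, seed, metric="tanimoto", **kw),
    "smotevdm": lambda dataset, seed=0, **kw: smote(dataset, seed, metric="vdm", **kw),
}

SAMPLER_NAMES: tuple[str, ...] = tuple(_SAMPLERS)


def apply_sampler(
    name: str, dataset: FingerprintDataset, seed: int = 0, **params
) -> SamplingResult:
    """Run the sampler called ``name`` (see :data:`SAMPLER_NAMES`)."""
    if name not in _SAMPLERS:
        raise ValueError(
            f"unknown sampling method {name!r}; valid methods: {', '.join(SAMPLER_NAMES)}"
        )
    return _SAMPLERS[name](dataset, seed=seed, **params)
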