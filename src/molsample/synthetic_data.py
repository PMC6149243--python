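"""Seeded generator of imbalanced binary fingerprint datasets.

A Bernoulli-mixture model: each class owns a handful of cluster
prototypes (random bit patterns); every row is its prototype with
independent per-bit flips.  A configurable fraction of minority
prototypes is drawn as a perturbation of a majority prototype, which
plants borderline minority samples near the decision boundary and makes
the minority class structurally heterogeneous while the majority stays
comparatively homogeneous — the regime in which plain classifiers go
specificity-heavy.  No chemistry is simulated: fingerprint space is the
algorithms' true domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from molsample._seeds import derive_seed
from molsample.fingerprints_io import FingerprintDataset


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic imbalanced fingerprint generator.

    Defaults give a 0.1 minority/majority ratio with half the minority
    prototypes overlapping the majority — the imbalanced, overlapping
    regime used throughout the test-suite.
    """

    n_bits: int = 166
    n_majority: int = 200
    n_minority: int = 20
    n_minority_clusters: int = 3
    n_majority_clusters: int = 1
    prototype_density: float = 0.3
    flip_noise: float = 0.15
    overlap: float = 0.5
    overlap_perturbation: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_bits <= 0 or self.n_majority <= 0 or self.n_minority <= 0:
            raise ValueError("n_bits and class counts must be positive")
        if self.n_minority_clusters <= 0 or self.n_majority_clusters <= 0:
            raise ValueError("cluster counts must be positive")
        if self.n_minority_clusters > self.n_minority:
            raise ValueError("more minority clusters than minority rows")
        if self.n_majority_clusters > self.n_majority:
            raise ValueError("more majority clusters than majority rows")
        for name in ("prototype_density", "flip_noise", "overlap", "overlap_perturbation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def imbalance_ratio(self) -> float:
        return self.n_minority / self.n_majority


def _rows_from_prototypes(
    rng: np.random.Generator,
    prototypes: np.ndarray,
    n_rows: int,
    flip_noise: float,
) -> tuple[np.ndarray, np.ndarray]:
    n_clusters = prototypes.shape[0]
    assignment = rng.integers(0, n_clusters, size=n_rows)
    rows = prototypes[assignment].copy()
    flips = rng.random(rows.shape) < flip_noise
    rows ^= flips.astype(np.uint8)
    return rows, assignment


def generate(spec: GeneratorSpec) -> tuple[FingerprintDataset, np.ndarray]:
    """Generate a dataset plus the latent row -> cluster map.

    Minority rows get label 1, majority rows label 0.  Cluster ids are
    strings like ``"maj0"`` / ``"min2"`` and are returned separately —
    they are never written into the dataset file, so downstream code
    cannot accidentally consume them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    maj_protos = (
        rng.random((spec.n_majority_clusters, spec.n_bits)) < spec.prototype_density
    ).astype(np.uint8)
    min_protos = np.empty((spec.n_minority_clusters, spec.n_bits), dtype=np.uint8)
    # deterministic overlapped-prototype count so every dataset realises the
    # requested borderline fraction, not a Bernoulli draw of it
    n_overlapped = int(round(spec.overlap * spec.n_minority_clusters))
    for c in range(spec.n_minority_clusters):
        if c < n_overlapped:
            base = maj_protos[rng.integers(0, spec.n_majority_clusters)].copy()
            flips = rng.random(spec.n_bits) < spec.overlap_perturbation
            min_protos[c] = base ^ flips.astype(np.uint8)
        else:
            min_protos[c] = (rng.random(spec.n_bits) < spec.prototype_density).astype(np.uint8)

    maj_rows, maj_assign = _rows_from_prototypes(rng, maj_protos, spec.n_majority, spec.flip_noise)
    min_rows, min_assign = _rows_from_prototypes(rng, min_protos, spec.n_minority, spec.flip_noise)

    X = np.vstack([maj_rows, min_rows])
    y = np.concatenate(
        [np.zeros(spec.n_majority, dtype=np.int64), np.ones(spec.n_minority, dtype=np.int64)]
    )
    ids = [f"cmpd-{i:05d}" for i in range(X.shape[0])]
    clusters = np.array(
        [f"maj{c}" for c in maj_assign] + [f"min{c}" for c in min_assign]
    )
    dataset = FingerprintDataset(ids=ids, X=X, y=y, descriptor_name="synthetic")
    return dataset, clusters


def generate_paperlike_pair(
    spec: GeneratorSpec, test_fraction: float = 0.2
) -> tuple[FingerprintDataset, FingerprintDataset]:
    """A (train, test) pair from one generated dataset, stratified so the
    test block preserves the class ratio within rounding."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    dataset, _ = generate(spec)
    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=dataset.y,
        random_state=derive_seed(spec.seed, "paperlike-split") % (2**32),
    )
    train = dataset.subset(np.sort(train_idx))
    test = dataset.subset(np.sort(test_idx))
    train.require_both_classes()
    test.require_both_classes()
    return train, test
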