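"""Compound-table ingestion, fingerprint computation and the dataset format.

The dense dataset format is plain text::

    #molsample-dataset v1
    #descriptor=maccs
    #bits=166
    <id>\t<label>\t<0/1 bit string>
    ...

``write_dataset`` followed by ``read_dataset`` is the identity on
:class:`FingerprintDataset`.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_FORMAT_MAGIC = "#molsample-dataset v1"


@dataclass(frozen=True)
class CompoundRecord:
    """A single labelled compound: identifier, SMILES and binary activity."""

    id: str
    smiles: str
    label: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be nonempty")
        if self.label not in (0, 1):
            raise ValueError(
                f"label for compound {self.id!r} must be 0 or 1, got {self.label!r}"
            )


@dataclass
class FingerprintDataset:
    """Binary fingerprint matrix with per-row labels and identifiers.

    ``X`` is an ``(n_samples, n_bits)`` array with entries in {0, 1};
    ``y`` holds binary activity labels (1 = active); ``ids`` are unique
    row identifiers.  This is the currency passed between every module.
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    descriptor_name: str = "synthetic"

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.uint8))
        self.y = np.asarray(self.y, dtype=np.int64).ravel()
        self.ids = [str(i) for i in self.ids]
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if len(self.ids) != n or self.y.shape[0] != n:
            raise ValueError(
                f"length mismatch: {n} rows, {len(self.ids)} ids, {self.y.shape[0]} labels"
            )
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("fingerprint entries must all be 0 or 1")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must all be 0 or 1")
        if len(set(self.ids)) != n:
            raise ValueError("compound ids must be unique within a dataset")
        if self.descriptor_name == "maccs" and self.X.shape[1] != 166:
            raise ValueError(
                f"maccs datasets must have 166 bits, got {self.X.shape[1]}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def bit_count(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {0: int(np.sum(self.y == 0)), 1: int(np.sum(self.y == 1))}

    def minority_label(self) -> int:
        """The rarer class label; ties resolve to 1 (the active class)."""
        counts = self.class_counts()
        return 1 if counts[1] <= counts[0] else 0

    def majority_label(self) -> int:
        return 1 - self.minority_label()

    def require_both_classes(self) -> None:
        counts = self.class_counts()
        if counts[0] == 0 or counts[1] == 0:
            raise ValueError("dataset must contain both classes")

    def subset(self, indices: Sequence[int]) -> "FingerprintDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return FingerprintDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            descriptor_name=self.descriptor_name,
        )

    def with_appended(
        self, ids: Sequence[str], X: np.ndarray, y: Sequence[int]
    ) -> "FingerprintDataset":
        X_new = np.asarray(X, dtype=np.uint8)
        if X_new.ndim == 1:
            X_new = X_new.reshape(1, -1)
        return FingerprintDataset(
            ids=list(self.ids) + [str(i) for i in ids],
            X=np.vstack([self.X, X_new]),
            y=np.concatenate([self.y, np.asarray(y, dtype=np.int64)]),
            descriptor_name=self.descriptor_name,
        )

    def copy(self) -> "FingerprintDataset":
        return FingerprintDataset(
            ids=list(self.ids),
            X=self.X.copy(),
            y=self.y.copy(),
            descriptor_name=self.descriptor_name,
        )


# ---------------------------------------------------------------------------
# Compound table reading
# ---------------------------------------------------------------------------


def _parseable_smiles(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        return bool(smiles) and Chem.MolFromSmiles(smiles) is not None
    finally:
        RDLogger.EnableLog("rdApp.error")


def _coerce_label(raw, where: str) -> int:
    txt = str(raw).strip().lower()
    if txt in {"1", "1.0", "true", "active", "pos", "positive", "yes"}:
        return 1
    if txt in {"0", "0.0", "false", "inactive", "neg", "negative", "no"}:
        return 0
    raise ValueError(f"label {raw!r} at {where} is not coercible to binary")


def _read_delimited(
    path: Path, id_field: str, smiles_field: str, label_field: str
) -> tuple[list[CompoundRecord], int]:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters=",\t;")
        except csv.Error:
            dialect = csv.excel
        reader = csv.DictReader(fh, dialect=dialect)
        if reader.fieldnames is None:
            raise ValueError(f"no parseable records in {path}")
        for col in (id_field, smiles_field, label_field):
            if col not in reader.fieldnames:
                raise ValueError(
                    f"column {col!r} missing from {path} (found {reader.fieldnames})"
                )
        records: list[CompoundRecord] = []
        skipped = 0
        for lineno, row in enumerate(reader, start=2):
            smiles = (row[smiles_field] or "").strip()
            if not _parseable_smiles(smiles):
                skipped += 1
                logger.warning(
                    "skipping row %d of %s: unparseable SMILES %r", lineno, path, smiles
                )
                continue
            label = _coerce_label(row[label_field], f"{path}:{lineno}")
            records.append(CompoundRecord(row[id_field].strip(), smiles, label))
    return records, skipped


def _read_smi(
    path: Path, label_table: Path, id_field: str, label_field: str
) -> tuple[list[CompoundRecord], int]:
    labels: dict[str, int] = {}
    with open(label_table, newline="") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters=",\t;")
        except csv.Error:
            dialect = csv.excel
        for row in csv.DictReader(fh, dialect=dialect):
            labels[row[id_field].strip()] = _coerce_label(
                row[label_field], f"{label_table}:{row[id_field]}"
            )
    records: list[CompoundRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                skipped += 1
                logger.warning("skipping line %d of %s: expected 'SMILES id'", lineno, path)
                continue
            smiles, cid = parts
            if not _parseable_smiles(smiles):
                skipped += 1
                logger.warning(
                    "skipping line %d of %s: unparseable SMILES %r", lineno, path, smiles
                )
                continue
            if cid not in labels:
                raise ValueError(f"no label for compound {cid!r} in {label_table}")
            records.append(CompoundRecord(cid, smiles, labels[cid]))
    return records, skipped


def _read_sdf(path: Path, label_field: str) -> tuple[list[CompoundRecord], int]:
    from rdkit import Chem

    records: list[CompoundRecord] = []
    skipped = 0
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("skipping molecule %d of %s: unparseable", i, path)
            continue
        if not mol.HasProp(label_field):
            raise ValueError(f"molecule {i} of {path} lacks property {label_field!r}")
        cid = mol.GetProp("_Name") or f"mol{i}"
        label = _coerce_label(mol.GetProp(label_field), f"{path}:mol{i}")
        records.append(CompoundRecord(cid, Chem.MolToSmiles(mol), label))
    return records, skipped


def read_compound_table(
    path: str | Path,
    format: str | None = None,
    label_field: str = "label",
    id_field: str = "id",
    smiles_field: str = "smiles",
    label_table: str | Path | None = None,
) -> tuple[list[CompoundRecord], int]:
    """Read labelled compounds from a delimited table, ``.smi`` file or SDF.

    Rows with unparseable SMILES are skipped with a logged warning.

    Returns
    -------
    (records, skipped)
        The parseable :class:`CompoundRecord` list and the skip count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound table not found: {path}")
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"smi": "smi", "sdf": "sdf"}.get(suffix, "csv")
    if format == "csv":
        records, skipped = _read_delimited(path, id_field, smiles_field, label_field)
    elif format == "smi":
        if label_table is None:
            raise ValueError(".smi input requires a sidecar label_table")
        records, skipped = _read_smi(path, Path(label_table), id_field, label_field)
    elif format == "sdf":
        records, skipped = _read_sdf(path, label_field)
    else:
        raise ValueError(f"unknown format {format!r} (expected csv, smi or sdf)")
    if not records:
        raise ValueError(f"no parseable records in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate compound id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records, skipped


# ---------------------------------------------------------------------------
# Fingerprint computation
# ---------------------------------------------------------------------------


def compute_fingerprints(
    records: Iterable[CompoundRecord],
    descriptor: str = "maccs",
    morgan_radius: int = 2,
    morgan_bits: int = 2048,
) -> FingerprintDataset:
    """Compute binary fingerprints for ``records``.

    ``maccs`` yields the canonical 166 structural keys (RDKit's unused
    leading position is dropped); ``morgan`` yields hashed circular
    fingerprints of the given radius folded to ``morgan_bits`` (a power
    of two).  Unparseable SMILES are hard errors here, naming the
    offending compound id.
    """
    from rdkit import Chem

    records = list(records)
    if not records:
        raise ValueError("no compound records supplied")
    if descriptor not in ("maccs", "morgan"):
        raise ValueError(f"unknown descriptor {descriptor!r} (expected maccs or morgan)")
    if descriptor == "morgan":
        if morgan_radius < 1:
            raise ValueError("morgan_radius must be >= 1")
        if morgan_bits <= 0 or morgan_bits & (morgan_bits - 1):
            raise ValueError("morgan_bits must be a positive power of two")

    if descriptor == "maccs":
        from rdkit.Chem import MACCSkeys

        n_bits = 166
    else:
        from rdkit.Chem import rdFingerprintGenerator

        generator = rdFingerprintGenerator.GetMorganGenerator(
            radius=morgan_radius, fpSize=morgan_bits
        )
        n_bits = morgan_bits

    X = np.zeros((len(records), n_bits), dtype=np.uint8)
    ids = []
    y = np.zeros(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {rec.id!r}: {rec.smiles!r}")
        if descriptor == "maccs":
            bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, index 0 unused
            X[i] = np.frombuffer(
                bytes(bv.ToBitString(), "ascii"), dtype=np.uint8
            )[1:] - ord("0")
        else:
            bv = generator.GetFingerprint(mol)
            X[i] = np.frombuffer(
                bytes(bv.ToBitString(), "ascii"), dtype=np.uint8
            ) - ord("0")
        ids.append(rec.id)
        y[i] = rec.label
    return FingerprintDataset(ids=ids, X=X, y=y, descriptor_name=descriptor)


# ---------------------------------------------------------------------------
# Dataset file format
# ---------------------------------------------------------------------------


def write_dataset(dataset: FingerprintDataset, path: str | Path) -> None:
    """Write ``dataset`` in the package's dense text format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_FORMAT_MAGIC}\n")
        fh.write(f"#descriptor={dataset.descriptor_name}\n")
        fh.write(f"#bits={dataset.bit_count}\n")
        for cid, label, row in zip(dataset.ids, dataset.y, dataset.X):
            bits = "".join("1" if b else "0" for b in row)
            fh.write(f"{cid}\t{int(label)}\t{bits}\n")


def read_dataset(path: str | Path) -> FingerprintDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _FORMAT_MAGIC:
            raise ValueError(f"{path}: malformed header (expected {_FORMAT_MAGIC!r})")
        descriptor = None
        bits = None
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line.rstrip("\n").lstrip("#").partition("=")
            if key == "descriptor":
                descriptor = value
            elif key == "bits":
                bits = int(value)
            pos = fh.tell()
            line = fh.readline()
        if descriptor is None or bits is None:
            raise ValueError(f"{path}: header missing descriptor or bits")
        fh.seek(pos)
        ids: list[str] = []
        labels: list[int] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed data row {lineno}")
            cid, label_txt, bitstr = parts
            if len(bitstr) != bits:
                raise ValueError(
                    f"{path}: row {lineno} ({cid!r}) has {len(bitstr)} bits, header says {bits}"
                )
            if set(bitstr) - {"0", "1"}:
                raise ValueError(f"{path}: row {lineno} ({cid!r}) has non-binary characters")
            ids.append(cid)
            labels.append(int(label_txt))
            rows.append(np.frombuffer(bitstr.encode("ascii"), dtype=np.uint8) - ord("0"))
    if not ids:
        raise ValueError(f"{path}: no data rows")
    return FingerprintDataset(
        ids=ids,
        X=np.vstack(rows),
        y=np.asarray(labels),
        descriptor_name=descriptor,
    )
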