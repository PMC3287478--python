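"""Readers, writers and validated containers for the tabular inputs.

All tables are UTF-8 TSV/CSV with a header row and the drug identifier in
the first column. The delimiter is auto-detected from the file extension
(``.tsv`` -> tab, ``.csv`` -> comma) unless given explicitly.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ATC_FULL = re.compile(r"^[A-Z][0-9]{2}[A-Z][A-Z][0-9]{2}$")
# valid prefixes of the 7-character grammar: 1, 3, 4 or 5 characters
_ATC_PREFIXES = (
    re.compile(r"^[A-Z]$"),
    re.compile(r"^[A-Z][0-9]{2}$"),
    re.compile(r"^[A-Z][0-9]{2}[A-Z]$"),
    re.compile(r"^[A-Z][0-9]{2}[A-Z][A-Z]$"),
)


def is_valid_atc(code: str) -> bool:
    """True when ``code`` is a full 7-character ATC code or a valid prefix."""
    if _ATC_FULL.match(code):
        return True
    return any(p.match(code) for p in _ATC_PREFIXES)


def detect_delimiter(path: str | Path, delimiter: str | None = None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


@dataclass(frozen=True)
class DrugRecord:
    """A drug identifier with an optional SMILES structure string."""

    drug_id: str
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


@dataclass
class DescriptorMatrix:
    """Drugs x numeric molecular descriptors, with a mask of missing cells.

    Cells that were empty or non-numeric in the source file are flagged in
    ``missing_mask`` (and hold NaN in ``values``); they are never silently
    zeroed. The cleaning stage decides their fate.
    """

    drug_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, d = self.values.shape
        if n != len(self.drug_ids) or d != len(self.descriptor_names):
            raise ValueError("matrix shape does not match id/name lists")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        for axis_name, ids in (("drug_id", self.drug_ids),
                               ("descriptor", self.descriptor_names)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {axis_name}(s): {dupes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids,
                            columns=self.descriptor_names)

    def select_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(
            drug_ids=list(self.drug_ids),
            descriptor_names=list(names),
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )


@dataclass
class FingerprintSet:
    """Binary substructure fingerprints for a set of drugs.

    ``kind`` is a free label (e.g. ``pubchem-like``, ``maccs``): the package
    treats any binary matrix uniformly and never enforces bit semantics.
    """

    drug_ids: list[str]
    n_bits: int
    bits: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.shape != (len(self.drug_ids), self.n_bits):
            raise ValueError("bits shape does not match drug_ids/n_bits")
        if not np.isin(self.bits, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.bits, (0, 1)))[0]
            raise ValueError(
                f"fingerprint cell outside {{0,1}} at drug "
                f"{self.drug_ids[bad[0]]!r}, bit {bad[1]}")
        self.bits = self.bits.astype(np.uint8)
        if pd.Index(self.drug_ids).has_duplicates:
            raise ValueError("duplicate drug_id in fingerprint set")

    def row(self, drug_id: str) -> np.ndarray:
        return self.bits[self.drug_ids.index(drug_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.drug_ids,
                            columns=[f"bit{i}" for i in range(self.n_bits)])


class InteractionMap:
    """Bipartite drug-target interaction map with forward and reverse indices."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._by_drug: dict[str, frozenset[str]] = {}
        for drug, targets in mapping.items():
            tset = frozenset(targets)
            if not tset:
                raise ValueError(f"drug {drug!r} has an empty target set")
            self._by_drug[drug] = tset
        by_target: dict[str, set[str]] = {}
        for drug, targets in self._by_drug.items():
            for t in targets:
                by_target.setdefault(t, set()).add(drug)
        self._by_target = {t: frozenset(d) for t, d in by_target.items()}

    def targets_of(self, drug_id: str) -> frozenset[str]:
        return self._by_drug.get(drug_id, frozenset())

    def drugs_of(self, target_id: str) -> frozenset[str]:
        return self._by_target.get(target_id, frozenset())

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._by_drug

    def __len__(self) -> int:
        return len(self._by_drug)

    @property
    def drugs(self) -> list[str]:
        return sorted(self._by_drug)

    @property
    def targets(self) -> list[str]:
        return sorted(self._by_target)

    @property
    def n_interactions(self) -> int:
        return sum(len(t) for t in self._by_drug.values())

    def items(self):
        return self._by_drug.items()

    def restrict_drugs(self, drug_ids: Iterable[str]) -> "InteractionMap":
        keep = set(drug_ids)
        return InteractionMap({d: t for d, t in self._by_drug.items() if d in keep})

    def without_drug(self, drug_id: str) -> "InteractionMap":
        return InteractionMap(
            {d: t for d, t in self._by_drug.items() if d != drug_id})


@dataclass
class AnnotationMap:
    """Entity -> annotation-set mapping; kind is ``domain`` or ``atc``.

    ATC codes are validated against the 7-character WHO grammar (one letter,
    two digits, two letters, two digits) or any valid prefix of it.
    """

    kind: str
    mapping: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("domain", "atc"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.kind == "atc":
            for entity, codes in self.mapping.items():
                for code in codes:
                    if not is_valid_atc(code):
                        raise ValueError(
                            f"invalid ATC code {code!r} for entity {entity!r}")

    def get(self, entity_id: str) -> set[str]:
        return self.mapping.get(entity_id, set())

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# readers


def read_descriptor_table(path: str | Path,
                          delimiter: str | None = None) -> DescriptorMatrix:
    """Parse a drugs x descriptors table.

    Non-numeric or empty cells are flagged in the missing mask. A duplicate
    drug_id is a hard error; a fully non-numeric column only warns (the
    cleaning stage will drop it).
    """
    sep = detect_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    dupes = raw.index[raw.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate drug_id(s) in {path}: {dupes}")
    def _parse(cell: str) -> float:
        try:
            return float(cell)  # correctly-rounded, round-trip exact
        except ValueError:
            return float("nan")

    numeric = raw.map(_parse)
    missing = numeric.isna().to_numpy()
    for j, name in enumerate(numeric.columns):
        if missing[:, j].all():
            warnings.warn(
                f"descriptor column {name!r} is fully non-numeric; "
                "it will be dropped by the cleaning stage", stacklevel=2)
    return DescriptorMatrix(
        drug_ids=raw.index.tolist(),
        descriptor_names=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        missing_mask=missing,
    )


def write_descriptor_table(matrix: DescriptorMatrix, path: str | Path,
                           delimiter: str | None = None) -> None:
    sep = detect_delimiter(path, delimiter)
    frame = matrix.to_frame().copy()
    frame[matrix.missing_mask] = np.nan
    frame.to_csv(path, sep=sep, index_label="drug_id", na_rep="")


def read_interactions(path: str | Path) -> InteractionMap:
    """Read a two-column (drug_id, target_id) TSV, optional header.

    Duplicate rows collapse; a row with a missing field raises with its
    line number.
    """
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.lower() for f in fields[:2]] == ["drug_id",
                                                                  "target_id"]:
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected two fields "
                    f"(drug_id, target_id), got {line!r}")
            mapping.setdefault(fields[0].strip(), set()).add(fields[1].strip())
            n_rows += 1
    if not mapping:
        warnings.warn(f"{path}: no interactions found", stacklevel=2)
        return InteractionMap({})
    imap = InteractionMap(mapping)
    logger.info("read %d interactions (%d drugs, %d targets) from %s "
                "(%d rows, %d duplicates collapsed)",
                imap.n_interactions, len(imap), len(imap.targets), path,
                n_rows, n_rows - imap.n_interactions)
    return imap


def write_interactions(imap: InteractionMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("drug_id\ttarget_id\n")
        for drug in imap.drugs:
            for target in sorted(imap.targets_of(drug)):
                handle.write(f"{drug}\t{target}\n")


def read_fingerprints(path: str | Path, kind: str = "generic",
                      delimiter: str | None = None) -> FingerprintSet:
    """Read a drugs x bits 0/1 table; any cell outside {0,1} is an error."""
    sep = detect_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    values = raw.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValueError(
            f"{path}: fingerprint cell outside {{0,1}} at drug "
            f"{raw.index[bad[0]]!r}, column {raw.columns[bad[1]]!r} "
            f"(value {values[tuple(bad)]!r})")
    return FingerprintSet(drug_ids=raw.index.tolist(),
                          n_bits=values.shape[1],
                          bits=values.astype(np.uint8), kind=kind)


def write_fingerprints(fps: FingerprintSet, path: str | Path,
                       delimiter: str | None = None) -> None:
    sep = detect_delimiter(path, delimiter)
    fps.to_frame().to_csv(path, sep=sep, index_label="drug_id")


def read_annotations(path: str | Path, kind: str) -> AnnotationMap:
    """Read a two-column (entity_id, annotation) TSV into an AnnotationMap."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("entity_id", "drug_id",
                                                     "target_id"):
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected two fields")
            mapping.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return AnnotationMap(kind=kind, mapping=mapping)


def write_annotations(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("entity_id\tannotation\n")
        for entity in sorted(amap.mapping):
            for code in sorted(amap.mapping[entity]):
                handle.write(f"{entity}\t{code}\n")


def read_smiles_table(path: str | Path) -> list[DrugRecord]:
    records = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "drug_id":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two fields")
            records.append(DrugRecord(drug_id=fields[0], smiles=fields[1]))
    return records


# ---------------------------------------------------------------------------
# optional fingerprint computation (RDKit)

_FP_KINDS = ("maccs", "morgan", "rdkit")


def compute_fingerprints(records: Sequence[DrugRecord],
                         kind: str = "maccs") -> FingerprintSet:
    """Compute binary fingerprints from SMILES via RDKit (optional extra).

    Unparsable SMILES are skipped with their ids logged; an absent toolkit
    raises with a pointer to the file-based input path.
    """
    if kind not in _FP_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}; "
                         f"choose from {_FP_KINDS}")
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - env always has rdkit
        raise ImportError(
            "RDKit is required to compute fingerprints from SMILES; install "
            "the 'chem' extra or supply a precomputed fingerprint table "
            "via read_fingerprints()") from exc
    RDLogger.DisableLog("rdApp.error")

    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    elif kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
    else:
        gen = None

    ids, rows, skipped = [], [], []
    for rec in records:
        if not rec.smiles:
            skipped.append(rec.drug_id)
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            skipped.append(rec.drug_id)
            continue
        fp = MACCSkeys.GenMACCSKeys(mol) if gen is None else gen.GetFingerprint(mol)
        arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        ids.append(rec.drug_id)
        rows.append(arr)
    if skipped:
        logger.warning("skipped %d record(s) with missing/unparsable SMILES: %s",
                       len(skipped), ", ".join(skipped))
    if not rows:
        raise ValueError("no valid SMILES among the given records")
    bits = np.vstack(rows)
    return FingerprintSet(drug_ids=ids, n_bits=bits.shape[1], bits=bits,
                          kind=kind)
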