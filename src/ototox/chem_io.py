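"""Reading, validating, canonicalizing and deduplicating labeled compounds.

Structures enter as SMILES strings (``.smi`` line files, CSV with a SMILES
column, or SDF) and are canonicalized with RDKit so that isomorphic
spellings of the same molecular graph collapse to one canonical string.
Metal-containing and multi-fragment structures (salts, coordination
complexes such as cisplatin) are kept intact — no fragment stripping —
because stripping would destroy or empty several clinically important
ototoxins; such records are flagged in their provenance notes instead.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping, Optional

from rdkit import Chem
from rdkit import RDLogger

if TYPE_CHECKING:  # pragma: no cover
    from .fingerprints import Fingerprint

# RDKit's parse warnings go to stderr by default; errors are surfaced as
# structured exceptions instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "Label",
    "Compound",
    "CompoundSet",
    "ParseError",
    "ReadReport",
    "DEFAULT_LABEL_POLICY",
    "parse_compound",
    "read_compound_file",
    "write_compound_file",
    "deduplicate",
]

# elements treated as organic-subset for the metal flag
_ORGANIC = {"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "Se", "Si"}


class Label(enum.Enum):
    """Ototoxicity class label of a compound."""

    OTOTOXIN = "ototoxin"
    NON_OTOTOXIN = "non-ototoxin"
    UNKNOWN = "unknown"


class ParseError(ValueError):
    """A SMILES string could not be parsed; carries id and offending input."""

    def __init__(self, compound_id: str, smiles: str, reason: str = "invalid SMILES"):
        self.compound_id = compound_id
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"{reason} for {compound_id!r}: {smiles!r}")


@dataclass(frozen=True)
class Compound:
    """One chemical record.

    ``smiles_canonical`` is RDKit's canonical SMILES of the full input
    structure and serves as the identity key everywhere downstream.
    ``fingerprint`` is an optional precomputed bit vector used by synthetic
    populations that bypass SMILES parsing.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str
    label: Label = Label.UNKNOWN
    source: str = "user"
    notes: tuple[str, ...] = ()
    fingerprint: Optional["Fingerprint"] = None

    def with_label(self, label: Label) -> "Compound":
        return replace(self, label=label)


@dataclass
class CompoundSet:
    """Ordered collection of compounds; deduplication makes canonical SMILES
    unique within the set."""

    compounds: list[Compound] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __getitem__(self, i):
        return self.compounds[i]

    def canonical_smiles(self) -> list[str]:
        return [c.smiles_canonical for c in self.compounds]

    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]


@dataclass
class ReadReport:
    """What a file read (or deduplication) skipped or removed, and why."""

    skipped: list[tuple[str, str]] = field(default_factory=list)  # (record, reason)
    removed_duplicates: list[tuple[str, str]] = field(default_factory=list)
    label_conflicts: list[str] = field(default_factory=list)  # canonical SMILES

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def parse_compound(
    smiles: str,
    id: str,
    label: Label = Label.UNKNOWN,
    source: str = "user",
) -> Compound:
    """Parse and canonicalize one SMILES record.

    Raises :class:`ParseError` on unparseable input.  Multi-fragment and
    metal-containing structures are retained intact and flagged in
    ``notes``.
    """
    if not smiles or not smiles.strip():
        raise ParseError(id, smiles, "empty SMILES")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(id, smiles)
    canonical = Chem.MolToSmiles(mol)
    notes = []
    if "." in canonical:
        notes.append("multi-fragment")
    if any(a.GetSymbol() not in _ORGANIC for a in mol.GetAtoms()):
        notes.append("contains-metal-or-unusual-element")
    return Compound(
        id=id,
        smiles_raw=smiles,
        smiles_canonical=canonical,
        label=label,
        source=source,
        notes=tuple(notes),
    )


DEFAULT_LABEL_POLICY: Mapping[str, Label] = {
    "ototoxin": Label.OTOTOXIN,
    "oto": Label.OTOTOXIN,
    "toxic": Label.OTOTOXIN,
    "positive": Label.OTOTOXIN,
    "1": Label.OTOTOXIN,
    "non-ototoxin": Label.NON_OTOTOXIN,
    "non_ototoxin": Label.NON_OTOTOXIN,
    "nontoxic": Label.NON_OTOTOXIN,
    "negative": Label.NON_OTOTOXIN,
    "0": Label.NON_OTOTOXIN,
    "unknown": Label.UNKNOWN,
    "": Label.UNKNOWN,
}


def _map_label(raw: str | None, policy: Mapping[str, Label]) -> Label:
    if raw is None:
        return Label.UNKNOWN
    key = raw.strip().lower()
    if key in policy:
        return policy[key]
    raise ValueError(f"unmapped label value {raw!r}")


def read_compound_file(
    path,
    format: str | None = None,
    label: Label = Label.UNKNOWN,
    label_policy: Mapping[str, Label] = DEFAULT_LABEL_POLICY,
    smiles_column: str = "smiles",
    id_column: str = "id",
    label_column: str = "label",
    sdf_label_tag: str = "label",
    source: str | None = None,
) -> tuple[CompoundSet, ReadReport]:
    """Read a labeled compound collection from ``.smi``, CSV or SDF.

    ``format`` defaults from the file extension.  Unparseable records are
    skipped and listed in the report, never dropped silently; ordering
    follows file order.  ``label`` is the default for records without a
    per-record label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound file not found: {path}")
    if format is None:
        ext = path.suffix.lower().lstrip(".")
        format = {"smi": "smi", "csv": "csv", "sdf": "sdf", "mol": "sdf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from extension of {path}")
    format = format.lower()
    if source is None:
        source = f"file:{path.name}"

    compounds: list[Compound] = []
    report = ReadReport()

    def try_add(smiles: str, cid: str, lab: Label, record_desc: str) -> None:
        try:
            compounds.append(parse_compound(smiles, cid, lab, source=source))
        except ParseError as e:
            report.skipped.append((record_desc, str(e)))

    if format == "smi":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smi = parts[0]
                cid = parts[1].strip() if len(parts) > 1 else f"{path.stem}-{lineno}"
                try_add(smi, cid, label, f"line {lineno}")
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise ValueError(
                    f"{path}: CSV is missing the SMILES column {smiles_column!r}"
                )
            for rowno, row in enumerate(reader, 2):
                smi = (row.get(smiles_column) or "").strip()
                cid = (row.get(id_column) or "").strip() or f"{path.stem}-{rowno}"
                try:
                    lab = (
                        _map_label(row.get(label_column), label_policy)
                        if label_column in (reader.fieldnames or [])
                        else label
                    )
                except ValueError as e:
                    report.skipped.append((f"row {rowno}", str(e)))
                    continue
                if lab is Label.UNKNOWN and label is not Label.UNKNOWN:
                    lab = label
                try_add(smi, cid, lab, f"row {rowno}")
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            desc = f"record {i + 1}"
            if mol is None:
                report.skipped.append((desc, "unreadable or missing structure block"))
                continue
            cid = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
                else f"{path.stem}-{i + 1}"
            )
            try:
                lab = (
                    _map_label(mol.GetProp(sdf_label_tag), label_policy)
                    if mol.HasProp(sdf_label_tag)
                    else label
                )
            except ValueError as e:
                report.skipped.append((desc, str(e)))
                continue
            try_add(Chem.MolToSmiles(mol), cid, lab, desc)
    else:
        raise ValueError(f"unknown compound file format {format!r}")

    return CompoundSet(compounds=compounds, name=path.stem), report


def write_compound_file(
    compounds: Iterable[Compound], path, format: str | None = None
) -> None:
    """Write compounds as ``.smi`` or CSV (canonical SMILES, id, label)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lower().lstrip(".") or "smi"
    format = format.lower()
    if format == "smi":
        with open(path, "w", encoding="utf-8") as fh:
            for c in compounds:
                fh.write(f"{c.smiles_canonical}\t{c.id}\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["smiles", "id", "label"])
            for c in compounds:
                writer.writerow([c.smiles_canonical, c.id, c.label.value])
    else:
        raise ValueError(f"unsupported output format {format!r}")


def deduplicate(cset: CompoundSet) -> tuple[CompoundSet, ReadReport]:
    """Remove structural duplicates, keeping the first occurrence.

    If the same structure appears labeled both OTOTOXIN and NON_OTOTOXIN,
    the conflict is reported and the structure is excluded entirely —
    mislabeled training compounds are a documented failure mode of earlier
    ototoxicity models, and exclusion is the conservative response.
    """
    first: dict[str, Compound] = {}
    labels_seen: dict[str, set[Label]] = {}
    report = ReadReport()
    for c in cset:
        key = c.smiles_canonical
        labels_seen.setdefault(key, set()).add(c.label)
        if key in first:
            report.removed_duplicates.append((c.id, key))
        else:
            first[key] = c
    conflicted = {
        key
        for key, labs in labels_seen.items()
        if Label.OTOTOXIN in labs and Label.NON_OTOTOXIN in labs
    }
    report.label_conflicts = sorted(conflicted)
    kept = [c for key, c in first.items() if key not in conflicted]
    # dict preserves insertion order, so first-occurrence order is stable
    return CompoundSet(compounds=kept, name=cset.name), report
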