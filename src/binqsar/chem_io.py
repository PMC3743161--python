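"""Compound table I/O and activity labelling.

Compound activity is handled on the pIC50 scale (``pIC50 = -log10(IC50 [M])``,
so 7.0 corresponds to 100 nM).  Records whose source reported a
"larger-than" IC50 carry the bound as their pIC50 together with
``censored=True``; such compounds are inactive at every threshold at or
below the bound, and labelling at a threshold *below* the bound is refused
rather than guessed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from rdkit import Chem

Label = Literal["active", "inactive", "unlabeled"]

#: pIC50 of an IC50 given in nanomolar: pIC50 = 9 - log10(IC50[nM]).
NM_LOG_OFFSET = 9.0


@dataclass(frozen=True)
class ActivityConfig:
    """Activity threshold on the pIC50 scale (default 7.0 == 100 nM)."""

    threshold: float = 7.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("activity threshold must be finite")


@dataclass
class CompoundRecord:
    """One compound: structure, identifier and (possibly censored) activity."""

    id: str
    mol: Chem.Mol
    pic50: float | None = None
    censored: bool = False
    label: Label = "unlabeled"

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass
class ReadReport:
    """Parse failures collected while reading a compound table."""

    failures: list[tuple[int, str]] = field(default_factory=list)

    def add(self, index: int, reason: str) -> None:
        self.failures.append((index, reason))


def pic50_from_nm(ic50_nm: float) -> float:
    """pIC50 of an IC50 expressed in nanomolar."""
    if ic50_nm <= 0:
        raise ValueError("IC50 must be positive")
    return NM_LOG_OFFSET - math.log10(ic50_nm)


def _parse_activity_field(raw: str) -> tuple[float | None, bool]:
    """Parse a pIC50 or IC50 cell into ``(pic50, censored)``.

    Accepts a plain pIC50 number, or an IC50-in-nM value written with a
    unit suffix (``"250 nM"``); a leading ``>`` marks a censored
    ("larger-than") measurement whose bound is stored.
    """
    text = raw.strip()
    if not text:
        return None, False
    censored = text.startswith(">")
    if censored:
        text = text[1:].strip()
    lowered = text.lower()
    if lowered.endswith("nm"):
        value = float(lowered[:-2].strip())
        return pic50_from_nm(value), censored
    return float(text), censored


def read_compound_table(
    path: str | Path,
    fmt: Literal["sdf", "smiles_csv"],
    *,
    pic50_tag: str = "pIC50",
) -> tuple[list[CompoundRecord], ReadReport]:
    """Read compounds from an SDF file or a SMILES CSV.

    The CSV dialect is UTF-8 with a header row and columns
    ``id,smiles,pic50[,censored]``; the ``pic50`` column accepts plain
    pIC50 values or ``"<value> nM"`` / ``"><value> nM"`` IC50 entries.
    Unparsable entries are reported, never silently dropped; input order
    is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "sdf":
        records, report = _read_sdf(path, pic50_tag)
    elif fmt == "smiles_csv":
        records, report = _read_smiles_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise ValueError(f"no parsable records in {path}")
    _check_duplicate_ids(records)
    return records, report


def _read_sdf(path: Path, pic50_tag: str) -> tuple[list[CompoundRecord], ReadReport]:
    report = ReadReport()
    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            report.add(i, "unparsable SDF record")
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
        pic50: float | None = None
        censored = False
        if mol.HasProp(pic50_tag):
            try:
                pic50, censored = _parse_activity_field(mol.GetProp(pic50_tag))
            except ValueError:
                report.add(i, f"bad {pic50_tag} value {mol.GetProp(pic50_tag)!r}")
        records.append(CompoundRecord(id=cid, mol=mol, pic50=pic50, censored=censored))
    return records, report


def _read_smiles_csv(path: Path) -> tuple[list[CompoundRecord], ReadReport]:
    report = ReadReport()
    records: list[CompoundRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: CSV must have a header row with a 'smiles' column")
        for i, row in enumerate(reader):
            smiles = (row.get("smiles") or "").strip()
            mol = Chem.MolFromSmiles(smiles) if smiles else None
            if mol is None:
                report.add(i, f"unparsable SMILES {smiles!r}")
                continue
            cid = (row.get("id") or "").strip() or f"mol_{i}"
            pic50: float | None = None
            censored = False
            raw = row.get("pic50") or ""
            try:
                pic50, censored = _parse_activity_field(raw)
            except ValueError:
                report.add(i, f"bad pic50 value {raw!r}")
                continue
            if (row.get("censored") or "").strip().lower() in {"1", "true", "yes"}:
                censored = True
            records.append(CompoundRecord(id=cid, mol=mol, pic50=pic50, censored=censored))
    return records, report


def _check_duplicate_ids(records: Sequence[CompoundRecord]) -> None:
    seen: dict[str, int] = {}
    dups: list[str] = []
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate compound ids: {', '.join(dups)}")


def assign_activity_labels(
    records: Iterable[CompoundRecord],
    cfg: ActivityConfig | None = None,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Label each record active/inactive at ``cfg.threshold``.

    A compound is active iff its pIC50 is >= the threshold and the
    measurement is not censored.  Censored ("larger-than" IC50) compounds
    are inactive at any threshold at or above the bound's pIC50; a
    threshold below the bound is an error because the true activity there
    is unknown.

    Returns the relabelled records (copies) and the per-class counts.
    """
    cfg = cfg or ActivityConfig()
    out: list[CompoundRecord] = []
    counts = {"active": 0, "inactive": 0}
    for rec in records:
        if rec.pic50 is None:
            raise ValueError(f"record {rec.id!r} has neither pIC50 nor a censored bound")
        if rec.censored:
            if cfg.threshold < rec.pic50:
                raise ValueError(
                    f"record {rec.id!r}: censored bound pIC50 {rec.pic50} exceeds "
                    f"threshold {cfg.threshold}; activity there is unknown"
                )
            label: Label = "inactive"
        else:
            label = "active" if rec.pic50 >= cfg.threshold else "inactive"
        counts[label] += 1
        out.append(replace(rec, label=label))
    return out, counts


def labels_to_binary(records: Sequence[CompoundRecord]) -> list[int]:
    """0/1 vector (active=1) for labelled records; errors on unlabeled."""
    y = []
    for r in records:
        if r.label == "unlabeled":
            raise ValueError(f"record {r.id!r} is unlabeled")
        y.append(1 if r.label == "active" else 0)
    return y


MODEL_SCHEMA_VERSION = 1


def write_model(model, path: str | Path) -> None:
    """Serialise a fitted binary QSAR model to JSON (schema-versioned)."""
    payload = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_model(path: str | Path):
    """Load a model written by :func:`write_model`; round-trips bit-exactly."""
    from .bqsar import BQSARModel

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty model file")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or corrupt model file") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: model schema version {version!r} not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return BQSARModel.from_dict(payload["model"])
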