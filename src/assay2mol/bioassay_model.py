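"""Domain types for screening-assay records, with JSON/CSV IO and SMILES utilities.

A corpus is a set of assay records.  Each record couples free-text fields
(title, description, protocol) with an optional protein-target annotation and
an ordered outcome table of tested molecules.  The on-disk schema is fixed so
that fixtures round-trip losslessly:

required keys
    ``aid`` (positive int), ``title``, ``description``, ``protocol`` (str),
    ``outcomes`` (list of outcome rows)
optional keys
    ``target`` (object with ``uniprot_id``/``name``/``sequence``),
    ``is_counterscreen_annotation`` (bool, ground-truth flag in fixtures)

Unknown top-level keys are preserved in a ``metadata`` bag and written back on
serialization.  Outcome labels are normalized case-insensitively through a
documented synonym map onto the three-label vocabulary
{Active, Unspecified, Inactive}.
"""

from __future__ import annotations

import enum
import json
import logging
from functools import lru_cache
from pathlib import Path
from typing import Any, Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator
from rdkit import Chem, RDLogger

from .exceptions import InvalidSmilesError, ParseError, SchemaError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # RDKit is chatty about every rejected SMILES

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class Outcome(str, enum.Enum):
    ACTIVE = "Active"
    UNSPECIFIED = "Unspecified"
    INACTIVE = "Inactive"


#: Case-insensitive synonym map for activity labels as they appear in public
#: exports.  Everything that is neither clearly active nor clearly inactive
#: maps to Unspecified.
OUTCOME_SYNONYMS: dict[str, Outcome] = {
    "active": Outcome.ACTIVE,
    "inactive": Outcome.INACTIVE,
    "unspecified": Outcome.UNSPECIFIED,
    "inconclusive": Outcome.UNSPECIFIED,
    "probe": Outcome.UNSPECIFIED,
    "undefined": Outcome.UNSPECIFIED,
}


def normalize_outcome(label: str) -> Outcome:
    """Map a raw activity label onto the three-label vocabulary."""
    try:
        return OUTCOME_SYNONYMS[str(label).strip().lower()]
    except KeyError:
        raise SchemaError(f"unrecognized outcome label: {label!r}") from None


class Relation(str, enum.Enum):
    LT = "<"
    EQ = "="
    GT = ">"


class Measurement(BaseModel):
    """One measured pharmacodynamic parameter, e.g. ``IC50 = 3.2 µM``."""

    std_type: str
    relation: Relation
    value: float = Field(ge=0)
    units: str


class MoleculeOutcome(BaseModel):
    """One row of an assay outcome table: a molecule and its activity call."""

    smiles: str
    outcome: Outcome
    measurement: Optional[Measurement] = None

    @field_validator("smiles")
    @classmethod
    def _smiles_parses(cls, v: str) -> str:
        if _canonical_or_none(v) is None:
            raise ValueError(f"invalid SMILES: {v!r}")
        return v


class TargetInfo(BaseModel):
    uniprot_id: Optional[str] = None
    name: str = ""
    sequence: Optional[str] = None

    @field_validator("sequence")
    @classmethod
    def _standard_residues(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and (bad := set(v.upper()) - _AMINO_ACIDS):
            raise ValueError(f"non-standard amino-acid letters: {sorted(bad)}")
        return v


class BioAssayRecord(BaseModel):
    aid: int = Field(gt=0)
    title: str = ""
    description: str = ""
    protocol: str = ""
    target: Optional[TargetInfo] = None
    outcomes: list[MoleculeOutcome] = Field(default_factory=list)
    is_counterscreen_annotation: Optional[bool] = None
    metadata: dict[str, Any] = Field(default_factory=dict)

    def n_actives(self) -> int:
        return sum(1 for o in self.outcomes if o.outcome is Outcome.ACTIVE)


class DesiredActivity(str, enum.Enum):
    INHIBITION = "inhibition"
    ACTIVATION = "activation"
    UNSPECIFIED = "unspecified"


class ProteinQuery(BaseModel):
    """Free-text description of the protein or phenotype to design for."""

    description: str = Field(min_length=1)
    uniprot_id: Optional[str] = None
    pdb_id: Optional[str] = None
    sequence: Optional[str] = None
    desired_activity: DesiredActivity = DesiredActivity.UNSPECIFIED

    @field_validator("sequence")
    @classmethod
    def _standard_residues(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and (bad := set(v.upper()) - _AMINO_ACIDS):
            raise ValueError(f"non-standard amino-acid letters: {sorted(bad)}")
        return v


# ---------------------------------------------------------------------------
# JSON IO

_KNOWN_KEYS = {
    "aid",
    "title",
    "description",
    "protocol",
    "target",
    "outcomes",
    "is_counterscreen_annotation",
    "metadata",
}


def record_from_dict(doc: dict[str, Any]) -> BioAssayRecord:
    """Build a record from a decoded JSON object, normalizing outcome labels."""
    if "aid" not in doc:
        raise SchemaError("missing required key 'aid'")
    rows = []
    for i, row in enumerate(doc.get("outcomes", [])):
        try:
            outcome = normalize_outcome(row["outcome"])
        except SchemaError as e:
            raise SchemaError(f"outcomes row {i}: {e}") from None
        try:
            rows.append(
                MoleculeOutcome(
                    smiles=row["smiles"],
                    outcome=outcome,
                    measurement=row.get("measurement"),
                )
            )
        except (KeyError, ValueError) as e:
            raise SchemaError(f"outcomes row {i}: {e}") from None
    extra = {k: v for k, v in doc.items() if k not in _KNOWN_KEYS}
    metadata = dict(doc.get("metadata", {}))
    metadata.update(extra)
    return BioAssayRecord(
        aid=doc["aid"],
        title=doc.get("title", ""),
        description=doc.get("description", ""),
        protocol=doc.get("protocol", ""),
        target=doc.get("target"),
        outcomes=rows,
        is_counterscreen_annotation=doc.get("is_counterscreen_annotation"),
        metadata=metadata,
    )


def parse_bioassay_json(text: str) -> BioAssayRecord:
    """Parse one assay record from a JSON document string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"malformed JSON at byte offset {e.pos}: {e.msg}") from None
    if not isinstance(doc, dict):
        raise SchemaError("top-level JSON value must be an object")
    return record_from_dict(doc)


def record_to_dict(record: BioAssayRecord) -> dict[str, Any]:
    """Serialize a record to a plain dict matching the on-disk schema."""
    doc: dict[str, Any] = {
        "aid": record.aid,
        "title": record.title,
        "description": record.description,
        "protocol": record.protocol,
        "outcomes": [
            row.model_dump(mode="json", exclude_none=True) for row in record.outcomes
        ],
    }
    if record.target is not None:
        doc["target"] = record.target.model_dump(mode="json", exclude_none=True)
    if record.is_counterscreen_annotation is not None:
        doc["is_counterscreen_annotation"] = record.is_counterscreen_annotation
    doc.update(record.metadata)
    return doc


def write_bioassay_json(record: BioAssayRecord) -> str:
    return json.dumps(record_to_dict(record), ensure_ascii=False)


def read_corpus_jsonl(path: str | Path) -> list[BioAssayRecord]:
    """Read a corpus from a JSON-lines file (one record per line)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(parse_bioassay_json(line))
    aids = [r.aid for r in records]
    if len(set(aids)) != len(aids):
        raise SchemaError("duplicate aid values in corpus")
    return records


def write_corpus_jsonl(records: Iterable[BioAssayRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for record in records:
            fh.write(write_bioassay_json(record) + "\n")


# ---------------------------------------------------------------------------
# CSV outcome tables

_CSV_COLUMNS = ["smiles", "outcome", "std_type", "relation", "value", "units"]


def outcomes_to_dataframe(outcomes: Iterable[MoleculeOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        m = o.measurement
        rows.append(
            {
                "smiles": o.smiles,
                "outcome": o.outcome.value,
                "std_type": m.std_type if m else "",
                "relation": m.relation.value if m else "",
                "value": m.value if m else None,
                "units": m.units if m else "",
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def outcomes_from_dataframe(df: pd.DataFrame) -> tuple[list[MoleculeOutcome], int]:
    """Convert a table to outcome rows.

    Rows whose SMILES does not parse are dropped with a warning; the dropped
    count is returned alongside the surviving rows.
    """
    outcomes: list[MoleculeOutcome] = []
    dropped = 0
    for _, row in df.iterrows():
        smiles = str(row["smiles"])
        if _canonical_or_none(smiles) is None:
            dropped += 1
            continue
        measurement = None
        std_type = row.get("std_type")
        if isinstance(std_type, str) and std_type:
            measurement = Measurement(
                std_type=std_type,
                relation=Relation(row["relation"]),
                value=float(row["value"]),
                units=str(row["units"]),
            )
        outcomes.append(
            MoleculeOutcome(
                smiles=smiles,
                outcome=normalize_outcome(row["outcome"]),
                measurement=measurement,
            )
        )
    if dropped:
        logger.warning("dropped %d rows with invalid SMILES", dropped)
    return outcomes, dropped


def read_outcome_csv(path: str | Path) -> tuple[list[MoleculeOutcome], int]:
    return outcomes_from_dataframe(pd.read_csv(path, keep_default_na=False))


def write_outcome_csv(outcomes: Iterable[MoleculeOutcome], path: str | Path) -> None:
    outcomes_to_dataframe(outcomes).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SMILES utilities

@lru_cache(maxsize=262144)
def _canonical_or_none(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical spelling of a molecule.

    Two strings denoting the same molecule map to the same output, which makes
    this the deduplication key used throughout the pipeline.
    """
    canonical = _canonical_or_none(smiles)
    if canonical is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    return canonical


def is_valid_smiles(smiles: str) -> bool:
    return _canonical_or_none(smiles) is not None


@lru_cache(maxsize=262144)
def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in the molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a SMILES file: one molecule per line, optional tab-separated name."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0].split()[0])
    return out


def write_smiles_file(smiles: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
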