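"""Synthetic assay corpora with planted structure, plus deterministic mocks.

The generator emulates a public screening-assay corpus at the structural
level needed to exercise every pipeline stage offline:

* each assay belongs to one of ``n_families`` synthetic target families;
  descriptions carry family-specific token signatures, so the hashed
  bag-of-tokens embedder separates families by construction;
* each family has a designated "query" UniProt accession (carried by a small
  fraction of its assays, to exercise query-target exclusion) and a query
  protein sequence from which per-assay target sequences are mutated with a
  known, recorded identity fraction;
* outcome tables draw actives from family-specific scaffold pools and
  non-actives from a shared pool, with the configured active fraction and a
  measured IC50 on most actives;
* a configured fraction of assays are counterscreens, flagged both in the
  record annotation and the manifest.

Everything derives from one seeded generator, and the returned ground-truth
manifest is sufficient to predict every filter decision by direct predicate
evaluation — which is exactly how the pipeline is tested.

What this corpus does *not* emulate: real assay prose style, inter-family
biological overlap, measurement noise semantics, or any real chemistry beyond
"same scaffold means similar fingerprint".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .bioassay_model import (
    BioAssayRecord,
    Measurement,
    MoleculeOutcome,
    Outcome,
    ProteinQuery,
    Relation,
    TargetInfo,
)
from .chem_pool import BASE_POOL, SCAFFOLD_TEMPLATES, full_pool, scaffold_family_pool
from .evaluation import tanimoto_similarity
from .exceptions import ContractError
from .providers import TextProvider  # noqa: F401  (protocol the mocks implement)

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_LEN = 64


class CorpusSpec(BaseModel):
    """Parameters of one synthetic corpus."""

    n_assays: int = Field(default=50, ge=1)
    n_families: int = Field(default=3, ge=1)
    actives_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    table_size_range: tuple[int, int] = (8, 40)
    counterscreen_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    #: fraction of each family's assays that carry the family's query accession
    query_target_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _range_ordered(self) -> "CorpusSpec":
        lo, hi = self.table_size_range
        if not (1 <= lo <= hi):
            raise ValueError("table_size_range must satisfy 1 <= min <= max")
        return self


@dataclass
class AssayTruth:
    """Ground truth for one synthetic assay."""

    aid: int
    family: int
    counterscreen: bool
    uniprot_id: str
    sequence_identity: float  # planted identity to the family query sequence
    table_len: int
    n_actives: int


@dataclass
class CorpusManifest:
    """Ground truth sufficient to predict every filter decision."""

    assays: dict[int, AssayTruth] = dataclass_field(default_factory=dict)
    family_query_uniprot: dict[int, str] = dataclass_field(default_factory=dict)
    family_query_sequence: dict[int, str] = dataclass_field(default_factory=dict)
    family_signature: dict[int, list[str]] = dataclass_field(default_factory=dict)
    family_active_pool: dict[int, list[str]] = dataclass_field(default_factory=dict)
    identity_table: dict[str, float] = dataclass_field(default_factory=dict)

    def relevant_to(self, aid: int, family: int) -> bool:
        return self.assays[aid].family == family


def _family_scaffolds(family: int, n_families: int) -> tuple[int, ...]:
    """Disjoint scaffold-template subset for one family (round-robin split)."""
    return tuple(
        i for i in range(len(SCAFFOLD_TEMPLATES)) if i % n_families == family % n_families
    )


def _random_sequence(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AMINO), size=_SEQ_LEN))


def _mutate(sequence: str, n_mutations: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(sequence), size=n_mutations, replace=False)
    chars = list(sequence)
    for pos in positions:
        alternatives = [a for a in _AMINO if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


_BOILERPLATE = (
    "Fluorescence-based dose response screening assay measuring compound "
    "activity against the target protein in a biochemical format."
)

_COUNTERSCREEN_TEXT = (
    "This is a counterscreen assay for off-target activity and assay "
    "artifact detection; hits here indicate undesirable promiscuity."
)


def make_corpus(spec: CorpusSpec) -> tuple[list[BioAssayRecord], CorpusManifest]:
    """Generate a corpus and its ground-truth manifest, reproducibly from seed."""
    rng = np.random.default_rng(spec.seed)
    manifest = CorpusManifest()
    n_fam = spec.n_families

    for family in range(n_fam):
        manifest.family_query_uniprot[family] = f"Q{90000 + family}"
        manifest.family_query_sequence[family] = _random_sequence(rng)
        manifest.family_signature[family] = [f"fam{family}sig{j}" for j in range(6)]
        manifest.family_active_pool[family] = list(
            scaffold_family_pool(_family_scaffolds(family, n_fam))
        )

    shared_pool = list(full_pool())

    records = []
    lo, hi = spec.table_size_range
    for i in range(spec.n_assays):
        aid = 1000 + i
        family = int(rng.integers(n_fam))
        counterscreen = bool(rng.random() < spec.counterscreen_fraction)
        carries_query_accession = bool(rng.random() < spec.query_target_fraction)
        uniprot = (
            manifest.family_query_uniprot[family]
            if carries_query_accession
            else f"P{10000 + aid}"
        )
        # planted sequence identity: high for half the family assays, low otherwise
        identity_target = float(rng.uniform(0.6, 0.95)) if rng.random() < 0.5 else float(
            rng.uniform(0.05, 0.30)
        )
        n_mut = round((1 - identity_target) * _SEQ_LEN)
        sequence = _mutate(manifest.family_query_sequence[family], n_mut, rng)
        identity = (_SEQ_LEN - n_mut) / _SEQ_LEN
        manifest.identity_table[sequence] = identity

        table_len = int(rng.integers(lo, hi + 1))
        n_actives = int(round(spec.actives_fraction * table_len))
        active_pool = manifest.family_active_pool[family]
        actives = [
            str(s)
            for s in rng.choice(active_pool, size=min(n_actives, len(active_pool)), replace=False)
        ]
        n_actives = len(actives)
        others = [
            str(s)
            for s in rng.choice(
                shared_pool, size=table_len - n_actives, replace=len(shared_pool) < table_len
            )
        ]
        outcomes = []
        for smiles in actives:
            measurement = None
            if rng.random() < 0.8:
                measurement = Measurement(
                    std_type="IC50",
                    relation=Relation.EQ,
                    value=float(np.round(rng.uniform(0.01, 50.0), 3)),
                    units="uM",
                )
            outcomes.append(
                MoleculeOutcome(smiles=smiles, outcome=Outcome.ACTIVE, measurement=measurement)
            )
        for smiles in others:
            outcome = Outcome.INACTIVE if rng.random() < 0.7 else Outcome.UNSPECIFIED
            outcomes.append(MoleculeOutcome(smiles=smiles, outcome=outcome))
        order = rng.permutation(len(outcomes))
        outcomes = [outcomes[j] for j in order]

        signature = " ".join(manifest.family_signature[family])
        description = f"{_BOILERPLATE} Target family markers: {signature}. {signature}. {signature}."
        if counterscreen:
            description += " " + _COUNTERSCREEN_TEXT
        records.append(
            BioAssayRecord(
                aid=aid,
                title=f"Screening assay {aid} for target family {family}",
                description=description,
                protocol=f"Compounds tested at 8-point dose response; plate {i % 12 + 1}.",
                target=TargetInfo(uniprot_id=uniprot, name=f"synthetic target {aid}", sequence=sequence),
                outcomes=outcomes,
                is_counterscreen_annotation=counterscreen,
            )
        )
        manifest.assays[aid] = AssayTruth(
            aid=aid,
            family=family,
            counterscreen=counterscreen,
            uniprot_id=uniprot,
            sequence_identity=identity,
            table_len=len(outcomes),
            n_actives=n_actives,
        )
    return records, manifest


def manifest_to_dict(manifest: CorpusManifest) -> dict:
    return {
        "assays": {str(aid): vars(t) for aid, t in manifest.assays.items()},
        "family_query_uniprot": {str(f): v for f, v in manifest.family_query_uniprot.items()},
        "family_query_sequence": {str(f): v for f, v in manifest.family_query_sequence.items()},
        "family_signature": {str(f): v for f, v in manifest.family_signature.items()},
        "family_active_pool": {str(f): v for f, v in manifest.family_active_pool.items()},
        "identity_table": manifest.identity_table,
    }


def manifest_from_dict(doc: dict) -> CorpusManifest:
    return CorpusManifest(
        assays={int(aid): AssayTruth(**t) for aid, t in doc["assays"].items()},
        family_query_uniprot={int(f): v for f, v in doc["family_query_uniprot"].items()},
        family_query_sequence={int(f): v for f, v in doc["family_query_sequence"].items()},
        family_signature={int(f): v for f, v in doc["family_signature"].items()},
        family_active_pool={int(f): v for f, v in doc["family_active_pool"].items()},
        identity_table=doc["identity_table"],
    )


def make_query(manifest: CorpusManifest, family: int, with_sequence: bool = True) -> ProteinQuery:
    """A query matching one synthetic family's planted token signature."""
    signature = " ".join(manifest.family_signature[family])
    return ProteinQuery(
        description=(
            f"Protein target with family markers {signature}. {signature}. "
            "Seeking small-molecule inhibitors of this enzyme."
        ),
        uniprot_id=manifest.family_query_uniprot[family],
        sequence=manifest.family_query_sequence[family] if with_sequence else None,
    )


def make_unrelated_query() -> ProteinQuery:
    """A query matching no synthetic family (for None-relevance runs)."""
    return ProteinQuery(
        description=(
            "Orphan membrane transporter zzztok0 zzztok1 zzztok2 with no "
            "characterized chemistry. zzztok0 zzztok1 zzztok2."
        ),
        uniprot_id="Q99999",
    )


# ---------------------------------------------------------------------------
# Deterministic mock text provider

_AID_RE = re.compile(r"AID (\d+)")
_BATCH_RE = re.compile(r"generate (\d+) new candidate molecules", re.IGNORECASE)
_OPTIMIZE_TAIL_RE = re.compile(r"single SMILES\):\n(\S+)")


class MockTextProvider:
    """Scripted text backend covering every request class the pipeline issues.

    * ``assess``: reads the AID from the prompt and answers from the
      ground-truth manifest (relevant iff the assay belongs to the query
      family; counterscreen from the planted flag).
    * ``summarize``: deterministic canned summary naming the AID.
    * ``keywords``: pass-through of the description block.
    * ``generate``: emits one SMILES per line from a molecule pool, without
      replacement, in a deterministic seeded order; when ``bias_molecules``
      is set the pool is reordered by fingerprint similarity to those
      molecules (most similar first), emulating in-context learning.  With
      ``corrupt_every`` = m, every m-th emitted line is unparsable garbage.
    * ``optimize``: echoes the input molecule (identity optimization) unless
      an ``optimize_script`` mapping is given.

    Unscripted request kinds raise, so tests notice unexpected traffic.
    """

    def __init__(
        self,
        manifest: Optional[CorpusManifest] = None,
        query_family: Optional[int] = None,
        pool: Optional[Sequence[str]] = None,
        seed: int = 0,
        corrupt_every: Optional[int] = None,
        bias_molecules: Optional[Sequence[str]] = None,
        optimize_script: Optional[dict[str, str]] = None,
        kinds: Optional[set[str]] = None,
    ):
        self.manifest = manifest
        self.query_family = query_family
        self.corrupt_every = corrupt_every
        self.optimize_script = optimize_script or {}
        self.kinds = kinds
        self._emitted = 0
        self._cursor = 0
        if pool is not None:
            pool = list(dict.fromkeys(pool))
            if bias_molecules:
                pool.sort(
                    key=lambda s: (
                        -max(tanimoto_similarity(s, b) for b in bias_molecules),
                        s,
                    )
                )
            else:
                rng = np.random.default_rng(seed)
                pool = [pool[i] for i in rng.permutation(len(pool))]
        self.pool = pool

    def _next_molecule(self) -> str:
        assert self.pool, "generation requested but no pool configured"
        smiles = self.pool[self._cursor % len(self.pool)]
        self._cursor += 1
        return smiles

    def complete(self, prompt: str, kind: str = "generate") -> str:
        if self.kinds is not None and kind not in self.kinds:
            raise ContractError(f"mock provider has no script for request kind {kind!r}")
        if kind == "assess":
            match = _AID_RE.search(prompt)
            if not match or self.manifest is None:
                raise ContractError("assess request without AID or manifest")
            truth = self.manifest.assays[int(match.group(1))]
            relevant = self.query_family is not None and truth.family == self.query_family
            return (
                f"RELEVANT: {'yes' if relevant else 'no'}\n"
                f"COUNTERSCREEN: {'yes' if truth.counterscreen else 'no'}"
            )
        if kind == "summarize":
            match = _AID_RE.search(prompt)
            aid = match.group(1) if match else "?"
            return (
                f"Assay {aid} screened compounds against its synthetic target "
                "family and reported dose-response activity calls."
            )
        if kind == "keywords":
            return prompt.split("Description:\n", 1)[1].strip()
        if kind == "generate":
            match = _BATCH_RE.search(prompt)
            batch_size = int(match.group(1)) if match else 10
            lines = []
            for _ in range(batch_size):
                self._emitted += 1
                if self.corrupt_every and self._emitted % self.corrupt_every == 0:
                    lines.append(f"@@garbage-not-a-molecule-{self._emitted}@@")
                else:
                    lines.append(self._next_molecule())
            return "\n".join(lines)
        if kind == "optimize":
            match = _OPTIMIZE_TAIL_RE.search(prompt)
            if not match:
                raise ContractError("optimize request without a molecule")
            original = match.group(1)
            return self.optimize_script.get(original, original)
        raise ContractError(f"unscripted request kind: {kind!r}")
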