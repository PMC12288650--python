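"""Filter cascade applied to retrieved assays, plus relevance classification.

After embedding retrieval, candidate assays pass through an ordered cascade:

1. **Query-target exclusion** — assays whose annotated target carries the same
   UniProt accession as the query are removed, so context never contains data
   measured directly on the query protein.
2. **Minimum table size** — assays with fewer tested molecules than
   ``min_mol_num`` are removed; assays with *zero* actives face the stricter
   threshold ``2 * n_mol``, because a no-active table only earns its context
   slot when it can fill the doubled fallback sample.
3. **Sequence-identity filter** (optional, off by default) — assays whose
   target exceeds the identity threshold with the query sequence (strictly
   ``> threshold``) are discarded; lower-ranked candidates flow up to replace
   them when the list is later truncated.
4. **LLM relevance/counterscreen assessment** — a text backend judges each
   survivor: is the assay biologically relevant to the query, and is it a
   counterscreen?  Counterscreens are kept but tagged; their actives become
   avoid-examples downstream.
5. **Truncation** to ``max_assay_num`` in similarity order.

Every stage is a pure function of its inputs, so each one is checkable
against a direct predicate scan of the ground-truth manifest in tests.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .bioassay_model import BioAssayRecord, ProteinQuery
from .embedding_index import RetrievalResult
from .exceptions import ContractError
from .providers import IdentityProvider, TextProvider

logger = logging.getLogger(__name__)


class RetrievalConfig(BaseModel):
    """Knobs for the retrieval/filter stage.

    Defaults follow the reference protocol: keep at most 10 assays, sample 8
    molecules per activity class, and drop context molecules above 45 heavy
    atoms.  ``k`` is the initial retrieval depth, deliberately larger than
    ``max_assay_num`` so filtered-out candidates have replacements.
    """

    k: int = Field(default=50, ge=1)
    min_mol_num: int = Field(default=4, ge=1)
    max_assay_num: int = Field(default=10, ge=1)
    max_mol_size: int = Field(default=45, ge=1)
    n_mol: int = Field(default=8, ge=1)
    seq_identity_threshold: float = Field(default=0.30, ge=0.0, le=1.0)
    use_identity_filter: bool = False
    seed: int = 0


@dataclass
class AssayAssessment:
    """One structured verdict per assay from the assessment pass."""

    aid: int
    relevant: bool
    counterscreen: bool
    summary: str = ""


class RelevanceGroup(str, Enum):
    HIGH = "High"
    MEDIUM = "Medium"
    LOW = "Low"
    NONE = "None"


# ---------------------------------------------------------------------------
# Cascade stages


def exclude_query_target(
    results: RetrievalResult,
    query: ProteinQuery,
    corpus: dict[int, BioAssayRecord],
) -> RetrievalResult:
    """Drop assays whose target UniProt accession matches the query's."""
    if query.uniprot_id is None:
        return RetrievalResult(list(results.ranked))
    kept = []
    for aid, sim in results.ranked:
        target = corpus[aid].target
        if target is not None and target.uniprot_id == query.uniprot_id:
            continue
        kept.append((aid, sim))
    return RetrievalResult(kept)


def filter_min_molecules(
    results: RetrievalResult,
    corpus: dict[int, BioAssayRecord],
    min_mol_num: int,
    n_mol: int,
) -> RetrievalResult:
    """Drop assays with too-small outcome tables.

    The threshold is inclusive (a table of exactly ``min_mol_num`` rows
    passes).  Assays with no active molecules must instead meet
    ``2 * n_mol``, matching the doubled fallback sample size used when
    selecting molecules from an all-inactive table.
    """
    if min_mol_num < 1:
        raise ContractError("min_mol_num must be >= 1")
    kept = []
    for aid, sim in results.ranked:
        record = corpus[aid]
        threshold = min_mol_num if record.n_actives() > 0 else max(min_mol_num, 2 * n_mol)
        if len(record.outcomes) >= threshold:
            kept.append((aid, sim))
    return RetrievalResult(kept)


def filter_sequence_identity(
    results: RetrievalResult,
    query: ProteinQuery,
    corpus: dict[int, BioAssayRecord],
    threshold: float,
    identity_provider: IdentityProvider,
) -> RetrievalResult:
    """Drop assays whose target sequence identity to the query exceeds the threshold.

    "Exceeds" is strict: identity equal to the threshold is retained.  Assays
    without an annotated target sequence pass with a warning.  Because the
    ranked list keeps all survivors in order, candidates below the eventual
    ``max_assay_num`` cut automatically replace discarded ones.
    """
    if query.sequence is None:
        raise ContractError("sequence identity filter requires query.sequence")
    kept = []
    for aid, sim in results.ranked:
        target = corpus[aid].target
        if target is None or target.sequence is None:
            logger.warning("assay %d has no target sequence; passing identity filter", aid)
            kept.append((aid, sim))
            continue
        if identity_provider(query.sequence, target.sequence) > threshold:
            continue
        kept.append((aid, sim))
    return RetrievalResult(kept)


_ASSESS_PROMPT = """You are screening-data curator reviewing whether one assay \
record is useful context for a molecule-design query.

Query protein/phenotype:
{query}

Assay record AID {aid}:
Title: {title}
Description: {description}
Protocol: {protocol}

Answer with exactly two lines:
RELEVANT: yes or no  (is this assay biologically relevant to the query target?)
COUNTERSCREEN: yes or no  (is this assay a counterscreen / off-target or \
artifact-detection assay?)
"""

_VERDICT_RE = re.compile(
    r"RELEVANT:\s*(yes|no).*?COUNTERSCREEN:\s*(yes|no)", re.IGNORECASE | re.DOTALL
)


def assess_assay(
    record: BioAssayRecord,
    query: ProteinQuery,
    text_provider: TextProvider,
) -> AssayAssessment:
    """Ask the text backend for a structured relevance/counterscreen verdict.

    Both judgments are requested in a single call.  A malformed reply is
    re-asked once; a second failure defaults to (not relevant, not
    counterscreen) with a warning, which errs toward dropping the assay.
    """
    prompt = _ASSESS_PROMPT.format(
        query=query.description,
        aid=record.aid,
        title=record.title,
        description=record.description,
        protocol=record.protocol,
    )
    for attempt in range(2):
        reply = text_provider.complete(prompt, kind="assess")
        match = _VERDICT_RE.search(reply)
        if match:
            return AssayAssessment(
                aid=record.aid,
                relevant=match.group(1).lower() == "yes",
                counterscreen=match.group(2).lower() == "yes",
            )
    logger.warning("unparsable assessment for assay %d after re-ask; defaulting to irrelevant", record.aid)
    return AssayAssessment(aid=record.aid, relevant=False, counterscreen=False)


def assess_all(
    results: RetrievalResult,
    corpus: dict[int, BioAssayRecord],
    query: ProteinQuery,
    text_providers: Sequence[TextProvider],
    aggregation: str = "or",
) -> list[AssayAssessment]:
    """Assess every ranked assay, optionally aggregating multiple providers.

    ``aggregation`` combines per-provider verdicts field-wise: ``or`` (any
    provider says yes), ``and`` (all must agree), or ``majority``.  Default is
    a single provider, where all three coincide.
    """
    if not text_providers:
        raise ContractError("at least one text provider required")
    if aggregation not in {"or", "and", "majority"}:
        raise ContractError(f"unknown aggregation rule: {aggregation}")

    def combine(votes: list[bool]) -> bool:
        if aggregation == "or":
            return any(votes)
        if aggregation == "and":
            return all(votes)
        return sum(votes) * 2 > len(votes)

    assessments = []
    for aid, _ in results.ranked:
        verdicts = [assess_assay(corpus[aid], query, tp) for tp in text_providers]
        assessments.append(
            AssayAssessment(
                aid=aid,
                relevant=combine([v.relevant for v in verdicts]),
                counterscreen=combine([v.counterscreen for v in verdicts]),
            )
        )
    return assessments


def select_assays(
    results: RetrievalResult,
    assessments: Sequence[AssayAssessment],
    max_assay_num: int,
) -> list[AssayAssessment]:
    """Keep relevant assays in similarity order, truncated at ``max_assay_num``.

    Counterscreen assays count as relevant context — they are retained and
    tagged so their active molecules become avoid-examples.  With zero
    relevant assays the result is empty and the pipeline falls back to
    description-only generation.
    """
    by_aid = {a.aid: a for a in assessments}
    selected = []
    for aid, _ in results.ranked:
        assessment = by_aid.get(aid)
        if assessment is None or not (assessment.relevant or assessment.counterscreen):
            continue
        selected.append(assessment)
        if len(selected) == max_assay_num:
            break
    return selected


def relevance_ratio(
    assessments: Sequence[AssayAssessment],
) -> tuple[float, RelevanceGroup]:
    """Fraction of assessed assays judged relevant, and its stratum.

    Strata: High when x >= 0.7; Medium when 0.4 < x < 0.7; Low when
    0.1 < x <= 0.4; None when x <= 0.1.  (x = 0.4 therefore falls in Low.)
    """
    if not assessments:
        raise ContractError("relevance ratio undefined for empty assessment set")
    x = sum(1 for a in assessments if a.relevant) / len(assessments)
    if x >= 0.7:
        group = RelevanceGroup.HIGH
    elif x > 0.4:
        group = RelevanceGroup.MEDIUM
    elif x > 0.1:
        group = RelevanceGroup.LOW
    else:
        group = RelevanceGroup.NONE
    return x, group


# ---------------------------------------------------------------------------
# Full cascade


@dataclass
class RetrievalAudit:
    """Per-stage record of which assays survived, for inspection and tests."""

    stages: list[tuple[str, list[int]]] = field(default_factory=list)

    def log(self, stage: str, results: RetrievalResult | list) -> None:
        aids = results.aids if isinstance(results, RetrievalResult) else [a.aid for a in results]
        self.stages.append((stage, aids))


def run_filter_cascade(
    results: RetrievalResult,
    corpus: dict[int, BioAssayRecord],
    query: ProteinQuery,
    config: RetrievalConfig,
    text_providers: Sequence[TextProvider],
    identity_provider: Optional[IdentityProvider] = None,
    aggregation: str = "or",
) -> tuple[list[AssayAssessment], list[AssayAssessment], RetrievalAudit]:
    """Apply the full cascade; returns (selected, all assessments, audit log)."""
    audit = RetrievalAudit()
    audit.log("retrieved", results)

    results = exclude_query_target(results, query, corpus)
    audit.log("exclude_query_target", results)

    results = filter_min_molecules(results, corpus, config.min_mol_num, config.n_mol)
    audit.log("filter_min_molecules", results)

    if config.use_identity_filter and query.sequence is not None:
        if identity_provider is None:
            raise ContractError("identity filter enabled but no identity provider given")
        results = filter_sequence_identity(
            results, query, corpus, config.seq_identity_threshold, identity_provider
        )
        audit.log("filter_sequence_identity", results)

    assessments = assess_all(results, corpus, query, text_providers, aggregation)
    selected = select_assays(results, assessments, config.max_assay_num)
    audit.log("select_assays", selected)
    return selected, assessments, audit
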