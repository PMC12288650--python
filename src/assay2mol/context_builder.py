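"""Layered context construction: summaries, tables, molecule selection, prompt.

Each selected assay contributes one context block to the generation prompt:

1. a concise text summary from the text backend (counterscreen assays get an
   explicit avoidance sentence appended by template);
2. the outcome table rendered as deterministic fixed-column text;
3. a class-balanced molecule selection:

   * more than ``n_mol`` actives: a uniform seeded sample of ``n_mol``;
   * 1..``n_mol`` actives: all of them;
   * in both cases, up to ``n_mol`` molecules sampled from the combined
     Unspecified and Inactive classes (all of them when fewer exist);
   * zero actives: fall back to all molecules, or a uniform sample of
     ``2 * n_mol`` when the table is larger than that.

Molecules above ``max_mol_size`` heavy atoms are pruned before selection so
oversized context molecules do not drag generated molecules upward in size.
Prompt assembly is a pure function of (query, blocks, template version, mode).
"""

from __future__ import annotations

import enum
import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bioassay_model import (
    BioAssayRecord,
    MoleculeOutcome,
    Outcome,
    ProteinQuery,
    heavy_atom_count,
)
from .exceptions import ContractError
from .providers import TextProvider
from .retrieval_filter import AssayAssessment, RetrievalConfig

logger = logging.getLogger(__name__)

TEMPLATE_VERSION = "v1"

#: crude token estimate used for the prompt budget: characters / 4
CHARS_PER_TOKEN = 4


def prune_by_size(
    outcomes: Sequence[MoleculeOutcome], max_mol_size: int
) -> list[MoleculeOutcome]:
    """Drop rows whose molecule exceeds ``max_mol_size`` heavy atoms (strict)."""
    if max_mol_size < 1:
        raise ContractError("max_mol_size must be >= 1")
    return [o for o in outcomes if heavy_atom_count(o.smiles) <= max_mol_size]


@dataclass
class MoleculeSelection:
    """Class-balanced molecule subset for one assay's context block."""

    actives: list[MoleculeOutcome]
    others: list[MoleculeOutcome]
    all_mode: bool = False  # no-active fallback used

    @property
    def rows(self) -> list[MoleculeOutcome]:
        return self.actives + self.others


def _sample_in_order(
    rows: list[MoleculeOutcome], n: int, rng: np.random.Generator
) -> list[MoleculeOutcome]:
    """Uniform sample without replacement, preserving input order."""
    if len(rows) <= n:
        return list(rows)
    idx = sorted(rng.choice(len(rows), size=n, replace=False))
    return [rows[i] for i in idx]


def select_molecules(
    outcomes: Sequence[MoleculeOutcome], n_mol: int, seed: int
) -> MoleculeSelection:
    """Select a class-balanced molecule subset, deterministically from seed."""
    if not outcomes:
        raise ContractError("cannot select molecules from an empty table")
    if n_mol < 1:
        raise ContractError("n_mol must be >= 1")
    rng = np.random.default_rng(seed)
    actives = [o for o in outcomes if o.outcome is Outcome.ACTIVE]
    others = [o for o in outcomes if o.outcome is not Outcome.ACTIVE]
    if actives:
        return MoleculeSelection(
            actives=_sample_in_order(actives, n_mol, rng),
            others=_sample_in_order(others, n_mol, rng),
        )
    return MoleculeSelection(
        actives=[],
        others=_sample_in_order(others, 2 * n_mol, rng),
        all_mode=True,
    )


def _measurement_cells(row: MoleculeOutcome) -> tuple[str, str, str, str]:
    m = row.measurement
    if m is None:
        return "", "", "", ""
    return m.std_type, m.relation.value, f"{m.value:g}", m.units


def render_table(rows: Sequence[MoleculeOutcome] | MoleculeSelection) -> str:
    """Render outcome rows as fixed-column text, actives first.

    Output is byte-identical across runs for the same input: column widths are
    derived from content only, and ordering is actives (in input order) then
    the rest (in input order).
    """
    if isinstance(rows, MoleculeSelection):
        ordered = rows.rows
    else:
        ordered = [r for r in rows if r.outcome is Outcome.ACTIVE] + [
            r for r in rows if r.outcome is not Outcome.ACTIVE
        ]
    header = ("SMILES", "Outcome", "Type", "Rel", "Value", "Units")
    body = [
        (r.smiles, r.outcome.value, *_measurement_cells(r)) for r in ordered
    ]
    widths = [
        max(len(header[c]), *(len(row[c]) for row in body)) if body else len(header[c])
        for c in range(len(header))
    ]
    lines = [
        " | ".join(cell.ljust(w) for cell, w in zip(header, widths)).rstrip(),
        "-+-".join("-" * w for w in widths),
    ]
    for row in body:
        lines.append(" | ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip())
    return "\n".join(lines)


_SUMMARY_PROMPT = """Summarize the following screening assay record in 2-4 \
sentences: its purpose, methodology, key results, and how its findings relate \
to this molecule-design query.

Query:
{query}

Assay record AID {aid}:
Title: {title}
Description: {description}
Protocol: {protocol}
"""

COUNTERSCREEN_AVOIDANCE = (
    " This assay is a counterscreen: its active molecules should be avoided."
)


def summarize_assay(
    record: BioAssayRecord,
    query: ProteinQuery,
    text_provider: TextProvider,
    counterscreen: bool = False,
) -> str:
    """Produce the per-assay summary; counterscreens get an avoidance clause."""
    prompt = _SUMMARY_PROMPT.format(
        query=query.description,
        aid=record.aid,
        title=record.title,
        description=record.description,
        protocol=record.protocol,
    )
    summary = text_provider.complete(prompt, kind="summarize").strip()
    if counterscreen:
        summary += COUNTERSCREEN_AVOIDANCE
    return summary


@dataclass
class ContextBlock:
    """One assay's contribution to the prompt."""

    aid: int
    summary: str
    table_text: str
    selection: MoleculeSelection
    counterscreen: bool = False


class PromptMode(str, enum.Enum):
    GENERATE = "generate"
    OPTIMIZE_ANTI_TARGET = "optimize_anti_target"


@dataclass
class GenerationContext:
    """Everything the generation stage needs: blocks, constraints, prompt text."""

    query_text: str
    blocks: list[ContextBlock] = field(default_factory=list)
    avoid_molecules: list[str] = field(default_factory=list)
    optimization_targets: Optional[list[str]] = None
    mode: PromptMode = PromptMode.GENERATE
    prompt: str = ""

    @property
    def context_hash(self) -> str:
        return hashlib.sha256(self.prompt.encode()).hexdigest()[:16]

    @property
    def context_smiles(self) -> list[str]:
        return [row.smiles for block in self.blocks for row in block.selection.rows]

    @property
    def context_actives(self) -> list[str]:
        """Active molecules from non-counterscreen blocks (the imitable examples)."""
        return [
            row.smiles
            for block in self.blocks
            if not block.counterscreen
            for row in block.selection.actives
        ]


_PROMPT_HEADER = """You are an expert medicinal chemist.  Design candidate \
molecules for the following target.

Target description:
{query}
"""

_BLOCK_TEMPLATE = """
--- Assay context {rank} (AID {aid}) ---
{summary}

Experimental results:
{table}
"""

_AVOID_TEMPLATE = """
Molecules active in counterscreen assays must be avoided.  Do NOT propose \
molecules similar to these:
{avoid}
"""

_GENERATE_INSTRUCTION = """
Based on the target description and the assay context above, generate \
{batch_size} new candidate molecules likely to show the desired activity \
against the target.  Reply with exactly {batch_size} SMILES strings, one per \
line, and no other text.
"""

_OPTIMIZE_INSTRUCTION = """
The assay context above describes an anti-target whose activity must be \
minimized.  Optimize each of the following molecules to REDUCE its binding \
affinity toward this anti-target while preserving its other properties.  \
Reply with one optimized SMILES per input molecule, one per line, in the same \
order, and no other text.

Molecules to optimize:
{targets}
"""


def build_prompt(
    query: ProteinQuery,
    blocks: Sequence[ContextBlock],
    mode: PromptMode = PromptMode.GENERATE,
    optimization_targets: Optional[Sequence[str]] = None,
    batch_size: int = 10,
    max_tokens: int = 32768,
) -> GenerationContext:
    """Assemble the final prompt from a versioned template.

    Blocks appear in the given (similarity-rank) order.  When the estimated
    token count exceeds ``max_tokens``, lowest-ranked blocks are dropped with
    a warning.  Zero blocks yields a description-only prompt.
    """
    if mode is PromptMode.OPTIMIZE_ANTI_TARGET and not optimization_targets:
        raise ContractError("optimize mode requires optimization_targets")
    blocks = list(blocks)
    avoid = _collect_avoid_molecules(blocks)

    def assemble(active_blocks: Sequence[ContextBlock]) -> str:
        parts = [_PROMPT_HEADER.format(query=query.description)]
        for rank, block in enumerate(active_blocks, start=1):
            parts.append(
                _BLOCK_TEMPLATE.format(
                    rank=rank, aid=block.aid, summary=block.summary, table=block.table_text
                )
            )
        if avoid:
            parts.append(_AVOID_TEMPLATE.format(avoid="\n".join(avoid)))
        if mode is PromptMode.OPTIMIZE_ANTI_TARGET:
            parts.append(
                _OPTIMIZE_INSTRUCTION.format(targets="\n".join(optimization_targets))
            )
        else:
            parts.append(_GENERATE_INSTRUCTION.format(batch_size=batch_size))
        return "".join(parts)

    kept = blocks
    prompt = assemble(kept)
    while kept and len(prompt) / CHARS_PER_TOKEN > max_tokens:
        kept = kept[:-1]
        logger.warning("prompt over token budget; dropping lowest-ranked block")
        prompt = assemble(kept)

    return GenerationContext(
        query_text=query.description,
        blocks=kept,
        avoid_molecules=avoid,
        optimization_targets=list(optimization_targets) if optimization_targets else None,
        mode=mode,
        prompt=prompt,
    )


def _collect_avoid_molecules(blocks: Sequence[ContextBlock]) -> list[str]:
    avoid = []
    for block in blocks:
        if block.counterscreen:
            avoid.extend(row.smiles for row in block.selection.actives)
    return avoid


def build_context(
    query: ProteinQuery,
    selected: Sequence[AssayAssessment],
    corpus: dict[int, BioAssayRecord],
    config: RetrievalConfig,
    text_provider: TextProvider,
    mode: PromptMode = PromptMode.GENERATE,
    optimization_targets: Optional[Sequence[str]] = None,
    batch_size: int = 10,
) -> GenerationContext:
    """Run summarization, pruning, selection and rendering for each selected assay."""
    blocks = []
    for i, assessment in enumerate(selected):
        record = corpus[assessment.aid]
        pruned = prune_by_size(record.outcomes, config.max_mol_size)
        if not pruned:
            logger.warning("assay %d lost all molecules to size pruning; skipped", record.aid)
            continue
        selection = select_molecules(pruned, config.n_mol, seed=config.seed + i)
        summary = summarize_assay(
            record, query, text_provider, counterscreen=assessment.counterscreen
        )
        blocks.append(
            ContextBlock(
                aid=record.aid,
                summary=summary,
                table_text=render_table(selection),
                selection=selection,
                counterscreen=assessment.counterscreen,
            )
        )
    return build_prompt(
        query,
        blocks,
        mode=mode,
        optimization_targets=optimization_targets,
        batch_size=batch_size,
    )
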