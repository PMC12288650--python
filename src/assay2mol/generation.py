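"""Batched molecule generation: provider calls, output parsing, deduplication.

Generation requests are issued in small independent batches (default 10
molecules per call) with identical prompts — no chat state is carried between
batches.  Small fresh batches counter the mode collapse observed when a model
is asked for many molecules at once and starts emitting near-duplicates.

The response parser makes no assumption about response formatting beyond
"candidates appear one per line": markup fences are stripped, each line is
split on whitespace, and the longest token that canonicalizes as a SMILES is
taken as that line's candidate.  Lines yielding no parsable token are kept as
invalid candidates so validity rates stay honest.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .bioassay_model import canonicalize_smiles, is_valid_smiles
from .context_builder import GenerationContext, PromptMode
from .exceptions import ContractError
from .providers import TextProvider

logger = logging.getLogger(__name__)

_FENCE_RE = re.compile(r"^```[a-zA-Z]*\s*$")
#: lines that are clearly prose/numbering wrappers, not candidates
_LIST_PREFIX_RE = re.compile(r"^\s*(?:\d+[.):]|[-*•])\s*")


@dataclass
class GeneratedMolecule:
    """One candidate molecule with provenance back to the prompt that made it."""

    smiles: str  # canonical when valid, raw candidate text otherwise
    raw_text: str
    batch_index: int
    valid: bool
    context_hash: str


def extract_candidates(response: str) -> list[str]:
    """Split a provider response into per-line candidate spans.

    Code fences and list numbering are stripped; blank lines are skipped.
    """
    candidates = []
    for line in response.splitlines():
        if _FENCE_RE.match(line.strip()):
            continue
        line = _LIST_PREFIX_RE.sub("", line).strip()
        if line:
            candidates.append(line)
    return candidates


def _best_token(candidate: str) -> Optional[str]:
    """Longest whitespace-delimited token in the span that canonicalizes."""
    tokens = sorted(candidate.split(), key=len, reverse=True)
    for token in tokens:
        if is_valid_smiles(token):
            return token
    return None


def parse_response(
    response: str, batch_index: int, context_hash: str
) -> list[GeneratedMolecule]:
    """Turn one provider response into GeneratedMolecule records."""
    molecules = []
    for span in extract_candidates(response):
        token = _best_token(span)
        if token is None:
            molecules.append(
                GeneratedMolecule(
                    smiles=span,
                    raw_text=span,
                    batch_index=batch_index,
                    valid=False,
                    context_hash=context_hash,
                )
            )
        else:
            molecules.append(
                GeneratedMolecule(
                    smiles=canonicalize_smiles(token),
                    raw_text=span,
                    batch_index=batch_index,
                    valid=True,
                    context_hash=context_hash,
                )
            )
    return molecules


def _hash_prompt(prompt: str) -> str:
    return hashlib.sha256(prompt.encode()).hexdigest()[:16]


def generate_batch(
    prompt: str,
    provider: TextProvider,
    batch_size: int = 10,
    batch_index: int = 0,
) -> list[GeneratedMolecule]:
    """Request one batch of candidates and parse the response."""
    if batch_size < 1:
        raise ContractError("batch_size must be >= 1")
    context_hash = _hash_prompt(prompt)
    response = provider.complete(prompt, kind="generate")
    logger.debug(
        "generate batch %d: prompt %s response %s",
        batch_index,
        context_hash,
        _hash_prompt(response),
    )
    molecules = parse_response(response, batch_index, context_hash)
    if not molecules:
        logger.warning("batch %d produced zero parsable candidates", batch_index)
    return molecules


def generate_n(
    prompt: str,
    provider: TextProvider,
    n_total: int,
    batch_size: int = 10,
    dedupe: bool = True,
    max_calls: Optional[int] = None,
) -> list[GeneratedMolecule]:
    """Collect ``n_total`` valid (and, if ``dedupe``, unique) molecules.

    Batches are issued with identical prompts until the quota is met or the
    call budget (default: 5x the minimum number of calls) is exhausted, in
    which case a partial result is returned with a warning.
    """
    if n_total < 1:
        raise ContractError("n_total must be >= 1")
    if max_calls is None:
        max_calls = 5 * -(-n_total // batch_size)
    collected: list[GeneratedMolecule] = []
    seen: set[str] = set()
    n_valid = 0
    calls = 0
    while n_valid < n_total and calls < max_calls:
        batch = generate_batch(prompt, provider, batch_size, batch_index=calls)
        calls += 1
        for mol in batch:
            if n_valid >= n_total:
                break
            if mol.valid and dedupe:
                if mol.smiles in seen:
                    continue
                seen.add(mol.smiles)
            collected.append(mol)
            if mol.valid:
                n_valid += 1
    if n_valid < n_total:
        logger.warning(
            "call budget (%d) exhausted with %d/%d valid molecules", max_calls, n_valid, n_total
        )
    return collected


def validity_rate(molecules: Sequence[GeneratedMolecule]) -> float:
    """Fraction of emitted candidates that parsed as valid molecules."""
    if not molecules:
        raise ContractError("validity rate undefined for empty molecule list")
    return sum(1 for m in molecules if m.valid) / len(molecules)


def optimize_against_anti_target(
    molecules: Sequence[str],
    anti_target_context: GenerationContext,
    provider: TextProvider,
) -> list[tuple[str, GeneratedMolecule]]:
    """Optimize molecules to lose affinity for the context's anti-target.

    One provider call per input molecule keeps the input/output pairing
    unambiguous.  An invalid optimized candidate is flagged and the original
    molecule retained as a fallback, so before/after metric deltas always
    have a complete paired table.
    """
    if not molecules:
        raise ContractError("no molecules to optimize")
    if anti_target_context.mode is not PromptMode.OPTIMIZE_ANTI_TARGET:
        raise ContractError("context was not built in optimize mode")
    pairs = []
    for i, original in enumerate(molecules):
        prompt = (
            anti_target_context.prompt
            + f"\nOptimize this molecule now (reply with a single SMILES):\n{original}\n"
        )
        response = provider.complete(prompt, kind="optimize")
        parsed = parse_response(response, batch_index=i, context_hash=anti_target_context.context_hash)
        valid = [m for m in parsed if m.valid]
        if valid:
            pairs.append((original, valid[0]))
        else:
            logger.warning("optimization of %s produced no valid molecule; keeping input", original)
            pairs.append(
                (
                    original,
                    GeneratedMolecule(
                        smiles=canonicalize_smiles(original),
                        raw_text=original,
                        batch_index=i,
                        valid=False,
                        context_hash=anti_target_context.context_hash,
                    ),
                )
            )
    return pairs
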