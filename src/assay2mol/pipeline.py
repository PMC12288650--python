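"""End-to-end orchestration: index, retrieve, filter, build context, generate.

This is the thin glue the CLI and offline experiments call; every stage
remains individually importable and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

from .bioassay_model import BioAssayRecord, ProteinQuery
from .context_builder import GenerationContext, build_context
from .embedding_index import EmbeddingIndex, RetrievalResult, embed_query
from .generation import GeneratedMolecule, generate_n
from .providers import EmbeddingProvider, IdentityProvider, TextProvider
from .retrieval_filter import (
    AssayAssessment,
    RetrievalAudit,
    RetrievalConfig,
    relevance_ratio,
    run_filter_cascade,
)

#: a generation backend, or a factory building one from the finished context
#: (mock backends use the factory form to bias output toward context actives)
GenerationBackend = Union[TextProvider, Callable[[GenerationContext], TextProvider]]


@dataclass
class PipelineResult:
    retrieval: RetrievalResult
    selected: list[AssayAssessment]
    assessments: list[AssayAssessment]
    relevance_x: float
    relevance_group: str
    context: GenerationContext
    molecules: list[GeneratedMolecule]
    audit: RetrievalAudit

    @property
    def valid_smiles(self) -> list[str]:
        return [m.smiles for m in self.molecules if m.valid]


def run_pipeline(
    records: Sequence[BioAssayRecord],
    query: ProteinQuery,
    config: RetrievalConfig,
    embedding_provider: EmbeddingProvider,
    text_provider: TextProvider,
    generation_backend: GenerationBackend,
    n_molecules: int = 100,
    batch_size: int = 10,
    identity_provider: Optional[IdentityProvider] = None,
    index: Optional[EmbeddingIndex] = None,
    dedupe: bool = True,
) -> PipelineResult:
    """Run retrieve -> filter -> context -> generate for one query."""
    corpus = {r.aid: r for r in records}
    if index is None:
        index = EmbeddingIndex.build(records, embedding_provider)
    query_vec = embed_query(query, embedding_provider)
    retrieved = index.top_k(query_vec, config.k)

    selected, assessments, audit = run_filter_cascade(
        retrieved, corpus, query, config, [text_provider], identity_provider
    )
    # the relevance stratum is defined over the top max_assay_num assays that
    # survived the deterministic filters, not over the full retrieval depth
    top = assessments[: config.max_assay_num]
    if top:
        x, group = relevance_ratio(top)
    else:
        x, group = 0.0, "None"

    context = build_context(
        query, selected, corpus, config, text_provider, batch_size=batch_size
    )
    provider = (
        generation_backend(context) if callable(generation_backend) else generation_backend
    )
    molecules = generate_n(
        context.prompt, provider, n_molecules, batch_size, dedupe=dedupe
    )
    return PipelineResult(
        retrieval=retrieved,
        selected=selected,
        assessments=assessments,
        relevance_x=x,
        relevance_group=str(getattr(group, "value", group)),
        context=context,
        molecules=molecules,
        audit=audit,
    )
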