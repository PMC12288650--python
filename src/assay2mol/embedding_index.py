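"""In-memory vector index over assay records and exact top-k cosine retrieval.

The index stores raw (unnormalized) embeddings; normalization happens inside
the cosine computation.  Retrieval is exhaustive — corpora here are at most a
few thousand records, so exact search is both fast and trivially testable
against a brute-force oracle.  Ties in similarity break by ascending assay id
for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .bioassay_model import BioAssayRecord, ProteinQuery, record_to_dict
from .exceptions import ContractError, DegenerateInputError, EmptyCorpusError
from .providers import EmbeddingProvider, TextProvider

INDEX_FORMAT_VERSION = 1


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ContractError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass
class RetrievalResult:
    """Ranked retrieval output: (aid, similarity) pairs, best first."""

    ranked: list[tuple[int, float]] = field(default_factory=list)

    @property
    def aids(self) -> list[int]:
        return [aid for aid, _ in self.ranked]

    def __len__(self) -> int:
        return len(self.ranked)


def record_embedding_text(record: BioAssayRecord) -> str:
    """Text embedded for one assay record: its JSON document minus the table.

    Outcome tables are dropped before embedding — similarity should reflect
    what the assay is about, not which molecules happened to be tested.
    """
    doc = record_to_dict(record)
    doc.pop("outcomes", None)
    return json.dumps(doc, ensure_ascii=False)


class EmbeddingIndex:
    """Exact-search vector index keyed by assay id."""

    def __init__(self, dim: int, provider_tag: str = "unknown"):
        self.dim = int(dim)
        self.provider_tag = provider_tag
        self._aids: list[int] = []
        self._matrix: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self._aids)

    @property
    def aids(self) -> list[int]:
        return list(self._aids)

    def add(self, aid: int, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=float).ravel()
        if vector.shape != (self.dim,):
            raise ContractError(f"vector has dimension {vector.shape[0]}, index expects {self.dim}")
        if not np.all(np.isfinite(vector)):
            raise ContractError("embedding contains non-finite entries")
        row = vector[np.newaxis, :]
        self._matrix = row if self._matrix is None else np.vstack([self._matrix, row])
        self._aids.append(int(aid))

    @classmethod
    def build(
        cls,
        corpus: Sequence[BioAssayRecord],
        provider: EmbeddingProvider,
        provider_tag: str = "mock",
    ) -> "EmbeddingIndex":
        index = cls(dim=provider.dim, provider_tag=provider_tag)
        for record in corpus:
            index.add(record.aid, provider.embed(record_embedding_text(record)))
        return index

    def top_k(self, query: np.ndarray, k: int) -> RetrievalResult:
        """The k records most cosine-similar to the query, ties by ascending aid."""
        if len(self) == 0:
            raise EmptyCorpusError("cannot query an empty index")
        if k < 1:
            raise ContractError("k must be >= 1")
        query = np.asarray(query, dtype=float).ravel()
        sims = np.array([cosine_similarity(query, row) for row in self._matrix])
        order = sorted(range(len(self)), key=lambda i: (-sims[i], self._aids[i]))
        top = order[: min(k, len(self))]
        return RetrievalResult([(self._aids[i], float(sims[i])) for i in top])

    # -- persistence: JSON manifest + CSV vector matrix --------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": INDEX_FORMAT_VERSION,
            "dim": self.dim,
            "provider_tag": self.provider_tag,
            "aids": self._aids,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savetxt(directory / "vectors.csv", self._matrix if self._matrix is not None else np.empty((0, self.dim)), delimiter=",")

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingIndex":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest["format_version"] != INDEX_FORMAT_VERSION:
            raise ContractError(f"unsupported index format version {manifest['format_version']}")
        index = cls(dim=manifest["dim"], provider_tag=manifest["provider_tag"])
        matrix = np.loadtxt(directory / "vectors.csv", delimiter=",", ndmin=2)
        for aid, row in zip(manifest["aids"], matrix):
            index.add(aid, row)
        return index


_KEYWORD_PROMPT = """Extract the key biological and chemical terms from the \
following protein or phenotype description.  Reply with a short comma-separated \
keyword list only.

Description:
{description}
"""


def embed_query(
    query: ProteinQuery,
    provider: EmbeddingProvider,
    keyword_provider: Optional[TextProvider] = None,
) -> np.ndarray:
    """Embed a query description, optionally condensed to keywords first.

    When ``keyword_provider`` is given, the description is first reduced to a
    keyword list by the text backend; otherwise the raw description is
    embedded directly.
    """
    text = query.description
    if keyword_provider is not None:
        text = keyword_provider.complete(
            _KEYWORD_PROMPT.format(description=query.description), kind="keywords"
        )
    return provider.embed(text)
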