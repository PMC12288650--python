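"""Backend provider interfaces: text generation, embeddings, sequence identity.

The pipeline never talks to a model directly; every LLM-ish step goes through
one of the small protocols below so that tests and offline runs can substitute
deterministic mocks.  Two embedding providers ship with the package:

* :class:`HashedTokenEmbedder` — a deterministic, seedable offline embedder
  that hashes a bag of word tokens into a fixed-dimension signed-count vector.
  It is not a semantic model; it exists so that retrieval is exactly testable
  and so that synthetic corpora with planted token signatures separate cleanly.
* :class:`HttpEmbeddingProvider` / :class:`HttpTextProvider` — thin stdlib
  wrappers for any OpenAI-style endpoint.  Untested network plumbing, off by
  default everywhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
import urllib.request
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .exceptions import BackendError

logger = logging.getLogger(__name__)


@runtime_checkable
class TextProvider(Protocol):
    """A text-completion backend.

    ``kind`` names the request class (``summarize``, ``assess``, ``generate``,
    ``optimize``, ``keywords``) so scripted mocks can dispatch on it; live
    backends are free to ignore it.
    """

    def complete(self, prompt: str, kind: str = "generate") -> str: ...


@runtime_checkable
class EmbeddingProvider(Protocol):
    #: embedding dimension, constant for the provider's lifetime
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


#: sequence identity provider: (query_sequence, target_sequence) -> fraction in [0, 1]
IdentityProvider = Callable[[str, str], float]


def with_retries(fn, attempts: int = 3, base_delay: float = 0.5):
    """Call ``fn`` with exponential backoff; raise BackendError when exhausted."""
    for attempt in range(attempts):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - backend failures are opaque
            if attempt == attempts - 1:
                raise BackendError(f"backend failed after {attempts} attempts: {e}") from e
            delay = base_delay * 2**attempt
            logger.warning("backend attempt %d failed (%s); retrying in %.1fs", attempt + 1, e, delay)
            time.sleep(delay)


_TOKEN_RE = re.compile(r"[a-z0-9]+")


class HashedTokenEmbedder:
    """Deterministic bag-of-tokens embedding via seeded feature hashing.

    Each lowercase token is hashed (BLAKE2, keyed by the seed) to a coordinate
    in ``dim`` dimensions and a sign; token counts accumulate into the signed
    coordinate.  Texts sharing many tokens therefore have high cosine
    similarity, which is all the retrieval stage requires.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = int(dim)
        self.seed = int(seed)
        self._key = str(seed).encode()

    def _slot(self, token: str) -> tuple[int, float]:
        h = hashlib.blake2b(token.encode(), key=self._key, digest_size=8).digest()
        value = int.from_bytes(h, "big")
        return value % self.dim, 1.0 if (value >> 32) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in _TOKEN_RE.findall(text.lower()):
            idx, sign = self._slot(token)
            vec[idx] += sign
        return vec


class HttpEmbeddingProvider:
    """OpenAI-style ``/embeddings`` endpoint wrapper (network plumbing, untested)."""

    def __init__(self, url: str, model: str, dim: int, api_key: str = "", timeout: float = 60.0):
        self.url, self.model, self.dim = url, model, int(dim)
        self.api_key, self.timeout = api_key, timeout

    def embed(self, text: str) -> np.ndarray:
        def call():
            payload = json.dumps({"model": self.model, "input": text}).encode()
            req = urllib.request.Request(
                self.url,
                data=payload,
                headers={
                    "Content-Type": "application/json",
                    "Authorization": f"Bearer {self.api_key}",
                },
            )
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.load(resp)
            return np.asarray(body["data"][0]["embedding"], dtype=float)

        return with_retries(call)


class HttpTextProvider:
    """OpenAI-style ``/chat/completions`` endpoint wrapper (network plumbing, untested)."""

    def __init__(self, url: str, model: str, api_key: str = "", timeout: float = 120.0, **params):
        self.url, self.model = url, model
        self.api_key, self.timeout = api_key, timeout
        self.params = params  # decoding parameters pass through unmodified

    def complete(self, prompt: str, kind: str = "generate") -> str:
        def call():
            payload = json.dumps(
                {
                    "model": self.model,
                    "messages": [{"role": "user", "content": prompt}],
                    **self.params,
                }
            ).encode()
            req = urllib.request.Request(
                self.url,
                data=payload,
                headers={
                    "Content-Type": "application/json",
                    "Authorization": f"Bearer {self.api_key}",
                },
            )
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.load(resp)
            return body["choices"][0]["message"]["content"]

        return with_retries(call)


def planted_identity_provider(table: dict[str, float], default: float = 0.0) -> IdentityProvider:
    """Identity provider that looks up the *target* sequence in a planted table."""

    def identity(query_seq: str, target_seq: str) -> float:
        if query_seq == target_seq:
            return 1.0
        return table.get(target_seq, default)

    return identity


def naive_identity_provider(query_seq: str, target_seq: str) -> float:
    """Fraction of matching positions over the longer sequence (ungapped).

    A crude stand-in for a real aligner, adequate for the synthetic sequences
    this package generates, where homology is planted as literal shared runs.
    """
    if not query_seq or not target_seq:
        return 0.0
    n = min(len(query_seq), len(target_seq))
    matches = sum(1 for a, b in zip(query_seq[:n], target_seq[:n]) if a == b)
    return matches / max(len(query_seq), len(target_seq))


def text_list(items: Sequence[str]) -> str:
    """Join items as newline-separated text (tiny helper shared by prompts)."""
    return "\n".join(items)
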