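"""Note chunking, retrieval, and majority-voted clinical-sign extraction.

The extractor backend is pluggable: any object with
``query(prompt, context, temperature, seed) -> str`` returning a JSON object
mapping the queried key to ``["Yes"|"No", justification]``. The shipped
:class:`MockLLMBackend` keys on the canonical phrase lexicon used by the
synthetic cohort generator, which makes extraction exact and testable; real
LLM backends are adapters behind the same interface.

Tokens are whitespace-delimited words; chunking uses windows of
``chunk_size`` tokens with stride ``chunk_size - chunk_overlap`` and keeps
the final partial window.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .ddx import BACTERIAL_SUSPICION, CatalogError, SymptomCatalog
from .model import NoteEvent

SYMPTOM_PROMPT = (
    "You are an ED doctor. Your task is to identify the following abnormal "
    "clinical signs and symptoms: {symptom}. Think step-by-step and provide "
    "your response in the following JSON format: "
    '{{<{symptom}>: ["Yes or No", "Concise justification?"]}} '
    "Medical note: {context}."
)

SEPSIS_PROMPT = (
    "You are an ED doctor. Your task is to identify if sepsis is present in "
    "the current admission. Think step-by-step and provide your response in "
    'the following JSON format: {{"Sepsis": ["Yes or No", "Concise '
    'justification?"]}}. Note that "Sepsis" is defined as suspicion or '
    "documentation of infection with evidence of organ dysfunction. "
    "Medical note: {context}."
)

SEPSIS_KEY = "Sepsis"


def canonical_phrase(symptom: str) -> str:
    """The one planted phrase per symptom the mock extractor keys on.

    Built so that no phrase is a substring of another symptom's phrase.
    """
    return f"sign of {symptom.replace(' + ', ' and ')} recorded"


class RetrievalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chunk_size: int = 1000
    chunk_overlap: int = 300
    top_k: int = 5
    temperature: float = 0.3
    n_votes: int = 3

    @model_validator(mode="after")
    def _check(self) -> "RetrievalConfig":
        if not (0 <= self.chunk_overlap < self.chunk_size):
            raise ValueError("chunk_overlap must satisfy 0 <= overlap < chunk_size")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_votes < 1 or self.n_votes % 2 == 0:
            raise ValueError("n_votes must be odd")
        return self


@dataclass(frozen=True)
class Chunk:
    text: str
    source_note_id: str
    start_token: int
    n_tokens: int


def chunk_notes(notes: Sequence[NoteEvent], config: RetrievalConfig) -> list[Chunk]:
    """Windowed token chunks per note, ordered by (note hour, start token)."""
    stride = config.chunk_size - config.chunk_overlap
    chunks: list[Chunk] = []
    for note in sorted(notes, key=lambda n: (n.hour, n.note_id)):
        tokens = note.text.split()
        if not tokens:
            continue
        start = 0
        while True:
            window = tokens[start : start + config.chunk_size]
            chunks.append(
                Chunk(
                    text=" ".join(window),
                    source_note_id=note.note_id,
                    start_token=start,
                    n_tokens=len(window),
                )
            )
            if start + config.chunk_size >= len(tokens):
                break
            start += stride
    return chunks


class HashingEmbedder:
    """Deterministic hashed bag-of-words embedder for tests and mocks."""

    def __init__(self, dim: int = 512):
        self.dim = dim

    def _index(self, token: str) -> int:
        digest = hashlib.md5(token.lower().encode()).digest()
        return int.from_bytes(digest[:4], "big") % self.dim

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in text.split():
            vec[self._index(token)] += 1.0
        return vec


def retrieve(
    query: str,
    chunks: Sequence[Chunk],
    config: RetrievalConfig,
    embedder: HashingEmbedder,
    chunk_vectors: Optional[Sequence[np.ndarray]] = None,
) -> list[Chunk]:
    """Top-k chunks by cosine similarity to the query embedding.

    Ties (and zero-norm vectors, which score 0) preserve chunk order.
    """
    if not chunks:
        return []
    q = embedder.embed(query)
    qn = np.linalg.norm(q)
    if chunk_vectors is None:
        chunk_vectors = [embedder.embed(c.text) for c in chunks]
    sims = []
    for v in chunk_vectors:
        vn = np.linalg.norm(v)
        sims.append(float(q @ v / (qn * vn)) if qn > 0 and vn > 0 else 0.0)
    order = sorted(range(len(chunks)), key=lambda i: (-sims[i], i))
    return [chunks[i] for i in order[: config.top_k]]


class ExtractorBackend(Protocol):
    def query(self, prompt: str, context: str, temperature: float, seed: int) -> str:
        ...


_PROMPT_SYMPTOM_RE = re.compile(
    r"clinical signs and symptoms: (?P<symptom>.*?)\. Think step-by-step"
)


class MockLLMBackend:
    """Deterministic extractor keyed on the canonical phrase lexicon.

    For a sign query it answers Yes iff the sign's canonical phrase occurs
    in the supplied context; for the direct sepsis query it answers Yes iff
    the bacterial-suspicion phrase occurs.
    """

    def query(self, prompt: str, context: str, temperature: float, seed: int) -> str:
        if "identify if sepsis is present" in prompt:
            hit = canonical_phrase(BACTERIAL_SUSPICION) in context
            return json.dumps(
                {SEPSIS_KEY: ["Yes" if hit else "No", "mock sepsis screen"]}
            )
        m = _PROMPT_SYMPTOM_RE.search(prompt)
        if m is None:
            return "unintelligible"
        symptom = m.group("symptom")
        hit = canonical_phrase(symptom) in context
        justification = (
            f"note contains '{canonical_phrase(symptom)}'" if hit else "no mention found"
        )
        return json.dumps({symptom: ["Yes" if hit else "No", justification]})


class BrokenBackend:
    """Always returns unparseable text; used to exercise the fail-safe path."""

    def query(self, prompt: str, context: str, temperature: float, seed: int) -> str:
        return "this is not JSON {"


@dataclass
class ExtractionResult:
    symptom: str
    present: bool
    justification: str
    votes: list[bool]
    parse_failures: int = 0


def derive_seed(encounter_id: str, symptom: str, run: int) -> int:
    """Stable per-run seed from (encounter, symptom, run index)."""
    digest = hashlib.sha256(f"{encounter_id}|{symptom}|{run}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def _parse_vote(raw: str, key: str) -> tuple[bool, str]:
    obj = json.loads(raw)
    if not isinstance(obj, dict):
        raise ValueError("expected a JSON object")
    for k, v in obj.items():
        if k.strip().lower() == key.strip().lower():
            answer = str(v[0]).strip().lower()
            justification = str(v[1]) if len(v) > 1 else ""
            return answer.startswith("yes"), justification
    raise ValueError(f"key {key!r} missing from output")


def _vote(
    prompt: str,
    key: str,
    context: str,
    config: RetrievalConfig,
    backend: ExtractorBackend,
    encounter_id: str,
) -> tuple[list[bool], str, int]:
    """Run the backend ``n_votes`` times; unparseable runs retry once then
    count as No (fail-safe toward not alerting)."""
    votes: list[bool] = []
    justification = ""
    failures = 0
    for run in range(config.n_votes):
        vote = None
        for attempt in range(2):
            seed = derive_seed(encounter_id, f"{key}#{attempt}", run)
            raw = backend.query(prompt, context, config.temperature, seed)
            try:
                vote, just = _parse_vote(raw, key)
            except (ValueError, KeyError, IndexError, TypeError):
                continue
            if vote and not justification:
                justification = just
            break
        if vote is None:
            failures += 1
            vote = False
        votes.append(vote)
    return votes, justification, failures


def extract_symptom(
    symptom: str,
    notes: Sequence[NoteEvent],
    config: RetrievalConfig,
    backend: ExtractorBackend,
    catalog: Optional[SymptomCatalog] = None,
    embedder: Optional[HashingEmbedder] = None,
    encounter_id: str = "",
    chunks: Optional[Sequence[Chunk]] = None,
    chunk_vectors: Optional[Sequence[np.ndarray]] = None,
) -> ExtractionResult:
    """Retrieve context for one sign and majority-vote its presence."""
    if catalog is not None and symptom not in catalog:
        raise CatalogError(f"unknown symptom: {symptom!r}")
    embedder = embedder or HashingEmbedder()
    if chunks is None:
        chunks = chunk_notes(notes, config)
    selected = retrieve(canonical_phrase(symptom), chunks, config, embedder, chunk_vectors)
    context = "\n".join(c.text for c in selected)
    prompt = SYMPTOM_PROMPT.format(symptom=symptom, context=context)
    votes, justification, failures = _vote(
        prompt, symptom, context, config, backend, encounter_id
    )
    present = sum(votes) * 2 > len(votes)
    return ExtractionResult(
        symptom=symptom,
        present=present,
        justification=justification,
        votes=votes,
        parse_failures=failures,
    )


def extract_all(
    symptoms: Sequence[str],
    notes: Sequence[NoteEvent],
    config: RetrievalConfig,
    backend: ExtractorBackend,
    catalog: Optional[SymptomCatalog] = None,
    embedder: Optional[HashingEmbedder] = None,
    encounter_id: str = "",
) -> tuple[set[str], dict[str, ExtractionResult]]:
    """Extraction results for every queried sign; returns (present-set, results)."""
    embedder = embedder or HashingEmbedder()
    chunks = chunk_notes(notes, config)
    vectors = [embedder.embed(c.text) for c in chunks]
    results: dict[str, ExtractionResult] = {}
    for symptom in symptoms:
        results[symptom] = extract_symptom(
            symptom,
            notes,
            config,
            backend,
            catalog=catalog,
            embedder=embedder,
            encounter_id=encounter_id,
            chunks=chunks,
            chunk_vectors=vectors,
        )
    present = {s for s, r in results.items() if r.present}
    return present, results


def extract_sepsis_direct(
    notes: Sequence[NoteEvent],
    config: RetrievalConfig,
    backend: ExtractorBackend,
    embedder: Optional[HashingEmbedder] = None,
    encounter_id: str = "",
) -> ExtractionResult:
    """Direct yes/no sepsis query over retrieved context (baseline variant)."""
    embedder = embedder or HashingEmbedder()
    chunks = chunk_notes(notes, config)
    selected = retrieve("sepsis infection organ dysfunction", chunks, config, embedder)
    context = "\n".join(c.text for c in selected)
    prompt = SEPSIS_PROMPT.format(context=context)
    votes, justification, failures = _vote(
        prompt, SEPSIS_KEY, context, config, backend, encounter_id
    )
    present = sum(votes) * 2 > len(votes)
    return ExtractionResult(
        symptom=SEPSIS_KEY,
        present=present,
        justification=justification,
        votes=votes,
        parse_failures=failures,
    )
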