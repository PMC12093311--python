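"""Prompt construction, model backends, structured-output parsing, retry.

The generation and proposal prompts are fixed templates with named
placeholders, stored as plain-text files under ``genesetlm/prompts/``.
Backends satisfy a small contract: ``complete(prompt, seed, system_message)``
returning text plus token usage, and ``embed(text)`` returning a
fixed-length vector.  A deterministic fixture backend replays canned
responses keyed on (prompt hash, seed) so every pipeline is testable
offline; a scripted backend generates responses programmatically and is
what the synthetic-data module builds on.

Model output is requested as a fenced JSON code block.  Parsing first
attempts strict JSON, then a small repair pass (trailing commas, quote
normalization, bracket balancing); unrepairable output yields a
``ParseFailure`` which triggers a retry with an incremented seed.
"""

from __future__ import annotations

import hashlib
import json
import re
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

GENE_SET_VARIANTS = ("plain", "reasoning", "confidence")
DEFAULT_BASE_SEED = 42
DEFAULT_MAX_RETRIES = 3
EMBED_DIM = 256


# ---------------------------------------------------------------------------
# Token accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenUsage:
    """Input/output token counts; additive across calls."""

    input_tokens: int = 0
    output_tokens: int = 0

    def __post_init__(self) -> None:
        if self.input_tokens < 0 or self.output_tokens < 0:
            raise ValueError("token counts must be non-negative")

    def __add__(self, other: "TokenUsage") -> "TokenUsage":
        return TokenUsage(
            self.input_tokens + other.input_tokens,
            self.output_tokens + other.output_tokens,
        )

    @property
    def total(self) -> int:
        return self.input_tokens + self.output_tokens


def whitespace_token_count(text: str) -> int:
    """Whitespace-delimited token count; the fixture stand-in for model
    tokenizers (no fidelity to any provider tokenizer is claimed)."""
    return len(text.split())


# ---------------------------------------------------------------------------
# Prompt templates
# ---------------------------------------------------------------------------

def _load_template(name: str) -> str:
    return resources.files("genesetlm.prompts").joinpath(name).read_text(
        encoding="utf-8"
    )


def default_system_message() -> str:
    """The default role prompt (a molecular-biology-expert persona).

    Role prompting is a toggle, not a constant: pass ``system_message=None``
    to backends to disable it.
    """
    return _load_template("system_role.txt").strip()


def render_gene_set_prompt(descr: str, variant: str = "plain") -> str:
    """Render the gene-generation prompt for a gene set description.

    The description is substituted at both placeholder positions of the
    fixed template.  ``reasoning`` additionally requires a one-sentence
    per-gene rationale; ``confidence`` requires a low/medium/high
    per-gene confidence field.
    """
    descr = descr.strip()
    if not descr:
        raise ValueError("gene set description must be non-empty")
    if variant not in GENE_SET_VARIANTS:
        raise ValueError(f"unknown prompt variant {variant!r}")
    template = _load_template(f"gene_set_{variant}.txt")
    return template.format(descr=descr)


def render_proposal_prompt(
    genes: Sequence[str], n_pathways: int, context: str | None = None
) -> str:
    """Render the pathway/process proposal prompt for a gene list.

    Genes are joined comma-separated.  When experimental context is given,
    the context sentence is inserted to steer proposals toward the
    experiment; the generation prompt never sees this context.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    joined = ", ".join(genes)
    if context is not None and context.strip():
        template = _load_template("propose_context.txt")
        return template.format(
            n_pathways=n_pathways, genes=joined, context=context.strip()
        )
    template = _load_template("propose.txt")
    return template.format(n_pathways=n_pathways, genes=joined)


# ---------------------------------------------------------------------------
# Structured-output parsing with repair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsedGeneEntry:
    """One entry of a parsed gene-array payload."""

    gene: str
    reason: str | None = None
    confidence: str | None = None


@dataclass(frozen=True)
class ParsedPayload:
    """Successful parse: entries plus count of dropped malformed entries."""

    entries: tuple
    n_dropped: int = 0
    repaired: bool = False


@dataclass(frozen=True)
class ParseFailure:
    """Unrepairable model output; signals the seed-incrementing retry path."""

    reason: str
    raw: str


_FENCE_RE = re.compile(r"```(?:json)?\s*\n(.*?)```", re.DOTALL)
_TRAILING_COMMA_RE = re.compile(r",(\s*[\]}])")
_CURLY_QUOTES = str.maketrans({"“": '"', "”": '"', "‘": "'", "’": "'"})


def _balance_brackets(text: str) -> str:
    """Append closers for unclosed [ or { outside string literals."""
    stack: list[str] = []
    in_str = False
    escape = False
    for ch in text:
        if in_str:
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_str = False
            continue
        if ch == '"':
            in_str = True
        elif ch in "[{":
            stack.append("]" if ch == "[" else "}")
        elif ch in "]}":
            if stack and stack[-1] == ch:
                stack.pop()
    if in_str:
        text += '"'
    return text + "".join(reversed(stack))


def repair_json(text: str):
    """Best-effort parse of almost-JSON text; returns the object or None.

    Handles the minor formatting errors models commonly make: fenced-block
    wrappers handled upstream, curly quotes, trailing commas, truncated
    output with unclosed brackets, and single-quoted strings.
    """
    candidates = [text]
    text = text.translate(_CURLY_QUOTES)
    candidates.append(text)
    no_trail = _TRAILING_COMMA_RE.sub(r"\1", text)
    candidates.append(no_trail)
    candidates.append(_balance_brackets(no_trail))
    if "'" in text and text.count('"') < 2:
        swapped = _TRAILING_COMMA_RE.sub(r"\1", text.replace("'", '"'))
        candidates.append(swapped)
        candidates.append(_balance_brackets(swapped))
    start = text.find("[")
    end = text.rfind("]")
    if start != -1 and end > start:
        inner = _TRAILING_COMMA_RE.sub(r"\1", text[start : end + 1])
        candidates.append(inner)
    elif start != -1:
        candidates.append(_balance_brackets(_TRAILING_COMMA_RE.sub(r"\1", text[start:])))
    for cand in candidates:
        try:
            return json.loads(cand)
        except (json.JSONDecodeError, RecursionError):
            continue
    return None


def _extract_block(response: str) -> str:
    match = _FENCE_RE.search(response)
    return match.group(1) if match else response


def parse_structured_block(response: str, expect: str) -> ParsedPayload | ParseFailure:
    """Parse a model response into a gene or pathway payload.

    ``expect`` is ``gene_array`` (objects with "gene" plus optional
    "reason"/"confidence") or ``pathway_array`` (objects with "p").
    Never raises on arbitrary text: unrepairable content returns a
    ``ParseFailure`` so the caller can retry with a new seed.
    """
    if expect not in ("gene_array", "pathway_array"):
        raise ValueError(f"unknown payload kind {expect!r}")
    block = _extract_block(response).strip()
    if not block:
        return ParseFailure(reason="empty response", raw=response)
    try:
        obj = json.loads(block)
        repaired = False
    except (json.JSONDecodeError, RecursionError):
        obj = repair_json(block)
        repaired = True
        if obj is None:
            return ParseFailure(reason="unrepairable JSON", raw=response)
    if isinstance(obj, dict):
        # some models wrap the array in a single-key object
        lists = [v for v in obj.values() if isinstance(v, list)]
        obj = lists[0] if lists else None
    if not isinstance(obj, list):
        return ParseFailure(reason="payload is not a JSON array", raw=response)

    n_dropped = 0
    if expect == "pathway_array":
        descrs: list[str] = []
        for item in obj:
            if isinstance(item, dict) and isinstance(item.get("p"), str) and item["p"].strip():
                descrs.append(item["p"].strip())
            elif isinstance(item, str) and item.strip():
                descrs.append(item.strip())
            else:
                n_dropped += 1
        return ParsedPayload(tuple(descrs), n_dropped=n_dropped, repaired=repaired)

    entries: list[ParsedGeneEntry] = []
    for item in obj:
        if isinstance(item, dict) and isinstance(item.get("gene"), str) and item["gene"].strip():
            conf = item.get("confidence")
            entries.append(
                ParsedGeneEntry(
                    gene=item["gene"].strip(),
                    reason=item.get("reason") if isinstance(item.get("reason"), str) else None,
                    confidence=conf.strip().lower() if isinstance(conf, str) else None,
                )
            )
        elif isinstance(item, str) and item.strip():
            entries.append(ParsedGeneEntry(gene=item.strip()))
        else:
            n_dropped += 1
    return ParsedPayload(tuple(entries), n_dropped=n_dropped, repaired=repaired)


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------

class BackendError(RuntimeError):
    """Transport- or fixture-level failure of a backend call."""


class TerminalGenerationError(RuntimeError):
    """All retries exhausted for one prompt."""

    def __init__(self, prompt: str, attempts: int, last_response: str | None):
        self.prompt = prompt
        self.attempts = attempts
        self.last_response = last_response
        head = prompt.splitlines()[0][:80] if prompt else ""
        super().__init__(
            f"generation failed after {attempts} attempt(s) for prompt starting: {head!r}"
        )


class Backend(Protocol):
    """Contract every model backend satisfies (live or fixture)."""

    embed_dim: int

    def complete(
        self, prompt: str, seed: int, system_message: str | None = None
    ) -> tuple[str, TokenUsage]: ...

    def embed(self, text: str) -> np.ndarray: ...


def prompt_hash(prompt: str) -> str:
    """Stable short hash used to key fixture responses."""
    return hashlib.sha256(prompt.encode("utf-8")).hexdigest()[:16]


def hashed_ngram_embedding(text: str, dim: int = EMBED_DIM, n: int = 3) -> np.ndarray:
    """Deterministic hashed character-n-gram embedding, unit-normalized.

    A transparent stand-in for a neural text embedding: identical strings
    embed identically (cosine 1), strings sharing no character n-grams are
    orthogonal, and lexical overlap varies the cosine in between.
    """
    text = " " + text.lower().strip() + " "
    vec = np.zeros(dim, dtype=np.float64)
    for i in range(max(1, len(text) - n + 1)):
        gram = text[i : i + n]
        idx = zlib.crc32(gram.encode("utf-8")) % dim
        # sign hashing reduces accidental collisions inflating similarity
        sign = 1.0 if zlib.crc32(b"s" + gram.encode("utf-8")) % 2 == 0 else -1.0
        vec[idx] += sign
    norm = np.linalg.norm(vec)
    if norm == 0:
        vec[0] = 1.0
        return vec
    return vec / norm


class _EmbeddingMixin:
    embed_dim: int = EMBED_DIM
    embedding_overrides: Mapping[str, Sequence[float]] | None = None

    def embed(self, text: str) -> np.ndarray:
        if self.embedding_overrides is not None and text in self.embedding_overrides:
            vec = np.asarray(self.embedding_overrides[text], dtype=np.float64)
            norm = np.linalg.norm(vec)
            return vec / norm if norm else vec
        return hashed_ngram_embedding(text, dim=self.embed_dim)


class FixtureBackend(_EmbeddingMixin):
    """Replays canned responses keyed on (prompt hash, seed).

    Deterministic: identical (prompt, seed, system_message) always return
    byte-identical text.  A missing key raises ``BackendError`` (treated
    like a transport failure, hence retried with the next seed).
    """

    def __init__(
        self,
        responses: Mapping[tuple[str, int], str],
        embed_dim: int = EMBED_DIM,
        embedding_overrides: Mapping[str, Sequence[float]] | None = None,
    ) -> None:
        self._responses = dict(responses)
        self.embed_dim = embed_dim
        self.embedding_overrides = embedding_overrides
        self.transcript: list[tuple[str, int, str]] = []

    @classmethod
    def from_prompt_responses(
        cls, entries: Sequence[tuple[str, int, str]], **kwargs
    ) -> "FixtureBackend":
        """Build from (full prompt text, seed, response) triples."""
        return cls({(prompt_hash(p), s): r for p, s, r in entries}, **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "FixtureBackend":
        """Load a fixture file: prompt_hash TAB seed TAB json-encoded response."""
        responses: dict[tuple[str, int], str] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                h, seed, payload = line.rstrip("\n").split("\t", 2)
                responses[(h, int(seed))] = json.loads(payload)
        return cls(responses, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{h}\t{seed}\t{json.dumps(resp)}"
            for (h, seed), resp in sorted(self._responses.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def complete(
        self, prompt: str, seed: int, system_message: str | None = None
    ) -> tuple[str, TokenUsage]:
        key = (prompt_hash(prompt), seed)
        if key not in self._responses:
            raise BackendError(f"no fixture response for prompt hash {key[0]} seed {seed}")
        response = self._responses[key]
        self.transcript.append((key[0], seed, response))
        n_in = whitespace_token_count(prompt) + (
            whitespace_token_count(system_message) if system_message else 0
        )
        return response, TokenUsage(n_in, whitespace_token_count(response))


class ScriptedBackend(_EmbeddingMixin):
    """Generates responses from a deterministic function of (prompt, seed).

    The synthetic-data module uses this to emulate a language model with
    planted statistical structure; any pure function works.
    """

    def __init__(
        self,
        script: Callable[[str, int], str],
        embed_dim: int = EMBED_DIM,
        embedding_overrides: Mapping[str, Sequence[float]] | None = None,
    ) -> None:
        self._script = script
        self.embed_dim = embed_dim
        self.embedding_overrides = embedding_overrides
        self.transcript: list[tuple[str, int, str]] = []

    def complete(
        self, prompt: str, seed: int, system_message: str | None = None
    ) -> tuple[str, TokenUsage]:
        response = self._script(prompt, seed)
        self.transcript.append((prompt_hash(prompt), seed, response))
        n_in = whitespace_token_count(prompt) + (
            whitespace_token_count(system_message) if system_message else 0
        )
        return response, TokenUsage(n_in, whitespace_token_count(response))


class OpenAIBackend(_EmbeddingMixin):
    """Live backend over the OpenAI chat/embeddings APIs.

    Requires the optional ``openai`` dependency and credentials in the
    environment; never exercised by the offline test suite.
    """

    def __init__(
        self,
        model: str = "gpt-4o-2024-08-06",
        embedding_model: str = "text-embedding-3-small",
        embed_dim: int = 1536,
    ) -> None:
        try:
            from openai import OpenAI
        except ImportError as exc:  # pragma: no cover - live only
            raise ImportError(
                "the live backend requires the optional 'openai' dependency "
                "(pip install genesetlm[live])"
            ) from exc
        self._client = OpenAI()
        self.model = model
        self.embedding_model = embedding_model
        self.embed_dim = embed_dim
        self.transcript: list[tuple[str, int, str]] = []

    def complete(
        self, prompt: str, seed: int, system_message: str | None = None
    ) -> tuple[str, TokenUsage]:  # pragma: no cover - live only
        messages = []
        if system_message:
            messages.append({"role": "system", "content": system_message})
        messages.append({"role": "user", "content": prompt})
        try:
            resp = self._client.chat.completions.create(
                model=self.model, messages=messages, seed=seed
            )
        except Exception as exc:
            raise BackendError(str(exc)) from exc
        text = resp.choices[0].message.content or ""
        usage = TokenUsage(resp.usage.prompt_tokens, resp.usage.completion_tokens)
        self.transcript.append((prompt_hash(prompt), seed, text))
        return text, usage

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - live only
        if self.embedding_overrides is not None and text in self.embedding_overrides:
            return super().embed(text)
        resp = self._client.embeddings.create(model=self.embedding_model, input=[text])
        vec = np.asarray(resp.data[0].embedding, dtype=np.float64)
        return vec / np.linalg.norm(vec)


# ---------------------------------------------------------------------------
# Retry loop
# ---------------------------------------------------------------------------

def call_with_retry(
    backend: Backend,
    prompt: str,
    expect: str,
    base_seed: int = DEFAULT_BASE_SEED,
    max_retries: int = DEFAULT_MAX_RETRIES,
    system_message: str | None = None,
) -> tuple[ParsedPayload, int, TokenUsage]:
    """Issue a prompt, retrying unparseable output with incremented seeds.

    Attempt ``i`` uses seed ``base_seed + i - 1``.  Token usage accumulates
    across all attempts (failed ones included — they were paid for).
    Returns (payload, attempts, usage) or raises ``TerminalGenerationError``.
    """
    if max_retries < 1:
        raise ValueError("max_retries must be >= 1")
    usage = TokenUsage()
    last_response: str | None = None
    for attempt in range(1, max_retries + 1):
        seed = base_seed + attempt - 1
        try:
            response, call_usage = backend.complete(prompt, seed, system_message)
        except BackendError:
            continue
        usage = usage + call_usage
        last_response = response
        result = parse_structured_block(response, expect)
        if isinstance(result, ParsedPayload):
            return result, attempt, usage
    raise TerminalGenerationError(prompt, max_retries, last_response)
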