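"""Synthetic universes, databases, queries, and mock language models.

Everything here is a pure function of its configuration and seed, so the
whole pipeline is testable offline and byte-reproducibly.  The mock
backend emulates the *statistical* behaviour of a language model asked to
generate a gene set: for a known description it returns a controlled
mixture of true members (planting a recall) and decoy genes (planting a
precision), varying with the request seed the way repeated sampled
generations would.  It makes no attempt to mimic linguistic variation —
descriptions are synthetic multi-word labels, useful for n-gram and
embedding metrics only as distinct tokens.

A malformed mode emits broken JSON payloads (trailing commas, missing
code fences, unparseable text) at a configured rate to exercise the
repair and seed-incrementing retry paths.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genesets import GeneSet, GeneSetDatabase, SymbolTable
from .llm_interface import ScriptedBackend

_DESCR_RE = re.compile(r'"""(.*?)"""', re.DOTALL)
_PROPOSE_RE = re.compile(r"^List (\d+) biological pathways", re.MULTILINE)

# word pool for synthetic descriptions: varied enough for n-gram metrics
_WORDS = (
    "regulation activation signaling transport response assembly repair "
    "biosynthesis degradation adhesion differentiation proliferation "
    "membrane nuclear mitochondrial ribosomal cytoskeletal synaptic immune "
    "metabolic oxidative inflammatory apoptotic autophagic lysosomal"
).split()


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic benchmark."""

    universe_size: int = 10_000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (20, 80)
    planted_precision: float = 0.8
    planted_recall: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.planted_precision <= 1.0):
            raise ValueError("planted_precision must be in (0, 1]")
        if not (0.0 < self.planted_recall <= 1.0):
            raise ValueError("planted_recall must be in (0, 1]")
        if self.set_size_range[1] > self.universe_size:
            raise ValueError("set sizes cannot exceed universe size")


def synth_universe(n: int, seed: int = 0) -> SymbolTable:
    """A universe of n synthetic gene symbols (deterministic naming)."""
    if n < 1:
        raise ValueError("universe size must be >= 1")
    width = max(5, len(str(n)))
    return SymbolTable(approved={f"SYNG{i:0{width}d}" for i in range(n)})


def _universe_list(universe: SymbolTable) -> list[str]:
    return sorted(universe.approved)


def synth_database(
    universe: SymbolTable,
    n_sets: int,
    size_range: tuple[int, int] = (20, 80),
    seed: int = 0,
    source_label: str = "synthetic",
) -> GeneSetDatabase:
    """Curated-style database: seeded random sets with multi-word names.

    Set sizes are uniform over ``size_range`` (the default brackets the
    median sizes of common curated pathway libraries); members are drawn
    without replacement per set from the universe.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    if hi > len(universe):
        raise ValueError("max set size exceeds universe size")
    rng = np.random.default_rng([seed, 0xDB])
    pool = _universe_list(universe)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(pool, size=size, replace=False))
        w1 = _WORDS[int(rng.integers(len(_WORDS)))]
        w2 = _WORDS[int(rng.integers(len(_WORDS)))]
        descr = f"{w1} of {w2} process {i:03d}"
        sets.append(GeneSet(description=descr, genes=members))
    return GeneSetDatabase(sets, universe=universe.approved, source_label=source_label)


def randomize_database_members(db: GeneSetDatabase, seed: int = 0) -> GeneSetDatabase:
    """Null counterpart of a database: same descriptions and set sizes,
    members resampled uniformly from the universe.

    Severs the description-membership link, so any benchmark run against
    the original database should show only alpha-level significance.
    """
    rng = np.random.default_rng([seed, 0x0])
    pool = sorted(db.universe)
    sets = []
    for descr in db.descriptions:
        size = len(db[descr])
        members = list(rng.choice(pool, size=size, replace=False))
        sets.append(GeneSet(description=descr, genes=members))
    return GeneSetDatabase(sets, universe=db.universe, source_label="randomized")


def synth_query(
    db: GeneSetDatabase,
    source_descriptions: Sequence[str],
    n_noise: int = 0,
    seed: int = 0,
    subsample_frac: float = 1.0,
) -> list[str]:
    """A query gene list: union of source-set members plus noise genes.

    Emulates a differential-expression hit list driven by the source
    processes, contaminated by ``n_noise`` unrelated genes from the
    universe.  ``subsample_frac`` < 1 keeps a random fraction of the union
    (not every member of a perturbed pathway responds).
    """
    missing = [d for d in source_descriptions if d not in db]
    if missing:
        raise ValueError(f"source descriptions not in database: {missing[:5]}")
    if not (0.0 < subsample_frac <= 1.0):
        raise ValueError("subsample_frac must be in (0, 1]")
    rng = np.random.default_rng([seed, 0x5E])
    union = sorted({g for d in source_descriptions for g in db[d].genes})
    if subsample_frac < 1.0:
        keep = max(1, round(subsample_frac * len(union)))
        idx = rng.choice(len(union), size=keep, replace=False)
        union = [union[i] for i in sorted(idx)]
    query = list(union)
    if n_noise > 0:
        outside = sorted(db.universe - {g for d in source_descriptions for g in db[d].genes})
        if n_noise > len(outside):
            raise ValueError("not enough universe genes outside the sources for noise")
        idx = rng.choice(len(outside), size=n_noise, replace=False)
        query += [outside[i] for i in sorted(idx)]
    return query


def _descr_seed(global_seed: int, descr: str, call_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        [global_seed & 0x7FFFFFFF, zlib.crc32(descr.encode("utf-8")), call_seed & 0x7FFFFFFF]
    )


def synth_llm_fixture(
    db: GeneSetDatabase,
    precision: float = 0.8,
    recall: float = 0.6,
    confidence_mix: tuple[float, float] | None = None,
    seed: int = 0,
    proposals: Sequence[str] | None = None,
    malformed_rate: float = 0.0,
    embedding_overrides=None,
) -> ScriptedBackend:
    """A scripted backend emulating gene set generation with planted
    precision and recall.

    For the gene-generation prompt of a description in ``db``, the
    response contains ``round(recall * |ref|)`` true members plus decoys
    from outside the reference so that true/(true+decoys) ≈ ``precision``;
    the sample varies with the request seed, as repeated model generations
    would.  When the prompt requests confidence labels, true members are
    labelled "high" with probability ``confidence_mix[0]`` (else medium)
    and decoys with probability ``confidence_mix[1]`` (else low).  The
    proposal prompt is answered with ``proposals`` (default: every
    database description, truncated to the requested count).

    ``malformed_rate`` > 0 makes responses malformed at that rate,
    cycling through trailing-comma (repairable), fence-missing
    (parseable), and plain-text (unrepairable, forcing a retry) payloads.
    """
    if not (0.0 < precision <= 1.0) or not (0.0 < recall <= 1.0):
        raise ValueError("precision and recall must be in (0, 1]")
    if not (0.0 <= malformed_rate <= 1.0):
        raise ValueError("malformed_rate must be in [0, 1]")
    conf_true, conf_decoy = confidence_mix if confidence_mix else (0.9, 0.1)
    pool = sorted(db.universe)
    # feasibility: worst-case decoy demand per set
    for descr in db.descriptions:
        ref_size = len(db[descr])
        n_true = max(1, round(recall * ref_size)) if ref_size else 0
        n_decoy = round(n_true / precision) - n_true
        if n_decoy > len(pool) - ref_size:
            raise ValueError(
                f"precision {precision} needs {n_decoy} decoys for {descr!r} "
                f"but only {len(pool) - ref_size} genes lie outside it"
            )
    default_proposals = list(proposals) if proposals is not None else db.descriptions

    def script(prompt: str, call_seed: int) -> str:
        propose_match = _PROPOSE_RE.search(prompt)
        if propose_match:
            n_req = int(propose_match.group(1))
            payload = [{"p": d} for d in default_proposals[:n_req]]
            return "```json\n" + json.dumps(payload) + "\n```"
        descr_match = _DESCR_RE.search(prompt)
        if not descr_match or descr_match.group(1) not in db:
            return "Sorry, I do not recognize this request."
        descr = descr_match.group(1)
        ref = db[descr].genes
        rng = _descr_seed(seed, descr, call_seed)
        n_true = max(1, round(recall * len(ref))) if ref else 0
        n_decoy = round(n_true / precision) - n_true
        true_idx = rng.choice(len(ref), size=n_true, replace=False)
        true_genes = [ref[i] for i in sorted(true_idx)]
        refset = set(ref)
        outside = [g for g in pool if g not in refset]
        decoy_idx = rng.choice(len(outside), size=n_decoy, replace=False)
        decoys = [outside[i] for i in sorted(decoy_idx)]
        want_conf = '"confidence"' in prompt
        want_reason = '"reason"' in prompt
        entries = []
        for g in true_genes:
            e: dict = {"gene": g}
            if want_reason:
                e["reason"] = f"{g} participates in {descr}."
            if want_conf:
                e["confidence"] = "high" if rng.random() < conf_true else "medium"
            entries.append(e)
        for g in decoys:
            e = {"gene": g}
            if want_reason:
                e["reason"] = f"{g} is linked to {descr}."
            if want_conf:
                e["confidence"] = "high" if rng.random() < conf_decoy else "low"
            entries.append(e)
        order = rng.permutation(len(entries))
        entries = [entries[i] for i in order]
        body = json.dumps(entries)
        if malformed_rate > 0 and rng.random() < malformed_rate:
            kind = ("trailing_comma", "no_fence", "garbage")[int(rng.integers(3))]
            if kind == "trailing_comma":
                return "```json\n" + body[:-1] + ",]\n```"
            if kind == "no_fence":
                return "Here are the genes: " + body
            return "I am sorry, I cannot list genes for that."
        return "```json\n" + body + "\n```"

    return ScriptedBackend(script, embedding_overrides=embedding_overrides)
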