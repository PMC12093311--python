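"""Gene set generation from natural-language descriptions.

Four strategies are supported:

* ``plain`` — the base prompt, one generation.
* ``reasoning`` — the prompt additionally requires a one-sentence rationale
  per gene; rationales are recorded but do not filter the set.
* ``confidence`` — the prompt requires a per-gene low/medium/high confidence
  label; only genes at or above a threshold level (default: high only) are
  kept.
* ``ensemble`` — the plain prompt is run with several seeds and only genes
  recurring in a consensus fraction of runs are kept.  With a consensus of
  1.0 (the default) this is the strict intersection across runs, so the
  result is never larger than the smallest individual run — recurrence
  across seeds acts as an implicit confidence signal and raises precision.

Generated symbols are deduplicated and validated against an approved-symbol
table; duplicate and invalid counts are retained as model-quality metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .genesets import GeneSet, SymbolTable, dedup_symbols, normalize_symbol
from .llm_interface import (
    Backend,
    DEFAULT_BASE_SEED,
    DEFAULT_MAX_RETRIES,
    ParsedGeneEntry,
    TerminalGenerationError,
    TokenUsage,
    call_with_retry,
    render_gene_set_prompt,
)

STRATEGIES = ("plain", "reasoning", "confidence", "ensemble")
_CONFIDENCE_LEVELS = {"low": 0, "medium": 1, "high": 2}


@dataclass
class GenerationRecord:
    """Everything produced while turning one description into a gene set.

    ``raw_genes`` keeps the parsed entries of every run (including invalid
    and filtered-out symbols) for audit; ``final_genes`` is the
    deduplicated, validated, strategy-filtered result used downstream.
    """

    description: str
    raw_genes: list[list[ParsedGeneEntry]]
    final_genes: list[str]
    n_duplicates: int
    n_invalid: int
    strategy: str
    n_runs: int
    usage: TokenUsage
    attempts: int
    n_failed_runs: int = 0

    @property
    def is_empty(self) -> bool:
        return not self.final_genes

    def to_gene_set(self) -> GeneSet:
        return GeneSet(description=self.description, genes=list(self.final_genes))


def _finalize(
    entries: Sequence[ParsedGeneEntry], table: SymbolTable | None
) -> tuple[list[str], int, int]:
    """Dedup then validate; returns (final, n_duplicates, n_invalid)."""
    unique, n_dup = dedup_symbols(e.gene for e in entries)
    if table is None:
        return unique, n_dup, 0
    final = []
    n_invalid = 0
    for sym in unique:
        resolved = table.resolve(sym)
        if resolved is None:
            n_invalid += 1
        elif resolved not in final:
            final.append(resolved)
    return final, n_dup, n_invalid


def generate_gene_set(
    backend: Backend,
    descr: str,
    strategy: str = "plain",
    table: SymbolTable | None = None,
    seed: int = DEFAULT_BASE_SEED,
    confidence_threshold: str = "high",
    max_retries: int = DEFAULT_MAX_RETRIES,
    system_message: str | None = None,
) -> GenerationRecord:
    """Generate one gene set from a description with a single-run strategy.

    ``confidence_threshold`` applies only to the confidence strategy and
    keeps entries at or above that level ("high" keeps high only; "medium"
    keeps medium+high; "low" keeps all labelled entries).
    """
    if strategy not in ("plain", "reasoning", "confidence"):
        raise ValueError(
            f"strategy {strategy!r} is not a single-run strategy "
            "(use generate_gene_set_ensemble for ensembling)"
        )
    if confidence_threshold not in _CONFIDENCE_LEVELS:
        raise ValueError(f"unknown confidence threshold {confidence_threshold!r}")
    prompt = render_gene_set_prompt(descr, variant=strategy)
    payload, attempts, usage = call_with_retry(
        backend,
        prompt,
        expect="gene_array",
        base_seed=seed,
        max_retries=max_retries,
        system_message=system_message,
    )
    entries = list(payload.entries)
    kept = entries
    if strategy == "confidence":
        floor = _CONFIDENCE_LEVELS[confidence_threshold]
        kept = [
            e
            for e in entries
            if e.confidence is not None and _CONFIDENCE_LEVELS.get(e.confidence, -1) >= floor
        ]
    final, n_dup, n_invalid = _finalize(kept, table)
    return GenerationRecord(
        description=descr.strip(),
        raw_genes=[entries],
        final_genes=final,
        n_duplicates=n_dup,
        n_invalid=n_invalid,
        strategy=strategy,
        n_runs=1,
        usage=usage,
        attempts=attempts,
    )


def generate_gene_set_ensemble(
    backend: Backend,
    descr: str,
    n_runs: int = 5,
    consensus_frac: float = 1.0,
    table: SymbolTable | None = None,
    base_seed: int = DEFAULT_BASE_SEED,
    max_retries: int = DEFAULT_MAX_RETRIES,
    system_message: str | None = None,
) -> GenerationRecord:
    """Generate a consensus gene set from repeated seeded generations.

    Runs the plain prompt with seeds ``base_seed .. base_seed+n_runs-1``
    and keeps genes appearing in at least ``ceil(consensus_frac * n_runs)``
    successful runs.  A run whose retries are exhausted is excluded
    (recorded in ``n_failed_runs``); if every run fails the error
    propagates.
    """
    if n_runs < 2:
        raise ValueError("ensembling requires n_runs >= 2")
    if not (0.0 < consensus_frac <= 1.0):
        raise ValueError("consensus_frac must be in (0, 1]")
    prompt = render_gene_set_prompt(descr, variant="plain")
    per_run: list[list[ParsedGeneEntry]] = []
    usage = TokenUsage()
    attempts_total = 0
    n_failed = 0
    last_error: TerminalGenerationError | None = None
    for i in range(n_runs):
        try:
            payload, attempts, run_usage = call_with_retry(
                backend,
                prompt,
                expect="gene_array",
                base_seed=base_seed + i,
                max_retries=max_retries,
                system_message=system_message,
            )
        except TerminalGenerationError as exc:
            n_failed += 1
            last_error = exc
            continue
        per_run.append(list(payload.entries))
        usage = usage + run_usage
        attempts_total += attempts
    if not per_run:
        assert last_error is not None
        raise last_error
    n_eff = len(per_run)
    needed = math.ceil(consensus_frac * n_eff)
    counts: dict[str, int] = {}
    order: list[str] = []
    for entries in per_run:
        run_syms, _ = dedup_symbols(e.gene for e in entries)
        for sym in run_syms:
            if sym not in counts:
                counts[sym] = 0
                order.append(sym)
            counts[sym] += 1
    consensus = [s for s in order if counts[s] >= needed]
    final, _, n_invalid = _finalize([ParsedGeneEntry(gene=s) for s in consensus], table)
    n_dup = sum(dedup_symbols(e.gene for e in entries)[1] for entries in per_run)
    return GenerationRecord(
        description=descr.strip(),
        raw_genes=per_run,
        final_genes=final,
        n_duplicates=n_dup,
        n_invalid=n_invalid,
        strategy="ensemble",
        n_runs=n_eff,
        usage=usage,
        attempts=attempts_total,
        n_failed_runs=n_failed,
    )
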