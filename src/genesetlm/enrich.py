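"""Hypergeometric overrepresentation analysis and the end-to-end pipeline.

The model: a query list D of |D| genes is drawn from a background universe
of B genes; a gene set G has |G| members in that universe.  Under the null
that D is a uniform draw, the overlap k = |D ∩ G| follows a hypergeometric
distribution, and the enrichment p-value is the upper tail

    p = P(X >= k),  X ~ Hypergeom(population B, successes |G|, draws |D|),

identical to a one-tailed Fisher's exact test on the 2x2 overlap table.
P-values across the tested sets of one run are adjusted by
Benjamini-Hochberg (q-values, the default) or Bonferroni.

The pipeline couples this to the language-model stages: propose candidate
descriptions from the query genes (optionally steered by experimental
context), generate each gene set blindly from its description alone, then
test the query for overrepresentation in every generated set.  Because
generation sees neither the query genes nor the context, steering can only
change which hypotheses are tested, never the gene sets themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genesets import GeneSet, GeneSetDatabase, SymbolTable, dedup_symbols
from .generate import GenerationRecord, generate_gene_set, generate_gene_set_ensemble
from .llm_interface import Backend, DEFAULT_BASE_SEED, TokenUsage
from .propose import ProposalResult, propose_gene_sets

CORRECTIONS = ("bh", "bonferroni")


@dataclass(frozen=True)
class ORAParams:
    """Parameters of one overrepresentation run.

    ``background_size`` is the hypergeometric population size B — the
    number of genes the query and the sets are considered drawn from
    (e.g. ~20000 protein-coding genes, or the size of an approved-symbol
    universe).  ``None`` defers to the database universe size.
    """

    background_size: int | None = None
    alpha: float = 0.01
    correction: str = "bh"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"correction must be one of {CORRECTIONS}")
        if self.background_size is not None and self.background_size < 1:
            raise ValueError("background_size must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set outcome of an overrepresentation test."""

    description: str
    set_size: int
    query_size: int
    overlap: int
    overlap_genes: tuple[str, ...]
    p_value: float
    q_value: float
    fold_enrichment: float
    significant: bool


def hypergeom_p(k: int, set_size: int, query_size: int, background: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    Population ``background``, ``set_size`` successes, ``query_size``
    draws.  Symmetric in (set_size, query_size), and equal to the
    one-tailed Fisher exact p of the corresponding 2x2 table.
    """
    if background < set_size:
        raise ValueError(f"background ({background}) < set_size ({set_size})")
    if background < query_size:
        raise ValueError(f"background ({background}) < query_size ({query_size})")
    if k < 0:
        raise ValueError(f"overlap k ({k}) is negative")
    if k > min(set_size, query_size):
        raise ValueError(
            f"overlap k ({k}) exceeds min(set_size={set_size}, query_size={query_size})"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); the k=0 edge is handled above
    return float(stats.hypergeom.sf(k - 1, background, set_size, query_size))


def fold_enrichment(k: int, set_size: int, query_size: int, background: int) -> float:
    """Observed over expected overlap: (k/|D|) / (|G|/B)."""
    if query_size <= 0:
        raise ValueError("query_size must be positive")
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if background <= 0:
        raise ValueError("background must be positive")
    return (k / query_size) / (set_size / background)


def adjust_pvalues(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, p*m).  ``bh``: Benjamini-Hochberg step-up with
    enforced monotonicity (q of the i-th smallest p is
    min over j>=i of p_(j)*m/j, capped at 1).
    """
    if method not in CORRECTIONS:
        raise ValueError(f"method must be one of {CORRECTIONS}")
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return list(np.minimum(1.0, p * m))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    # guard the q >= p invariant against float rounding in (p*m)/rank
    return list(np.maximum(q, p))


def run_ora(
    query: Sequence[str],
    db: GeneSetDatabase,
    params: ORAParams = ORAParams(),
) -> list[EnrichmentResult]:
    """Test a query gene list against every set of a database.

    Query symbols are normalized and deduplicated; genes outside the
    database universe are dropped before testing (the hypergeometric model
    requires all counts within one population).  Results are sorted by
    ascending p-value with ties broken by description.
    """
    if len(db) == 0:
        return []
    query_unique, _ = dedup_symbols(query)
    filtered = [g for g in query_unique if g in db.universe]
    background = params.background_size or len(db.universe)
    max_set = max((len(gs) for gs in db.sets.values()), default=0)
    if background < len(filtered) or background < max_set:
        raise ValueError(
            f"background ({background}) smaller than query ({len(filtered)}) "
            f"or largest set ({max_set})"
        )
    query_set = set(filtered)
    rows = []
    for descr, gs in db.sets.items():
        overlap = [g for g in gs.genes if g in query_set]
        k = len(overlap)
        p = hypergeom_p(k, len(gs), len(filtered), background)
        if len(gs) > 0 and len(filtered) > 0:
            fe = fold_enrichment(k, len(gs), len(filtered), background)
        else:
            fe = 0.0
        rows.append((descr, gs, overlap, k, p, fe))
    q_values = adjust_pvalues([r[4] for r in rows], method=params.correction)
    results = [
        EnrichmentResult(
            description=descr,
            set_size=len(gs),
            query_size=len(filtered),
            overlap=k,
            overlap_genes=tuple(overlap),
            p_value=p,
            q_value=q,
            fold_enrichment=fe,
            significant=q < params.alpha,
        )
        for (descr, gs, overlap, k, p, fe), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.description))
    return results


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage label and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineResult:
    """All three layers of one pipeline run, kept for audit."""

    proposals: ProposalResult
    database: GeneSetDatabase
    results: list[EnrichmentResult]
    records: list[GenerationRecord] = field(default_factory=list)

    @property
    def usage(self) -> TokenUsage:
        total = self.proposals.usage
        for rec in self.records:
            total = total + rec.usage
        return total


def run_pipeline(
    backend: Backend,
    query: Sequence[str],
    n_pathways: int,
    context: str | None = None,
    params: ORAParams = ORAParams(),
    gen_strategy: str = "plain",
    table: SymbolTable | None = None,
    seed: int = DEFAULT_BASE_SEED,
    n_runs: int = 5,
    consensus_frac: float = 1.0,
    system_message: str | None = None,
) -> PipelineResult:
    """Propose descriptions for the query, generate their gene sets blindly,
    and test the query for overrepresentation in each.

    The generation stage receives each proposed description alone — no
    query genes and no context — so the generated database cannot be
    steered toward the query.  The ORA universe is the generated gene
    union plus the query (or the symbol table when provided); the
    hypergeometric population size is ``params.background_size``.
    """
    if not query:
        raise ValueError("query gene list must be non-empty")
    query_unique, _ = dedup_symbols(query)
    try:
        proposals = propose_gene_sets(
            backend,
            query_unique,
            n_pathways,
            context=context,
            seed=seed,
            system_message=system_message,
        )
    except Exception as exc:
        raise PipelineStageError("propose", exc) from exc

    records: list[GenerationRecord] = []
    try:
        for descr in proposals.descriptions:
            if gen_strategy == "ensemble":
                rec = generate_gene_set_ensemble(
                    backend,
                    descr,
                    n_runs=n_runs,
                    consensus_frac=consensus_frac,
                    table=table,
                    base_seed=seed,
                    system_message=system_message,
                )
            else:
                rec = generate_gene_set(
                    backend,
                    descr,
                    strategy=gen_strategy,
                    table=table,
                    seed=seed,
                    system_message=system_message,
                )
            records.append(rec)
    except Exception as exc:
        raise PipelineStageError("generate", exc) from exc

    if table is not None:
        universe = set(table.approved)
    else:
        universe = set(query_unique)
        for rec in records:
            universe.update(rec.final_genes)
    try:
        db = GeneSetDatabase(
            (rec.to_gene_set() for rec in records),
            universe=universe,
            source_label="generated",
        )
        results = run_ora(query_unique, db, params)
    except Exception as exc:
        raise PipelineStageError("ora", exc) from exc
    return PipelineResult(
        proposals=proposals, database=db, results=results, records=records
    )
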