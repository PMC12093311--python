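"""Proposal of candidate pathway/process descriptions for a gene list.

Given a query gene list (typically differentially expressed genes) the
backend is asked to name the biological pathways, processes, or cellular
components the genes belong to.  Free-text experimental context, when
supplied, steers the proposals toward the experiment; downstream gene set
generation never sees that context, so steering affects only which
hypotheses are tested, not the gene sets themselves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .llm_interface import (
    Backend,
    DEFAULT_BASE_SEED,
    DEFAULT_MAX_RETRIES,
    TokenUsage,
    call_with_retry,
    render_proposal_prompt,
)


@dataclass
class ProposalResult:
    """Ordered, case-insensitively deduplicated proposed descriptions.

    ``undercount`` flags a backend that returned fewer distinct
    descriptions than requested (accepted as-is, not re-queried);
    over-long returns are truncated to the first ``requested_n`` in listed
    order, treating the model's ordering as an implicit ranking.
    """

    descriptions: list[str]
    requested_n: int
    usage: TokenUsage
    attempts: int
    undercount: bool = False
    echoed_inputs: list[str] | None = None


def propose_gene_sets(
    backend: Backend,
    genes: Sequence[str],
    n_pathways: int,
    context: str | None = None,
    seed: int = DEFAULT_BASE_SEED,
    max_retries: int = DEFAULT_MAX_RETRIES,
    system_message: str | None = None,
) -> ProposalResult:
    """Propose up to ``n_pathways`` gene set descriptions for a gene list.

    The prompt asks the model not to echo gene names into the proposals;
    descriptions that nonetheless contain a query symbol are recorded in
    ``echoed_inputs`` (a warning signal, not an error).
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    prompt = render_proposal_prompt(genes, n_pathways, context=context)
    payload, attempts, usage = call_with_retry(
        backend,
        prompt,
        expect="pathway_array",
        base_seed=seed,
        max_retries=max_retries,
        system_message=system_message,
    )
    seen: set[str] = set()
    descriptions: list[str] = []
    for descr in payload.entries:
        key = descr.lower()
        if key in seen:
            continue
        seen.add(key)
        descriptions.append(descr)
    descriptions = descriptions[:n_pathways]
    gene_tokens = {g.strip().upper() for g in genes}
    echoed = [
        d
        for d in descriptions
        if any(tok.upper() in gene_tokens for tok in _words(d))
    ]
    return ProposalResult(
        descriptions=descriptions,
        requested_n=n_pathways,
        usage=usage,
        attempts=attempts,
        undercount=len(descriptions) < n_pathways,
        echoed_inputs=echoed or None,
    )


def _words(text: str) -> list[str]:
    return re.findall(r"[A-Za-z0-9]+", text)
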