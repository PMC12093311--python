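import json

import pytest

from genesetlm.genesets import SymbolTable
from genesetlm.llm_interface import (
    FixtureBackend,
    render_gene_set_prompt,
    render_proposal_prompt,
)


def fenced(payload) -> str:
    """Wrap a JSON payload in the fenced code block a well-behaved model emits."""
    return "```json\n" + json.dumps(payload) + "\n```"


def gene_payload(genes) -> str:
    """Fenced gene-array response; entries may be symbols or full dicts."""
    return fenced([g if isinstance(g, dict) else {"gene": g} for g in genes])


def pathway_payload(descriptions) -> str:
    return fenced([{"p": d} for d in descriptions])


def make_gene_backend(descr, runs, variant="plain", **kwargs) -> FixtureBackend:
    """Fixture backend answering the gene-generation prompt for one description.

    ``runs`` maps seed -> list of genes (symbols or entry dicts) or a raw
    response string.
    """
    prompt = render_gene_set_prompt(descr, variant)
    entries = []
    for seed, genes in runs.items():
        response = genes if isinstance(genes, str) else gene_payload(genes)
        entries.append((prompt, seed, response))
    return FixtureBackend.from_prompt_responses(entries, **kwargs)


def make_proposal_backend(genes, n, descriptions, context=None, seed=42, **kwargs):
    prompt = render_proposal_prompt(genes, n, context)
    response = (
        descriptions if isinstance(descriptions, str) else pathway_payload(descriptions)
    )
    return FixtureBackend.from_prompt_responses([(prompt, seed, response)], **kwargs)


@pytest.fixture
def small_table() -> SymbolTable:
    return SymbolTable(approved={"TP53", "BAX", "APOE", "CASP3", "TREM2", "TYROBP"})
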