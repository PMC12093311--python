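"""Benchmarking of generated gene sets and recovered descriptions.

Two families of evaluation:

* **Gene-level** — is a generated gene set significantly overrepresented in
  the curated set with the same description (hypergeometric test against a
  background universe), and what are its precision and recall against the
  curated members?

* **Text-level** — how well does a recovered description match the ground
  truth?  Lexical agreement is the fraction of the truth's distinct
  unigrams/bigrams present in the candidate; semantic agreement is the
  cosine similarity between backend embeddings.  Top-k variants score a
  ranked list by the per-metric maximum over its first k entries, which is
  how an ORA result list (top-5) or a mixed-set recovery (top-2) is judged.

The mixed gene set experiment unions pairs of gene sets and asks whether a
method recovers *both* underlying descriptions — the failure mode of
single-prompt approaches that collapse a mixture into one label.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .enrich import adjust_pvalues, hypergeom_p
from .genesets import GeneSet, GeneSetDatabase
from .llm_interface import Backend

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# minimal English stopword list for the optional filtered tokenization;
# GO-style names are dense in "of/in/to" which can inflate unigram overlap
_STOPWORDS = frozenset(
    "a an and as at by for from in into of on or the to via with".split()
)


@dataclass(frozen=True)
class SimilarityScore:
    """Text agreement between a candidate and a ground-truth description."""

    unigram_frac: float
    bigram_frac: float
    cosine: float
    flagged: bool = False


@dataclass(frozen=True)
class MatchedPair:
    """A query description matched to its most similar reference."""

    query_description: str
    reference_description: str
    cosine: float
    query_source: str = ""
    reference_source: str = ""


@dataclass(frozen=True)
class MixedCase:
    """Union of two gene sets standing in for a two-process experiment."""

    description_a: str
    description_b: str
    combined_genes: tuple[str, ...]
    source_db: str = ""
    reused_members: bool = False


@dataclass
class BenchmarkSummary:
    """Cross-database overrepresentation benchmark outcome."""

    n_sets: int
    n_significant: int
    fraction_significant: float
    records: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Gene-level metrics
# ---------------------------------------------------------------------------

def precision_recall(generated: GeneSet, reference: GeneSet) -> tuple[float, float]:
    """Precision and recall of a generated set against a curated reference.

    precision = |gen ∩ ref| / |gen|; recall = |gen ∩ ref| / |ref|.
    An empty generated set yields precision 0.0 (undefined, reported as 0);
    an empty reference is an error — there is nothing to recall.
    """
    ref = set(reference.genes)
    if not ref:
        raise ValueError(f"reference set {reference.description!r} is empty")
    gen = set(generated.genes)
    inter = len(gen & ref)
    precision = inter / len(gen) if gen else 0.0
    recall = inter / len(ref)
    return precision, recall


def overrep_benchmark(
    generated_db: GeneSetDatabase,
    curated_db: GeneSetDatabase,
    background: int,
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> BenchmarkSummary:
    """Test each generated set for overrepresentation in the curated set
    sharing its description.

    For every description present in both databases, the overlap of the
    generated genes with the curated members is tested hypergeometrically
    against ``background``; p-values are adjusted across all tested
    descriptions.  The headline number is the fraction of descriptions
    whose generated set is significant after correction — high when the
    generator reproduces curated biology, near the alpha level when the
    generated sets are random.
    """
    shared = [d for d in generated_db.descriptions if d in curated_db]
    if not shared:
        raise ValueError("generated and curated databases share no descriptions")
    rows = []
    for descr in shared:
        gen = generated_db[descr]
        cur = curated_db[descr]
        k = len(set(gen.genes) & set(cur.genes))
        p = hypergeom_p(k, len(cur), len(gen), background)
        prec, rec = (
            precision_recall(gen, cur) if len(cur) else (0.0, 0.0)
        )
        rows.append(
            {
                "description": descr,
                "generated_size": len(gen),
                "curated_size": len(cur),
                "overlap": k,
                "p": p,
                "precision": prec,
                "recall": rec,
            }
        )
    q = adjust_pvalues([r["p"] for r in rows], method=correction)
    n_sig = 0
    for row, qv in zip(rows, q):
        row["q"] = qv
        row["significant"] = qv < alpha
        n_sig += row["significant"]
    return BenchmarkSummary(
        n_sets=len(rows),
        n_significant=n_sig,
        fraction_significant=n_sig / len(rows),
        records=rows,
    )


# ---------------------------------------------------------------------------
# Text-level metrics
# ---------------------------------------------------------------------------

def tokenize(text: str, remove_stopwords: bool = False) -> list[str]:
    """Lowercase and split on non-alphanumeric runs; no stemming."""
    tokens = _TOKEN_RE.findall(text.lower())
    if remove_stopwords:
        tokens = [t for t in tokens if t not in _STOPWORDS]
    return tokens


def _ngrams(tokens: Sequence[str], n: int) -> set[tuple[str, ...]]:
    return {tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)}


def shared_ngram_fraction(
    truth: str, candidate: str, n: int, remove_stopwords: bool = False
) -> float:
    """Fraction of the truth's distinct n-grams present in the candidate.

    Set semantics: repeating content in the candidate cannot change the
    score.  An empty candidate scores 0; a truth with no n-grams of the
    requested order is an error.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 (unigrams) or 2 (bigrams)")
    truth_tokens = tokenize(truth, remove_stopwords)
    truth_grams = _ngrams(truth_tokens, n)
    if not truth_grams:
        raise ValueError(f"truth description {truth!r} yields no {n}-grams")
    cand_grams = _ngrams(tokenize(candidate, remove_stopwords), n)
    return len(truth_grams & cand_grams) / len(truth_grams)


def cosine_similarity(backend: Backend, a: str, b: str) -> float:
    """Cosine of backend embeddings of two texts (unit-normalized)."""
    if not a.strip() or not b.strip():
        raise ValueError("texts must be non-empty")
    va = np.asarray(backend.embed(a), dtype=np.float64)
    vb = np.asarray(backend.embed(b), dtype=np.float64)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def similarity(
    backend: Backend, truth: str, candidate: str, remove_stopwords: bool = False
) -> SimilarityScore:
    """All three agreement metrics for one candidate description."""
    return SimilarityScore(
        unigram_frac=shared_ngram_fraction(truth, candidate, 1, remove_stopwords),
        bigram_frac=(
            shared_ngram_fraction(truth, candidate, 2, remove_stopwords)
            if len(tokenize(truth, remove_stopwords)) >= 2
            else 0.0
        ),
        cosine=cosine_similarity(backend, truth, candidate),
    )


def topk_max_similarity(
    truth: str,
    ranked_descriptions: Sequence[str],
    k: int,
    backend: Backend,
    remove_stopwords: bool = False,
) -> SimilarityScore:
    """Per-metric maximum agreement over the first k ranked candidates.

    Scores a ranked result list (e.g. the top-5 significant ORA hits) by
    the best it offers on each metric independently.  An empty list scores
    zeros, flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top = [d for d in ranked_descriptions[:k] if d.strip()]
    if not top:
        return SimilarityScore(0.0, 0.0, 0.0, flagged=True)
    scores = [similarity(backend, truth, d, remove_stopwords) for d in top]
    return SimilarityScore(
        unigram_frac=max(s.unigram_frac for s in scores),
        bigram_frac=max(s.bigram_frac for s in scores),
        cosine=max(s.cosine for s in scores),
    )


def match_descriptions(
    query_db: GeneSetDatabase,
    reference_db: GeneSetDatabase,
    backend: Backend,
    threshold: float = 0.7,
) -> list[MatchedPair]:
    """Match each query description to its best-cosine reference.

    Only the best reference per query is considered, retained when its
    cosine exceeds ``threshold``; ties break toward the earlier reference.
    Near-equivalent descriptions across independently curated databases,
    found this way, give set pairs curated by different humans for the
    same biology — a human-vs-human baseline.
    """
    if len(query_db) == 0 or len(reference_db) == 0:
        raise ValueError("both databases must be non-empty")
    ref_descrs = reference_db.descriptions
    ref_vecs = np.stack([np.asarray(backend.embed(d), float) for d in ref_descrs])
    ref_norms = np.linalg.norm(ref_vecs, axis=1)
    pairs: list[MatchedPair] = []
    for q in query_db.descriptions:
        vq = np.asarray(backend.embed(q), float)
        nq = np.linalg.norm(vq)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = ref_vecs @ vq / (ref_norms * nq)
        cos = np.nan_to_num(cos)
        best = int(np.argmax(cos))  # argmax takes the first maximum: earlier ref wins ties
        if cos[best] > threshold:
            pairs.append(
                MatchedPair(
                    query_description=q,
                    reference_description=ref_descrs[best],
                    cosine=float(cos[best]),
                    query_source=query_db.source_label,
                    reference_source=reference_db.source_label,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Mixed gene set experiment
# ---------------------------------------------------------------------------

def build_mixed_cases(
    db: GeneSetDatabase,
    eligible: Sequence[str],
    n_pairs: int,
    seed: int,
) -> list[MixedCase]:
    """Sample unordered pairs of eligible sets and union their members.

    Pairs are member-disjoint (each set used once) while the eligible pool
    allows; beyond that, distinct pairs are drawn with member reuse and
    flagged.  Sampling is seeded and reproducible.
    """
    eligible = list(eligible)
    if len(eligible) < 2:
        raise ValueError("need at least 2 eligible descriptions")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    missing = [d for d in eligible if d not in db]
    if missing:
        raise ValueError(f"eligible descriptions not in database: {missing[:5]}")
    max_distinct = len(eligible) * (len(eligible) - 1) // 2
    if n_pairs > max_distinct:
        raise ValueError(
            f"cannot draw {n_pairs} distinct pairs from {len(eligible)} eligible sets"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(eligible)
    rng.shuffle(shuffled)
    chosen: list[tuple[str, str]] = []
    # member-disjoint pairs first
    for i in range(0, 2 * min(n_pairs, len(shuffled) // 2), 2):
        chosen.append((shuffled[i], shuffled[i + 1]))
    reused = False
    if len(chosen) < n_pairs:
        reused = True
        all_pairs = list(itertools.combinations(sorted(eligible), 2))
        taken = {tuple(sorted(p)) for p in chosen}
        remaining = [p for p in all_pairs if tuple(sorted(p)) not in taken]
        idx = rng.choice(len(remaining), size=n_pairs - len(chosen), replace=False)
        chosen += [remaining[i] for i in sorted(idx)]
    cases = []
    for a, b in chosen:
        union = sorted(set(db[a].genes) | set(db[b].genes))
        cases.append(
            MixedCase(
                description_a=a,
                description_b=b,
                combined_genes=tuple(union),
                source_db=db.source_label,
                reused_members=reused,
            )
        )
    return cases


def evaluate_mixed_recovery(
    case: MixedCase,
    predicted_descriptions: Sequence[str],
    k: int,
    backend: Backend,
    remove_stopwords: bool = False,
) -> tuple[SimilarityScore, SimilarityScore]:
    """Score recovery of both underlying descriptions of a mixed case.

    Each truth description is scored by its best match among the top-k
    predictions.  Concatenation-style baselines pass a single concatenated
    text as the prediction list.
    """
    score_a = topk_max_similarity(
        case.description_a, predicted_descriptions, k, backend, remove_stopwords
    )
    score_b = topk_max_similarity(
        case.description_b, predicted_descriptions, k, backend, remove_stopwords
    )
    return score_a, score_b
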