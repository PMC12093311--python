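# Methods

## The statistical model

Overrepresentation analysis treats a query gene list D as a uniform draw
of |D| genes from a background universe of B genes. For a gene set G with
|G| members in the universe, the overlap k = |D ∩ G| is hypergeometric
under the null, and the reported p-value is the upper tail P(X ≥ k). This
equals a one-tailed Fisher's exact test on the 2×2 table
[[k, |D|−k], [|G|−k, B−|G|−|D|+k]]. The implementation computes the tail
directly at k (the survival function at k−1), with the k = 0 case
returned as exactly 1 rather than via 1−CDF(−1); the test suite verifies
agreement with exhaustive enumeration of all draws for every
configuration with B ≤ 12 (absolute error ≤ 1e-12) and with Fisher's
exact test on random larger instances.

Fold enrichment is the observed overlap fraction over its expectation,
(k/|D|)/(|G|/B). Multiple-testing adjustment is Benjamini–Hochberg
step-up by default (matching the "q-value" semantics of the pipeline's
output) or Bonferroni; q-values are computed across exactly the sets
tested in one run, never pooled across runs. BH output is clamped to
q ≥ p elementwise because the floating evaluation of (p·m)/rank can land
one ulp below p at rank m.

The choice of B matters and is exposed, never guessed: it defaults to
the database universe size, and a common practical choice is the size of
the approved-symbol table (~20,000 protein-coding genes, or the 10,000
used by the synthetic benchmarks). All overlap counts are computed after
restricting both query and sets to the universe, since the
hypergeometric model requires every count to live in one population.
Query genes outside the universe are dropped with a count; tested sets
are not filtered by any minimum size or overlap before adjustment.

## Language-model stages

Two fixed prompt templates (plain-text files with named placeholders
under `genesetlm/prompts/`) drive the model. The gene-generation prompt
asks for all genes directly and indirectly involved in a described
process, requires HGNC symbols, and requests a fenced JSON array of
`{"gene": ...}` objects; the description is substituted at two positions.
The proposal prompt asks for `n_pathways` non-overlapping pathway/process
descriptions containing the query genes (as a JSON array of `{"p": ...}`
objects) and, when experimental context is supplied, inserts one
additional sentence asking the model to consider that context. The
pipeline keeps generation blind: each proposed description is expanded
into a gene set with no access to the query genes or the context, so
steering affects hypothesis selection only.

A role prompt (system message presenting a molecular-biology expert) is
on by default but is a toggle, since its observed effect on generation
quality is small; the exact wording lives in `prompts/system_role.txt`.

Model output is parsed from the first fenced code block (or the whole
response), first strictly, then through a small repair pass: curly-quote
normalization, trailing-comma removal, bracket balancing for truncated
output, single→double quote swaps, and extraction of the outermost JSON
array. Unrepairable output yields a `ParseFailure`, and the call is
retried with the seed incremented by one per attempt (default base seed
42, at most 3 attempts — the retry-with-new-seed strategy needs a bound
and 3 keeps worst-case cost at 3× while leaving unparseable-prompt
failures visible). Token usage accumulates across attempts, failed ones
included, because they were paid for. Fixture backends count
whitespace-delimited tokens — the shape of the metric without any claim
of tokenizer fidelity; the live backend reports provider counts.

## Generation strategies

* **plain** — one generation per description.
* **reasoning** — the schema additionally requires a one-sentence
  rationale per gene; rationales are recorded for audit but never filter
  the set, so final genes match the plain strategy on equal payloads.
* **confidence** — the schema requires a low/medium/high label per gene
  and the final set keeps labels at or above a threshold (default: high
  only, with medium+ and low+ exposed).
* **ensemble** — the plain prompt is run with n_runs consecutive seeds
  (default 5) and genes recurring in ≥ ceil(consensus_frac · n_runs)
  successful runs are kept. The default consensus of 1.0 is the strict
  intersection: the result can never exceed the smallest run, and raising
  the fraction can only shrink the set. Recurrence across seeds acts as
  an implicit confidence signal and trades recall for precision. A run
  whose retries are exhausted is excluded and counted, with the consensus
  threshold recomputed over the runs that succeeded.

Generated symbols are uppercased, deduplicated (first occurrence kept,
duplicates counted — duplication is a model-quality signal and is never
silently lost), and validated against an approved-symbol table with
optional aliases; invalid symbols are excluded from the final set but
retained in the raw per-run record.

## Benchmarking machinery

Gene-level: `overrep_benchmark` tests, for every description present in
both a generated and a curated database, whether the generated members
are overrepresented in the curated set (hypergeometric against a stated
background, Bonferroni 0.01 by convention), and reports the fraction of
descriptions passing — near 1 for a faithful generator, near the alpha
level for a random one. `precision_recall` is |gen ∩ ref|/|gen| and
|gen ∩ ref|/|ref|; an empty generated set reports precision 0 with a
flag, an empty reference is an error.

Text-level: recovered descriptions are scored against ground truth by
(i) the fraction of the truth's *distinct* unigrams/bigrams present in
the candidate — tokenization lowercases and splits on non-alphanumeric
runs, no stemming, stopwords kept by default (removal is an option since
"of/in" inflate overlap in GO-style names), set semantics so repetition
cannot inflate scores; and (ii) cosine similarity of backend embeddings.
Ranked result lists (top-5 ORA hits, top-2 mixed-recovery predictions)
are scored by the per-metric maximum over the first k entries.
`match_descriptions` pairs each query description with its best-cosine
reference above a threshold (0.7 by convention), query→reference only,
first-maximum tie-break — the device used to find near-equivalent sets
curated independently in different databases.

Mixed cases union two gene sets and ask whether a method recovers *both*
underlying descriptions; pairs are sampled seeded, member-disjoint while
the eligible pool allows, with distinct-pair reuse beyond that flagged.

## The embedding stand-in

Offline cosine similarity uses a deterministic hashed character-3-gram
embedding: grams hash (CRC-32) into a 256-dimensional signed-count
vector, L2-normalized. Identical strings embed identically; strings
sharing no character 3-grams are near-orthogonal; lexical overlap varies
the cosine in between. It is a transparent, dependency-free vector model
— adequate for exercising the matching/threshold machinery and for
synthetic labels, but it measures surface similarity only: semantically
equivalent but lexically disjoint descriptions ("programmed cell death"
vs "apoptosis") score near zero, unlike a neural embedding. Tests that
need exact planted similarities bypass it with per-text embedding
overrides. Live runs may use a provider embedding model instead.

## Synthetic data: what it emulates and what it does not

`synth_universe` names n synthetic symbols deterministically;
`synth_database` draws sets of uniform size in a range (default 20–80,
bracketing the median sizes of common curated pathway libraries) without
replacement from the universe, with distinct multi-word labels.
`synth_query` emulates a DEG list: the union of chosen source sets,
optionally subsampled, plus noise genes from outside them (defaults of a
few dozen genes match typical modest DEG lists).

`synth_llm_fixture` is the mock model: for a known description it
returns round(recall · |ref|) true members plus decoys from outside the
reference so that true/(true+decoys) ≈ precision, resampled per request
seed the way repeated sampled generations vary. Decoys are drawn without
replacement so they do not interact with the deduplication logic under
test. When the prompt requests confidence labels, true members are
labelled high with one probability and decoys with another (defaults
0.9/0.1), so confidence filtering has signal to find. A malformed mode
emits trailing-comma, fence-missing, and plain-text payloads at a
configured rate to exercise repair and retry.

Passing these benchmarks therefore demonstrates that the statistics,
filtering, ensembling, and recovery machinery behave correctly under
controlled signal — not that any real language model achieves a given
precision/recall, and not that the text metrics reflect biological
synonymy. Real-model quality must be measured with the live backend
against real curated databases.

## Problem sizes and numerical choices

The bundled benchmarks use a 10,000-gene universe with 50 sets of 100
genes for parameter recovery, 500 sets for null calibration, and 100
pipeline replicates for mixed-signal recovery — sizes chosen so each
statistic is stable to well under its tolerance (binomial SE < 2
percentage points) while the whole suite runs in seconds. Enumeration
checks cover every hypergeometric configuration with B ≤ 12 exactly.
Sorting of results is total and deterministic (ascending p, ties by
description). Degenerate inputs are defined rather than accidental:
empty query → all p = 1; empty set → p = 1, fold 0; empty database →
empty result; empty generated set → a valid, flagged record.

## Known limitations

* The GMT dialect is fixed (field 2 written as `na`; < 2 fields
  rejected); exotic dialects with per-set URLs in field 2 lose that field.
* Symbol validation is one namespace (HGNC-style, uppercase) with a flat
  alias map; no cross-species or historic-ID resolution.
* The fixture token counts are whitespace tokens, not provider tokens;
  cross-model token comparisons require the live backend.
* Live-backend behaviour (rate limits, drift across model versions) is
  outside the test surface; the contract is only that it satisfies the
  same backend protocol.
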