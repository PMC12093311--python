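"""Benchmark metrics: precision/recall, overrepresentation, text similarity,
description matching, and the mixed gene set machinery."""

import numpy as np
import pytest

from genesetlm.benchmark import (
    build_mixed_cases,
    cosine_similarity,
    evaluate_mixed_recovery,
    match_descriptions,
    overrep_benchmark,
    precision_recall,
    shared_ngram_fraction,
    similarity,
    topk_max_similarity,
)
from genesetlm.genesets import GeneSet, GeneSetDatabase
from genesetlm.llm_interface import ScriptedBackend
from genesetlm.synthdata import (
    randomize_database_members,
    synth_database,
    synth_universe,
)


def text_backend(**kwargs):
    return ScriptedBackend(lambda p, s: "", **kwargs)


class TestPrecisionRecall:
    def test_identical_sets(self):
        gs = GeneSet("a", ["X1", "X2"])
        assert precision_recall(gs, gs) == (1.0, 1.0)

    def test_disjoint_sets(self):
        gen = GeneSet("a", ["X1", "X2"])
        ref = GeneSet("a", ["Y1", "Y2"])
        assert precision_recall(gen, ref) == (0.0, 0.0)

    def test_partial_overlap_counts(self):
        gen = GeneSet("a", ["A1", "B1", "C1", "D1"])
        ref = GeneSet("a", ["A1", "B1", "E1", "F1", "G1", "H1"])
        prec, rec = precision_recall(gen, ref)
        assert prec == pytest.approx(0.5)
        assert rec == pytest.approx(1 / 3)

    def test_empty_generated_reports_zero(self):
        assert precision_recall(GeneSet("a", []), GeneSet("a", ["X1"]))[0] == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(GeneSet("a", ["X1"]), GeneSet("a", []))


class TestOverrepBenchmark:
    def test_self_enrichment_fraction_one(self):
        universe = synth_universe(2000)
        db = synth_database(universe, n_sets=10, size_range=(20, 40), seed=1)
        summary = overrep_benchmark(db, db, background=2000)
        assert summary.fraction_significant == 1.0
        assert summary.n_sets == 10

    def test_label_permuted_sets_drop_to_null(self):
        universe = synth_universe(5000)
        curated = synth_database(universe, n_sets=60, size_range=(20, 60), seed=2)
        random_gen = randomize_database_members(curated, seed=3)
        summary = overrep_benchmark(random_gen, curated, background=5000)
        assert summary.fraction_significant <= 0.05

    def test_planted_half_overlap_significant(self):
        # 50% member overlap, sets of 20 in a background of 1000
        universe = synth_universe(1000)
        pool = sorted(universe.approved)
        cur = GeneSet("planted", pool[:20])
        gen = GeneSet("planted", pool[10:30])
        summary = overrep_benchmark(
            GeneSetDatabase([gen], universe=universe.approved),
            GeneSetDatabase([cur], universe=universe.approved),
            background=1000,
        )
        assert summary.records[0]["overlap"] == 10
        assert summary.fraction_significant == 1.0

    def test_no_shared_descriptions_rejected(self):
        a = GeneSetDatabase([GeneSet("only-a", ["X1"])])
        b = GeneSetDatabase([GeneSet("only-b", ["X1"])])
        with pytest.raises(ValueError, match="share no"):
            overrep_benchmark(a, b, background=100)


class TestSharedNgrams:
    def test_identity_scores_one(self):
        assert shared_ngram_fraction("regulation of apoptosis", "regulation of apoptosis", 1) == 1.0
        assert shared_ngram_fraction("regulation of apoptosis", "regulation of apoptosis", 2) == 1.0

    def test_worked_example_unigrams_and_bigrams(self):
        truth = "positive regulation of apoptosis"
        cand = "regulation of apoptosis"
        # truth unigrams {positive, regulation, of, apoptosis}: 3 of 4 present
        assert shared_ngram_fraction(truth, cand, 1) == pytest.approx(3 / 4)
        # truth bigrams {positive-regulation, regulation-of, of-apoptosis}: 2 of 3
        assert shared_ngram_fraction(truth, cand, 2) == pytest.approx(2 / 3)

    def test_no_shared_words(self):
        assert shared_ngram_fraction("apoptosis", "ribosome biogenesis", 1) == 0.0

    def test_candidate_repetition_cannot_inflate_score(self):
        truth = "dna repair pathway"
        cand = "dna repair"
        doubled = "dna repair dna repair dna repair"
        for n in (1, 2):
            assert shared_ngram_fraction(truth, cand, n) == shared_ngram_fraction(
                truth, doubled, n
            )

    def test_tokenization_lowercases_and_splits_on_punctuation(self):
        assert shared_ngram_fraction("DNA-repair", "dna repair", 1) == 1.0

    def test_stopword_removal_option(self):
        truth = "regulation of apoptosis"
        cand = "control of the cell"
        with_stop = shared_ngram_fraction(truth, cand, 1)
        without = shared_ngram_fraction(truth, cand, 1, remove_stopwords=True)
        assert with_stop > 0.0  # "of" matches
        assert without == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            shared_ngram_fraction("...", "anything", 1)


class TestCosine:
    def test_identity_and_symmetry(self):
        backend = text_backend()
        a, b = "regulation of apoptosis", "dna damage response"
        assert cosine_similarity(backend, a, a) == pytest.approx(1.0, abs=1e-6)
        assert cosine_similarity(backend, a, b) == pytest.approx(
            cosine_similarity(backend, b, a)
        )

    def test_orthogonal_fixture_embeddings(self):
        backend = text_backend(
            embedding_overrides={"one": [1.0, 0.0], "two": [0.0, 1.0]}
        )
        assert cosine_similarity(backend, "one", "two") == pytest.approx(0.0)


class TestMatchDescriptions:
    def test_identical_description_matched_near_one(self):
        q = GeneSetDatabase([GeneSet("dna repair", ["X1"])], source_label="q")
        r = GeneSetDatabase(
            [GeneSet("dna repair", ["Y1"]), GeneSet("lipid transport", ["Y2"])],
            source_label="r",
        )
        pairs = match_descriptions(q, r, text_backend(), threshold=0.7)
        assert len(pairs) == 1
        assert pairs[0].reference_description == "dna repair"
        assert pairs[0].cosine == pytest.approx(1.0, abs=1e-6)

    def test_unreachable_threshold_empty(self):
        q = GeneSetDatabase([GeneSet("dna repair", ["X1"])])
        r = GeneSetDatabase([GeneSet("dna repair", ["Y1"])])
        assert match_descriptions(q, r, text_backend(), threshold=1.1) == []

    def test_planted_similarities_filtered_at_threshold(self):
        s = np.sqrt(1 - 0.9**2)
        t = np.sqrt(1 - 0.5**2)
        overrides = {
            "query one": [1.0, 0.0, 0.0],
            "query two": [0.0, 1.0, 0.0],
            "ref close": [0.9, s, 0.0],   # cos 0.9 with "query one"
            "ref far": [0.0, 0.5, t],     # cos 0.5 with "query two"
        }
        q = GeneSetDatabase([GeneSet("query one", ["X1"]), GeneSet("query two", ["X2"])])
        r = GeneSetDatabase([GeneSet("ref close", ["Y1"]), GeneSet("ref far", ["Y2"])])
        pairs = match_descriptions(
            q, r, text_backend(embedding_overrides=overrides), threshold=0.7
        )
        assert [(p.query_description, p.reference_description) for p in pairs] == [
            ("query one", "ref close")
        ]
        assert pairs[0].cosine == pytest.approx(0.9)


class TestTopK:
    def test_truth_present_within_k_scores_one(self):
        ranked = ["aaa bbb", "ccc ddd", "positive regulation of apoptosis", "eee", "fff"]
        score = topk_max_similarity(
            "positive regulation of apoptosis", ranked, 5, text_backend()
        )
        assert score.unigram_frac == 1.0
        assert score.bigram_frac == 1.0
        assert score.cosine == pytest.approx(1.0, abs=1e-6)

    def test_truth_beyond_k_with_disjoint_top(self):
        ranked = ["aaa", "bbb", "ccc", "ddd", "eee", "dna repair"]
        score = topk_max_similarity("dna repair", ranked, 5, text_backend())
        assert score.unigram_frac == 0.0 and score.bigram_frac == 0.0

    def test_k_one_reduces_to_single_similarity(self):
        backend = text_backend()
        truth = "regulation of apoptosis"
        ranked = ["apoptosis control", "ignored entry"]
        top1 = topk_max_similarity(truth, ranked, 1, backend)
        single = similarity(backend, truth, ranked[0])
        assert top1 == single

    def test_empty_ranked_list_flagged_zeros(self):
        score = topk_max_similarity("dna repair", [], 5, text_backend())
        assert score.flagged and score.cosine == 0.0


class TestMixedCases:
    def make_db(self, n=6):
        universe = synth_universe(500)
        return synth_database(universe, n_sets=n, size_range=(10, 20), seed=4)

    def test_seeded_selection_deterministic(self):
        db = self.make_db()
        a = build_mixed_cases(db, db.descriptions, 2, seed=11)
        b = build_mixed_cases(db, db.descriptions, 2, seed=11)
        assert [(c.description_a, c.description_b) for c in a] == [
            (c.description_a, c.description_b) for c in b
        ]

    def test_union_arithmetic_disjoint_and_overlapping(self):
        u = synth_universe(100)
        pool = sorted(u.approved)
        db = GeneSetDatabase(
            [GeneSet("left set", pool[:10]), GeneSet("right set", pool[10:25]),
             GeneSet("mid set", pool[5:20])],
            universe=u.approved,
        )
        disjoint = build_mixed_cases(db, ["left set", "right set"], 1, seed=1)[0]
        assert len(disjoint.combined_genes) == 25
        overlapping = build_mixed_cases(db, ["left set", "mid set"], 1, seed=1)[0]
        assert len(overlapping.combined_genes) == 20  # 5 shared genes

    def test_insufficient_eligible_rejected(self):
        db = self.make_db(3)
        with pytest.raises(ValueError):
            build_mixed_cases(db, db.descriptions[:1], 1, seed=0)
        with pytest.raises(ValueError):
            build_mixed_cases(db, db.descriptions, 4, seed=0)  # > C(3,2)

    def test_member_reuse_only_when_pool_too_small_and_flagged(self):
        db = self.make_db(6)
        disjoint = build_mixed_cases(db, db.descriptions, 3, seed=5)
        used = [d for c in disjoint for d in (c.description_a, c.description_b)]
        assert len(used) == len(set(used))
        assert not any(c.reused_members for c in disjoint)
        more = build_mixed_cases(db, db.descriptions, 5, seed=5)
        assert any(c.reused_members for c in more)
        pairs = {tuple(sorted((c.description_a, c.description_b))) for c in more}
        assert len(pairs) == 5  # pairs themselves stay distinct


class TestMixedRecovery:
    def case(self):
        db = GeneSetDatabase(
            [GeneSet("dna repair", ["X1", "X2"]), GeneSet("lipid transport", ["X3"])]
        )
        return build_mixed_cases(db, db.descriptions, 1, seed=0)[0]

    def test_both_truths_verbatim_scores_one(self):
        case = self.case()
        preds = ["dna repair", "lipid transport"]
        sa, sb = evaluate_mixed_recovery(case, preds, 2, text_backend())
        assert sa.unigram_frac == 1.0 and sb.unigram_frac == 1.0
        assert sa.cosine == pytest.approx(1.0, abs=1e-6)

    def test_one_truth_recovered(self):
        case = self.case()
        truth_a = case.description_a
        preds = [truth_a, "zzz qqq"]
        sa, sb = evaluate_mixed_recovery(case, preds, 2, text_backend())
        assert sa.unigram_frac == 1.0
        assert sb.unigram_frac == 0.0

    def test_empty_predictions_flagged(self):
        sa, sb = evaluate_mixed_recovery(self.case(), [], 2, text_backend())
        assert sa.flagged and sb.flagged
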