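"""Relaxed tier, directness classification, aggregation, baseline."""

import pytest

from conftest import make_sentence, run_setting
from mirrel import examples
from mirrel.assembly import (
    aggregate_document,
    apply_relaxed,
    classify_directness,
    cooccurrence_baseline,
)
from mirrel.linking import resolve_matches
from mirrel.model import Direction, Directness, Tier
from mirrel.rules import match_rules, pair_same_trigger
from mirrel.triggers import default_lexicon, find_triggers


def sentence_analysis(fx, direction=Direction.mirna_to_gene):
    s = next(fx.doc.sentences())
    mentions = fx.mentions_by_sent.get(s.sent_id, [])
    triggers = find_triggers(s, default_lexicon(), mentions)
    matches = match_rules(s, triggers, mentions, direction)
    resolved = resolve_matches(matches, s, mentions)
    st = pair_same_trigger(resolved, s)
    return s, resolved, st


class TestRelaxedTier:
    def test_different_trigger_pair_recovered(self, curated):
        fx = examples.as_fixture(examples.by_example_id(15))
        s, resolved, st = sentence_analysis(fx)
        assert st == []
        relaxed = apply_relaxed(resolved, st, s, Direction.mirna_to_gene)
        assert [(r.agent.norm, r.theme.norm, r.tier) for r in relaxed] == \
            [("miR-125b", "EIF4EBP1", Tier.relaxed)]

    def test_no_leftovers_no_relaxed_relations(self):
        fx = examples.as_fixture(examples.by_example_id(16))
        s, resolved, st = sentence_analysis(fx)
        assert len(st) == 3
        assert apply_relaxed(resolved, st, s, Direction.mirna_to_gene) == []

    def test_relaxed_only_is_combinatorial(self):
        fx = examples.as_fixture(examples.by_example_id(16))
        s, resolved, _ = sentence_analysis(fx)
        relaxed = apply_relaxed(resolved, [], s, Direction.mirna_to_gene)
        assert len(relaxed) == 6
        assert {(r.agent.norm, r.theme.norm) for r in relaxed} == {
            (m, g) for m in ("let-7", "miR-15a", "miR-16-1")
            for g in ("Ras", "Bcl-2")}

    def test_never_matched_entities_are_not_paired(self):
        # the cluster mention is argument of no trigger, so even the
        # relaxed tier ignores it
        fx = examples.as_fixture(examples.by_example_id(16))
        s, resolved, _ = sentence_analysis(fx)
        relaxed = apply_relaxed(resolved, [], s, Direction.mirna_to_gene)
        assert all(r.agent.norm != "miR-17-92" for r in relaxed)


class TestDirectness:
    def _classify(self, example_id):
        fx = examples.as_fixture(examples.by_example_id(example_id))
        rels = run_setting(fx, "full")
        assert rels, f"no relations extracted for example {example_id}"
        return {r.directness for r in rels}

    def test_plain_regulation_is_unknown(self):
        assert self._classify(1) == {Directness.unknown}

    def test_indirectly_vetoes_all_other_evidence(self):
        assert self._classify(2) == {Directness.unknown}

    def test_binding_with_utr_is_direct(self):
        assert self._classify(3) == {Directness.direct}

    def test_target_noun_is_direct(self):
        assert self._classify(4) == {Directness.direct}

    def test_directly_modifier_is_direct(self):
        s = make_sentence("(S (NP (NN miR-5)) (VP (ADVP (RB directly)) "
                          "(VBZ represses) (NP (NN GENA1))))")
        from conftest import make_sentence as _
        from mirrel.entities import recognize_mirna, GeneLexicon, match_genes
        mirnas = recognize_mirna(s)
        mentions = mirnas + match_genes(s, GeneLexicon.from_names(["GENA1"]),
                                        mirnas)
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        rels = pair_same_trigger(resolve_matches(matches, s, mentions), s)
        assert [classify_directness(r, s) for r in rels] == [Directness.direct]

    def test_null_arg_with_down_polarity_is_direct(self):
        fx = examples.as_fixture(examples.by_example_id(9))
        s, resolved, st = sentence_analysis(fx)
        # Example 9's embedded trigger is neutral ("regulating") -> unknown
        assert [classify_directness(r, s) for r in st] == [Directness.unknown]
        # with a down-polarity embedded trigger the same shape is direct
        s2 = make_sentence(
            "(S (NP (NN miR-5)) (VP (VBZ reduces) (NP (NN growth)) "
            "(PP (IN by) (S (VP (VBG suppressing) (NP (NN GENA1)))))))")
        from mirrel.entities import recognize_mirna, GeneLexicon, match_genes
        mirnas = recognize_mirna(s2)
        mentions = mirnas + match_genes(s2, GeneLexicon.from_names(["GENA1"]),
                                        mirnas)
        triggers = find_triggers(s2, default_lexicon(), mentions)
        matches = match_rules(s2, triggers, mentions, Direction.mirna_to_gene)
        rels = pair_same_trigger(resolve_matches(matches, s2, mentions), s2)
        assert [classify_directness(r, s2) for r in rels] == [Directness.direct]

    @pytest.mark.parametrize("snippet", [
        "translation", "3'UTR", "3' UTR", "3'-UTR",
        "3' untranslated region", "three prime untranslated region"])
    def test_utr_variants_are_direct_evidence(self, snippet):
        parse = ("(S (NP (NN miR-5)) (VP (VBZ represses) (NP (NN GENA1)) "
                 f"(PP (IN via) (NP (NN {snippet.split()[0]})))))")
        # build the sentence with the full variant in running text
        s = make_sentence(parse)
        s.text = s.text + f" {snippet}"
        from mirrel.entities import recognize_mirna, GeneLexicon, match_genes
        mirnas = recognize_mirna(s)
        mentions = mirnas + match_genes(s, GeneLexicon.from_names(["GENA1"]),
                                        mirnas)
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        rels = pair_same_trigger(resolve_matches(matches, s, mentions), s)
        assert [classify_directness(r, s) for r in rels] == [Directness.direct]


class TestAggregation:
    def _two_sentence_candidates(self):
        fx1 = examples.as_fixture(examples.by_example_id(1))
        s, resolved, st = sentence_analysis(fx1)
        for r in st:
            r.directness = Directness.unknown.value
        direct = [c for c in st]
        # duplicate the same pair from a "second sentence", one marked direct
        import copy
        dup = copy.deepcopy(st)
        for r in dup:
            r.sent_id = "other"
            r.directness = Directness.direct.value
        return st + dup

    def test_merge_keeps_direct_and_all_evidence(self):
        cands = self._two_sentence_candidates()
        rels = aggregate_document(cands, "d1")
        assert len(rels) == 1
        assert rels[0].directness is Directness.direct
        assert len(rels[0].evidence) == 2

    def test_direction_distinguishes_pairs(self):
        fx5 = examples.as_fixture(examples.by_example_id(5))
        s5, _, st5 = sentence_analysis(fx5, Direction.gene_to_mirna)
        fx1 = examples.as_fixture(examples.by_example_id(1))
        _, _, st1 = sentence_analysis(fx1)
        rels = aggregate_document(st5 + st1, "d")
        assert len(rels) == 2
        assert {r.direction for r in rels} == set(Direction)

    def test_idempotent_under_duplication(self):
        cands = self._two_sentence_candidates()
        once = aggregate_document(cands, "d1")
        twice = aggregate_document(cands + cands, "d1")
        assert [(r.key(), r.directness, tuple(r.evidence)) for r in once] == \
               [(r.key(), r.directness, tuple(r.evidence)) for r in twice]

    def test_subset_law_direct_within_mirna_to_gene(self, curated, synth_corpus):
        for fx in list(curated) + synth_corpus:
            rels = run_setting(fx, "full")
            m2g = {(r.mirna_norm, r.gene_norm) for r in rels
                   if r.direction is Direction.mirna_to_gene}
            direct = {(r.mirna_norm, r.gene_norm) for r in rels
                      if r.directness is Directness.direct}
            assert direct <= m2g


class TestCooccurrenceBaseline:
    def test_simple_pair(self):
        fx = examples.as_fixture(examples.by_example_id(6))
        s = next(fx.doc.sentences())
        rels = cooccurrence_baseline(s, default_lexicon(),
                                     fx.mentions_by_sent[s.sent_id])
        assert [(r.agent.norm, r.theme.norm) for r in rels] == \
            [("hsa-miR-222", "MMP1")]

    def test_overgenerates_on_coordination(self):
        fx = examples.as_fixture(examples.by_example_id(16))
        s = next(fx.doc.sentences())
        rels = cooccurrence_baseline(s, default_lexicon(),
                                     fx.mentions_by_sent[s.sent_id])
        assert len(rels) == 8  # 4 specific miRNAs x 2 genes

    def test_requires_a_trigger(self):
        s = make_sentence("(S (NP (NN miR-1)) (VP (VBD rose) (PP (IN with) "
                          "(NP (NN GENA1)))))")
        from mirrel.entities import recognize_mirna, GeneLexicon, match_genes
        mirnas = recognize_mirna(s)
        mentions = mirnas + match_genes(s, GeneLexicon.from_names(["GENA1"]),
                                        mirnas)
        assert cooccurrence_baseline(s, default_lexicon(), mentions) == []

    def test_baseline_dominates_same_trigger_tier(self, synth_corpus):
        """Within single sentences the baseline output contains every
        non-anaphoric same-trigger pair."""
        from mirrel.pipeline import extract_baseline
        for fx in synth_corpus:
            st = {(r.mirna_norm, r.gene_norm)
                  for r in run_setting(fx, "same-trigger")
                  if r.direction is Direction.mirna_to_gene}
            base = {(r.mirna_norm, r.gene_norm)
                    for r in extract_baseline(fx.doc, fx.mentions_by_sent)}
            assert st <= base, fx.doc_id
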