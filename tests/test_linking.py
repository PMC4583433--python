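"""Referential linking and anaphora resolution."""

import pytest

from conftest import make_sentence, pair_set, run_setting
from mirrel.entities import load_standoff
from mirrel.linking import resolve_matches
from mirrel.model import Direction
from mirrel.rules import match_rules, pair_same_trigger
from mirrel.textprep import document_from_abstract
from mirrel.triggers import default_lexicon, find_triggers


def resolved_pairs(fx):
    """Same-trigger pairs after full referential resolution, per sentence."""
    lex = default_lexicon()
    out = []
    for s in fx.doc.sentences():
        mentions = fx.mentions_by_sent.get(s.sent_id, [])
        triggers = find_triggers(s, lex, mentions)
        for direction in (Direction.mirna_to_gene, Direction.gene_to_mirna):
            matches = match_rules(s, triggers, mentions, direction)
            resolved = resolve_matches(matches, s, mentions)
            out.extend(pair_same_trigger(resolved, s))
    return out


def methods_used(fx):
    lex = default_lexicon()
    methods = set()
    for s in fx.doc.sentences():
        mentions = fx.mentions_by_sent.get(s.sent_id, [])
        triggers = find_triggers(s, lex, mentions)
        for direction in (Direction.mirna_to_gene, Direction.gene_to_mirna):
            matches = match_rules(s, triggers, mentions, direction)
            for m in resolve_matches(matches, s, mentions):
                if m.linking_method:
                    methods.add(m.linking_method)
    return methods


class TestReferentialLinking:
    def test_is_a_copula(self, curated):
        fx = next(f for f in curated if f.doc_id == "PMID-22870299")
        rels = resolved_pairs(fx)
        assert [(r.agent.norm, r.theme.norm) for r in rels] == \
            [("miR-142-3p", "IL1A")]
        assert "is_a" in methods_used(fx)

    def test_appositive(self, curated):
        fx = next(f for f in curated if f.doc_id == "PMID-23041385")
        rels = resolved_pairs(fx)
        assert [(r.agent.norm, r.theme.norm) for r in rels] == \
            [("miR-21", "TGF-betaR2")]
        assert "appositive" in methods_used(fx)

    def test_as_predicative_gene_mirna(self, curated):
        fx = next(f for f in curated if f.doc_id == "PMID-23190608")
        rels = resolved_pairs(fx)
        assert [(r.agent.norm, r.theme.norm, r.direction) for r in rels] == \
            [("Sp1", "miR-29b", Direction.gene_to_mirna)]

    def test_collection_list_yields_all_members(self, curated):
        fx = next(f for f in curated if f.doc_id == "PMID-22465011")
        rels = resolved_pairs(fx)
        assert sorted(r.theme.norm for r in rels) == \
            ["GATA4", "MEF2C", "NKx2.5", "cTnI"]

    def test_member_collection_cue_outside_containment(self):
        # referential plural phrase resolved through an explicit cue list
        parse = ("(S (NP (NN miR-7)) (VP (VBZ suppresses) "
                 "(NP (NP (PRP$ its) (NNS targets)) (, ,) "
                 "(PP (VBG including) (NP (NP (NN GENA1)) (CC and) "
                 "(NP (NN GENB2)))))))")
        s = make_sentence(parse)
        doc = document_from_abstract("d", "", s.text)
        ann = []
        for i, (t, name) in enumerate(
                [("miRNA", "miR-7"), ("gene", "GENA1"), ("gene", "GENB2")], 1):
            st = s.text.find(name)
            ann.append(f"T{i}\t{t} {st} {st + len(name)}\t{name}")
        mentions = load_standoff("\n".join(ann), doc)
        for m in mentions:
            m.sent_id = "s0"
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        resolved = resolve_matches(matches, s, mentions)
        rels = pair_same_trigger(resolved, s)
        assert sorted(r.theme.norm for r in rels) == ["GENA1", "GENB2"]


class TestAnaphora:
    def test_possessive_resolves_to_unique_mirna(self, curated):
        fx = next(f for f in curated if f.doc_id == "PMID-20545570")
        rels = resolved_pairs(fx)
        assert sorted((r.agent.norm, r.theme.norm) for r in rels) == [
            ("miR-21", "hPDCD4"), ("miR-21", "hPTEN"), ("miR-21", "hSPRY2")]
        assert "anaphora" in methods_used(fx)

    def test_ambiguous_it_without_subject_preference_unresolved(self):
        # two miRNAs, neither inside the subject NP: abstain
        parse = ("(S (NP (NN results)) (VP (VBD showed) (SBAR (IN that) "
                 "(S (NP (PRP it)) (VP (VBZ suppresses) (NP (NN GENA1)))))) "
                 "(PP (IN for) (NP (NP (NN miR-1)) (CC and) (NP (NN miR-2)))))")
        s = make_sentence(parse)
        doc = document_from_abstract("d", "", s.text)
        ann = []
        for i, (t, name) in enumerate(
                [("miRNA", "miR-1"), ("miRNA", "miR-2"), ("gene", "GENA1")], 1):
            st = s.text.find(name)
            ann.append(f"T{i}\t{t} {st} {st + len(name)}\t{name}")
        mentions = load_standoff("\n".join(ann), doc)
        for m in mentions:
            m.sent_id = "s0"
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        resolved = resolve_matches(matches, s, mentions)
        assert pair_same_trigger(resolved, s) == []

    def test_their_with_single_antecedent_unresolved(self):
        parse = ("(S (NP (NN miR-9)) (VP (VBD was) (VP (VBN overexpressed))) "
                 "(CC and) (S (NP (PRP$ their) (NN target) (NNS genes)) "
                 "(VP (VBD were) (VP (VBN downregulated)))))")
        s = make_sentence(parse)
        doc = document_from_abstract("d", "", s.text)
        st = s.text.find("miR-9")
        mentions = load_standoff(f"T1\tmiRNA {st} {st + 5}\tmiR-9", doc)
        for m in mentions:
            m.sent_id = "s0"
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        resolved = resolve_matches(matches, s, mentions)
        # number agreement fails: 'their' needs a multi-entity antecedent
        assert all(m.referential_kind != "possessive" for m in resolved)


class TestRelativePronoun:
    def test_nearest_compatible_np_wins_and_lists_expand(self, curated):
        fx = next(f for f in curated if f.doc_id == "PMID-23104180")
        rels = resolved_pairs(fx)
        assert sorted((r.agent.norm, r.theme.norm) for r in rels) == [
            ("miR-15a", "BCL2"), ("miR-16", "BCL2")]

    def test_no_compatible_np_unresolved(self):
        parse = ("(S (NP (NP (NN GENA1)) (, ,) (SBAR (WHNP (WDT which)) "
                 "(S (VP (VBP act) (PP (IN by) (S (VP (VBG targeting) "
                 "(NP (NN GENB2))))))))) (VP (VBD was) (VP (VBN studied))))")
        s = make_sentence(parse)
        doc = document_from_abstract("d", "", s.text)
        ann = []
        for i, name in enumerate(["GENA1", "GENB2"], 1):
            st = s.text.find(name)
            ann.append(f"T{i}\tgene {st} {st + len(name)}\t{name}")
        mentions = load_standoff("\n".join(ann), doc)
        for m in mentions:
            m.sent_id = "s0"
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        resolved = resolve_matches(matches, s, mentions)
        # the agent slot needs a miRNA; no compatible NP exists
        assert pair_same_trigger(resolved, s) == []

    def test_nearest_beats_farther_compatible_np(self):
        parse = ("(S (NP (NP (NN miR-1)) (, ,) (NP (NN miR-2)) (, ,) "
                 "(SBAR (WHNP (WDT which)) (S (VP (VBP act) (PP (IN by) "
                 "(S (VP (VBG targeting) (NP (NN GENA1))))))))) "
                 "(VP (VBD was) (VP (VBN studied))))")
        s = make_sentence(parse)
        doc = document_from_abstract("d", "", s.text)
        ann = []
        for i, (t, name) in enumerate(
                [("miRNA", "miR-1"), ("miRNA", "miR-2"), ("gene", "GENA1")], 1):
            st = s.text.find(name)
            ann.append(f"T{i}\t{t} {st} {st + len(name)}\t{name}")
        mentions = load_standoff("\n".join(ann), doc)
        for m in mentions:
            m.sent_id = "s0"
        triggers = find_triggers(s, default_lexicon(), mentions)
        matches = match_rules(s, triggers, mentions, Direction.mirna_to_gene)
        resolved = resolve_matches(matches, s, mentions)
        rels = pair_same_trigger(resolved, s)
        assert sorted((r.agent.norm, r.theme.norm) for r in rels) == \
            [("miR-2", "GENA1")]


class TestLinkingInvariants:
    def test_type_safety(self, curated, synth_corpus):
        lex = default_lexicon()
        for fx in list(curated) + synth_corpus[:40]:
            for s in fx.doc.sentences():
                mentions = fx.mentions_by_sent.get(s.sent_id, [])
                triggers = find_triggers(s, lex, mentions)
                for direction in Direction:
                    matches = match_rules(s, triggers, mentions, direction)
                    for m in resolve_matches(matches, s, mentions):
                        for e in m.resolved_entities:
                            assert e.etype is m.required_type

    def test_monotone_recall(self, curated, synth_corpus):
        """Enabling linking never removes a same-trigger relation."""
        for fx in list(curated) + synth_corpus[:40]:
            st = pair_set(run_setting(fx, "same-trigger"))
            lk = pair_set(run_setting(fx, "linking"))
            full = pair_set(run_setting(fx, "full"))
            assert st <= lk <= full, fx.doc_id

    def test_scope_containment(self, curated, synth_corpus):
        """Antecedents always come from within the same sentence (or the
        same section for backward anaphora)."""
        lex = default_lexicon()
        for fx in list(curated) + synth_corpus[:40]:
            sent_ids = {s.sent_id for s in fx.doc.sentences()}
            for s in fx.doc.sentences():
                mentions = fx.mentions_by_sent.get(s.sent_id, [])
                triggers = find_triggers(s, lex, mentions)
                matches = match_rules(s, triggers, mentions,
                                      Direction.mirna_to_gene)
                for m in resolve_matches(matches, s, mentions):
                    for e in m.resolved_entities:
                        assert e.sent_id in sent_ids
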