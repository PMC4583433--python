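"""miRNA grammar recognition, gene lexicon matching, standoff IO, normalization."""

import pytest
from hypothesis import given, settings, strategies as st

from mirrel.entities import (
    AnnotationError,
    GeneLexicon,
    load_standoff,
    match_genes,
    normalize_gene_name,
    normalize_mirna_name,
    recognize_mirna,
    write_standoff,
)
from mirrel.model import EntityType
from mirrel.textprep import document_from_abstract, split_sentences


def sent(text):
    return split_sentences(text)[0]


class TestRecognizeMirna:
    def test_species_prefix(self):
        ms = recognize_mirna(sent("hsa-miR-222 regulates the MMP1 expression"))
        assert len(ms) == 1
        assert ms[0].norm == "hsa-miR-222"
        assert ms[0].specific

    def test_slash_conjunction_expansion(self):
        ms = recognize_mirna(sent("miR-15a/-16-1 represses Bcl-2"))
        assert sorted(m.norm for m in ms) == ["miR-15a", "miR-16-1"]
        # conjuncts share the span of the full mention
        assert ms[0].start == ms[1].start and ms[0].end == ms[1].end

    def test_slash_without_hyphen(self):
        ms = recognize_mirna(sent("miR-15a/16-1 was measured"))
        assert sorted(m.norm for m in ms) == ["miR-15a", "miR-16-1"]

    def test_no_mirna_tokens(self):
        assert recognize_mirna(sent("the kinase phosphorylates the receptor")) == []

    def test_family_mention_not_specific(self):
        ms = recognize_mirna(sent("Several miRNAs were profiled"))
        assert len(ms) == 1
        assert not ms[0].specific

    def test_bracketed_prefix_cluster(self):
        ms = recognize_mirna(sent("the miRNA (miR) -17-92 cluster is oncogenic"))
        specific = [m for m in ms if m.specific]
        assert [m.norm for m in specific] == ["miR-17-92"]

    @pytest.mark.parametrize("text,norm", [
        ("let-7 represses Ras", "let-7"),
        ("lin-4 was the first", "lin-4"),
        ("miR-142-3p binds IL1A", "miR-142-3p"),
        ("MicroRNA-223 regulates FOXO1", "miR-223"),
        ("miR 21 was elevated", "miR-21"),
    ])
    def test_grammar_coverage(self, text, norm):
        ms = [m for m in recognize_mirna(sent(text)) if m.specific]
        assert norm in {m.norm for m in ms}

    @given(st.integers(1, 999),
           st.lists(st.tuples(st.integers(1, 99),
                              st.sampled_from(["", "a", "b"])),
                    min_size=1, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_expansion_count_equals_conjuncts(self, num, extras):
        name = f"miR-{num}" + "".join(f"/-{n}{suf}" for n, suf in extras)
        ms = recognize_mirna(sent(f"{name} was studied"))
        assert len(ms) == 1 + len(extras)
        for m in ms:
            # every conjunct re-normalizes to itself (grammar membership)
            assert normalize_mirna_name(m.norm) == m.norm

    def test_no_overlapping_mentions_of_same_type(self):
        ms = recognize_mirna(sent("hsa-miR-222 and miR-15a/-16-1 and miRNAs"))
        spans = sorted({(m.start, m.end) for m in ms})
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestMatchGenes:
    def test_single_gene(self):
        lx = GeneLexicon.from_names(["FOXO1"])
        s = sent("MicroRNA-223 regulates FOXO1 expression and cell proliferation.")
        ms = match_genes(s, lx)
        assert [(m.norm, m.surface) for m in ms] == [("FOXO1", "FOXO1")]

    def test_two_genes(self):
        lx = GeneLexicon.from_names(["Bcl-2", "Ras"])
        s = sent("let-7 represses Ras and miR-15a/-16-1 represses Bcl-2")
        assert sorted(m.norm for m in match_genes(s, lx)) == ["Bcl-2", "Ras"]

    def test_empty_lexicon(self):
        assert match_genes(sent("anything"), GeneLexicon()) == []

    def test_longest_match_wins(self):
        lx = GeneLexicon.from_names(["NF-kappa B", "B"])
        ms = match_genes(sent("LMP1 activated NF-kappa B via phosphorylation."), lx)
        assert [m.norm for m in ms] == ["NF-kappa B"]

    def test_match_inside_mirna_span_discarded(self):
        s = sent("miR-21 represses PTEN")
        mirna = recognize_mirna(s)
        lx = GeneLexicon.from_names(["miR-21", "PTEN"])
        ms = match_genes(s, lx, mirna)
        assert [m.norm for m in ms] == ["PTEN"]


class TestStandoff:
    TEXT = "hsa-miR-222 regulates the MMP1 expression."

    def test_consistent_record(self):
        doc = document_from_abstract("d1", "", self.TEXT)
        ms = load_standoff("T1\tmiRNA 0 11\thsa-miR-222\n", doc)
        assert len(ms) == 1
        assert ms[0].etype is EntityType.miRNA
        assert ms[0].norm == "hsa-miR-222"

    def test_surface_mismatch_errors_with_line(self):
        doc = document_from_abstract("d1", "", self.TEXT)
        with pytest.raises(AnnotationError, match="line 1"):
            load_standoff("T1\tmiRNA 0 11\twrong-text\n", doc)

    def test_mixed_types_counted(self):
        text = "miR-1 and miR-2 regulate GeneA, GeneB and GeneC."
        doc = document_from_abstract("d2", "", text)
        lines = []
        for i, name in enumerate(["miR-1", "miR-2"], 1):
            s = text.find(name)
            lines.append(f"T{i}\tmiRNA {s} {s + len(name)}\t{name}")
        for i, name in enumerate(["GeneA", "GeneB", "GeneC"], 3):
            s = text.find(name)
            lines.append(f"T{i}\tgene {s} {s + len(name)}\t{name}")
        ms = load_standoff("\n".join(lines), doc)
        assert sum(m.etype is EntityType.miRNA for m in ms) == 2
        assert sum(m.etype is EntityType.gene for m in ms) == 3

    def test_round_trip(self):
        doc = document_from_abstract("d1", "", self.TEXT)
        original = load_standoff("T1\tmiRNA 0 11\thsa-miR-222\n", doc)
        again = load_standoff(write_standoff(original, doc), doc)
        assert [(m.start, m.end, m.etype, m.norm) for m in again] == \
               [(m.start, m.end, m.etype, m.norm) for m in original]

    def test_norm_override_column(self):
        doc = document_from_abstract("d1", "", "miR-15a/-16-1 works.")
        ms = load_standoff(
            "T1\tmiRNA 0 13\tmiR-15a/-16-1\tmiR-15a\n"
            "T2\tmiRNA 0 13\tmiR-15a/-16-1\tmiR-16-1\n", doc)
        assert sorted(m.norm for m in ms) == ["miR-15a", "miR-16-1"]


class TestNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("the MMP1 expression", "MMP1"),
        ("TGF-betaR2 mRNA", "TGF-betaR2"),
        ("Bcl-2", "Bcl-2"),
        ("a  FOXO1   gene", "FOXO1"),
    ])
    def test_gene_normal_form(self, raw, expected):
        assert normalize_gene_name(raw) == expected

    @pytest.mark.parametrize("raw,expected", [
        ("MicroRNA-223", "miR-223"),
        ("microRNA miR-124", "miR-124"),
        ("hsa-miR-222", "hsa-miR-222"),
        ("miR 21", "miR-21"),
        ("let-7", "let-7"),
    ])
    def test_mirna_normal_form(self, raw, expected):
        assert normalize_mirna_name(raw) == expected

    @given(st.sampled_from([
        "MicroRNA-223", "the MMP1 expression", "hsa-miR-222", "miR-15a",
        "TGF-betaR2 mRNA", "Bcl-2", "a validated target", "let-7", "miR 21",
    ]))
    @settings(max_examples=20, deadline=None)
    def test_idempotence(self, name):
        m = normalize_mirna_name(name)
        g = normalize_gene_name(name)
        assert normalize_mirna_name(m) == m
        assert normalize_gene_name(g) == g
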