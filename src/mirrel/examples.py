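"""Curated regression fixtures: real literature sentences with gold parses.

Sixteen sentences from published abstracts (doc ids are their PMIDs) cover
the extraction constructions the pipeline supports: active and passive
verbs, process-noun and by-phrases, null-argument clauses, is-a,
appositive and member-collection linking, possessive and relative-pronoun
anaphora, the relaxed tier, a combinatorial coordination sentence, and a
gene-miRNA direction case.  Parses are hand-written; mentions are gold
standoff records.  These fixtures, not any external corpus, are the
primary regression suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import Fixture, build_fixture
from .evaluation import GoldAnnotation
from .model import Direction, Directness


@dataclass(frozen=True)
class Example:
    example_ids: tuple[int, ...]
    doc_id: str
    text: str
    parse: str
    # (etype, surface, occurrence_index, norm_override_or_None)
    mentions: tuple = ()
    # (mirna, gene, direction, directness)
    gold: tuple = ()
    requires: str = "same_trigger"  # minimal tier set that recovers the gold
    note: str = ""


def _g(mirna: str, gene: str, direction: str = "mirna_to_gene",
       directness: str = "unknown") -> tuple:
    return (mirna, gene, direction, directness)


EXAMPLES: list[Example] = [
    Example(
        example_ids=(1,), doc_id="PMID-22569260",
        text="MicroRNA-223 regulates FOXO1 expression and cell proliferation.",
        parse="""
        (S (NP (NN MicroRNA-223))
           (VP (VBZ regulates)
               (NP (NP (NN FOXO1) (NN expression))
                   (CC and)
                   (NP (NN cell) (NN proliferation))))
           (. .))
        """,
        mentions=(("miRNA", "MicroRNA-223", 0, None),
                  ("gene", "FOXO1", 0, None)),
        gold=(_g("miR-223", "FOXO1"),),
        note="active verb; directness unknown"),
    Example(
        example_ids=(2,), doc_id="PMID-23861775",
        text=("CyclinB1, cyclinA, bcl-xl and AKt are indirectly regulated by "
              "miR-26a in a CKS2-dependent manner."),
        parse="""
        (S (NP (NP (NN CyclinB1)) (, ,) (NP (NN cyclinA)) (, ,)
               (NP (NN bcl-xl)) (CC and) (NP (NN AKt)))
           (VP (VBP are) (ADVP (RB indirectly))
               (VP (VBN regulated)
                   (PP (IN by) (NP (NN miR-26a)))
                   (PP (IN in) (NP (DT a) (JJ CKS2-dependent) (NN manner)))))
           (. .))
        """,
        mentions=(("gene", "CyclinB1", 0, None), ("gene", "cyclinA", 0, None),
                  ("gene", "bcl-xl", 0, None), ("gene", "AKt", 0, None),
                  ("miRNA", "miR-26a", 0, None)),
        gold=(_g("miR-26a", "CyclinB1"), _g("miR-26a", "cyclinA"),
              _g("miR-26a", "bcl-xl"), _g("miR-26a", "AKt")),
        note="passive coordination; 'indirectly' vetoes directness"),
    Example(
        example_ids=(3,), doc_id="PMID-23579289",
        text=("The direct binding of miR-214 to the Osx 3' untranslated "
              "region (3' UTR) was demonstrated by a luciferase reporter "
              "assay using a construct containing the Osx 3' UTR."),
        parse="""
        (S (NP (NP (DT The) (JJ direct) (NN binding))
               (PP (IN of) (NP (NN miR-214)))
               (PP (TO to)
                   (NP (DT the) (NN Osx) (NN 3') (JJ untranslated)
                       (NN region) (-LRB- -LRB-) (NN 3') (NN UTR)
                       (-RRB- -RRB-))))
           (VP (VBD was)
               (VP (VBN demonstrated)
                   (PP (IN by)
                       (NP (NP (DT a) (NN luciferase) (NN reporter) (NN assay))
                           (VP (VBG using)
                               (NP (NP (DT a) (NN construct))
                                   (VP (VBG containing)
                                       (NP (DT the) (NN Osx) (NN 3')
                                           (NN UTR)))))))))
           (. .))
        """,
        mentions=(("miRNA", "miR-214", 0, None),
                  ("gene", "Osx", 0, None), ("gene", "Osx", 1, None)),
        gold=(_g("miR-214", "Osx", directness="direct"),),
        note="process noun 'binding of X to Y'; direct by trigger class, "
             "modifier and 3'UTR evidence"),
    Example(
        example_ids=(4, 11), doc_id="PMID-23041385",
        text=("TGF-betaR2 mRNA, a validated miR-21 target, showed the "
              "highest expression in the leukocytes from a subset of the "
              "octogenarians."),
        parse="""
        (S (NP (NP (NN TGF-betaR2) (NN mRNA)) (, ,)
               (NP (DT a) (VBN validated) (NN miR-21) (NN target)) (, ,))
           (VP (VBD showed)
               (NP (DT the) (JJS highest) (NN expression))
               (PP (IN in)
                   (NP (NP (DT the) (NNS leukocytes))
                       (PP (IN from)
                           (NP (NP (DT a) (NN subset))
                               (PP (IN of)
                                   (NP (DT the) (NNS octogenarians))))))))
           (. .))
        """,
        mentions=(("gene", "TGF-betaR2", 0, None),
                  ("miRNA", "miR-21", 0, None)),
        gold=(_g("miR-21", "TGF-betaR2", directness="direct"),),
        requires="linking",
        note="entity-noun premodifier agent; theme via appositive"),
    Example(
        example_ids=(5,), doc_id="PMID-23190608",
        text=("We identified Sp1, a transcription factor endowed with "
              "oncogenic activity, as a negative regulator of miR-29b "
              "expression in MM cells."),
        parse="""
        (S (NP (PRP We))
           (VP (VBD identified)
               (NP (NP (NN Sp1)) (, ,)
                   (NP (NP (DT a) (NN transcription) (NN factor))
                       (VP (VBN endowed)
                           (PP (IN with) (NP (JJ oncogenic) (NN activity)))))
                   (, ,))
               (PP (IN as)
                   (NP (NP (DT a) (JJ negative) (NN regulator))
                       (PP (IN of)
                           (NP (NP (NN miR-29b) (NN expression))
                               (PP (IN in) (NP (NN MM) (NNS cells))))))))
           (. .))
        """,
        mentions=(("gene", "Sp1", 0, None),
                  ("miRNA", "miR-29b", 0, None)),
        gold=(("miR-29b", "Sp1", "gene_to_mirna", "unknown"),),
        requires="linking",
        note="gene-miRNA direction; agentive entity noun resolved via "
             "as-predicative"),
    Example(
        example_ids=(6,), doc_id="PMID-19487542",
        text=("Taken together, these results suggested that hsa-miR-222 "
              "regulates the MMP1 expression."),
        parse="""
        (S (S (VP (VBN Taken) (ADVP (RB together)))) (, ,)
           (NP (DT these) (NNS results))
           (VP (VBD suggested)
               (SBAR (IN that)
                     (S (NP (NN hsa-miR-222))
                        (VP (VBZ regulates)
                            (NP (DT the) (NN MMP1) (NN expression))))))
           (. .))
        """,
        mentions=(("miRNA", "hsa-miR-222", 0, None),
                  ("gene", "MMP1", 0, None)),
        gold=(_g("hsa-miR-222", "MMP1"),),
        note="active verb inside complement clause"),
    Example(
        example_ids=(7,), doc_id="PMID-23303397",
        text="regulation of RhoG expression by the microRNA miR-124",
        parse="""
        (NP (NP (NN regulation))
            (PP (IN of) (NP (NN RhoG) (NN expression)))
            (PP (IN by) (NP (DT the) (NN microRNA) (NN miR-124))))
        """,
        mentions=(("gene", "RhoG", 0, None),
                  ("miRNA", "miR-124", 0, None)),
        gold=(_g("miR-124", "RhoG"),),
        note="process noun with of-theme and by-agent"),
    Example(
        example_ids=(8,), doc_id="PMID-11780335",
        text="LMP1 activated NF-kappa B via phosphorylation.",
        parse="""
        (S (NP (NN LMP1))
           (VP (VBD activated)
               (NP (NN NF-kappa) (NN B))
               (PP (IN via) (NP (NN phosphorylation))))
           (. .))
        """,
        mentions=(("gene", "LMP1", 0, None),
                  ("gene", "NF-kappa B", 0, None)),
        gold=(),
        note="null-argument construction shape; no miRNA, no relations"),
    Example(
        example_ids=(9,), doc_id="PMID-24099915",
        text=("MicroRNA-31 inhibits cisplatin-induced apoptosis in "
              "non-small cell lung cancer cells by regulating the drug "
              "transporter ABCB9."),
        parse="""
        (S (NP (NN MicroRNA-31))
           (VP (VBZ inhibits)
               (NP (JJ cisplatin-induced) (NN apoptosis))
               (PP (IN in)
                   (NP (JJ non-small) (NN cell) (NN lung) (NN cancer)
                       (NNS cells)))
               (PP (IN by)
                   (S (VP (VBG regulating)
                          (NP (DT the) (NN drug) (NN transporter)
                              (NN ABCB9))))))
           (. .))
        """,
        mentions=(("miRNA", "MicroRNA-31", 0, None),
                  ("gene", "ABCB9", 0, None)),
        gold=(_g("miR-31", "ABCB9"),),
        note="null-argument agent for the embedded trigger"),
    Example(
        example_ids=(10,), doc_id="PMID-22870299",
        text=("We show that the proinflammatory cytokine interleukin 1 "
              "alpha (IL1A) is a target for miR-142-3p."),
        parse="""
        (S (NP (PRP We))
           (VP (VBP show)
               (SBAR (IN that)
                     (S (NP (DT the) (JJ proinflammatory) (NN cytokine)
                            (NN interleukin) (CD 1) (NN alpha)
                            (-LRB- -LRB-) (NN IL1A) (-RRB- -RRB-))
                        (VP (VBZ is)
                            (NP (NP (DT a) (NN target))
                                (PP (IN for) (NP (NN miR-142-3p))))))))
           (. .))
        """,
        mentions=(("gene", "IL1A", 0, None),
                  ("miRNA", "miR-142-3p", 0, None)),
        gold=(_g("miR-142-3p", "IL1A", directness="direct"),),
        requires="linking",
        note="referential theme resolved through is-a"),
    Example(
        example_ids=(12,), doc_id="PMID-22465011",
        text=("Over-expression of miR-499 in rat BM-MSCs increased the "
              "expression of cardiac-specific genes, such as NKx2.5, "
              "GATA4, MEF2C, and cTnI."),
        parse="""
        (S (NP (NP (NN Over-expression))
               (PP (IN of) (NP (NN miR-499)))
               (PP (IN in) (NP (NN rat) (NNS BM-MSCs))))
           (VP (VBD increased)
               (NP (NP (DT the) (NN expression))
                   (PP (IN of)
                       (NP (NP (JJ cardiac-specific) (NNS genes)) (, ,)
                           (PP (JJ such) (IN as)
                               (NP (NP (NN NKx2.5)) (, ,) (NP (NN GATA4))
                                   (, ,) (NP (NN MEF2C)) (, ,) (CC and)
                                   (NP (NN cTnI))))))))
           (. .))
        """,
        mentions=(("miRNA", "miR-499", 0, None),
                  ("gene", "NKx2.5", 0, None), ("gene", "GATA4", 0, None),
                  ("gene", "MEF2C", 0, None), ("gene", "cTnI", 0, None)),
        gold=(_g("miR-499", "NKx2.5"), _g("miR-499", "GATA4"),
              _g("miR-499", "MEF2C"), _g("miR-499", "cTnI")),
        note="member-collection list inside the theme phrase"),
    Example(
        example_ids=(13,), doc_id="PMID-20545570",
        text=("the miR-21 was upregulated in 0.5 Gy-treated TK6 cells and "
              "its target genes programmed cell death factor 4 (hPDCD4) "
              "phosphatase and tensin homolog (hPTEN), and sprouty homolog "
              "2 (hSPRY2) were found to be downregulated in these cells."),
        parse="""
        (S (S (NP (DT the) (NN miR-21))
              (VP (VBD was)
                  (VP (VBN upregulated)
                      (PP (IN in)
                          (NP (CD 0.5) (JJ Gy-treated) (NN TK6)
                              (NNS cells))))))
           (CC and)
           (S (NP (NP (PRP$ its) (NN target) (NNS genes))
                  (NP (NP (VBN programmed) (NN cell) (NN death) (NN factor)
                          (CD 4) (-LRB- -LRB-) (NN hPDCD4) (-RRB- -RRB-))
                      (NP (NN phosphatase) (CC and) (NN tensin) (NN homolog)
                          (-LRB- -LRB-) (NN hPTEN) (-RRB- -RRB-))
                      (, ,) (CC and)
                      (NP (JJ sprouty) (NN homolog) (CD 2)
                          (-LRB- -LRB-) (NN hSPRY2) (-RRB- -RRB-))))
              (VP (VBD were)
                  (VP (VBN found)
                      (S (VP (TO to)
                             (VP (VB be)
                                 (VP (VBN downregulated)
                                     (PP (IN in)
                                         (NP (DT these) (NNS cells))))))))))
           (. .))
        """,
        mentions=(("miRNA", "miR-21", 0, None),
                  ("gene", "hPDCD4", 0, None), ("gene", "hPTEN", 0, None),
                  ("gene", "hSPRY2", 0, None)),
        gold=(_g("miR-21", "hPDCD4", directness="direct"),
              _g("miR-21", "hPTEN", directness="direct"),
              _g("miR-21", "hSPRY2", directness="direct")),
        requires="linking",
        note="possessive anaphora agent; theme via bare apposition to the "
             "gene list"),
    Example(
        example_ids=(14,), doc_id="PMID-23104180",
        text=("Two miRNAs, miR-15a and miR-16, which act as putative tumor "
              "suppressor by targeting the oncogene BCL2, have been "
              "implicated in cell cycle, apoptosis and proliferation."),
        parse="""
        (S (NP (NP (CD Two) (NNS miRNAs)) (, ,)
               (NP (NP (NN miR-15a)) (CC and) (NP (NN miR-16))) (, ,)
               (SBAR (WHNP (WDT which))
                     (S (VP (VBP act)
                            (PP (IN as)
                                (NP (JJ putative) (NN tumor) (NN suppressor)))
                            (PP (IN by)
                                (S (VP (VBG targeting)
                                       (NP (NP (DT the) (NN oncogene))
                                           (NP (NN BCL2)))))))))
               (, ,))
           (VP (VBP have)
               (VP (VBN been)
                   (VP (VBN implicated)
                       (PP (IN in)
                           (NP (NP (NN cell) (NN cycle)) (, ,)
                               (NP (NN apoptosis)) (CC and)
                               (NP (NN proliferation)))))))
           (. .))
        """,
        mentions=(("miRNA", "miR-15a", 0, None),
                  ("miRNA", "miR-16", 0, None),
                  ("gene", "BCL2", 0, None)),
        gold=(_g("miR-15a", "BCL2", directness="direct"),
              _g("miR-16", "BCL2", directness="direct")),
        requires="linking",
        note="relative pronoun agent of a null-argument trigger"),
    Example(
        example_ids=(15,), doc_id="PMID-17891175",
        text=("we have identified additional potential mRNA targets of one "
              "of the miRNAs, (miR-125b) that are upregulated in prostate "
              "cancer and confirmed increased expression of one of these "
              "targets, EIF4EBP1."),
        parse="""
        (S (NP (PRP we))
           (VP (VP (VBP have)
                   (VP (VBN identified)
                       (NP (NP (JJ additional) (JJ potential) (NN mRNA)
                               (NNS targets))
                           (PP (IN of)
                               (NP (NP (CD one))
                                   (PP (IN of)
                                       (NP (NP (DT the) (NNS miRNAs)) (, ,)
                                           (NP (-LRB- -LRB-) (NN miR-125b)
                                               (-RRB- -RRB-))
                                           (SBAR (WHNP (WDT that))
                                                 (S (VP (VBP are)
                                                        (VP (VBN upregulated)
                                                            (PP (IN in)
                                                                (NP (NN prostate)
                                                                    (NN cancer))))))))))))))
               (CC and)
               (VP (VBD confirmed)
                   (NP (NP (VBN increased) (NN expression))
                       (PP (IN of)
                           (NP (NP (CD one))
                               (PP (IN of)
                                   (NP (NP (DT these) (NNS targets)) (, ,)
                                       (NP (NN EIF4EBP1)))))))))
           (. .))
        """,
        mentions=(("miRNA", "miR-125b", 0, None),
                  ("gene", "EIF4EBP1", 0, None)),
        gold=(_g("miR-125b", "EIF4EBP1", directness="direct"),),
        requires="relaxed",
        note="agent and theme carried by different trigger occurrences"),
    Example(
        example_ids=(16,), doc_id="PMID-16784027",
        text=("the miRNA (miR) -17-92 cluster has been characterized as an "
              "oncogene, while let-7 represses Ras and miR-15a/-16-1 "
              "represses Bcl-2, thereby acting as tumor suppressors."),
        parse="""
        (S (S (NP (DT the) (NN miRNA) (-LRB- -LRB-) (NN miR) (-RRB- -RRB-)
                  (NN -17-92) (NN cluster))
              (VP (VBZ has)
                  (VP (VBN been)
                      (VP (VBN characterized)
                          (PP (IN as) (NP (DT an) (NN oncogene)))))))
           (, ,)
           (SBAR (IN while)
                 (S (S (NP (NN let-7))
                       (VP (VBZ represses) (NP (NN Ras))))
                    (CC and)
                    (S (NP (NN miR-15a/-16-1))
                       (VP (VBZ represses) (NP (NN Bcl-2))))))
           (, ,)
           (S (ADVP (RB thereby))
              (VP (VBG acting)
                  (PP (IN as) (NP (NN tumor) (NNS suppressors)))))
           (. .))
        """,
        mentions=(("miRNA", "(miR) -17-92", 0, "miR-17-92"),
                  ("miRNA", "let-7", 0, None),
                  ("miRNA", "miR-15a/-16-1", 0, "miR-15a"),
                  ("miRNA", "miR-15a/-16-1", 0, "miR-16-1"),
                  ("gene", "Ras", 0, None),
                  ("gene", "Bcl-2", 0, None)),
        gold=(_g("let-7", "Ras"), _g("miR-15a", "Bcl-2"),
              _g("miR-16-1", "Bcl-2")),
        note="coordination with slash conjunction; the cluster mention "
             "participates in no relation"),
]


def _nth_offset(text: str, surface: str, n: int) -> int:
    pos = -1
    for _ in range(n + 1):
        pos = text.find(surface, pos + 1)
        if pos < 0:
            raise ValueError(f"surface {surface!r} (occurrence {n}) not in text")
    return pos


def standoff_for(example: Example) -> str:
    lines = []
    for i, (etype, surface, n, norm) in enumerate(example.mentions, start=1):
        start = _nth_offset(example.text, surface, n)
        norm_col = f"\t{norm}" if norm else ""
        lines.append(f"T{i}\t{etype} {start} {start + len(surface)}"
                     f"\t{surface}{norm_col}")
    return "\n".join(lines) + ("\n" if lines else "")


def as_fixture(example: Example) -> Fixture:
    gold = [GoldAnnotation(example.doc_id, m, g, Direction(d), Directness(x))
            for (m, g, d, x) in example.gold]
    return build_fixture(example.doc_id, example.text, [example.parse],
                         standoff_for(example), gold,
                         provenance=f"curated:{example.doc_id}")


def fixtures() -> list[Fixture]:
    """All curated fixtures (one per document; two examples share a PMID)."""
    return [as_fixture(e) for e in EXAMPLES]


def by_example_id(example_id: int) -> Example:
    for e in EXAMPLES:
        if example_id in e.example_ids:
            return e
    raise KeyError(example_id)


def gold_annotations() -> list[GoldAnnotation]:
    out = []
    for e in EXAMPLES:
        for (m, g, d, x) in e.gold:
            out.append(GoldAnnotation(e.doc_id, m, g, Direction(d), Directness(x)))
    return out
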