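"""Synthetic fixture generator: template sentences with gold parses.

Each template instantiates one construction from the rule inventory
(active/passive verb, process noun, null-argument clause, is-a,
appositive, member-collection list, possessive and relative-pronoun
anaphora, a different-trigger sentence reachable only by the relaxed tier,
a gene-miRNA direction sentence, and a trigger/entity co-occurrence
distractor with no true relation).  Sentences carry programmatically
constructed gold parses, so the whole pipeline is testable without an
external parser.  Generation is deterministic for a fixed seed.

Because templates are built from the very constructions the rules cover,
perfect scores on generated corpora are a closure property of the system,
not a claim about real text.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .corpus import Fixture, build_fixture
from .evaluation import GoldAnnotation
from .model import Direction, Directness
from .textprep import read_ptb_trees


class TemplateError(ValueError):
    """Unknown template id."""


_NO_SPACE_BEFORE = set(",.;:!?)]}")
_NO_SPACE_AFTER = set("([{")


def detokenize(tokens: list[str]) -> str:
    out = ""
    for t in tokens:
        if out and t not in _NO_SPACE_BEFORE and out[-1] not in _NO_SPACE_AFTER:
            out += " "
        out += t
    return out


def _text_from_parse(parse: str) -> str:
    tree = read_ptb_trees(parse)[0]
    return detokenize(tree.leaf_surfaces())


@dataclass
class TemplateOutput:
    parse: str
    mentions: list[tuple]  # (etype, surface)
    gold: list[tuple]      # (mirna, gene, direction, directness)
    requires: str          # same_trigger | linking | relaxed | none


def _mirna_names(rng: random.Random, k: int) -> list[str]:
    nums = rng.sample(range(100, 1000), k)
    return [f"miR-{n}{rng.choice(['', 'a', 'b'])}" for n in nums]


def _gene_names(rng: random.Random, k: int) -> list[str]:
    out = []
    while len(out) < k:
        name = "".join(rng.choice(string.ascii_uppercase) for _ in range(4))
        name += str(rng.randint(1, 9))
        if name not in out and not name.startswith("MIR"):
            out.append(name)
    return out


def t_active_verb(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    verb = rng.choice(["regulates", "suppresses", "represses", "inhibits",
                       "downregulates", "upregulates"])
    direct = rng.random() < 0.4
    adv = "(ADVP (RB directly)) " if direct else ""
    parse = (f"(S (NP (NN {m})) (VP {adv}(VBZ {verb}) "
             f"(NP (NP (NN {g}) (NN expression)) "
             f"(PP (IN in) (NP (NN tumor) (NNS cells))))) (. .))")
    return TemplateOutput(parse, [("miRNA", m), ("gene", g)],
                          [(m, g, "mirna_to_gene",
                            "direct" if direct else "unknown")],
                          "same_trigger")


def t_passive_verb(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    vbn = rng.choice(["regulated", "suppressed", "repressed", "inhibited"])
    parse = (f"(S (NP (NN {g})) (VP (VBZ is) (VP (VBN {vbn}) "
             f"(PP (IN by) (NP (NN {m}))))) (. .))")
    return TemplateOutput(parse, [("gene", g), ("miRNA", m)],
                          [(m, g, "mirna_to_gene", "unknown")], "same_trigger")


def t_process_noun(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    noun = rng.choice(["regulation", "suppression", "repression", "inhibition"])
    parse = (f"(S (NP (PRP We)) (VP (VBP report) "
             f"(NP (NP (DT the) (NN {noun})) "
             f"(PP (IN of) (NP (NN {g}))) "
             f"(PP (IN by) (NP (NN {m}))))) (. .))")
    return TemplateOutput(parse, [("gene", g), ("miRNA", m)],
                          [(m, g, "mirna_to_gene", "unknown")], "same_trigger")


def t_null_arg(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    vbg = rng.choice(["suppressing", "repressing", "downregulating"])
    prep = rng.choice(["by", "via", "through"])
    parse = (f"(S (NP (NN {m})) (VP (VBZ reduces) "
             f"(NP (NN tumor) (NN growth)) "
             f"(PP (IN {prep}) (S (VP (VBG {vbg}) (NP (NN {g})))))) (. .))")
    # null-argument rule + down-polarity trigger => direct
    return TemplateOutput(parse, [("miRNA", m), ("gene", g)],
                          [(m, g, "mirna_to_gene", "direct")], "same_trigger")


def t_is_a(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    parse = (f"(S (NP (NN {g})) (VP (VBZ is) "
             f"(NP (NP (DT a) (JJ direct) (NN target)) "
             f"(PP (IN of) (NP (NN {m}))))) (. .))")
    return TemplateOutput(parse, [("gene", g), ("miRNA", m)],
                          [(m, g, "mirna_to_gene", "direct")], "linking")


def t_appositive(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    parse = (f"(S (NP (NP (NN {g}) (NN mRNA)) (, ,) "
             f"(NP (DT a) (VBN validated) (NN {m}) (NN target)) (, ,)) "
             f"(VP (VBD showed) (NP (VBN reduced) (NN expression))) (. .))")
    return TemplateOutput(parse, [("gene", g), ("miRNA", m)],
                          [(m, g, "mirna_to_gene", "direct")], "linking")


def t_member_collection(rng: random.Random) -> TemplateOutput:
    (m,) = _mirna_names(rng, 1)
    k = rng.randint(2, 4)
    genes = _gene_names(rng, k)
    gene_nps = []
    for i, g in enumerate(genes):
        if i == len(genes) - 1 and len(genes) > 1:
            gene_nps.append(f"(CC and) (NP (NN {g}))")
        elif i:
            gene_nps.append(f"(, ,) (NP (NN {g}))")
        else:
            gene_nps.append(f"(NP (NN {g}))")
    parse = (f"(S (NP (NN {m})) (VP (VBD increased) "
             f"(NP (NP (DT the) (NN expression)) "
             f"(PP (IN of) (NP (NP (JJ stress-responsive) (NNS genes)) (, ,) "
             f"(PP (JJ such) (IN as) (NP {' '.join(gene_nps)})))))) (. .))")
    return TemplateOutput(parse, [("miRNA", m)] + [("gene", g) for g in genes],
                          [(m, g, "mirna_to_gene", "unknown") for g in genes],
                          "same_trigger")


def t_its_possessive(rng: random.Random) -> TemplateOutput:
    (m,) = _mirna_names(rng, 1)
    g1, g2 = _gene_names(rng, 2)
    parse = (f"(S (S (NP (NN {m})) (VP (VBD was) (VP (VBN overexpressed) "
             f"(PP (IN in) (NP (NN tumor) (NNS cells)))))) (CC and) "
             f"(S (NP (NP (PRP$ its) (NN target) (NNS genes)) "
             f"(NP (NP (NN {g1})) (CC and) (NP (NN {g2})))) "
             f"(VP (VBD were) (VP (VBN downregulated)))) (. .))")
    return TemplateOutput(parse,
                          [("miRNA", m), ("gene", g1), ("gene", g2)],
                          [(m, g1, "mirna_to_gene", "direct"),
                           (m, g2, "mirna_to_gene", "direct")], "linking")


def t_which_relative(rng: random.Random) -> TemplateOutput:
    m1, m2 = _mirna_names(rng, 2)
    (g,) = _gene_names(rng, 1)
    parse = (f"(S (NP (NP (CD Two) (NNS miRNAs)) (, ,) "
             f"(NP (NP (NN {m1})) (CC and) (NP (NN {m2}))) (, ,) "
             f"(SBAR (WHNP (WDT which)) (S (VP (VBP promote) "
             f"(NP (NN tumor) (NN growth)) "
             f"(PP (IN by) (S (VP (VBG targeting) (NP (NN {g})))))))) (, ,)) "
             f"(VP (VBD were) (VP (VBN analyzed))) (. .))")
    return TemplateOutput(parse,
                          [("miRNA", m1), ("miRNA", m2), ("gene", g)],
                          [(m1, g, "mirna_to_gene", "direct"),
                           (m2, g, "mirna_to_gene", "direct")], "linking")


def t_different_trigger(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    parse = (f"(S (NP (PRP we)) (VP (VP (VBD identified) "
             f"(NP (NP (JJ putative) (NNS targets)) "
             f"(PP (IN of) (NP (NN {m}))))) (CC and) "
             f"(VP (VBD confirmed) (NP (NP (CD one)) "
             f"(PP (IN of) (NP (NP (DT these) (NNS targets)) (, ,) "
             f"(NP (NN {g}))))))) (. .))")
    return TemplateOutput(parse, [("miRNA", m), ("gene", g)],
                          [(m, g, "mirna_to_gene", "direct")], "relaxed")


def t_gene_mirna(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    parse = (f"(S (NP (NN {g})) (VP (VBZ is) "
             f"(NP (NP (DT a) (JJ negative) (NN regulator)) "
             f"(PP (IN of) (NP (NN {m}) (NN expression))))) (. .))")
    return TemplateOutput(parse, [("gene", g), ("miRNA", m)],
                          [(m, g, "gene_to_mirna", "unknown")], "linking")


def t_cooc_distractor(rng: random.Random) -> TemplateOutput:
    (m,), (g,) = _mirna_names(rng, 1), _gene_names(rng, 1)
    parse = (f"(S (NP (CC Both) (NP (NN {m})) (CC and) (NP (NN {g}))) "
             f"(VP (VBD were) (VP (VBN detected) "
             f"(PP (IN in) (NP (NP (NNS samples)) "
             f"(PP (IN with) (NP (NP (JJ aberrant) (NN regulation)) "
             f"(PP (IN of) (NP (NN apoptosis))))))))) (. .))")
    return TemplateOutput(parse, [("miRNA", m), ("gene", g)], [], "none")


TEMPLATES: dict[str, Callable[[random.Random], TemplateOutput]] = {
    "active_verb": t_active_verb,
    "passive_verb": t_passive_verb,
    "process_noun": t_process_noun,
    "null_arg": t_null_arg,
    "is_a": t_is_a,
    "appositive": t_appositive,
    "member_collection": t_member_collection,
    "its_possessive": t_its_possessive,
    "which_relative": t_which_relative,
    "different_trigger": t_different_trigger,
    "gene_mirna": t_gene_mirna,
    "cooc_distractor": t_cooc_distractor,
}


def instantiate(template_id: str, rng: random.Random,
                doc_id: str) -> Fixture:
    builder = TEMPLATES.get(template_id)
    if builder is None:
        raise TemplateError(f"unknown template id {template_id!r}")
    out = builder(rng)
    text = _text_from_parse(out.parse)
    lines = []
    for i, (etype, surface) in enumerate(out.mentions, start=1):
        start = text.find(surface)
        lines.append(f"T{i}\t{etype} {start} {start + len(surface)}\t{surface}")
    gold = [GoldAnnotation(doc_id, mi, ge, Direction(d), Directness(x))
            for (mi, ge, d, x) in out.gold]
    fx = build_fixture(doc_id, text, [out.parse],
                       "\n".join(lines) + ("\n" if lines else ""), gold,
                       provenance=f"generated:{template_id}")
    fx.template_id = template_id  # type: ignore[attr-defined]
    fx.requires = out.requires    # type: ignore[attr-defined]
    return fx


def generate_fixtures(seed: int, n: int,
                      templates: Optional[Iterable[str]] = None) -> list[Fixture]:
    """Generate ``n`` fixtures, reproducibly for a fixed seed.

    Templates are cycled so every construction is represented, with the
    per-fixture entity names and lexical choices drawn from the seeded RNG.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = list(templates) if templates is not None else list(TEMPLATES)
    for t in ids:
        if t not in TEMPLATES:
            raise TemplateError(f"unknown template id {t!r}")
    rng = random.Random(seed)
    out = []
    for i in range(n):
        tid = ids[i % len(ids)]
        out.append(instantiate(tid, rng, f"SYN-{tid}-{i:04d}"))
    return out
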