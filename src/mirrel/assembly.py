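"""Relation assembly: relaxed tier, directness, aggregation, baseline.

The same-trigger tier extracts high-confidence relations.  The relaxed
tier then pairs, combinatorially, any leftover miRNA matched as an agent
with any leftover gene matched as a theme — "leftover" meaning the entity
participates in no same-trigger relation of that sentence.  A miRNA-gene
regulation relation is additionally classified as a direct miRNA-target
relation when in-sentence evidence supports direct binding of the miRNA to
the gene's mRNA.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable

from .model import Direction, Directness, EntityMention, EntityType, Sentence, Tier
from .rules import ArgumentMatch, CandidateRelation
from .triggers import TriggerLexicon, TriggerOccurrence, find_triggers

# sentence-level lexical evidence for directness
_UTR_RE = re.compile(
    r"3\s*['′’]\s*-?\s*(?:UTR|untranslated\s+region)"
    r"|three\s+prime\s+untranslated\s+region"
    r"|\btranslation\b",
    re.IGNORECASE)

_DIRECT_MODIFIERS = {"direct", "directly", "immediate", "immediately"}
_INDIRECT = {"indirect", "indirectly"}


def apply_relaxed(matches: Iterable[ArgumentMatch],
                  same_trigger: Iterable[CandidateRelation],
                  sentence: Sentence,
                  direction: Direction) -> list[CandidateRelation]:
    """Pair leftover agent-matched miRNAs with leftover theme-matched genes.

    Only entities that were matched as arguments by some rule but do not
    participate in any same-trigger relation of the sentence are paired;
    the pairing is combinatorial and the trigger words need not agree.
    """
    participants = set()
    for rel in same_trigger:
        if rel.direction is direction:
            participants.add(rel.agent.norm)
            participants.add(rel.theme.norm)
    agents: dict[str, tuple[EntityMention, ArgumentMatch]] = {}
    themes: dict[str, tuple[EntityMention, ArgumentMatch]] = {}
    for m in matches:
        if m.direction is not direction or not m.resolved_entities:
            continue
        slot = agents if m.role == "agent" else themes
        for e in m.resolved_entities:
            if e.norm not in participants:
                slot.setdefault(e.norm, (e, m))
    out = []
    for a_norm in sorted(agents):
        for t_norm in sorted(themes):
            a, am = agents[a_norm]
            t, tm = themes[t_norm]
            out.append(CandidateRelation(
                sent_id=sentence.sent_id, sent_text=sentence.text,
                direction=direction, agent=a, theme=t,
                triggers=list({id(x): x for x in (am.trigger, tm.trigger)}.values()),
                tier=Tier.relaxed,
                rule_ids=sorted({am.rule_id, tm.rule_id}),
                linking_methods=sorted({x for x in (am.linking_method,
                                                    tm.linking_method) if x})))
    return out


def classify_directness(relation: CandidateRelation, sentence: Sentence) -> Directness:
    """Direct iff any evidence holds, unless an explicit "indirect(ly)" vetoes.

    Evidence: (1) a binding-class trigger (target/bind/interact or derived
    form); (2) the trigger modified by direct(ly)/immediate(ly); (3) a
    null-argument rule fired and the trigger down-regulates its theme;
    (4) "translation" or a 3'UTR variant occurs in the sentence.
    """
    if relation.direction is not Direction.mirna_to_gene:
        return Directness.unknown
    toks = [t.surface.lower() for t in sentence.tokens]
    if any(t in _INDIRECT for t in toks):
        return Directness.unknown
    for occ in relation.triggers:
        if occ.entry.directness_class:
            return Directness.direct
        lo, hi = max(0, occ.token_index - 2), min(len(toks), occ.token_index + 3)
        if any(toks[i] in _DIRECT_MODIFIERS for i in range(lo, hi)
               if i != occ.token_index):
            return Directness.direct
    if any("null-arg" in rid for rid in relation.rule_ids):
        if any(occ.entry.polarity == "down" for occ in relation.triggers):
            return Directness.direct
    if _UTR_RE.search(sentence.text):
        return Directness.direct
    return Directness.unknown


def cooccurrence_baseline(sentence: Sentence, lexicon: TriggerLexicon,
                          mentions: Iterable[EntityMention]) -> list[CandidateRelation]:
    """Sentence co-occurrence baseline: a trigger anywhere plus a miRNA and
    a gene in the same sentence yields all pairs (no parse required)."""
    mentions = list(mentions)
    triggers = find_triggers(sentence, lexicon, mentions)
    if not triggers:
        return []
    mirnas = {m.norm: m for m in mentions if m.etype is EntityType.miRNA and m.specific}
    genes = {m.norm: m for m in mentions if m.etype is EntityType.gene}
    out = []
    for mn in sorted(mirnas):
        for gn in sorted(genes):
            rel = CandidateRelation(
                sent_id=sentence.sent_id, sent_text=sentence.text,
                direction=Direction.mirna_to_gene,
                agent=mirnas[mn], theme=genes[gn], triggers=list(triggers),
                tier=Tier.cooccurrence, rule_ids=["cooccurrence"])
            # directness from lexical evidence only (E1/E4)
            if any(t.entry.directness_class for t in triggers) or _UTR_RE.search(sentence.text):
                if not any(tok.surface.lower() in _INDIRECT for tok in sentence.tokens):
                    rel.directness = Directness.direct.value
            out.append(rel)
    return out


# --- document-level aggregation -------------------------------------------

@dataclass
class Relation:
    """A unique document-level relation with merged evidence."""

    doc_id: str
    mirna_norm: str
    gene_norm: str
    direction: Direction
    directness: Directness
    triggers: list[str]
    tier: Tier
    evidence: list[tuple[str, str]]  # (sent_id, sentence text)
    rule_trace: list[str] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.doc_id, self.mirna_norm, self.gene_norm, self.direction)

    def to_row(self) -> list[str]:
        return [self.doc_id, self.mirna_norm, self.gene_norm,
                self.direction.value, self.directness.value,
                "|".join(self.triggers), self.tier.value,
                "|".join(s for s, _ in self.evidence)]

    def to_json(self) -> dict:
        return {
            "doc_id": self.doc_id, "miRNA": self.mirna_norm,
            "gene": self.gene_norm, "direction": self.direction.value,
            "directness": self.directness.value, "triggers": self.triggers,
            "tier": self.tier.value,
            "evidence": [{"sent_id": s, "text": t} for s, t in self.evidence],
            "rule_trace": self.rule_trace,
        }


TSV_HEADER = ["doc_id", "miRNA", "gene", "direction", "directness",
              "triggers", "tier", "sentence_ids"]

_TIER_ORDER = {Tier.same_trigger: 0, Tier.relaxed: 1, Tier.cooccurrence: 2}


def aggregate_document(candidates: Iterable[CandidateRelation],
                       doc_id: str) -> list[Relation]:
    """Merge sentence-level candidates into unique document-level relations.

    Grouping is by (miRNA, gene, direction); directness is direct if any
    member is direct; the tier kept is the most confident one.  Output
    ordering is deterministic (direction, miRNA, gene).  Idempotent.
    """
    groups: dict[tuple, Relation] = {}
    for c in candidates:
        key = (c.mirna_norm, c.gene_norm, c.direction)
        directness = (c.directness if isinstance(c.directness, Directness)
                      else Directness(c.directness))
        trace = [f"{c.sent_id}:{rid}" for rid in c.rule_ids] + [
            f"{c.sent_id}:link={m}" for m in c.linking_methods]
        if key not in groups:
            groups[key] = Relation(
                doc_id=doc_id, mirna_norm=c.mirna_norm, gene_norm=c.gene_norm,
                direction=c.direction, directness=directness,
                triggers=sorted({t.lemma for t in c.triggers}),
                tier=c.tier, evidence=[(c.sent_id, c.sent_text)],
                rule_trace=trace)
        else:
            r = groups[key]
            if directness is Directness.direct:
                r.directness = Directness.direct
            r.triggers = sorted(set(r.triggers) | {t.lemma for t in c.triggers})
            if (c.sent_id, c.sent_text) not in r.evidence:
                r.evidence.append((c.sent_id, c.sent_text))
            if _TIER_ORDER[c.tier] < _TIER_ORDER[r.tier]:
                r.tier = c.tier
            r.rule_trace = sorted(set(r.rule_trace) | set(trace))
    return sorted(groups.values(),
                  key=lambda r: (r.direction.value, r.mirna_norm, r.gene_norm))


def relations_to_tsv(relations: Iterable[Relation]) -> str:
    lines = ["\t".join(TSV_HEADER)]
    for r in relations:
        lines.append("\t".join(r.to_row()))
    return "\n".join(lines) + "\n"


def relations_to_json(relations: Iterable[Relation]) -> str:
    return json.dumps([r.to_json() for r in relations], indent=2)
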