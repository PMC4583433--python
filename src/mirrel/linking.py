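"""Referential linking and anaphora resolution.

Argument phrases often refer to an entity instead of naming it: "a
validated miR-21 target", "its target genes", "which".  This module
resolves such phrases to actual entity mentions using, in order, is-a
(copular and as-predicative) constructions, appositives, and
member-collection lists; pronouns and demonstrative/numeric NPs are
resolved by scoped anaphora resolution with number and type agreement;
relative pronouns are linked to the nearest type-compatible NP inside the
constituent that hosts the relative clause.

Resolution only ever adds relations: an unresolved referential argument is
dropped from pairing, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import EntityMention, ParseNode, Sentence
from .rules import (
    ArgumentMatch,
    KIND_DEMONSTRATIVE,
    KIND_ENTITY_NOUN,
    KIND_NUMERIC,
    KIND_POSSESSIVE,
    KIND_PRONOUN,
    KIND_RELATIVE,
    mentions_within,
)
from .treequery import head_preterminal, leaf_surface

METHOD_IS_A = "is_a"
METHOD_APPOSITIVE = "appositive"
METHOD_MEMBER_COLLECTION = "member_collection"
METHOD_ANAPHORA = "anaphora"
METHOD_RELATIVE = "relative_pronoun"
METHOD_UNRESOLVED = "unresolved"

_BE = {"be", "is", "are", "was", "were", "been", "being", "am", "remains",
       "remain"}

_COLLECTION_CUES = (["such", "as"], ["including"], ["like"], ["namely"],
                    ["e.g."], ["i.e."], [":"])


@dataclass
class ResolutionResult:
    antecedents: list[EntityMention]
    method: str

    @property
    def resolved(self) -> bool:
        return bool(self.antecedents)


UNRESOLVED = ResolutionResult([], METHOD_UNRESOLVED)


def _within(inner: ParseNode, outer: ParseNode) -> bool:
    return outer.span[0] <= inner.span[0] and inner.span[1] <= outer.span[1]


def _disjoint(a: ParseNode, b: ParseNode) -> bool:
    return a.span[1] <= b.span[0] or b.span[1] <= a.span[0]


# --- referential linking ---------------------------------------------------

def _is_a(phrase: ParseNode, sentence: Sentence, mentions, etype) -> list[EntityMention]:
    tree = sentence.parse
    for node in tree.nodes():
        if not node.label.startswith("S"):
            continue
        subj = next((c for c in node.children if c.label.startswith("NP")
                     and not c.is_leaf), None)
        vp = next((c for c in node.children if c.label.startswith("VP")
                   and not c.is_leaf), None)
        if subj is None or vp is None:
            continue
        head = head_preterminal(vp)
        if head is None or leaf_surface(head).lower() not in _BE:
            continue
        if _within(phrase, vp) and _disjoint(phrase, subj):
            ants = mentions_within(subj, sentence, mentions, etype)
            if ants:
                return ants
        if _within(phrase, subj):
            ants = mentions_within(vp, sentence, mentions, etype)
            if ants:
                return ants
    # as-predicatives: "identified X ... as <phrase>"
    for node in tree.nodes():
        if not node.label.startswith("VP"):
            continue
        obj = next((c for c in node.children if c.label.startswith("NP")
                    and not c.is_leaf), None)
        if obj is None or not _disjoint(phrase, obj):
            continue
        for pp in node.children:
            if pp.label != "PP" or pp.is_leaf:
                continue
            first = pp.preterminals()[0] if pp.preterminals() else None
            if first is None or leaf_surface(first).lower() != "as":
                continue
            if _within(phrase, pp):
                ants = mentions_within(obj, sentence, mentions, etype)
                if ants:
                    return ants
    return []


def _appositive(phrase: ParseNode, sentence: Sentence, mentions, etype) -> list[EntityMention]:
    parent = phrase.parent
    if parent is None or not parent.label.startswith("NP"):
        return []
    kids = parent.children
    try:
        idx = kids.index(phrase)
    except ValueError:
        return []

    def scan(direction: int) -> list[EntityMention]:
        j = idx + direction
        while 0 <= j < len(kids):
            k = kids[j]
            if k.is_preterminal and leaf_surface(k) in {",", "—", "-"}:
                j += direction
                continue
            if k.label.startswith("NP") and not k.is_leaf:
                return mentions_within(k, sentence, mentions, etype)
            return []
        return []

    return scan(-1) or scan(+1)


def _member_collection(phrase: ParseNode, sentence: Sentence, mentions,
                       etype) -> list[EntityMention]:
    regions = [phrase] + ([phrase.parent] if phrase.parent is not None else [])
    toks = [t.surface.lower() for t in sentence.tokens]
    for region in regions:
        lo, hi = region.span
        for cue in _COLLECTION_CUES:
            n = len(cue)
            for i in range(lo, hi - n + 1):
                if toks[i:i + n] == cue:
                    cs = sentence.tokens[i + n - 1].end
                    ce = sentence.tokens[hi - 1].end
                    ants = [m for m in mentions
                            if m.sent_id == sentence.sent_id and m.specific
                            and m.etype is etype and cs <= m.start and m.end <= ce]
                    if ants:
                        return ants
    return []


def link_referential(match: ArgumentMatch, sentence: Sentence,
                     mentions: Iterable[EntityMention]) -> ResolutionResult:
    """Resolve an entity-noun referential phrase: is-a, then appositive,
    then member-collection."""
    mentions = list(mentions)
    etype = match.required_type
    phrase = match.arg_node
    ants = _is_a(phrase, sentence, mentions, etype)
    if ants:
        return ResolutionResult(ants, METHOD_IS_A)
    ants = _appositive(phrase, sentence, mentions, etype)
    if ants:
        return ResolutionResult(ants, METHOD_APPOSITIVE)
    ants = _member_collection(phrase, sentence, mentions, etype)
    if ants:
        return ResolutionResult(ants, METHOD_MEMBER_COLLECTION)
    return UNRESOLVED


# --- anaphora --------------------------------------------------------------

def _np_candidates(sentence: Sentence, mentions, etype, min_count: int,
                   exact: Optional[int] = None,
                   before_token: Optional[int] = None) -> list[tuple[ParseNode, list[EntityMention]]]:
    tree = sentence.parse
    out = []
    for node in tree.nodes():
        if not node.label.startswith("NP"):
            continue
        if before_token is not None and node.span[1] > before_token:
            continue
        ms = mentions_within(node, sentence, mentions, etype)
        if exact is not None:
            if len(ms) == exact:
                out.append((node, ms))
        elif len(ms) >= min_count:
            out.append((node, ms))
    return out


def resolve_anaphora(match: ArgumentMatch, sentence: Sentence,
                     mentions: Iterable[EntityMention],
                     context: Iterable[tuple[Sentence, list[EntityMention]]] = ()
                     ) -> ResolutionResult:
    """Scoped anaphora resolution with number and type agreement.

    it/its: a single type-compatible entity in the same sentence, preferring
    the subject when ambiguous.  their/they/them: the nearest preceding
    phrase mentioning more than one entity in the same sentence.
    these/those-NPs and numeric NPs ("two miRNAs") search backwards through
    the section for a phrase with the agreeing number of entities.
    """
    mentions = list(mentions)
    etype = match.required_type
    kind = match.referential_kind
    phrase_start = match.arg_node.span[0]

    if kind in {KIND_PRONOUN, KIND_POSSESSIVE} and match.required_count == 1:
        cs, ce = sentence.token_span_chars(*match.arg_node.span)
        cands = [m for m in mentions if m.sent_id == sentence.sent_id
                 and m.specific and m.etype is etype
                 and (m.end <= cs or m.start >= ce)]
        uniq = {m.norm: m for m in cands}
        if len(uniq) == 1:
            return ResolutionResult([next(iter(uniq.values()))], METHOD_ANAPHORA)
        if len(uniq) > 1 and sentence.parse is not None:
            root = sentence.parse.root
            subj = next((c for c in root.children
                         if c.label.startswith("NP") and not c.is_leaf), None)
            if subj is not None:
                inside = {m.norm: m for m in cands
                          if m.start >= sentence.token_span_chars(*subj.span)[0]
                          and m.end <= sentence.token_span_chars(*subj.span)[1]}
                if len(inside) == 1:
                    return ResolutionResult([next(iter(inside.values()))],
                                            METHOD_ANAPHORA)
        return UNRESOLVED

    if kind in {KIND_PRONOUN, KIND_POSSESSIVE}:  # plural
        cands = _np_candidates(sentence, mentions, etype, min_count=2,
                               before_token=phrase_start)
        if cands:
            node, ms = max(cands, key=lambda c: (c[0].span[1], -(c[0].span[1] - c[0].span[0])))
            return ResolutionResult(ms, METHOD_ANAPHORA)
        return UNRESOLVED

    if kind in {KIND_DEMONSTRATIVE, KIND_NUMERIC}:
        exact = match.required_count if kind == KIND_NUMERIC else None
        min_count = 2 if kind == KIND_DEMONSTRATIVE else 0
        cands = _np_candidates(sentence, mentions, etype, min_count=min_count,
                               exact=exact, before_token=phrase_start)
        if cands:
            node, ms = max(cands, key=lambda c: c[0].span[1])
            return ResolutionResult(ms, METHOD_ANAPHORA)
        for prev_sent, prev_mentions in reversed(list(context)):
            if prev_sent.parse is None:
                continue
            cands = _np_candidates(prev_sent, prev_mentions, etype,
                                   min_count=min_count, exact=exact)
            if cands:
                node, ms = max(cands, key=lambda c: c[0].span[1])
                return ResolutionResult(ms, METHOD_ANAPHORA)
        return UNRESOLVED

    return UNRESOLVED


def resolve_relative_pronoun(match: ArgumentMatch, sentence: Sentence,
                             mentions: Iterable[EntityMention]) -> ResolutionResult:
    """Link which/that to the nearest preceding type-compatible NP within
    the constituent containing the relative clause; appositive lists yield
    all their entities."""
    mentions = list(mentions)
    etype = match.required_type
    node = match.arg_node
    sbar = node
    while sbar is not None and sbar.label != "SBAR":
        sbar = sbar.parent
    container = sbar.parent if sbar is not None and sbar.parent is not None else (
        sentence.parse.root if sentence.parse else None)
    if container is None:
        return UNRESOLVED
    best: Optional[tuple[ParseNode, list[EntityMention]]] = None
    for cand in [container, *container.descendants()]:
        if not cand.label.startswith("NP") or cand.is_leaf:
            continue
        if cand.span[1] > node.span[0]:
            continue
        ms = mentions_within(cand, sentence, mentions, etype)
        if not ms:
            continue
        if best is None or cand.span[1] > best[0].span[1] or (
                cand.span[1] == best[0].span[1]
                and (cand.span[1] - cand.span[0]) > (best[0].span[1] - best[0].span[0])):
            best = (cand, ms)
    if best is None:
        return UNRESOLVED
    return ResolutionResult(best[1], METHOD_RELATIVE)


# --- driver ----------------------------------------------------------------

def resolve_matches(matches: list[ArgumentMatch], sentence: Sentence,
                    mentions: Iterable[EntityMention],
                    context: Iterable[tuple[Sentence, list[EntityMention]]] = (),
                    enable_linking: bool = True) -> list[ArgumentMatch]:
    """Fill in resolved_entities for referential matches.

    With linking disabled, referential matches are dropped.  Unresolvable
    matches are likewise dropped (they never pair).
    """
    mentions = list(mentions)
    out = []
    for m in matches:
        if not m.is_referential:
            out.append(m)
            continue
        if not enable_linking:
            continue
        if m.referential_kind == KIND_ENTITY_NOUN:
            res = link_referential(m, sentence, mentions)
        elif m.referential_kind == KIND_RELATIVE:
            res = resolve_relative_pronoun(m, sentence, mentions)
        else:
            res = resolve_anaphora(m, sentence, mentions, context)
        if res.resolved:
            m.resolved_entities = res.antecedents
            m.linking_method = res.method
            out.append(m)
    return out
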