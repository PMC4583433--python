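"""Rule engine: compile tree patterns, match one-argument rules, pair by trigger.

Every rule captures exactly one argument (``arg``) for one trigger token
(``trig``); a relation is only formed when an agent match and a theme match
share the same trigger occurrence (the same-trigger constraint).  Passive
voice is handled by separate rules gated on the voice of the trigger verb,
computed from its auxiliary chain.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

from .model import (
    Direction,
    EntityMention,
    EntityType,
    ParseNode,
    Sentence,
    Tier,
)
from .treequery import (
    PatternNode,
    PatternSyntaxError,
    compile_expr,
    head_preterminal,
    leaf_surface,
    match_expr,
)
from .triggers import ENTITY_NOUN, VERB, TriggerOccurrence

ROLES = {"agent", "theme", "self", "other"}
VOICES = {"active", "passive", "any"}
FORMS = {"verb", "process_noun", "entity_noun", "adjective"}

# referential phrase kinds
KIND_ENTITY_NOUN = "entity_noun"
KIND_PRONOUN = "pronoun"
KIND_POSSESSIVE = "possessive"
KIND_DEMONSTRATIVE = "demonstrative_np"
KIND_NUMERIC = "numeric_np"
KIND_RELATIVE = "relative_pronoun"

_NUMBER_WORDS = {"one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
                 "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10}

_BE_FORMS = {"be", "is", "are", "was", "were", "been", "being", "am",
             "'s", "'re", "get", "gets", "got", "getting"}
_HAVE_FORMS = {"have", "has", "had", "having"}


class RuleCompileError(ValueError):
    pass


@dataclass(frozen=True)
class TreePattern:
    pattern_id: str
    role: str
    trigger_form: str
    voice: str
    expr: PatternNode

    @classmethod
    def compile(cls, pattern_id: str, role: str, trigger_form: str, voice: str,
                spec: str) -> "TreePattern":
        if role not in ROLES:
            raise RuleCompileError(f"{pattern_id}: unknown role {role!r}")
        if trigger_form not in FORMS:
            raise RuleCompileError(f"{pattern_id}: unknown form {trigger_form!r}")
        if voice not in VOICES:
            raise RuleCompileError(f"{pattern_id}: unknown voice {voice!r}")
        try:
            expr = compile_expr(spec)
        except PatternSyntaxError as exc:
            raise RuleCompileError(f"{pattern_id}: {exc}") from exc
        caps = expr.captures()
        if caps != {"trig", "arg"}:
            raise RuleCompileError(
                f"{pattern_id}: pattern must capture exactly 'trig' and 'arg', "
                f"got {sorted(caps)}")
        return cls(pattern_id, role, trigger_form, voice, expr)


def compile_pattern(spec_line: str) -> TreePattern:
    """Compile one rule record ``pattern_id<TAB>role<TAB>form<TAB>voice<TAB>expr``."""
    parts = [p.strip() for p in spec_line.split("\t")]
    if len(parts) != 5:
        raise RuleCompileError("rule record needs 5 tab-separated fields")
    return TreePattern.compile(*parts)


def load_rules(stream: TextIO | str) -> list[TreePattern]:
    text = stream if isinstance(stream, str) else stream.read()
    rules = []
    seen = set()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        pat = compile_pattern(line)
        if pat.pattern_id in seen:
            raise RuleCompileError(f"duplicate pattern_id {pat.pattern_id!r}")
        seen.add(pat.pattern_id)
        rules.append(pat)
    return rules


def default_rules() -> list[TreePattern]:
    data = importlib.resources.files("mirrel.data").joinpath("rules.tsv")
    return load_rules(data.read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------


def verb_voice(preterminal: ParseNode) -> str:
    """active/passive for a verbal preterminal, from its auxiliary chain.

    VBN is passive under a be/get auxiliary or with no auxiliary at all
    (reduced relatives); under bare have-auxiliaries it is an active
    perfect.  All other verb tags are active.
    """
    if preterminal.label != "VBN":
        return "active"
    node = preterminal
    while node.parent is not None and node.parent.label.startswith("VP"):
        parent = node.parent
        for sib in parent.children:
            if sib is node:
                break
            if sib.is_preterminal and sib.label.startswith(("VB", "MD")):
                aux = leaf_surface(sib).lower()
                if aux in _BE_FORMS:
                    return "passive"
                if aux in _HAVE_FORMS:
                    return "active"
        node = parent
    return "passive"


@dataclass
class ArgumentMatch:
    sent_id: str
    trigger: TriggerOccurrence
    role: str  # concrete: agent | theme
    arg_node: ParseNode
    rule_id: str
    direction: Direction
    required_type: EntityType
    resolved_entities: list[EntityMention] = field(default_factory=list)
    is_referential: bool = False
    referential_kind: Optional[str] = None
    required_count: Optional[int] = None  # None = unconstrained, -1 = many
    linking_method: Optional[str] = None


def required_type_for(role: str, direction: Direction) -> EntityType:
    if direction is Direction.mirna_to_gene:
        return EntityType.miRNA if role == "agent" else EntityType.gene
    return EntityType.gene if role == "agent" else EntityType.miRNA


def mentions_within(node: ParseNode, sentence: Sentence,
                    mentions: Iterable[EntityMention],
                    etype: Optional[EntityType] = None) -> list[EntityMention]:
    """Specific mentions whose character span lies inside the node's tokens."""
    if not node.span or node.span[0] >= node.span[1]:
        return []
    cs, ce = sentence.token_span_chars(*node.span)
    out = []
    for m in mentions:
        if m.sent_id != sentence.sent_id or not m.specific:
            continue
        if etype is not None and m.etype is not etype:
            continue
        if cs <= m.start and m.end <= ce:
            out.append(m)
    return out


def _first_preterminal(node: ParseNode) -> Optional[ParseNode]:
    pres = node.preterminals() if not node.is_preterminal else [node]
    return pres[0] if pres else None


def classify_referential(arg: ParseNode, rule_role: str) -> tuple[Optional[str], Optional[int]]:
    """(kind, required_count) for an argument phrase without direct mentions."""
    if rule_role == "self":
        return KIND_ENTITY_NOUN, None
    node = arg
    # unwrap single-child NPs: (NP (PRP it))
    while (not node.is_preterminal and len([c for c in node.children if not c.is_leaf]) == 1
           and node.label.startswith(("NP", "WHNP"))):
        node = [c for c in node.children if not c.is_leaf][0]
    if node.label == "WHNP" or (node.is_preterminal and node.label in {"WDT", "WP"}):
        return KIND_RELATIVE, None
    if node.is_preterminal:
        w = leaf_surface(node).lower()
        if node.label == "PRP$" or w in {"its", "their"}:
            return KIND_POSSESSIVE, (1 if w == "its" else -1)
        if node.label == "PRP" and w in {"it", "they", "them"}:
            return KIND_PRONOUN, (1 if w == "it" else -1)
        return None, None
    first = _first_preterminal(arg)
    if first is not None:
        w = leaf_surface(first).lower()
        if w in {"these", "those"}:
            return KIND_DEMONSTRATIVE, -1
        if first.label == "CD" or w in _NUMBER_WORDS:
            n = _NUMBER_WORDS.get(w)
            if n is None:
                try:
                    n = int(w)
                except ValueError:
                    n = None
            if n is not None:
                return KIND_NUMERIC, n
    return None, None


def match_rules(sentence: Sentence, triggers: Iterable[TriggerOccurrence],
                mentions: Iterable[EntityMention], direction: Direction,
                rules: Optional[list[TreePattern]] = None) -> list[ArgumentMatch]:
    """All one-argument matches of the rule inventory against one sentence.

    An argument phrase is accepted if it contains a specific mention of the
    required type, or if it is referential (entity-noun phrase, pronoun,
    demonstrative/numeric NP, relative pronoun) — the latter are emitted
    unresolved for the linking stage.
    """
    if sentence.parse is None:
        raise ValueError(f"{sentence.sent_id}: sentence has no parse attached")
    if rules is None:
        rules = default_rules()
    tree = sentence.parse
    mentions = list(mentions)
    trig_by_tok = {t.token_index: t for t in triggers}
    out: list[ArgumentMatch] = []
    seen: set[tuple] = set()
    for rule in rules:
        for binding in match_expr(rule.expr, tree):
            tnode, arg = binding["trig"], binding["arg"]
            if not tnode.is_preterminal or arg is tnode:
                continue
            occ = trig_by_tok.get(tnode.children[0].token_index)
            if occ is None or occ.form != rule.trigger_form:
                continue
            if rule.trigger_form == VERB and rule.voice != "any":
                if verb_voice(tnode) != rule.voice:
                    continue
            role = rule.role
            if role in {"self", "other"}:
                if occ.form != ENTITY_NOUN:
                    continue
                denoted = ("agent" if occ.entry.entity_noun_denotes_agent(occ.surface)
                           else "theme")
                role = denoted if rule.role == "self" else (
                    "theme" if denoted == "agent" else "agent")
            req = required_type_for(role, direction)
            key = (rule.pattern_id, occ.token_index, arg.span, role, direction)
            if key in seen:
                continue
            seen.add(key)
            ents = mentions_within(arg, sentence, mentions, req)
            if rule.role != "self":
                # exclude mentions overlapping the trigger token itself
                ts, te = sentence.token_span_chars(*tnode.span)
                ents = [m for m in ents if m.end <= ts or m.start >= te]
            if ents:
                out.append(ArgumentMatch(
                    sent_id=sentence.sent_id, trigger=occ, role=role,
                    arg_node=arg, rule_id=rule.pattern_id, direction=direction,
                    required_type=req, resolved_entities=ents))
            else:
                kind, count = classify_referential(arg, rule.role)
                if kind is not None:
                    out.append(ArgumentMatch(
                        sent_id=sentence.sent_id, trigger=occ, role=role,
                        arg_node=arg, rule_id=rule.pattern_id,
                        direction=direction, required_type=req,
                        is_referential=True, referential_kind=kind,
                        required_count=count))
    return out


@dataclass
class CandidateRelation:
    sent_id: str
    sent_text: str
    direction: Direction
    agent: EntityMention
    theme: EntityMention
    triggers: list[TriggerOccurrence]
    tier: Tier
    rule_ids: list[str] = field(default_factory=list)
    linking_methods: list[str] = field(default_factory=list)
    directness: str = "unknown"

    @property
    def mirna_norm(self) -> str:
        return (self.agent if self.direction is Direction.mirna_to_gene
                else self.theme).norm

    @property
    def gene_norm(self) -> str:
        return (self.theme if self.direction is Direction.mirna_to_gene
                else self.agent).norm

    def pair_key(self) -> tuple:
        return (self.direction, self.mirna_norm, self.gene_norm)


def pair_same_trigger(matches: Iterable[ArgumentMatch],
                      sentence: Sentence) -> list[CandidateRelation]:
    """Cross-product pairing of resolved agent/theme matches per trigger.

    Referential matches must already be resolved (or they are ignored).
    """
    by_trigger: dict[tuple, dict[str, list[ArgumentMatch]]] = {}
    for m in matches:
        if not m.resolved_entities:
            continue
        slot = by_trigger.setdefault((m.trigger.token_index, m.direction), {})
        slot.setdefault(m.role, []).append(m)
    out: list[CandidateRelation] = []
    seen: set[tuple] = set()
    for (_, direction), slots in sorted(by_trigger.items(),
                                        key=lambda kv: kv[0][0]):
        agents = slots.get("agent", [])
        themes = slots.get("theme", [])
        for am in agents:
            for tm in themes:
                for a in am.resolved_entities:
                    for t in tm.resolved_entities:
                        rel = CandidateRelation(
                            sent_id=sentence.sent_id, sent_text=sentence.text,
                            direction=direction, agent=a, theme=t,
                            triggers=[am.trigger],
                            tier=Tier.same_trigger,
                            rule_ids=sorted({am.rule_id, tm.rule_id}),
                            linking_methods=sorted(
                                {x for x in (am.linking_method, tm.linking_method)
                                 if x}))
                        if rel.pair_key() in seen:
                            continue
                        seen.add(rel.pair_key())
                        out.append(rel)
    return out
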