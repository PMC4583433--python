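"""Trigger-word lexicon: regulation verbs with derived noun/adjective forms.

A trigger word signals a regulation relation and anchors rule matching.
Each entry is keyed by the verb lemma and carries:

* ``noun_forms`` — process nouns ("regulation", "targeting"): in "X of Y"
  the of-argument is the theme, as for the verb's object;
* ``entity_noun_forms`` — result/entity nouns ("target", "regulator"): the
  noun itself names one participant, so "target of X" makes X the agent
  while "regulator of X" makes X the theme.  Which participant the noun
  denotes is derived from its agentive suffix (-or/-er => agent);
* ``adjective_forms`` — adjectival derivations ("regulatory");
* ``polarity`` — up/down/neutral effect on the theme;
* ``directness_class`` — True exactly for the binding-class lemmas
  (target/bind/interact), whose use is itself evidence of a direct
  miRNA-target relation.

Inflected verb forms are generated with a small English inflector so that
"regulates", "regulated" and "regulating" all hit lemma "regulate".
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .model import EntityMention, Sentence

VERB = "verb"
PROCESS_NOUN = "process_noun"
ENTITY_NOUN = "entity_noun"
ADJECTIVE = "adjective"

POLARITIES = {"up", "down", "neutral"}

_IRREGULAR_VERBS = {
    "bind": {"bound"},
    "cleave": {"cleft", "cloven"},
}

_VOWELS = "aeiou"

_AGENTIVE_SUFFIXES = ("or", "er", "ant")


class TriggerConfigError(ValueError):
    """Malformed trigger lexicon input."""


def verb_inflections(lemma: str) -> set[str]:
    """All inflected surface forms of an English verb lemma (lowercase)."""
    forms = {lemma}
    if lemma.endswith("e"):
        forms.add(lemma + "d")
        forms.add(lemma[:-1] + "ing")
        forms.add(lemma + "s")
    elif lemma.endswith("y") and len(lemma) > 1 and lemma[-2] not in _VOWELS:
        forms.add(lemma[:-1] + "ied")
        forms.add(lemma[:-1] + "ies")
        forms.add(lemma + "ing")
    else:
        stem = lemma
        # consonant doubling for short final stressed CVC syllables
        if (len(lemma) >= 3 and lemma[-1] not in _VOWELS + "wxy"
                and lemma[-2] in _VOWELS and lemma[-3] not in _VOWELS
                and len(lemma) <= 4):
            stem = lemma + lemma[-1]
        forms.add(stem + "ed")
        forms.add(stem + "ing")
        if lemma.endswith(("s", "x", "z", "ch", "sh", "o")):
            forms.add(lemma + "es")
        else:
            forms.add(lemma + "s")
    forms |= _IRREGULAR_VERBS.get(lemma, set())
    return forms


def noun_plural(noun: str) -> str:
    if noun.endswith(("s", "x", "z", "ch", "sh")):
        return noun + "es"
    if noun.endswith("y") and len(noun) > 1 and noun[-2] not in _VOWELS:
        return noun[:-1] + "ies"
    return noun + "s"


@dataclass(frozen=True)
class TriggerEntry:
    lemma: str
    noun_forms: tuple[str, ...] = ()
    entity_noun_forms: tuple[str, ...] = ()
    adjective_forms: tuple[str, ...] = ()
    polarity: str = "neutral"
    directness_class: bool = False

    def __post_init__(self) -> None:
        if self.lemma != self.lemma.lower():
            raise TriggerConfigError(f"lemma must be lowercase: {self.lemma!r}")
        if self.polarity not in POLARITIES:
            raise TriggerConfigError(
                f"unknown polarity {self.polarity!r} for {self.lemma!r}")

    def entity_noun_denotes_agent(self, form_surface: str) -> bool:
        """True if this entity noun names the agent ("regulator") rather
        than the theme ("target")."""
        base = form_surface.rstrip("s")
        return base.endswith(_AGENTIVE_SUFFIXES)


@dataclass
class TriggerOccurrence:
    token_index: int
    lemma: str
    form: str  # verb | process_noun | entity_noun | adjective
    entry: TriggerEntry
    surface: str = ""


@dataclass
class TriggerLexicon:
    entries: dict[str, TriggerEntry] = field(default_factory=dict)
    _surface_map: dict[str, list[tuple[TriggerEntry, str]]] = field(
        default_factory=dict, repr=False)

    def add(self, entry: TriggerEntry) -> None:
        if entry.lemma in self.entries:
            raise TriggerConfigError(f"duplicate trigger lemma {entry.lemma!r}")
        self.entries[entry.lemma] = entry
        for f in verb_inflections(entry.lemma):
            self._surface_map.setdefault(f, []).append((entry, VERB))
        for n in entry.noun_forms:
            for f in (n, noun_plural(n)):
                self._surface_map.setdefault(f.lower(), []).append((entry, PROCESS_NOUN))
        for n in entry.entity_noun_forms:
            for f in (n, noun_plural(n)):
                self._surface_map.setdefault(f.lower(), []).append((entry, ENTITY_NOUN))
        for a in entry.adjective_forms:
            self._surface_map.setdefault(a.lower(), []).append((entry, ADJECTIVE))

    def candidates(self, surface: str) -> list[tuple[TriggerEntry, str]]:
        return self._surface_map.get(surface.lower(), [])

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _split_list(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell or cell in {"-", "—"}:
        return ()
    return tuple(x.strip().lower() for x in cell.split("|") if x.strip())


def load_triggers(stream: TextIO | str) -> TriggerLexicon:
    """Load a trigger lexicon from TSV.

    Columns: lemma, noun_forms, entity_noun_forms, adjective_forms,
    polarity, directness_class.  List cells are "|"-separated; "-" means
    empty.  Duplicate lemmas and unknown polarity values are rejected.
    """
    text = stream if isinstance(stream, str) else stream.read()
    lex = TriggerLexicon()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 6:
            raise TriggerConfigError(
                f"line {lineno}: expected 6 tab-separated columns, got {len(parts)}")
        lemma, nouns, entnouns, adjs, polarity, direct = parts
        entry = TriggerEntry(
            lemma=lemma.lower(),
            noun_forms=_split_list(nouns),
            entity_noun_forms=_split_list(entnouns),
            adjective_forms=_split_list(adjs),
            polarity=polarity.lower(),
            directness_class=direct.lower() in {"true", "1", "yes"},
        )
        lex.add(entry)
    return lex


def default_lexicon() -> TriggerLexicon:
    """The bundled seed lexicon (user-extensible via a custom TSV)."""
    data = importlib.resources.files("mirrel.data").joinpath("triggers.tsv")
    return load_triggers(data.read_text(encoding="utf-8"))


_POS_COMPAT = {
    VERB: ("VB",),
    PROCESS_NOUN: ("NN",),
    ENTITY_NOUN: ("NN",),
    ADJECTIVE: ("JJ",),
}


def find_triggers(sentence: Sentence, lexicon: TriggerLexicon,
                  mentions: Iterable[EntityMention] = ()) -> list[TriggerOccurrence]:
    """Locate trigger occurrences in a sentence.

    Matching is by inflected surface form; POS tags (when present) select
    the syntactic form of ambiguous surfaces ("targets" as VBZ vs NNS).
    Tokens inside an entity mention span are never triggers (entity wins).
    Each token yields at most one occurrence.
    """
    spans = [(m.start, m.end) for m in mentions]
    out: list[TriggerOccurrence] = []
    for tok in sentence.tokens:
        if any(s < tok.end and tok.start < e for s, e in spans):
            continue
        cands = lexicon.candidates(tok.surface)
        if not cands:
            continue
        chosen = None
        if tok.pos:
            for entry, form in cands:
                if any(tok.pos.startswith(p) for p in _POS_COMPAT[form]):
                    chosen = (entry, form)
                    break
            if chosen is None:
                continue  # POS incompatible with every reading
        else:
            chosen = cands[0]
        out.append(TriggerOccurrence(token_index=tok.index, lemma=chosen[0].lemma,
                                     form=chosen[1], entry=chosen[0],
                                     surface=tok.surface))
    return out
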