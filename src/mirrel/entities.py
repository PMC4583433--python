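"""miRNA and gene mention recognition and name normalization.

miRNA nomenclature is regular enough that a grammar-based recognizer covers
nearly all mentions: an optional species prefix ("hsa-"), a core prefix
(miR/miRNA/microRNA or the historical let/lin families), a unique
identifying number, optional letter suffix, optional arm (-3p/-5p) and an
optional extra numeric suffix ("miR-16-1").  Slash conjunctions
("miR-15a/-16-1") are expanded into one mention per conjunct, the later
conjuncts inheriting the prefix of the first.

Gene recognition is lexicon-based (longest match wins); evaluation corpora
normally supply gold gene mentions as standoff annotations instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .model import Document, EntityMention, EntityType, Sentence
from .textprep import tokenize


class AnnotationError(ValueError):
    """Standoff record inconsistent with the document text."""


# --- miRNA grammar ---------------------------------------------------------

_CORE = r"(?:miRNA|microRNA|MicroRNA|Microrna|miR|MiR|mir|let|lin)"
_NUMPART = r"(?P<num>\d+)(?P<let>[a-z]?)(?P<tail>(?:-(?:[35]p|\d+[a-z]?))*)"

_MIRNA_RE = re.compile(
    rf"(?P<species>\b[a-z]{{3,4}}-)?"
    rf"(?P<bracket>\(\s*(?:miR|mir|miRNA|microRNA)\s*\)\s*-?|"
    rf"(?P<prefix>{_CORE})[-\s]?)"
    rf"{_NUMPART}"
    rf"(?P<conj>(?:/\s?-?\d+[a-z]?(?:-(?:[35]p|\d+[a-z]?))*)*)"
)

_FAMILY_RE = re.compile(r"\b(?:miRNAs?|microRNAs?|MicroRNAs?|Micrornas?|miRs?)\b")

_CONJ_RE = re.compile(r"/\s?(?P<dash>-?)(?P<num>\d+)(?P<let>[a-z]?)"
                      r"(?P<tail>(?:-(?:[35]p|\d+[a-z]?))*)")


def _canonical_core(prefix: str) -> str:
    p = prefix.lower()
    if p in {"let", "lin"}:
        return p
    return "miR"


def _mirna_norm(species: str, prefix: str, num: str, let: str, tail: str) -> str:
    return f"{species}{_canonical_core(prefix)}-{num}{let}{tail}"


def normalize_mirna_name(name: str) -> str:
    """Canonical hyphenation for a miRNA name ("MicroRNA-223" -> "miR-223")."""
    name = re.sub(r"^(?:the|a|an)\s+", "", name.strip(), flags=re.IGNORECASE)
    m = _MIRNA_RE.search(name)
    if not m:
        return name
    species = m.group("species") or ""
    prefix = m.group("prefix") or "miR"
    return _mirna_norm(species, prefix, m.group("num"), m.group("let"),
                       m.group("tail") or "")


_GENE_HEAD_NOUNS = {"expression", "mrna", "gene", "genes", "levels", "level",
                    "protein", "proteins"}
_DETERMINERS = {"the", "a", "an"}


def normalize_gene_name(name: str) -> str:
    """Trim determiners and trailing head nouns; preserve gene-symbol case."""
    words = name.strip().split()
    while words and words[0].lower() in _DETERMINERS:
        words = words[1:]
    while words and words[-1].lower() in _GENE_HEAD_NOUNS:
        words = words[:-1]
    return " ".join(words)


def normalize_name(mention: EntityMention) -> str:
    if mention.etype is EntityType.miRNA:
        return normalize_mirna_name(mention.norm or mention.surface)
    return normalize_gene_name(mention.norm or mention.surface)


def recognize_mirna(sentence: Sentence) -> list[EntityMention]:
    """Find miRNA mentions by nomenclature grammar, expanding conjunctions.

    Family-only mentions ("miRNAs") are returned with ``specific=False`` and
    are never used as relation arguments downstream.
    """
    out: list[EntityMention] = []
    text = sentence.text
    taken: list[tuple[int, int]] = []

    def emit(start: int, end: int, norm: str, specific: bool) -> None:
        out.append(EntityMention(
            mention_id=f"{sentence.sent_id}:m{len(out)}",
            sent_id=sentence.sent_id, start=start, end=end,
            surface=text[start:end], etype=EntityType.miRNA, norm=norm,
            specific=specific))

    for m in _MIRNA_RE.finditer(text):
        if m.start() > 0 and (text[m.start() - 1].isalnum() or text[m.start() - 1] == "-"):
            continue
        species = m.group("species") or ""
        prefix = m.group("prefix") or "miR"
        base_norm = _mirna_norm(species, prefix, m.group("num"), m.group("let"),
                                m.group("tail") or "")
        taken.append((m.start(), m.end()))
        emit(m.start(), m.end(), base_norm, True)
        for c in _CONJ_RE.finditer(m.group("conj") or ""):
            emit(m.start(), m.end(),
                 _mirna_norm(species, prefix, c.group("num"), c.group("let"),
                             c.group("tail") or ""), True)
    for m in _FAMILY_RE.finditer(text):
        if any(s <= m.start() < e for s, e in taken):
            continue
        if m.end() < len(text) and text[m.end():m.end() + 1] in "-0123456789":
            continue
        emit(m.start(), m.end(), "miRNA", False)
    out.sort(key=lambda e: (e.start, e.norm))
    return out


# --- gene lexicon ----------------------------------------------------------

@dataclass
class GeneLexicon:
    """Alias -> canonical symbol table with deterministic longest-match lookup."""

    entries: dict[str, str] = field(default_factory=dict)
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        for alias, canon in self.entries.items():
            if not alias or not canon:
                raise ValueError("gene lexicon entries must be non-empty")

    def add(self, alias: str, canonical: str) -> None:
        if not alias or not canonical:
            raise ValueError("gene lexicon entries must be non-empty")
        self.entries[alias] = canonical

    def _key(self, s: str) -> str:
        return s.lower() if self.case_insensitive else s

    def lookup_table(self) -> dict[tuple[str, ...], str]:
        table = {}
        for alias, canon in sorted(self.entries.items()):
            toks = tuple(t.surface for t in tokenize(alias))
            table[tuple(self._key(t) for t in toks)] = canon
        return table

    @classmethod
    def from_tsv(cls, stream: TextIO | str, case_insensitive: bool = False) -> "GeneLexicon":
        text = stream if isinstance(stream, str) else stream.read()
        lex = cls(case_insensitive=case_insensitive)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            alias = parts[0].strip()
            canon = parts[1].strip() if len(parts) > 1 else alias
            lex.add(alias, canon)
        return lex

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "GeneLexicon":
        lex = cls()
        for n in names:
            lex.add(n, n)
        return lex


def match_genes(sentence: Sentence, lexicon: GeneLexicon,
                mirna_mentions: Iterable[EntityMention] = ()) -> list[EntityMention]:
    """Token-boundary, longest-match gene lookup.

    Matches inside a miRNA mention span are discarded; overlapping shorter
    matches are suppressed.
    """
    table = lexicon.lookup_table()
    if not table:
        return []
    max_len = max(len(k) for k in table)
    toks = sentence.tokens
    keys = [lexicon._key(t.surface) for t in toks]
    blocked = [(m.start, m.end) for m in mirna_mentions]
    out: list[EntityMention] = []
    i = 0
    while i < len(toks):
        found = None
        for L in range(min(max_len, len(toks) - i), 0, -1):
            canon = table.get(tuple(keys[i:i + L]))
            if canon is not None:
                found = (L, canon)
                break
        if found:
            L, canon = found
            start, end = toks[i].start, toks[i + L - 1].end
            if not any(bs < end and start < be for bs, be in blocked):
                out.append(EntityMention(
                    mention_id=f"{sentence.sent_id}:g{len(out)}",
                    sent_id=sentence.sent_id, start=start, end=end,
                    surface=sentence.text[start:end], etype=EntityType.gene,
                    norm=canon))
            i += L
        else:
            i += 1
    return out


# --- standoff annotations --------------------------------------------------

_TYPE_MAP = {
    "mirna": EntityType.miRNA, "microrna": EntityType.miRNA,
    "gene": EntityType.gene, "protein": EntityType.gene,
    "gene_protein": EntityType.gene,
}


def load_standoff(stream: TextIO | str, doc: Document) -> list[EntityMention]:
    """Read BRAT-like records ``ID<TAB>TYPE START END<TAB>SURFACE[<TAB>NORM]``.

    Offsets are document-level and validated against the document text, then
    mapped to sentence-local offsets.  The optional fourth column overrides
    the normalized name; two records may share a span with different norms
    (expanded slash conjunctions such as "miR-15a/-16-1").
    """
    text = stream if isinstance(stream, str) else stream.read()
    sentences = list(doc.sentences())
    out: list[EntityMention] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise AnnotationError(f"line {lineno}: expected 3 tab-separated fields")
        mid, spec, surface = parts[0], parts[1], parts[2]
        try:
            tname, s_str, e_str = spec.split()
            start, end = int(s_str), int(e_str)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: bad span spec {spec!r}") from exc
        etype = _TYPE_MAP.get(tname.lower())
        if etype is None:
            raise AnnotationError(f"line {lineno}: unknown entity type {tname!r}")
        if doc.text and doc.text[start:end] != surface:
            raise AnnotationError(
                f"line {lineno}: surface {surface!r} != text slice "
                f"{doc.text[start:end]!r}")
        sent = next((s for s in sentences
                     if s.doc_offset <= start and end <= s.doc_offset + len(s.text)),
                    None)
        if sent is None:
            raise AnnotationError(f"line {lineno}: span outside any sentence")
        ls, le = start - sent.doc_offset, end - sent.doc_offset
        override = parts[3].strip() if len(parts) > 3 and parts[3].strip() else None
        if etype is EntityType.miRNA:
            norm = override or normalize_mirna_name(surface)
            specific = bool(re.search(r"\d", norm))
        else:
            norm = override or normalize_gene_name(surface)
            specific = True
        out.append(EntityMention(mention_id=mid, sent_id=sent.sent_id,
                                 start=ls, end=le, surface=surface, etype=etype,
                                 norm=norm, specific=specific))
    return out


def write_standoff(mentions: Iterable[EntityMention], doc: Document) -> str:
    """Serialize mentions back to the standoff dialect (round-trip safe)."""
    sent_off = {s.sent_id: s.doc_offset for s in doc.sentences()}
    lines = []
    for m in mentions:
        off = sent_off.get(m.sent_id, 0)
        lines.append(f"{m.mention_id}\t{m.etype.value} {m.start + off} "
                     f"{m.end + off}\t{m.surface}\t{m.norm}")
    return "\n".join(lines) + ("\n" if lines else "")
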