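"""Core document model: documents, sections, sentences, tokens and parse trees.

The pipeline works on sentences that carry a constituency parse in Penn
Treebank style.  Parses come from a pluggable adapter or, in the test and
fixture paths, from gold bracketed trees shipped with the corpus; nothing in
the package depends on a statistical parser being present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional


class SourceKind(str, Enum):
    abstract = "abstract"
    fulltext = "fulltext"


class SectionType(str, Enum):
    Abstract = "Abstract"
    Results = "Results"
    Discussion = "Discussion"
    FigureCaptions = "FigureCaptions"
    Introduction = "Introduction"
    Methods = "Methods"
    Conclusion = "Conclusion"
    Unknown = "Unknown"


@dataclass
class Token:
    """A sentence token with 0-based half-open character offsets."""

    index: int
    start: int
    end: int
    surface: str
    lemma: str = ""
    pos: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"token {self.index}: start must be < end")
        if not self.lemma:
            self.lemma = self.surface.lower()


# Bracket escapes used by Penn Treebank tokenization.
PTB_UNESCAPE = {
    "-LRB-": "(",
    "-RRB-": ")",
    "-LSB-": "[",
    "-RSB-": "]",
    "-LCB-": "{",
    "-RCB-": "}",
}
PTB_ESCAPE = {v: k for k, v in PTB_UNESCAPE.items()}


class ParseNode:
    """A node of a constituency tree.

    Leaves hold a surface string and (after attachment) a token index.
    Internal nodes hold ordered children.  ``span`` is the half-open leaf
    index range covered by the node.
    """

    __slots__ = ("label", "children", "surface", "token_index", "parent", "span")

    def __init__(self, label: str, children: Optional[list["ParseNode"]] = None,
                 surface: Optional[str] = None):
        self.label = label
        self.children: list[ParseNode] = children or []
        self.surface = surface
        self.token_index: Optional[int] = None
        self.parent: Optional[ParseNode] = None
        self.span: tuple[int, int] = (0, 0)

    @property
    def is_leaf(self) -> bool:
        return self.surface is not None

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and self.children[0].is_leaf

    def leaves(self) -> list["ParseNode"]:
        if self.is_leaf:
            return [self]
        out: list[ParseNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def preterminals(self) -> list["ParseNode"]:
        if self.is_preterminal:
            return [self]
        out: list[ParseNode] = []
        for c in self.children:
            if not c.is_leaf:
                out.extend(c.preterminals())
        return out

    def descendants(self) -> Iterator["ParseNode"]:
        for c in self.children:
            if not c.is_leaf:
                yield c
                yield from c.descendants()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.surface!r})"
        return f"ParseNode({self.label}, span={self.span})"


class ParseTree:
    """A constituency tree bound (after :func:`attach_parse`) to a sentence."""

    def __init__(self, root: ParseNode):
        self.root = root
        self._index()

    def _index(self) -> None:
        idx = 0
        for leaf in self.root.leaves():
            leaf.token_index = idx
            leaf.span = (idx, idx + 1)
            idx += 1
        self._set_spans(self.root)
        self._set_parents(self.root)

    def _set_spans(self, node: ParseNode) -> tuple[int, int]:
        if node.is_leaf:
            return node.span
        spans = [self._set_spans(c) for c in node.children]
        node.span = (spans[0][0], spans[-1][1])
        # internal spans must be contiguous unions of the children
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if b != c:
                raise ValueError("non-contiguous child spans in parse tree")
        return node.span

    def _set_parents(self, node: ParseNode) -> None:
        for c in node.children:
            c.parent = node
            self._set_parents(c)

    def leaves(self) -> list[ParseNode]:
        return self.root.leaves()

    def preterminals(self) -> list[ParseNode]:
        return self.root.preterminals()

    def nodes(self) -> list[ParseNode]:
        """All non-leaf nodes, preorder."""
        return [self.root, *self.root.descendants()]

    def preterminal_at(self, token_index: int) -> ParseNode:
        for p in self.preterminals():
            if p.children[0].token_index == token_index:
                return p
        raise IndexError(token_index)

    def leaf_surfaces(self) -> list[str]:
        return [PTB_UNESCAPE.get(l.surface, l.surface) for l in self.leaves()]

    def serialize(self) -> str:
        def rec(n: ParseNode) -> str:
            if n.is_leaf:
                return PTB_ESCAPE.get(n.surface, n.surface)
            inner = " ".join(rec(c) for c in n.children)
            return f"({n.label} {inner})"

        return rec(self.root)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParseTree):
            return NotImplemented
        return self.serialize() == other.serialize()

    def __hash__(self) -> int:
        return hash(self.serialize())


@dataclass
class Sentence:
    sent_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    parse: Optional[ParseTree] = None
    doc_offset: int = 0  # character offset of this sentence in the document text

    def token_span_chars(self, start_tok: int, end_tok: int) -> tuple[int, int]:
        """Character span covered by the half-open token range."""
        return self.tokens[start_tok].start, self.tokens[end_tok - 1].end

    def reconstruct(self) -> str:
        """Rebuild the sentence text from token offsets (identity check)."""
        out = []
        pos = 0
        for t in self.tokens:
            out.append(self.text[pos:t.start])
            out.append(self.text[t.start:t.end])
            pos = t.end
        out.append(self.text[pos:])
        return "".join(out)


@dataclass
class Section:
    section_id: str
    section_type: SectionType
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Document:
    doc_id: str
    sections: list[Section] = field(default_factory=list)
    source_kind: SourceKind = SourceKind.abstract
    text: str = ""  # raw document text, for standoff offset validation

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def sentences(self) -> Iterator[Sentence]:
        for sec in self.sections:
            yield from sec.sentences


class EntityType(str, Enum):
    miRNA = "miRNA"
    gene = "gene"


@dataclass
class EntityMention:
    """A typed entity span within one sentence.

    ``specific`` is True when a miRNA mention carries a unique identifying
    number ("miR-21"); bare family mentions ("miRNAs", "microRNA") are kept
    for bookkeeping but never used as relation arguments.  Gene mentions are
    always specific.
    """

    mention_id: str
    sent_id: str
    start: int
    end: int
    surface: str
    etype: EntityType
    norm: str
    specific: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("mention start must be < end")
        if not self.norm:
            raise ValueError("mention norm must be non-empty")
        if self.etype is EntityType.gene:
            self.specific = True


class Direction(str, Enum):
    mirna_to_gene = "mirna_to_gene"
    gene_to_mirna = "gene_to_mirna"


class Directness(str, Enum):
    direct = "direct"
    unknown = "unknown"


class Tier(str, Enum):
    same_trigger = "same_trigger"
    relaxed = "relaxed"
    cooccurrence = "cooccurrence"
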