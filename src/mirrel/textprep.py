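"""Text pre-processing: sentence splitting, tokenization, parse ingestion.

Sentence splitting is abbreviation-aware and never breaks inside a
parenthesized span or inside digit-hyphen names such as "miR-15a/-16-1".
Parses are read from Penn Treebank bracketed notation and attached to
sentences by aligning leaves to tokens.
"""

from __future__ import annotations

import re
from typing import Iterable, TextIO

from .model import (
    Document,
    ParseNode,
    ParseTree,
    PTB_UNESCAPE,
    Section,
    SectionType,
    Sentence,
    SourceKind,
    Token,
)


class ParseFormatError(ValueError):
    """Malformed bracketed parse input."""


class AlignmentError(ValueError):
    """Parse leaves do not line up with sentence tokens."""


# Abbreviations after which a period never ends a sentence.
_ABBREVIATIONS = {
    "al", "e.g", "i.e", "fig", "figs", "vs", "etc", "ca", "cf", "no",
    "dr", "st", "approx", "resp",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s+\S|\s*$)")


def _protected(text: str, idx: int) -> bool:
    """True when the boundary candidate at ``idx`` must not split."""
    # inside parentheses / brackets
    depth = 0
    for ch in text[:idx]:
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
    if depth > 0:
        return True
    prefix = text[:idx]
    m = re.search(r"(\S+)$", prefix)
    last = m.group(1) if m else ""
    low = last.lower().rstrip(".")
    if low in _ABBREVIATIONS or low.endswith((".e", ".g")):
        return True
    # digit-period-digit ("0.5 Gy", "NKx2.5") and digit-hyphen names
    after = text[idx + 1: idx + 2]
    if last and last[-1].isdigit() and after.isdigit():
        return True
    if re.fullmatch(r"\d+", low):
        # "NKx2.5" style: token before the period ends in a digit and the
        # next char is a digit -- handled above; bare numbers ("Fig. 2.")
        # still split when followed by a capital.
        pass
    return False


def split_sentences(text: str, sent_prefix: str = "s") -> list[Sentence]:
    """Split ``text`` into sentences with exact character offsets.

    Empty input yields an empty list.  Each returned sentence is tokenized;
    parses are attached separately.
    """
    if not text or not text.strip():
        return []
    boundaries: list[int] = []
    for m in _BOUNDARY.finditer(text):
        idx = m.start()
        end = m.end()
        if end >= len(text.rstrip()) and not text[end:].strip():
            boundaries.append(end)
            continue
        nxt = text[end:].lstrip()
        if not nxt:
            boundaries.append(end)
            continue
        if _protected(text, idx):
            continue
        boundaries.append(end)
    if not boundaries or boundaries[-1] < len(text.rstrip()):
        boundaries.append(len(text))
    sentences: list[Sentence] = []
    prev = 0
    for n, b in enumerate(boundaries):
        chunk = text[prev:b]
        stripped = chunk.strip()
        if stripped:
            offset = prev + chunk.index(stripped[0])
            sent = Sentence(sent_id=f"{sent_prefix}{len(sentences)}", text=stripped,
                            doc_offset=offset)
            sent.tokens = tokenize(stripped)
            sentences.append(sent)
        prev = b
    return sentences


_TOKEN_RE = re.compile(
    r"""
    [A-Za-z0-9]\S*?[A-Za-z0-9%'′’]   # word-ish run, may contain - / . '
    | [A-Za-z0-9]                    # single alphanumeric
    | \S                             # any lone symbol
    """,
    re.VERBOSE,
)

_TRAILING_PUNCT = re.compile(r"^(?P<core>.*?[A-Za-z0-9%'′’])(?P<tail>[.,;:!?]+)$")


def tokenize(text: str) -> list[Token]:
    """Whitespace/punctuation tokenizer compatible with the fixture parses.

    Hyphens, slashes and primes stay inside tokens ("miR-15a/-16-1",
    "3'UTR"); sentence-final punctuation and commas are split off;
    parentheses are always their own tokens.
    """
    tokens: list[Token] = []

    def push(surface: str, start: int) -> None:
        tokens.append(Token(index=len(tokens), start=start,
                            end=start + len(surface), surface=surface))

    pos = 0
    for raw in re.finditer(r"\S+", text):
        chunk, cstart = raw.group(0), raw.start()
        # peel off parentheses and quotes
        i = 0
        while i < len(chunk):
            ch = chunk[i]
            if ch in "()[]{}\"“”":
                push(ch, cstart + i)
                i += 1
                continue
            # consume up to next bracket
            j = i
            while j < len(chunk) and chunk[j] not in "()[]{}\"“”":
                j += 1
            piece = chunk[i:j]
            m = _TRAILING_PUNCT.match(piece)
            if m and not re.search(r"\d[.,]\d$", piece):
                push(m.group("core"), cstart + i)
                for k, p in enumerate(m.group("tail")):
                    push(p, cstart + i + len(m.group("core")) + k)
            elif piece in {",", ";", ":", ".", "!", "?"} or piece:
                if len(piece) > 1 and piece[0] in ",;:":
                    push(piece[0], cstart + i)
                    push(piece[1:], cstart + i + 1)
                else:
                    push(piece, cstart + i)
            i = j
    _ = pos
    return tokens


# ---------------------------------------------------------------------------
# Penn Treebank bracketed trees


def _parse_sexpr(s: str, record: int) -> ParseNode:
    toks = re.findall(r"\(|\)|[^\s()]+", s)
    pos = 0

    def rec() -> ParseNode:
        nonlocal pos
        if pos >= len(toks) or toks[pos] != "(":
            raise ParseFormatError(f"record {record}: expected '('")
        pos += 1
        if pos >= len(toks):
            raise ParseFormatError(f"record {record}: truncated tree")
        label = toks[pos] if toks[pos] not in "()" else ""
        if label:
            pos += 1
        children: list[ParseNode] = []
        leaf_surface = None
        while pos < len(toks) and toks[pos] != ")":
            if toks[pos] == "(":
                children.append(rec())
            else:
                leaf_surface = toks[pos]
                children.append(ParseNode(label="", surface=leaf_surface))
                pos += 1
        if pos >= len(toks):
            raise ParseFormatError(f"record {record}: unbalanced '('")
        pos += 1  # consume ')'
        node = ParseNode(label=label, children=children)
        return node

    root = rec()
    if pos != len(toks):
        raise ParseFormatError(f"record {record}: unbalanced ')'")
    # unwrap "( (S ...) )" style roots
    while root.label == "" and len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
    return root


def read_ptb_trees(stream: TextIO | Iterable[str] | str) -> list[ParseTree]:
    """Read bracketed trees: one per line, or s-expression blocks.

    Raises :class:`ParseFormatError` (with the 1-based record number) on
    unbalanced brackets.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = "".join(stream) if not hasattr(stream, "read") else stream.read()
    # split into balanced top-level records
    records: list[str] = []
    depth = 0
    start = None
    for i, ch in enumerate(text):
        if ch == "(":
            if depth == 0:
                start = i
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseFormatError(f"record {len(records) + 1}: unbalanced ')'")
            if depth == 0 and start is not None:
                records.append(text[start:i + 1])
                start = None
    if depth != 0:
        raise ParseFormatError(f"record {len(records) + 1}: unbalanced '('")
    trees = []
    for n, rec in enumerate(records, start=1):
        trees.append(ParseTree(_parse_sexpr(rec, n)))
    return trees


def attach_parse(sentence: Sentence, tree: ParseTree) -> Sentence:
    """Attach ``tree`` to ``sentence``, aligning leaves 1:1 onto tokens.

    Leaf surfaces are compared after bracket unescaping.  On mismatch an
    :class:`AlignmentError` reports the first divergent index.  Leaf POS
    labels are copied onto the tokens.
    """
    leaves = tree.leaf_surfaces()
    surfaces = [t.surface for t in sentence.tokens]
    for i, (a, b) in enumerate(zip(leaves, surfaces)):
        if a != b:
            raise AlignmentError(
                f"{sentence.sent_id}: leaf/token mismatch at index {i}: "
                f"{a!r} != {b!r}")
    if len(leaves) != len(surfaces):
        raise AlignmentError(
            f"{sentence.sent_id}: leaf count {len(leaves)} != token count "
            f"{len(surfaces)} (first divergence at {min(len(leaves), len(surfaces))})")
    for pre in tree.preterminals():
        tok = sentence.tokens[pre.children[0].token_index]
        tok.pos = pre.label
    sentence.parse = tree
    return sentence


def sentence_from_tree(sent_id: str, text: str, tree: ParseTree) -> Sentence:
    """Build a sentence whose tokens are the tree's leaves located in ``text``.

    Used by fixture corpora, where the gold parse defines the tokenization.
    """
    tokens: list[Token] = []
    pos = 0
    for i, surface in enumerate(tree.leaf_surfaces()):
        found = text.find(surface, pos)
        # prefer a word-boundary occurrence for alphanumeric leaves so that
        # e.g. a leaf "in" never lands inside "binding"
        if surface and surface[0].isalnum():
            probe = found
            while probe >= 0:
                left_ok = probe == 0 or not text[probe - 1].isalnum()
                right = probe + len(surface)
                right_ok = (right >= len(text)
                            or not (surface[-1].isalnum() and text[right].isalnum()))
                if left_ok and right_ok:
                    found = probe
                    break
                probe = text.find(surface, probe + 1)
            else:
                found = -1
        if found < 0:
            raise AlignmentError(f"{sent_id}: leaf {surface!r} not found in text")
        tokens.append(Token(index=i, start=found, end=found + len(surface),
                            surface=surface))
        pos = found + len(surface)
    sent = Sentence(sent_id=sent_id, text=text, tokens=tokens)
    return attach_parse(sent, tree)


# ---------------------------------------------------------------------------
# Document construction


def document_from_abstract(doc_id: str, title: str, body: str) -> Document:
    """Abstract document: title concatenated before the abstract body."""
    text = (title.strip() + " " + body.strip()).strip() if title else body.strip()
    sec = Section(section_id=f"{doc_id}:Abstract", section_type=SectionType.Abstract,
                  sentences=split_sentences(text, sent_prefix=f"{doc_id}:s"))
    return Document(doc_id=doc_id, sections=[sec], source_kind=SourceKind.abstract,
                    text=text)


def read_medline(stream: TextIO | str) -> list[Document]:
    """Read Medline-style records with PMID, TI and AB fields."""
    text = stream if isinstance(stream, str) else stream.read()
    docs = []
    pmid, ti, ab, last = None, [], [], None
    def flush():
        if pmid is not None:
            docs.append(document_from_abstract(pmid, " ".join(ti), " ".join(ab)))
    for line in text.splitlines():
        if not line.strip():
            continue
        m = re.match(r"^(PMID|TI|AB)\s*-\s*(.*)$", line)
        if m:
            tag, val = m.group(1), m.group(2)
            if tag == "PMID":
                flush()
                pmid, ti, ab = val.strip(), [], []
            elif tag == "TI":
                ti.append(val.strip())
            else:
                ab.append(val.strip())
            last = tag
        elif line.startswith(" ") and last in {"TI", "AB"}:
            (ti if last == "TI" else ab).append(line.strip())
    flush()
    return docs
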