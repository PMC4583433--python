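"""A small tree-query language for matching patterns against parse trees.

Rules over constituency trees are written as s-expressions::

    (S < NP=arg < (VP <h VB*=trig))

Semantics:

* a node test is a label alternation ("NP|WHNP"), where a trailing "*" is a
  prefix glob ("VB*" matches VBZ, VBD, ...); an optional "=name" captures
  the matched node;
* ``<`` requires a matching child, ``<<`` a matching proper descendant,
  ``<h`` requires the node's lexical head preterminal to match (the head of
  a VP chain is its main verb, so auxiliaries are skipped);
* a quoted string inside a node test ("(IN \"of|for\")") constrains the
  leaf surface of a preterminal (case-insensitive alternation);
* consecutive items of one node must match nodes in left-to-right order
  and must not overlap, which encodes linear precedence.

Matching is exhaustive: every tree node is tried as an anchor and every
consistent assignment of captures is returned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .model import ParseNode, ParseTree, PTB_UNESCAPE


class PatternSyntaxError(ValueError):
    """Syntax error in a pattern spec; message carries the position."""


_TOKEN_RE = re.compile(r"<<|<h|<|\(|\)|=|\"[^\"]*\"|[^\s()<=\"]+")


@dataclass
class PatternNode:
    labels: tuple[str, ...]
    capture: Optional[str] = None
    words: Optional[frozenset[str]] = None
    items: list[tuple[str, "PatternNode"]] = field(default_factory=list)

    def captures(self) -> set[str]:
        out = {self.capture} if self.capture else set()
        for _, child in self.items:
            out |= child.captures()
        return out


def _label_ok(labels: tuple[str, ...], node_label: str) -> bool:
    for lab in labels:
        if lab.endswith("*"):
            if node_label.startswith(lab[:-1]):
                return True
        elif node_label == lab:
            return True
    return False


def compile_expr(spec: str) -> PatternNode:
    """Parse a pattern spec into an AST; positions are reported on error."""
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(spec)]
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos][0] if pos < len(tokens) else None

    def err(msg: str) -> PatternSyntaxError:
        at = tokens[pos][1] if pos < len(tokens) else len(spec)
        return PatternSyntaxError(f"{msg} at position {at}")

    def parse_test() -> PatternNode:
        nonlocal pos
        tok = peek()
        if tok is None or tok in "()<" or tok in {"<<", "<h", "="}:
            raise err("expected node test")
        labels = tuple(tok.split("|"))
        pos += 1
        capture = None
        if peek() == "=":
            pos += 1
            cap = peek()
            if cap is None or cap in "()<":
                raise err("expected capture name after '='")
            capture = cap
            pos += 1
        return PatternNode(labels=labels, capture=capture)

    def parse_pattern() -> PatternNode:
        nonlocal pos
        if peek() != "(":
            raise err("expected '('")
        pos += 1
        node = parse_test()
        while peek() not in (")", None):
            tok = peek()
            if tok.startswith('"'):
                node.words = frozenset(w.lower() for w in tok[1:-1].split("|"))
                pos += 1
                continue
            if tok not in {"<", "<<", "<h"}:
                raise err(f"expected operator, got {tok!r}")
            op = tok
            pos += 1
            nxt = peek()
            if nxt == "(":
                operand = parse_pattern()
            elif nxt is None or nxt == ")":
                raise err("expected operand")
            else:
                operand = parse_test()
            node.items.append((op, operand))
        if peek() != ")":
            raise err("expected ')'")
        pos += 1
        return node

    root = parse_pattern()
    if pos != len(tokens):
        raise err("trailing input after pattern")
    return root


# --- head finding ----------------------------------------------------------

_VERB_POS = ("VB", "MD")


def head_preterminal(node: ParseNode) -> Optional[ParseNode]:
    """Lexical head preterminal of a constituent.

    VP: the head of the first nested VP (skipping auxiliaries), else the
    first verbal preterminal child.  S/SBAR: the head of the first VP
    child.  NP: the rightmost nominal preterminal child, else the head of
    the last NP child.
    """
    if node.is_preterminal:
        return node
    if node.is_leaf:
        return None
    lbl = node.label
    if lbl.startswith("VP"):
        for c in node.children:
            if c.label.startswith("VP") and not c.is_leaf:
                return head_preterminal(c)
        for c in node.children:
            if c.is_preterminal and c.label.startswith(_VERB_POS):
                return c
        return None
    if lbl in {"S", "SBAR", "SINV", "SQ"}:
        for c in node.children:
            if c.label.startswith("VP"):
                return head_preterminal(c)
        return None
    if lbl.startswith("NP") or lbl == "WHNP":
        nominal = [c for c in node.children
                   if c.is_preterminal and c.label.startswith(("NN", "PRP", "WDT", "WP"))]
        if nominal:
            return nominal[-1]
        nps = [c for c in node.children if c.label.startswith("NP") and not c.is_leaf]
        if nps:
            return head_preterminal(nps[-1])
        return None
    return None


def leaf_surface(preterminal: ParseNode) -> str:
    s = preterminal.children[0].surface
    return PTB_UNESCAPE.get(s, s)


# --- matching --------------------------------------------------------------

def _merge(a: dict, b: dict) -> Optional[dict]:
    out = dict(a)
    for k, v in b.items():
        if k in out and out[k] is not v:
            return None
        out[k] = v
    return out


def match_at(pattern: PatternNode, node: ParseNode) -> list[dict]:
    """All capture bindings for ``pattern`` anchored at ``node``."""
    if node.is_leaf or not _label_ok(pattern.labels, node.label):
        return []
    if pattern.words is not None:
        if not node.is_preterminal or leaf_surface(node).lower() not in pattern.words:
            return []
    partials: list[tuple[dict, int]] = [({}, node.span[0])]
    for op, operand in pattern.items:
        nxt: list[tuple[dict, int]] = []
        for binding, minpos in partials:
            if op == "<":
                cands = [c for c in node.children if not c.is_leaf]
            elif op == "<<":
                cands = list(node.descendants())  # all non-leaf proper descendants
            else:  # <h
                h = head_preterminal(node)
                cands = [h] if h is not None else []
            for cand in cands:
                if cand.span[0] < minpos:
                    continue
                for sub in match_at(operand, cand):
                    merged = _merge(binding, sub)
                    if merged is not None:
                        nxt.append((merged, cand.span[1]))
        partials = nxt
        if not partials:
            return []
    results = []
    seen = set()
    for binding, _ in partials:
        if pattern.capture:
            binding = _merge(binding, {pattern.capture: node})
            if binding is None:
                continue
        key = tuple(sorted((k, id(v)) for k, v in binding.items()))
        if key not in seen:
            seen.add(key)
            results.append(binding)
    return results


def match_expr(pattern: PatternNode, tree: ParseTree) -> list[dict]:
    """Match ``pattern`` at every node of ``tree`` (exhaustive)."""
    out = []
    seen = set()
    for node in tree.nodes():
        for binding in match_at(pattern, node):
            key = tuple(sorted((k, id(v)) for k, v in binding.items()))
            if key not in seen:
                seen.add(key)
                out.append(binding)
    return out
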