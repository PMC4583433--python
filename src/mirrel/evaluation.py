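"""Scoring of predicted relations against gold corpora.

Abstract-level evaluation counts unique (document, miRNA, gene, direction)
tuples; mention-level evaluation (for corpora that annotate duplicated
pairs) matches each predicted instance against at most one gold instance.
miRNA names are compared case-insensitively, gene symbols case-sensitively;
an optional arm-insensitive mode strips -3p/-5p before comparison.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .assembly import Relation
from .model import Direction, Directness

RELATION_CLASSES = ("mirna_gene_regulation", "gene_mirna_regulation",
                    "mirna_target")
LEVELS = ("abstract", "mention")


class CorpusError(ValueError):
    """Inconsistent gold corpus (dangling references, bad files)."""


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    mirna_norm: str
    gene_norm: str
    direction: Direction
    directness: Directness = Directness.unknown


@dataclass
class EvalReport:
    relation_class: str
    level: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


_ARM_RE = re.compile(r"-[35]p$")

RelLike = Union[Relation, GoldAnnotation]


def _as_tuple(r: RelLike, arm_insensitive: bool) -> tuple:
    mirna = r.mirna_norm.lower()
    if arm_insensitive:
        mirna = _ARM_RE.sub("", mirna)
    return (r.doc_id, mirna, r.gene_norm, r.direction)


def _directness(r: RelLike) -> Directness:
    d = r.directness
    return d if isinstance(d, Directness) else Directness(d)


def _filter(items: Sequence[RelLike], relation_class: str,
            arm_insensitive: bool) -> list[tuple]:
    if relation_class == "mirna_gene_regulation":
        keep = [r for r in items if r.direction is Direction.mirna_to_gene]
    elif relation_class == "gene_mirna_regulation":
        keep = [r for r in items if r.direction is Direction.gene_to_mirna]
    elif relation_class == "mirna_target":
        keep = [r for r in items if r.direction is Direction.mirna_to_gene
                and _directness(r) is Directness.direct]
    else:
        raise CorpusError(f"unknown relation class {relation_class!r}")
    return [_as_tuple(r, arm_insensitive) for r in keep]


def score(pred: Sequence[RelLike], gold: Sequence[RelLike],
          relation_class: str = "mirna_gene_regulation",
          level: str = "abstract", arm_insensitive: bool = False) -> EvalReport:
    """Precision/recall/F for one relation class at one evaluation level."""
    if level not in LEVELS:
        raise CorpusError(f"unknown evaluation level {level!r}")
    p = _filter(pred, relation_class, arm_insensitive)
    g = _filter(gold, relation_class, arm_insensitive)
    if level == "abstract":
        ps, gs = set(p), set(g)
        tp = len(ps & gs)
        return EvalReport(relation_class, level, tp, len(ps) - tp, len(gs) - tp)
    pc, gc = Counter(p), Counter(g)
    tp = sum(min(pc[k], gc[k]) for k in pc)
    return EvalReport(relation_class, level, tp, sum(pc.values()) - tp,
                      sum(gc.values()) - tp)


def load_gold_relations(text: str) -> list[GoldAnnotation]:
    """Parse a gold relation TSV: doc_id, miRNA, gene, direction, directness."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("doc_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise CorpusError(f"relations line {lineno}: expected >=4 columns")
        doc_id, mirna, gene, direction = parts[:4]
        directness = parts[4] if len(parts) > 4 and parts[4] else "unknown"
        try:
            out.append(GoldAnnotation(doc_id, mirna, gene,
                                      Direction(direction),
                                      Directness(directness)))
        except ValueError as exc:
            raise CorpusError(f"relations line {lineno}: {exc}") from exc
    return out


def format_table(reports: dict[str, dict[str, EvalReport]]) -> str:
    """Pretty ablation table: systems as rows, relation classes as columns."""
    classes = RELATION_CLASSES
    header = f"{'System':<16}" + "".join(
        f"{c:>42}" for c in ("miRNA-gene regulation", "Gene-miRNA regulation",
                             "miRNA-target"))
    sub = f"{'':<16}" + ("".join(f"{h:>14}" for h in ("P", "R", "F"))) * 3
    lines = [header, sub]
    for system, per_class in reports.items():
        row = f"{system:<16}"
        for c in classes:
            rep = per_class.get(c)
            if rep is None:
                row += f"{'-':>14}" * 3
            else:
                row += (f"{rep.precision:>14.2f}{rep.recall:>14.2f}"
                        f"{rep.f_score:>14.2f}")
        lines.append(row)
    return "\n".join(lines)


def agreement_f(ann_a: Sequence[RelLike], ann_b: Sequence[RelLike],
                relation_class: str = "mirna_gene_regulation") -> float:
    """Inter-annotator agreement as an F-style score: one annotation set is
    taken as gold and the other contrasted with it (convenience flag)."""
    return score(ann_a, ann_b, relation_class).f_score
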