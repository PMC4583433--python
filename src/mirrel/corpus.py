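"""Fixture/corpus container and the on-disk corpus directory format.

A corpus directory holds, per document, ``<doc_id>.txt`` (plain text),
``<doc_id>.ann`` (standoff entity mentions, document-level offsets) and
``<doc_id>.ptb`` (one gold bracketed parse per sentence, in order), plus a
shared ``relations.tsv`` with the gold relations.  Everything is plain
text, so corpora can be versioned and inspected directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .entities import load_standoff, write_standoff
from .evaluation import CorpusError, GoldAnnotation, load_gold_relations
from .model import Document, EntityMention, Section, SectionType, SourceKind
from .textprep import ParseFormatError, read_ptb_trees, sentence_from_tree, split_sentences


@dataclass
class Fixture:
    """A self-consistent document with parses, mentions and gold relations."""

    doc: Document
    mentions_by_sent: dict[str, list[EntityMention]] = field(default_factory=dict)
    gold: list[GoldAnnotation] = field(default_factory=list)
    provenance: str = ""

    @property
    def doc_id(self) -> str:
        return self.doc.doc_id

    def all_mentions(self) -> list[EntityMention]:
        return [m for ms in self.mentions_by_sent.values() for m in ms]

    def validate(self) -> None:
        """Gold relations must reference normalized names of annotated mentions."""
        norms = {(m.etype.value, m.norm.lower()) for m in self.all_mentions()}
        for g in self.gold:
            if g.doc_id != self.doc_id:
                raise CorpusError(f"{self.doc_id}: foreign gold doc_id {g.doc_id}")
            m_key = ("miRNA", g.mirna_norm.lower())
            g_key = ("gene", g.gene_norm.lower())
            if m_key not in norms:
                raise CorpusError(
                    f"{self.doc_id}: gold miRNA {g.mirna_norm!r} not among "
                    f"annotated mentions")
            if g_key not in norms:
                raise CorpusError(
                    f"{self.doc_id}: gold gene {g.gene_norm!r} not among "
                    f"annotated mentions")


def build_fixture(doc_id: str, text: str, parses: list[str],
                  standoff: str, gold: list[GoldAnnotation],
                  provenance: str = "") -> Fixture:
    """Assemble a fixture from raw pieces, aligning parses to sentences."""
    sentences = split_sentences(text, sent_prefix=f"{doc_id}:s")
    trees = []
    for p in parses:
        trees.extend(read_ptb_trees(p))
    if len(trees) != len(sentences):
        raise CorpusError(
            f"{doc_id}: {len(trees)} parses for {len(sentences)} sentences "
            f"({[s.sent_id for s in sentences]})")
    parsed = []
    for sent, tree in zip(sentences, trees):
        ps = sentence_from_tree(sent.sent_id, sent.text, tree)
        ps.doc_offset = sent.doc_offset
        parsed.append(ps)
    section = Section(section_id=f"{doc_id}:Abstract",
                      section_type=SectionType.Abstract, sentences=parsed)
    doc = Document(doc_id=doc_id, sections=[section],
                   source_kind=SourceKind.abstract, text=text)
    mentions = load_standoff(standoff, doc) if standoff else []
    by_sent: dict[str, list[EntityMention]] = {}
    for m in mentions:
        by_sent.setdefault(m.sent_id, []).append(m)
    fx = Fixture(doc=doc, mentions_by_sent=by_sent, gold=list(gold),
                 provenance=provenance)
    fx.validate()
    return fx


def write_corpus(fixtures: Iterable[Fixture], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rel_lines = ["doc_id\tmiRNA\tgene\tdirection\tdirectness"]
    for fx in fixtures:
        (path / f"{fx.doc_id}.txt").write_text(fx.doc.text, encoding="utf-8")
        (path / f"{fx.doc_id}.ann").write_text(
            write_standoff(fx.all_mentions(), fx.doc), encoding="utf-8")
        trees = [s.parse.serialize() for s in fx.doc.sentences() if s.parse]
        (path / f"{fx.doc_id}.ptb").write_text("\n".join(trees) + "\n",
                                               encoding="utf-8")
        for g in fx.gold:
            rel_lines.append("\t".join([g.doc_id, g.mirna_norm, g.gene_norm,
                                        g.direction.value, g.directness.value]))
    (path / "relations.tsv").write_text("\n".join(rel_lines) + "\n",
                                        encoding="utf-8")


def load_gold_corpus(path: str | Path) -> list[Fixture]:
    """Load a corpus directory; every fixture is validated on load."""
    path = Path(path)
    if not path.is_dir():
        raise CorpusError(f"not a corpus directory: {path}")
    rel_file = path / "relations.tsv"
    gold_all = (load_gold_relations(rel_file.read_text(encoding="utf-8"))
                if rel_file.exists() else [])
    by_doc: dict[str, list[GoldAnnotation]] = {}
    for g in gold_all:
        by_doc.setdefault(g.doc_id, []).append(g)
    fixtures = []
    for txt in sorted(path.glob("*.txt")):
        doc_id = txt.stem
        text = txt.read_text(encoding="utf-8")
        ann = path / f"{doc_id}.ann"
        ptb = path / f"{doc_id}.ptb"
        if not ptb.exists():
            raise CorpusError(f"{doc_id}: missing parse file {ptb.name}")
        try:
            fx = build_fixture(
                doc_id, text, [ptb.read_text(encoding="utf-8")],
                ann.read_text(encoding="utf-8") if ann.exists() else "",
                by_doc.get(doc_id, []), provenance=f"corpus:{path.name}")
        except (ParseFormatError, ValueError) as exc:
            raise CorpusError(f"{doc_id}: {exc}") from exc
        fixtures.append(fx)
    known = {fx.doc_id for fx in fixtures}
    dangling = set(by_doc) - known
    if dangling:
        raise CorpusError(f"gold relations reference unknown documents: "
                          f"{sorted(dangling)}")
    return fixtures
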