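"""Pipeline orchestration: tiers, directions, per-document extraction.

Three cumulative system settings mirror the ablation of the extraction
method: same-trigger rules only; plus the linking component; plus the
relaxed-constraint rules.  A sentence-co-occurrence baseline is provided
for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .assembly import (
    CandidateRelation,
    Relation,
    aggregate_document,
    apply_relaxed,
    classify_directness,
    cooccurrence_baseline,
)
from .linking import resolve_matches
from .model import Direction, Document, EntityMention, Sentence, Tier
from .rules import TreePattern, default_rules, match_rules, pair_same_trigger
from .triggers import TriggerLexicon, default_lexicon, find_triggers

logger = logging.getLogger("mirrel")

TIER_NAMES = {"same_trigger", "linking", "relaxed"}


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or missing input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    tiers: frozenset[str] = frozenset({"same_trigger", "linking", "relaxed"})
    directions: tuple[Direction, ...] = (Direction.mirna_to_gene,
                                         Direction.gene_to_mirna)
    trigger_lexicon: Optional[TriggerLexicon] = None
    rules: Optional[list[TreePattern]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        tiers = frozenset(self.tiers)
        unknown = tiers - TIER_NAMES
        if unknown:
            raise ConfigError(f"unknown tiers: {sorted(unknown)}")
        if "linking" in tiers and "same_trigger" not in tiers:
            raise ConfigError("the linking tier requires the same_trigger tier")
        if "relaxed" in tiers and "same_trigger" not in tiers:
            raise ConfigError("the relaxed tier requires the same_trigger tier")
        object.__setattr__(self, "tiers", tiers)
        if self.trigger_lexicon is None:
            self.trigger_lexicon = default_lexicon()
        if self.rules is None:
            self.rules = default_rules()


def analyze_sentence(sentence: Sentence, mentions: list[EntityMention],
                     config: PipelineConfig,
                     context: Iterable[tuple[Sentence, list[EntityMention]]] = ()
                     ) -> list[CandidateRelation]:
    """Run the configured tiers over one parsed sentence."""
    if sentence.parse is None:
        raise DataError(f"no parse available for sentence {sentence.sent_id}")
    triggers = find_triggers(sentence, config.trigger_lexicon, mentions)
    if not triggers:
        return []
    candidates: list[CandidateRelation] = []
    linking = "linking" in config.tiers
    for direction in config.directions:
        matches = match_rules(sentence, triggers, mentions, direction,
                              config.rules)
        resolved = resolve_matches(matches, sentence, mentions, context,
                                   enable_linking=linking)
        same_trigger = (pair_same_trigger(resolved, sentence)
                        if "same_trigger" in config.tiers else [])
        candidates.extend(same_trigger)
        if "relaxed" in config.tiers:
            candidates.extend(apply_relaxed(resolved, same_trigger,
                                            sentence, direction))
        for m in resolved:
            logger.debug("%s match rule=%s role=%s trig=%s ents=%s link=%s",
                         sentence.sent_id, m.rule_id, m.role, m.trigger.lemma,
                         [e.norm for e in m.resolved_entities],
                         m.linking_method)
    # drop relaxed candidates that duplicate a same-trigger pair
    st_keys = {c.pair_key() for c in candidates if c.tier is Tier.same_trigger}
    candidates = [c for c in candidates
                  if c.tier is Tier.same_trigger or c.pair_key() not in st_keys]
    for c in candidates:
        c.directness = classify_directness(c, sentence).value
    return candidates


def extract_document(doc: Document,
                     mentions_by_sent: dict[str, list[EntityMention]],
                     config: PipelineConfig) -> list[Relation]:
    """Extract unique relations from one document.

    Anaphora scope for cross-sentence search is the enclosing section.
    """
    candidates: list[CandidateRelation] = []
    for section in doc.sections:
        context: list[tuple[Sentence, list[EntityMention]]] = []
        for sentence in section.sentences:
            mentions = mentions_by_sent.get(sentence.sent_id, [])
            candidates.extend(analyze_sentence(sentence, mentions, config,
                                               context))
            context.append((sentence, mentions))
    return aggregate_document(candidates, doc.doc_id)


def extract_baseline(doc: Document,
                     mentions_by_sent: dict[str, list[EntityMention]],
                     lexicon: Optional[TriggerLexicon] = None) -> list[Relation]:
    """Co-occurrence baseline over a whole document (no parses needed)."""
    lexicon = lexicon or default_lexicon()
    candidates: list[CandidateRelation] = []
    for sentence in doc.sentences():
        mentions = mentions_by_sent.get(sentence.sent_id, [])
        candidates.extend(cooccurrence_baseline(sentence, lexicon, mentions))
    return aggregate_document(candidates, doc.doc_id)


def config_for_setting(setting: str, **kwargs) -> PipelineConfig:
    """Named ablation settings: 'same-trigger', 'linking', 'full'."""
    tiers = {
        "same-trigger": {"same_trigger"},
        "linking": {"same_trigger", "linking"},
        "full": {"same_trigger", "linking", "relaxed"},
    }.get(setting)
    if tiers is None:
        raise ConfigError(f"unknown setting {setting!r}")
    return PipelineConfig(tiers=frozenset(tiers), **kwargs)
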