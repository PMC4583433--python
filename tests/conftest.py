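import pytest

from mirrel import examples
from mirrel.pipeline import config_for_setting, extract_document
from mirrel.rules import default_rules
from mirrel.synth import detokenize, generate_fixtures
from mirrel.textprep import read_ptb_trees, sentence_from_tree
from mirrel.triggers import default_lexicon


@pytest.fixture(scope="session")
def curated():
    """The curated literature fixtures (gold parses + gold mentions)."""
    return examples.fixtures()


@pytest.fixture(scope="session")
def synth_corpus():
    return generate_fixtures(seed=11, n=120)


@pytest.fixture(scope="session")
def trig_lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def rule_inventory():
    return default_rules()


def make_sentence(parse: str, sent_id: str = "s0", text: str | None = None):
    """Build a parsed sentence directly from a bracketed tree."""
    tree = read_ptb_trees(parse)[0]
    if text is None:
        text = detokenize(tree.leaf_surfaces())
    return sentence_from_tree(sent_id, text, tree)


def run_setting(fixture, setting: str):
    cfg = config_for_setting(setting)
    return extract_document(fixture.doc, fixture.mentions_by_sent, cfg)


def pair_set(relations):
    return {(r.mirna_norm, r.gene_norm, r.direction.value) for r in relations}


def full_set(relations):
    return {(r.mirna_norm, r.gene_norm, r.direction.value, r.directness.value)
            for r in relations}


def gold_full_set(gold):
    return {(g.mirna_norm, g.gene_norm, g.direction.value, g.directness.value)
            for g in gold}
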