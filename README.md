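# mirrel

Rule-based extraction of **miRNA–gene regulation relations** from
biomedical text.

MicroRNAs (miRNAs) are ~22 nt non-coding RNAs that repress gene expression
by base-pairing with target mRNAs, typically at the 3'UTR.  Experimentally
validated miRNA targets are reported across a rapidly growing literature,
and curators, database builders and bench scientists need to find them.
`mirrel` reads sentences with constituency parses and extracts three
relation classes:

* **miRNA–gene regulation** — a directed relation: the miRNA regulates the
  gene (directness unspecified);
* **miRNA–target** — the subset of miRNA–gene relations judged *direct*
  (the miRNA binds the gene's mRNA); and
* **gene–miRNA regulation** — the opposite direction: a gene product
  (e.g. a transcription factor) regulates a miRNA's expression.

## Method

Extraction is anchored on **trigger words** — regulation verbs such as
*regulate*, *suppress*, *target* and their nominal/adjectival derivations
(*regulation*, *regulator*, *targeting*, *target*).  Lexico-syntactic
rules are tree patterns over the sentence's constituency parse, written in
a small tree-query language, e.g. the active subject rule

```
agent: NP-VP    (S < NP=arg < (VP <h VB*=trig))
```

Each rule captures **one argument per trigger** (the agent — the
regulator — or the theme — the regulated entity), with typing constraints:
in miRNA→gene mode the agent must be a miRNA mention and the theme a gene
mention; swapping the typing constraints yields gene→miRNA extraction.  A
relation is formed only when an agent match and a theme match share the
**same trigger occurrence**.

Recall is then improved in two stages:

1. **Linking.**  Argument phrases that *refer* to an entity instead of
   naming it ("a validated miR-21 target", "its target genes", "which")
   are resolved by referential linking — is-a/copular and as-predicative
   constructions, appositives, member–collection lists ("genes such as A,
   B and C") — and by scoped anaphora resolution with number and type
   agreement (it/its/their, these/those-NPs, numeric NPs, relative
   pronouns).
2. **Relaxed tier.**  Entities that were matched as arguments but
   participate in no same-trigger relation are paired combinatorially
   (leftover agent-matched miRNA × leftover theme-matched gene), covering
   sentences where agent and theme hang off different trigger
   occurrences.

A miRNA→gene relation is classified **direct** when any in-sentence
evidence holds: a binding-class trigger (*target*/*bind*/*interact*), a
*direct(ly)*/*immediate(ly)* modifier on the trigger, a null-argument rule
with a down-regulating trigger, or a mention of *translation*/the 3'UTR —
unless an explicit *indirect(ly)* vetoes.  A sentence-co-occurrence
baseline (miRNA + gene + any trigger in one sentence) is included for
comparison.

Evaluation is **abstract-level**: unique (document, miRNA, gene,
direction) tuples, with precision/recall/F; mention-level scoring is
available for corpora that annotate duplicate pairs.

No statistical parser is bundled: parses enter through a plain adapter
contract (tokenized sentence in, Penn-Treebank bracketed tree out), and
all shipped corpora — 16 curated literature sentences and a seeded
synthetic generator — carry gold parses, so everything runs offline and
deterministically.

## Worked example

```python
from mirrel import examples
from mirrel.pipeline import config_for_setting, extract_document

fx = examples.as_fixture(examples.by_example_id(14))
rels = extract_document(fx.doc, fx.mentions_by_sent, config_for_setting("full"))
for r in rels:
    print(r.mirna_norm, r.gene_norm, r.direction.value,
          r.directness.value, "|".join(r.triggers), r.tier.value)
```

prints

```
miR-15a BCL2 mirna_to_gene direct target same_trigger
miR-16 BCL2 mirna_to_gene direct target same_trigger
```

The sentence is "Two miRNAs, miR-15a and miR-16, which act as putative
tumor suppressor by targeting the oncogene BCL2, …": the relative pronoun
*which* is detected as the agent of *targeting* by a null-argument rule
and linked to the nearest miRNA-typed noun phrase, which is the
coordination "miR-15a and miR-16" — so both miRNAs are returned, each in a
*direct* (miRNA-target) relation with BCL2 because the trigger is
binding-class.

The same pipeline runs from the shell:

```sh
mirrel fixtures --seed 1 --n 8 --out corpus/          # synthetic gold corpus
mirrel extract  --input corpus/ --out pred.tsv
mirrel evaluate --gold corpus/ --pred pred.tsv --class regulation
# class=mirna_gene_regulation level=abstract tp=10 fp=0 fn=0 P=1.0000 R=1.0000 F=1.0000
mirrel report-ablation --corpus corpus/               # 3 settings x 3 classes
```

`extract` accepts a corpus directory (text + standoff mentions + PTB
parses), a raw text file with `--parses`, or a Medline-style record file;
`--tiers same-trigger,linking,relaxed` selects the system setting.

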