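# Methods

## Model

The extractor treats a regulation statement as a trigger word plus two
semantic arguments: the **agent** (regulator) and the **theme** (regulated
entity).  Both arguments are invariably syntactic dependents of the
trigger, so extraction is driven by lexico-syntactic rules matched against
the sentence's constituency parse.  Design commitments:

* **One argument per rule.**  A rule binds one trigger occurrence and one
  argument phrase; agent rules and theme rules are separate.  This keeps
  the inventory small (one rule per syntactic configuration rather than
  per configuration pair) at the cost of a pairing step.
* **Same-trigger constraint.**  An agent match and a theme match form a
  relation only if they share the same trigger token.  This is the
  high-precision core tier.
* **Typing, not parsing, decides direction.**  miRNA→gene and gene→miRNA
  extraction use the same patterns with the agent/theme type constraints
  exchanged.
* **Arguments may denote entities indirectly.**  A phrase counts as an
  argument if it contains a specific mention of the required type
  ("the MMP1 expression" → MMP1 — expression-of phrases resolve to the
  embedded entity automatically by containment), or if it is a
  *referential phrase* to be resolved by the linking stage.

### Trigger lexicon

Entries are verb lemmas with derived forms, polarity and a directness
class.  The bundled seed lexicon (`mirrel/data/triggers.tsv`) holds the
lemmas regulate, target, bind, interact, suppress, repress, inhibit,
increase, decrease, mediate, cleave, and both spellings of
down-/up-regulate; users extend it by passing their own TSV.  Polarity:
suppress/repress/inhibit/decrease/cleave/downregulate/target are *down*,
increase/upregulate *up*, the rest *neutral*.  The directness class is
exactly {target, bind, interact}.  Verb inflections are generated by a
small English inflector (with an irregular table, e.g. *bound*), so
matching is tense- and number-insensitive; ambiguous surfaces ("targets"
as VBZ vs NNS) are resolved by the POS tag from the parse.

Process nouns ("regulation", "targeting") keep the verb's argument
mapping: in "X of Y", the of-argument is the theme.  Entity nouns denote
one participant themselves: "target of X" makes X the agent, while
"regulator of X" makes X the theme.  Which participant an entity noun
denotes is derived from its agentive suffix (-or/-er/-ant → agent,
otherwise theme); the noun phrase containing the entity noun is emitted as
a referential phrase for the denoted role.

### Tree-query language

Rules are s-expressions over constituent labels with four operators:
`<` (child), `<<` (proper descendant), `<h` (lexical head preterminal;
VP heads skip auxiliaries) and a quoted word test on preterminals.
Consecutive items of one node must bind non-overlapping constituents in
left-to-right order, which encodes linear precedence and prevents an item
from reaching inside a previously bound sibling (important for the
null-argument rule, where the by-/via-clause must follow the subject).
Matching is exhaustive over anchors and capture assignments; the test
suite checks it against a brute-force enumerator on all trees ≤ 15
leaves.  Passive voice is not encoded structurally but computed from the
trigger's auxiliary chain (VBN under be/get → passive; under bare have →
active perfect; bare VBN → passive, covering reduced relatives), and
rules declare the voice they require.

The default inventory (`mirrel/data/rules.tsv`, 14 rules) covers: active
subject/object, verbal to-PP themes, passive subject themes with by-PP
agents, process-noun of/by/to arguments (including "binding of X to Y",
where the of-argument is the agent precisely when a to-PP is present),
entity-noun self/of-for/premodifier rules, a null-argument rule for the
agent role (prepositions via/by/through/upon/after), and an adjectival
premodifier rule.  Null-argument extraction is implemented for the agent
role only — the role with clear worked cases; a theme-side analogue would
be speculative and is left out deliberately.

### Linking

Referential phrases are resolved in a fixed order; failure at every step
drops the argument (the system abstains rather than guesses):

1. **is-a** — copular sentences in either direction, plus as-predicatives
   ("identified X … as a negative regulator of …");
2. **appositive** — an adjacent NP sibling under the same parent, comma
   optional.  Allowing the comma-less case is needed for bare gene-list
   appositions ("its target genes hPDCD4 …, hPTEN …"); the risk of
   over-linking is bounded because the sibling must contain a mention of
   the required type;
3. **member-collection** — a cue (such as, including, like, namely, e.g.,
   i.e., ":") inside the phrase or its parent, collecting the
   type-compatible mentions after the cue.

Anaphora resolution enforces number and type agreement with per-kind
scopes: *it/its* need a unique type-compatible entity in the sentence
(two-candidate ties are broken only by the main-clause subject, otherwise
unresolved; a unique non-subject candidate is accepted, since uniqueness
already satisfies the single-entity-in-sentence requirement);
*their/they/them* need a preceding phrase with more than one entity;
*these/those X* and numeric NPs ("two miRNAs") search backwards through
the enclosing section for a phrase with the agreeing count.  Relative
pronouns are linked to the nearest preceding type-compatible NP (by token
distance) inside the constituent hosting the relative clause; when that
NP is a coordination or appositive list, all its entities are returned.
Sections are the hard outer scope: full-text documents are processed
subsection by subsection, and no antecedent ever crosses a section
boundary.

### Relaxed tier

After the same-trigger tier, entities that were matched as an argument by
*some* rule but participate in no same-trigger relation of the sentence
are paired combinatorially: every leftover agent-matched miRNA with every
leftover theme-matched gene.  The trigger words of the two matches need
not agree — requiring them to differ would be wrong, because with the
same-trigger tier disabled the tier must reduce to the full combinatorial
pairing (the three-miRNA/two-gene coordination sentence then yields six
pairs, of which only three are correct; with the same-trigger tier active
it yields zero, because all argument-matched entities already
participate).  Entities never matched as arguments (e.g. a cluster
mention that is the subject of a non-trigger verb) are never paired.

### Directness

A miRNA→gene relation is *direct* (a miRNA-target relation) iff any of:

* E1 — a binding-class trigger (target/bind/interact or derived form);
* E2 — direct/directly/immediate/immediately within ±2 tokens of the
  trigger;
* E3 — the relation was extracted by a null-argument rule *and* the
  trigger that extracted the theme has down polarity.  The polarity test
  is on the embedded trigger, not the governing verb: "inhibits … by
  regulating G" stays unknown (neutral embedded trigger), "reduces … by
  suppressing G" is direct;
* E4 — *translation* or a 3'UTR variant anywhere in the sentence.  The
  variant set is case-insensitive and whitespace/prime-tolerant
  (3'UTR, 3' UTR, 3'-UTR, 3' untranslated region, three prime
  untranslated region);

vetoed by an explicit *indirect/indirectly* token anywhere in the
sentence.  The veto is sentence-scope rather than trigger-attached: it
trades a little recall on contrastive sentences for not asserting
directness against the author's explicit hedge.  Direct relations are by
construction a subset of miRNA→gene relations; the co-occurrence baseline
classifies directness from E1/E4 only, having no rule structure.

### Aggregation and scoring

Sentence-level candidates are merged to unique document-level relations
on (miRNA, gene, direction); directness is direct if any member is
direct; evidence sentences and triggers accumulate; ordering is
deterministic.  Abstract-level scoring compares unique tuples; the
mention level matches instance multiplicities (Counter intersection).
miRNA names are compared case-insensitively after canonical hyphenation
("MicroRNA-223" → "miR-223"; species prefixes retained), genes
case-sensitively; an off-by-default arm-insensitive flag strips -3p/-5p.

## Inputs and mention recognition

miRNA mentions are recognized by a nomenclature grammar: optional species
prefix, core prefix (miR/miRNA/microRNA, the historical let/lin families,
and a bracketed "(miR) -17-92" cluster form), identifying number,
optional letter suffix, arm (-3p/-5p) and extra numeric suffix.  Slash
conjunctions expand into one mention per conjunct with prefix inheritance
("miR-15a/-16-1" → miR-15a, miR-16-1), sharing the textual span.
Family-only mentions ("miRNAs") are kept but flagged non-specific and
never become relation arguments.  Clusters are a single mention, not
expanded into members.  The exact suffix coverage beyond the common forms
is a deliberate superset choice.

Gene recognition is lexicon-based (longest match, token boundaries,
matches inside miRNA spans discarded); the evaluation pathway normally
consumes manually checked standoff mentions instead, because statistical
gene NER would dominate the error analysis of a rule-based extractor.
The standoff dialect is `ID<TAB>TYPE START END<TAB>SURFACE[<TAB>NORM]`;
the optional NORM column lets two records share a span with different
normalized names (expanded conjunctions).

## Synthetic data

`mirrel.synth` generates fixture documents from twelve templates, one per
construction: active/passive verbs, process nouns, null-argument clauses,
is-a, appositives, member-collection lists (2–4 genes), possessive
anaphora, relative pronouns, a different-trigger sentence reachable only
by the relaxed tier, a gene→miRNA sentence, and a co-occurrence
distractor (trigger + miRNA + gene with no syntactic relation) that the
baseline must over-generate on and the rule system must not.  Entity
names are drawn from disjoint synthetic vocabularies (miR-100…999 with
optional letter; four-letter uppercase symbols with a digit); parses are
instantiated from hand-written template trees, and generation is
byte-reproducible for a fixed seed.

What the generator emulates: every construction in the rule inventory, in
clean single-sentence form, with gold mentions and exactly known gold
relations.  What it does not emulate: parser errors, unseen trigger
words, nested/coordinated clause interactions beyond the templates,
negation and speculation, cross-sentence discourse structure, or the
mention-detection noise of real abstracts.  Perfect scores on generated
corpora are therefore a *closure* property — they show the pipeline
implements its own rule inventory and tiers correctly — and the ablation
trend (recall rising from the same-trigger tier through linking to the
full system at constant precision, with the baseline trading precision
for recall) is a qualitative, not quantitative, reproduction of
corpus-scale behavior.  Corpus-level scores from annotated literature
depend on the external parser and corpus and are intentionally not
asserted by the test suite.

## Numerical and procedural choices

* Offsets are 0-based half-open throughout (standoff interchange
  convention).
* Sentence splitting protects abbreviations (et al., e.g., i.e., Fig.,
  vs., …), digit-period-digit, and parenthesized spans; it does not
  require the next sentence to start uppercase, since biomedical
  sentences often begin with "miR-…".  No correction pass is applied for
  splitter errors before parsing.
* Fixture corpora align tokens to the gold parse leaves (word-boundary
  aware), so tokenization can never disagree with the parse in tests.
* When a token is both a trigger candidate and part of an entity mention,
  the entity wins (no trigger occurrence is emitted).
* Competing pattern matches on the same trigger are all kept; pairing and
  deduplication (by normalized pair within a sentence, then by document
  aggregation) absorb the redundancy.
* Degenerate inputs: empty text yields no sentences; a sentence without a
  parse is a data error in `extract` but fine for the baseline; an empty
  gene lexicon simply yields no gene mentions.

## Evaluation problem sizes

The shipped regression suite uses the 16 curated literature sentences and
seeded synthetic corpora of 96–240 documents; the ablation acceptance run
uses 240 fixtures (~20 per template).  These sizes give stable two-decimal
precision/recall estimates for the deterministic pipeline while keeping
the whole suite in the seconds range on one CPU.

## Known limitations

* Recall on real text is bounded by the seed trigger lexicon and the
  14-rule inventory; both are user-extensible files, which is the
  intended path for domain adaptation.
* The relaxed tier inherits the precision risk of combinatorial pairing
  in sentences with many leftover argument matches.
* Anaphora resolution is heuristic and abstains when ambiguous; sortal
  anaphora beyond the listed kinds, cross-section coreference and event
  nesting (regulation of regulation) are out of scope.
* Directness classification is sentence-local; evidence spread across
  sentences (e.g. a 3'UTR assay described two sentences later) is
  missed.
* No negation or speculation handling: "does not regulate" currently
  yields a relation.
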