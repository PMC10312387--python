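# Methods

## Models

Word forms are modelled as sequences of sound tokens (segments). Three
relations between the forms of one language are detected, each giving rise
to a cross-linguistic network over concepts:

- **full colexification**: two forms with distinct concepts have identical
  token sequences; undirected.
- **affix colexification**: the whole form expressing concept A is a
  proper prefix or suffix of the form expressing concept B; directed
  A → B, from the concept whose word recurs as an affix to the concept of
  the word containing it. Both directions may coexist as distinct edges.
- **overlap colexification**: two forms share a substring that is a prefix
  or suffix of each, while neither form is identical to, nor a prefix or
  suffix of, the other; undirected, with the shared substring stored as
  the witness.

These relations approximate the sharing of a non-grammatical morpheme with
identical surface form. They do not require morpheme segmentation, which
is rarely available at scale; the price is noise from chance resemblance
and from grammatical marking, which is controlled by length thresholds
(below) and, across languages, by the family-level edge weights.

## Thresholds

Two thresholds gate every partial candidate, both read as *exclusive*
bounds: a shared part of length L is admitted only if `L > affix_len_min`,
and every unshared remainder R only if `R > residue_len_min`. Defaults are
(2, 2) for affix inference — minimum shared affix 3 sounds, minimum
remainder 3 sounds, which biases detection toward compounding rather than
inflection — and (4, 3) for overlap inference, whose search space is
noisier. The same exclusive convention is applied to both kinds for
consistency; both values are configurable per run (`--affix-min`,
`--residue-min`). Thresholds count *sounds*, which is why segmented
phonetic input is the primary format; per-character tokenization exists
for orthographic toy data, where a "sound" degrades to a letter.

## Inference algorithm

Per language, a two-pass associative-array scheme:

1. every admissible prefix and suffix of every form is entered into an
   index mapping the affix (as a token tuple) to the list of (form, side)
   pairs exhibiting it — a form of n tokens contributes at most
   `2·(n − affix_len_min − residue_len_min − 1)` entries and never its
   whole self;
2. - *affix*: the original forms are walked longest-first (ties broken by
     form string, then concept); a form found verbatim as an index key
     yields one directed instance per indexed host with a distinct
     concept.
   - *overlap*: the index keys are walked longest-first (ties broken by
     token sequence); each unordered pair of distinct-concept forms under
     a key is emitted at most once — at its longest shared admissible
     substring — provided the forms are not identical and neither is a
     prefix/suffix of the other.

Full colexification uses the degenerate form of the same scheme with the
whole form as the key.

A naive all-pairs implementation applying the same admissibility
predicates by direct comparison is part of the package and is asserted
(unit and property tests) to produce the identical canonicalized instance
set; it is the correctness oracle for the index-based methods.

Design choices where the procedure was genuinely open:

- **Side mixing in overlaps**: the index is keyed by the substring alone,
  so a substring that is a suffix of one form and a prefix of the other is
  admitted. This is the natural behaviour of the index scheme; a
  `same_side_only` switch restricts to equal sides. The witnessed sides
  are recorded on every instance either way.
- **Overlap de-duplication**: without longest-match de-duplication, a pair
  sharing a 6-token prefix would be reported again under its 5-token
  prefix, double-counting weights; each unordered form pair is therefore
  reported once, at its longest shared admissible key. A consequence is
  that the *witness* of a pair can shorten when thresholds are raised (a
  long key may lose remainder admissibility while a shorter one survives);
  the relation set itself is monotone in the thresholds, and the tests
  check monotonicity at that level.
- **Deterministic tie-breaks**: forms and keys of equal length are ordered
  by string/token-tuple comparison; undirected instances are canonicalized
  by sorting their two slots by (concept, form, entry id). Identical
  inputs and configuration therefore yield byte-identical exports.

## Aggregation and weights

Per-language instances merge into one network per kind. Every concept
attested in the wordlist becomes a node (isolated concepts included), so
degree vectors share a common index. Each edge stores all witness
instances and three weights: `weight_forms` (number of witnesses),
`weight_languages`, and `weight_families` (distinct languages/families
among them), hence `weight_families ≤ weight_languages ≤ weight_forms`.
When no family metadata exists, each language counts as its own family.
Duplicate (language, concept, form) rows are dropped on reading by
default, since they would inflate `weight_forms` without evidence; a
switch keeps them. All admitted synonym forms of a concept participate in
inference.

## Analysis

Weighted degree is the sum of incident edge weights; directed networks
distinguish in- and out-degree. The default weight for degree computations
is `weight_families`, which damps family-internal homophony; forms,
languages, or unweighted degrees are selectable. Two degree vectors are
compared by Spearman rank correlation over the *intersection* of their
concept sets (n ≥ 3 required), with average ranks for ties; p-values are
the standard two-sided large-sample approximation, with an exact
permutation p (full enumeration of the n! pairings) available for n ≤ 10.
Subgraph extraction is induced and annotation-preserving; concepts missing
from the network are added as isolated nodes with a warning. Community
detection is delegated to igraph (Infomap or label propagation) behind a
small registry; igraph draws randomness from Python's `random` module, so
the partition is made deterministic by seeding that generator.

## Synthetic data

The generator builds one global lexicon plan — which concepts are simple
roots, which reuse another concept's root slot (planting full
colexifications), which are two-slot compounds (planting directed affix
links from the member concepts, and overlap links between compounds
sharing a slot peripherally) — and realises the plan independently in each
language with freshly sampled roots. Languages are assigned round-robin to
families. Defaults: 5 languages, 30 concepts, compound probability 0.4,
full-colexification probability 0.1, root lengths 5–7 tokens over a
21-sound inventory — sizes at which every planted relation clears the
default thresholds of all three inference kinds and collision-free
sampling succeeds easily.

Roots are rejection-sampled so that two distinct roots never share a
peripheral substring of more than one token and never contain one another
at any position. Under plain concatenative compounding these two
conditions exclude every accidental full, affix, or overlap relation
between forms built from distinct slots, so the planted relation sets are
*exactly* the inferable ones and precision/recall against the ground truth
is a sharp 1.0/1.0 test rather than a statistical one. A `perturb`
operation rewrites a fraction of forms to collide peripherally with
others, creating controlled false-positive candidates for threshold
tests.

What the generator does **not** emulate: sound change and cognate
variation across languages (every language realises the same plan),
grammatical affixes, morphophonological alternations at compound
boundaries, or realistic phonotactics. Passing the recovery tests
therefore shows that the inference machinery is exact on transparent
concatenative morphology, not that real lexicons are this clean — on real
data, the thresholds and family weights do the noise suppression, and
precision against a (nonexistent) gold standard cannot be 1.

## Problem sizes

Unit and property tests run on wordlists of 3–80 forms; the oracle
equivalence and recovery properties use ten seeds of 5-language /
50-form lexicons plus perturbed variants, sizes at which the naive
quadratic oracle is instantaneous while still exercising thousands of
index entries. The acceptance script uses two-word wordlists with planted
prefixes of length 1–5. Full-scale runs (hundreds of languages, ~10⁶
tokens) are supported by the same code paths but require the external
dataset referenced in the README.

## Known limitations

- Partial colexification here requires *surface-identical* shared
  material; shared but sound-shifted (merely cognate) morphemes are out of
  scope.
- No suffix-tree or other asymptotically better index; the associative
  array is linear in the number of admissible affixes, which suffices for
  current dataset sizes.
- Overlap inference reports each form pair once; alternative shared
  substrings of the same pair are not enumerated.
- The exact permutation p-value enumerates n! pairings and is gated to
  n ≤ 10.
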