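# colexnet

Inference and analysis of **full and partial colexification networks** from
multilingual wordlists.

A *colexification* occurs when one word form of a language expresses two or
more distinct concepts (Russian *mir* "peace" and "world"), and aggregating
such cases across many languages yields semantic networks over concepts.
Beyond the classical full case, `colexnet` detects two *partial*
colexification relations between word forms modelled as sound sequences:

- **affix colexification** — the entire form expressing concept A is a
  prefix or suffix (in the computer-science sense) of the form expressing
  concept B, as German *Hand* in *Handschuh* "glove"; this is a *directed*
  relation A → B, from the word recurring as an affix to the word
  containing it;
- **overlap colexification** — two forms share a peripheral substring (a
  prefix or suffix of each) while neither contains the other, as English
  *waterfall* / *watermelon* sharing *water*; this relation is undirected
  and the shared substring is stored as its witness.

Because partial similarities between words constantly arise by chance or
through grammatical marking, candidates are gated by two length thresholds:
the shared part must exceed `affix_len_min` tokens and every unshared
remainder must exceed `residue_len_min` tokens. The defaults — (2, 2) for
affix, (4, 3) for the noisier overlap search — mean a shared affix of at
least 3 sounds with remainders of at least 3 sounds, and a shared overlap
of at least 5 sounds with remainders of at least 4.

Detection is a two-pass associative-array scheme per language: pass one
indexes every admissible prefix/suffix of every form; pass two resolves the
index into relations. A quadratic all-pairs reference implementation with
the same admissibility predicates is included and produces identical
results; the test suite asserts this equivalence on randomized inputs.
Per-language relations are merged into annotated networks whose edges count
witness forms, languages, and language families
(`weight_families ≤ weight_languages ≤ weight_forms`), with every witness
form and shared substring stored on the edge.

The analysis layer computes (weighted, in-/out-) degree vectors, compares
them across networks with the Spearman rank correlation, extracts induced
subgraphs, and delegates community detection (Infomap, label propagation)
to igraph. The weighted out-degree of a concept in the affix network is a
proxy for its *lexical root productivity* (how often its words are reused
as building blocks of other words); the affix in-degree and the overlap
degree measure *compoundhood* (how often the concept is expressed by
morphologically complex words).

The audience is computational lexical typologists and anyone who needs
cross-linguistic semantic networks: the library is usable from Python, and
a `colexnet` command-line tool covers the whole pipeline.

## Worked example

A three-word toy wordlist (orthographic, hence character tokenization and
lowercasing):

```sh
printf 'ID\tDOCULECT\tCONCEPT\tFORM\tTOKENS
1\tgerman\tHAND\tHand\t
2\tgerman\tSHOE\tSchuh\t
3\tgerman\tGLOVE\tHandschuh\t
' > glove.tsv
colexnet infer --input glove.tsv --kind affix --tokenizer character \
    --lowercase --output glove-affix.tsv --format tsv
cat glove-affix.tsv
```

prints

```
affix network: 1 languages, 3 forms, 3 nodes, 2 edges -> glove-affix.tsv
concept_a	concept_b	direction	weight_forms	weight_languages	weight_families
HAND	GLOVE	->	1	1	1
SHOE	GLOVE	->	1	1	1
```

*hand* is an admissible prefix of *handschuh* and *schuh* an admissible
suffix, so the concepts HAND and SHOE each send one directed edge to GLOVE;
each edge is witnessed by one form in one language (= one family, since
toy data carry no family metadata).

The same pipeline on a synthetic wordlist with planted compounds, followed
by a degree-distribution comparison:

```sh
colexnet synth --languages 4 --concepts 20 --seed 3 \
    --output synth.tsv --truth truth.json
colexnet infer --input synth.tsv --kind affix --output affix.json
colexnet infer --input synth.tsv --kind full  --output full.json
colexnet analyze degrees --network affix.json --mode out \
    --weight languages --output deg-out.tsv
colexnet analyze degrees --network full.json \
    --weight languages --output deg-full.tsv
colexnet analyze compare --a deg-full.tsv --b deg-out.tsv
```

prints

```
wrote 80 forms, 4 languages -> synth.tsv
affix network: 4 languages, 80 forms, 20 nodes, 13 edges -> affix.json
full network: 4 languages, 80 forms, 20 nodes, 1 edges -> full.json
rho	0.5932
p	0.00583362
n	20
```

`rho` is the Spearman rank correlation between the weighted degree of each
concept in the full network and its weighted out-degree in the affix
network, over the `n = 20` shared concepts: concepts that colexify fully
also tend to be productive roots in this synthetic lexicon. Networks can
also be exported as GML or GraphML (`--format gml|graphml`) for Cytoscape
or Gephi.

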