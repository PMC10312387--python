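"""Inference of full, affix, and overlap colexifications.

Three relations between the word forms of one language are detected, each
over forms modelled as sound sequences:

* **full colexification** — two forms expressing different concepts are
  identical;
* **affix colexification** — the entire form expressing one concept is a
  prefix or suffix (in the computer-science sense) of the form expressing
  another concept; the relation is directed, from the affix word's concept
  to the host word's concept (FINGER → FINGERNAIL);
* **overlap colexification** — two forms share a peripheral substring (a
  prefix or suffix of each) but neither contains the other; the relation is
  undirected and the shared substring is stored as the witness.

Because partial similarities between words arise constantly by chance and
through grammatical marking, both partial relations are gated by two length
thresholds: the shared part must be longer than ``affix_len_min`` tokens and
the unshared remainder of every participating form longer than
``residue_len_min`` tokens ("strictly greater than", so the defaults 2/2
admit affixes of three or more sounds with remainders of three or more
sounds; the noisier overlap search defaults to 4/3).

Detection is a two-pass associative-array scheme per language: pass one
indexes every admissible prefix/suffix of every form; pass two resolves the
index into relations.  A quadratic all-pairs reference implementation
(:func:`naive_partial_colexifications`) applies the same admissibility
predicates by direct comparison and must produce the identical instance set
— it serves as a correctness oracle, not as a fallback.

Per-language instances are aggregated over all languages of a wordlist into
an annotated network (:func:`build_network`) whose edge weights count
witness forms, languages, and language families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import networkx as nx

from .errors import ConfigurationError
from .wordlist import FormEntry, SoundSequence, Wordlist

Side = Literal["prefix", "suffix", "whole"]
Kind = Literal["full", "affix", "overlap"]

KINDS: tuple[Kind, ...] = ("full", "affix", "overlap")

_SIDE_ORDER = {"prefix": 0, "suffix": 1, "whole": 2}


@dataclass(frozen=True)
class InferenceConfig:
    """Length thresholds and side restrictions for partial colexification.

    ``affix_len_min`` and ``residue_len_min`` are *exclusive* lower bounds:
    a shared part of length L is admitted only if ``L > affix_len_min`` and
    every remainder R only if ``R > residue_len_min``.  ``sides`` restricts
    which word edges are indexed; ``same_side_only`` additionally requires
    an overlap to sit on the same side of both forms (by default a substring
    that is a suffix of one word and a prefix of the other is admitted).
    """

    affix_len_min: int = 2
    residue_len_min: int = 2
    sides: str = "both"
    same_side_only: bool = False

    def __post_init__(self) -> None:
        if self.affix_len_min < 1:
            raise ConfigurationError("affix_len_min must be >= 1")
        if self.residue_len_min < 0:
            raise ConfigurationError("residue_len_min must be >= 0")
        if self.sides not in ("prefix", "suffix", "both"):
            raise ConfigurationError(f"invalid sides: {self.sides!r}")


#: Defaults for affix inference: shared part > 2 tokens, remainder > 2.
AFFIX_DEFAULTS = InferenceConfig(affix_len_min=2, residue_len_min=2)
#: Defaults for overlap inference: shared part > 4 tokens, remainders > 3.
OVERLAP_DEFAULTS = InferenceConfig(affix_len_min=4, residue_len_min=3)


def default_config(kind: Kind) -> InferenceConfig:
    """The default threshold configuration for a network kind."""
    if kind == "overlap":
        return OVERLAP_DEFAULTS
    if kind in ("affix", "full"):
        return AFFIX_DEFAULTS
    raise ConfigurationError(f"unknown colexification kind: {kind!r}")


@dataclass(frozen=True)
class ColexInstance:
    """One witnessed colexification between two concepts in one language.

    ``shared`` is the witness token sequence: the common form for full
    colexifications, the affix word's whole form for affix colexifications,
    and the shared peripheral substring for overlaps.  ``sides`` records
    where the shared part sits in ``form_a`` and ``form_b`` respectively
    (``"whole"`` when it is the entire form).
    """

    language_id: str
    family: str
    concept_a: str
    concept_b: str
    form_a: str
    form_b: str
    tokens_a: tuple[str, ...]
    tokens_b: tuple[str, ...]
    shared: tuple[str, ...]
    sides: tuple[Side, Side]

    def __post_init__(self) -> None:
        if self.concept_a == self.concept_b:
            raise ValueError("a colexification needs two distinct concepts")

    def sort_key(self):
        return (
            self.language_id,
            self.concept_a,
            self.concept_b,
            self.form_a,
            self.form_b,
            self.shared,
            self.sides,
        )


def _instance(
    a: FormEntry,
    b: FormEntry,
    shared: tuple[str, ...],
    sides: tuple[Side, Side],
    *,
    directed: bool,
) -> ColexInstance:
    """Build an instance; undirected instances are canonicalised by slot."""
    slot_a = (a.concept_id, a.form, a.entry_id)
    slot_b = (b.concept_id, b.form, b.entry_id)
    if not directed and slot_b < slot_a:
        a, b = b, a
        sides = (sides[1], sides[0])
    return ColexInstance(
        language_id=a.language_id,
        family=a.family_or_language,
        concept_a=a.concept_id,
        concept_b=b.concept_id,
        form_a=a.form,
        form_b=b.form,
        tokens_a=a.segments.tokens,
        tokens_b=b.segments.tokens,
        shared=shared,
        sides=sides,
    )


# ---------------------------------------------------------------------------
# full colexifications


def full_colexifications(forms: Sequence[FormEntry]) -> list[ColexInstance]:
    """All pairs of same-language entries whose token sequences are identical
    while their concepts differ.

    Indexing is by the token sequence, so two forms that differ only in
    orthography but segment identically do colexify.
    """
    index: dict[tuple[str, ...], list[FormEntry]] = {}
    for entry in forms:
        index.setdefault(entry.segments.tokens, []).append(entry)
    instances = []
    for key in sorted(index):
        for a, b in combinations(index[key], 2):
            if a.concept_id != b.concept_id:
                instances.append(
                    _instance(a, b, key, ("whole", "whole"), directed=False)
                )
    return instances


# ---------------------------------------------------------------------------
# affix indexing


def enumerate_affixes(
    seq: SoundSequence | Sequence[str], cfg: InferenceConfig
) -> list[tuple[tuple[str, ...], Side]]:
    """Every admissible prefix and suffix of a token sequence.

    A prefix/suffix of length L from a sequence of n tokens is admissible
    iff ``L > cfg.affix_len_min`` and ``n - L > cfg.residue_len_min``; the
    full sequence itself is therefore never returned.
    """
    tokens = tuple(seq.tokens if isinstance(seq, SoundSequence) else seq)
    n = len(tokens)
    out: list[tuple[tuple[str, ...], Side]] = []
    lengths = range(cfg.affix_len_min + 1, n - cfg.residue_len_min)
    if cfg.sides in ("prefix", "both"):
        out.extend((tokens[:length], "prefix") for length in lengths)
    if cfg.sides in ("suffix", "both"):
        out.extend((tokens[n - length:], "suffix") for length in lengths)
    return out


def build_affix_index(
    forms: Sequence[FormEntry], cfg: InferenceConfig
) -> dict[tuple[str, ...], list[tuple[FormEntry, Side]]]:
    """Pass one: map every admissible affix to the forms exhibiting it."""
    index: dict[tuple[str, ...], list[tuple[FormEntry, Side]]] = {}
    for entry in sorted(forms, key=lambda e: e.entry_id):
        for affix, side in enumerate_affixes(entry.segments, cfg):
            index.setdefault(affix, []).append((entry, side))
    return index


# ---------------------------------------------------------------------------
# affix colexifications


def affix_colexifications(
    forms: Sequence[FormEntry], cfg: InferenceConfig = AFFIX_DEFAULTS
) -> list[ColexInstance]:
    """Directed affix colexifications within one language.

    Pass one indexes every admissible prefix/suffix of every form; pass two
    walks the original forms longest-first and, whenever a whole form occurs
    verbatim as an index key, links its concept to the concept of every
    indexed host form (the form the affix was cut from), one instance per
    (host, side) with a distinct concept.
    """
    index = build_affix_index(forms, cfg)
    instances = []
    for entry in sorted(
        forms, key=lambda e: (-len(e.segments), e.form, e.concept_id, e.entry_id)
    ):
        for host, side in index.get(entry.segments.tokens, ()):
            if host.concept_id != entry.concept_id:
                instances.append(
                    _instance(
                        entry, host, entry.segments.tokens, ("whole", side),
                        directed=True,
                    )
                )
    return instances


# ---------------------------------------------------------------------------
# overlap colexifications


def _is_part_of(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    """Proper peripheral part-of: ``short`` is a prefix or suffix of ``long``."""
    return len(short) < len(long) and (
        long[: len(short)] == short or long[len(long) - len(short):] == short
    )


def _part_of_either(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    return _is_part_of(a, b) or _is_part_of(b, a)


def _choose_sides(
    sides_a: Iterable[Side], sides_b: Iterable[Side], same_side_only: bool
) -> tuple[Side, Side] | None:
    """Deterministically pick the witnessed side pair for an overlap.

    Combinations are ranked prefix-before-suffix on each slot; under
    ``same_side_only`` only equal-side combinations qualify.
    """
    combos = sorted(
        (sa, sb)
        for sa in set(sides_a)
        for sb in set(sides_b)
        if not same_side_only or sa == sb
    )
    return combos[0] if combos else None


def overlap_colexifications(
    forms: Sequence[FormEntry], cfg: InferenceConfig = OVERLAP_DEFAULTS
) -> list[ColexInstance]:
    """Undirected overlap colexifications within one language.

    The affix index is walked longest-key-first (ties broken by token
    sequence), and each unordered pair of distinct-concept forms sharing a
    key is emitted exactly once, at its longest shared admissible substring,
    provided the forms are not identical and neither is a prefix or suffix
    of the other (those pairs belong to the full and affix relations
    respectively).
    """
    index = build_affix_index(forms, cfg)
    instances = []
    seen: set[tuple[str, str]] = set()
    for key in sorted(index, key=lambda k: (-len(k), k)):
        bucket: dict[str, tuple[FormEntry, set[Side]]] = {}
        for entry, side in index[key]:
            bucket.setdefault(entry.entry_id, (entry, set()))[1].add(side)
        for id_a, id_b in combinations(sorted(bucket), 2):
            a, sides_a = bucket[id_a]
            b, sides_b = bucket[id_b]
            if a.concept_id == b.concept_id:
                continue
            if a.segments.tokens == b.segments.tokens:
                continue
            if _part_of_either(a.segments.tokens, b.segments.tokens):
                continue
            pair = (id_a, id_b)
            if pair in seen:
                continue
            sides = _choose_sides(sides_a, sides_b, cfg.same_side_only)
            if sides is None:
                continue
            seen.add(pair)
            instances.append(_instance(a, b, key, sides, directed=False))
    return instances


# ---------------------------------------------------------------------------
# naive all-pairs oracle


def naive_partial_colexifications(
    forms: Sequence[FormEntry],
    cfg: InferenceConfig,
    kind: Kind,
) -> list[ColexInstance]:
    """Quadratic reference search applying the admissibility predicates
    directly to every pair of forms.

    Produces the same canonicalised instance set as the index-based methods;
    kept as a correctness oracle and for benchmarking, not for production
    use on large wordlists.
    """
    if kind == "affix":
        return _naive_affix(forms, cfg)
    if kind == "overlap":
        return _naive_overlap(forms, cfg)
    raise ConfigurationError(f"naive search supports affix/overlap, not {kind!r}")


def _naive_affix(
    forms: Sequence[FormEntry], cfg: InferenceConfig
) -> list[ColexInstance]:
    instances = []
    for a in forms:
        for b in forms:
            if a is b or a.concept_id == b.concept_id:
                continue
            ta, tb = a.segments.tokens, b.segments.tokens
            if len(ta) <= cfg.affix_len_min:
                continue
            if len(tb) - len(ta) <= cfg.residue_len_min:
                continue
            if cfg.sides in ("prefix", "both") and tb[: len(ta)] == ta:
                instances.append(
                    _instance(a, b, ta, ("whole", "prefix"), directed=True)
                )
            if cfg.sides in ("suffix", "both") and tb[len(tb) - len(ta):] == ta:
                instances.append(
                    _instance(a, b, ta, ("whole", "suffix"), directed=True)
                )
    return instances


def _naive_overlap(
    forms: Sequence[FormEntry], cfg: InferenceConfig
) -> list[ColexInstance]:
    instances = []
    ordered = sorted(forms, key=lambda e: e.entry_id)
    for a, b in combinations(ordered, 2):
        if a.concept_id == b.concept_id:
            continue
        ta, tb = a.segments.tokens, b.segments.tokens
        if ta == tb or _part_of_either(ta, tb):
            continue
        affixes_a: dict[tuple[str, ...], set[Side]] = {}
        for affix, side in enumerate_affixes(ta, cfg):
            affixes_a.setdefault(affix, set()).add(side)
        affixes_b: dict[tuple[str, ...], set[Side]] = {}
        for affix, side in enumerate_affixes(tb, cfg):
            affixes_b.setdefault(affix, set()).add(side)
        best: tuple[tuple[int, tuple[str, ...]], tuple[Side, Side]] | None = None
        for key in set(affixes_a) & set(affixes_b):
            sides = _choose_sides(affixes_a[key], affixes_b[key], cfg.same_side_only)
            if sides is None:
                continue
            rank = (-len(key), key)
            if best is None or rank < best[0]:
                best = (rank, sides)
        if best is not None:
            instances.append(_instance(a, b, best[0][1], best[1], directed=False))
    return instances


# ---------------------------------------------------------------------------
# cross-linguistic aggregation


@dataclass
class ColexNetwork:
    """An annotated colexification network over concepts.

    Nodes carry ``n_forms`` / ``n_languages`` / ``n_families`` counts and a
    per-language form listing; edges carry ``weight_forms`` (number of
    witnessing instances), ``weight_languages``, ``weight_families`` and the
    witness instances themselves.  Affix networks are directed; full and
    overlap networks are undirected.
    """

    kind: Kind
    graph: nx.Graph | nx.DiGraph
    config: InferenceConfig = field(default_factory=InferenceConfig)

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def concepts(self) -> list[str]:
        return sorted(self.graph.nodes)


def infer_language(
    forms: Sequence[FormEntry], kind: Kind, cfg: InferenceConfig | None = None
) -> list[ColexInstance]:
    """Run one language's inference for the requested network kind."""
    cfg = cfg or default_config(kind)
    if kind == "full":
        return full_colexifications(forms)
    if kind == "affix":
        return affix_colexifications(forms, cfg)
    if kind == "overlap":
        return overlap_colexifications(forms, cfg)
    raise ConfigurationError(f"unknown colexification kind: {kind!r}")


def build_network(
    wordlist: Wordlist, kind: Kind, cfg: InferenceConfig | None = None
) -> ColexNetwork:
    """Aggregate per-language colexifications into one annotated network.

    Every concept attested in the wordlist becomes a node, isolated or not.
    Instances for the same concept pair accumulate: ``weight_forms`` counts
    every witness, ``weight_languages`` and ``weight_families`` count the
    distinct languages and families among them, so
    ``weight_families <= weight_languages <= weight_forms`` holds on every
    edge.
    """
    if kind not in KINDS:
        raise ConfigurationError(f"unknown colexification kind: {kind!r}")
    cfg = cfg or default_config(kind)
    graph: nx.Graph | nx.DiGraph = nx.DiGraph() if kind == "affix" else nx.Graph()

    node_forms: dict[str, dict[str, list[str]]] = {}
    node_families: dict[str, set[str]] = {}
    for entry in wordlist.entries:
        node_forms.setdefault(entry.concept_id, {}).setdefault(
            entry.language_id, []
        ).append(entry.form)
        node_families.setdefault(entry.concept_id, set()).add(
            entry.family_or_language
        )
    for concept in sorted(node_forms):
        forms_by_language = {
            lang: sorted(node_forms[concept][lang])
            for lang in sorted(node_forms[concept])
        }
        graph.add_node(
            concept,
            n_forms=sum(len(v) for v in forms_by_language.values()),
            n_languages=len(forms_by_language),
            n_families=len(node_families[concept]),
            forms=forms_by_language,
        )

    edge_witnesses: dict[tuple[str, str], list[ColexInstance]] = {}
    for language, forms in wordlist.languages.items():
        for instance in infer_language(forms, kind, cfg):
            pair = (instance.concept_a, instance.concept_b)
            edge_witnesses.setdefault(pair, []).append(instance)

    for pair in sorted(edge_witnesses):
        witnesses = sorted(edge_witnesses[pair], key=ColexInstance.sort_key)
        graph.add_edge(
            *pair,
            weight_forms=len(witnesses),
            weight_languages=len({w.language_id for w in witnesses}),
            weight_families=len({w.family for w in witnesses}),
            witnesses=witnesses,
        )
    return ColexNetwork(kind=kind, graph=graph, config=cfg)
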