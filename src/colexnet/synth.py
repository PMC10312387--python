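"""Synthetic wordlists with planted, exactly known colexification structure.

The generator builds a cross-linguistic lexicon plan once and realises it
independently in every language:

* each *simple* concept is expressed by a single root;
* with probability ``full_colex_probability`` a simple concept reuses the
  root slot of an earlier simple concept, planting a full colexification;
* each *compound* concept (probability ``compound_probability``) is
  expressed as the concatenation of the roots of two distinct slots,
  planting directed affix colexifications from the member concepts and —
  whenever two compounds share a slot peripherally — an overlap
  colexification between them.

Within each language, roots are rejection-sampled so that two distinct
roots never stand in a part-of relation and never share a peripheral
substring of more than one token.  Compounding is plain concatenation (no
sandhi), so every relation that holds between the generated forms is
planted and every planted relation is realised with admissible lengths:
the planted sets *are* the inferable sets, which makes precision/recall
against :class:`GroundTruth` exact rather than probabilistic.

This emulates the combinatorial skeleton of real lexical data (roots,
transparent compounds, homophony) but none of its phonology: no sound
change, no cognate variation across languages, no grammatical affixes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import GenerationError
from .inference import ColexNetwork
from .wordlist import FormEntry, SoundSequence, Wordlist

#: ~20-sound default inventory; large enough that collision-free root
#: sampling succeeds comfortably for the default problem sizes.
DEFAULT_ALPHABET = (
    "p", "t", "k", "b", "d", "g", "m", "n", "ŋ", "s", "ʃ",
    "z", "l", "r", "w", "j", "a", "e", "i", "o", "u",
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic wordlist.

    Root lengths default to 5–7 tokens so that every planted relation
    clears the default admissibility thresholds of *all three* inference
    kinds (an affix word needs > 2 tokens with a remainder > 2; an overlap
    needs a shared part > 4 with remainders > 3).
    """

    n_languages: int = 5
    n_concepts: int = 30
    compound_probability: float = 0.4
    full_colex_probability: float = 0.1
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    root_length_range: tuple[int, int] = (5, 7)
    root_inventory_size: int | None = None
    n_families: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.compound_probability <= 1:
            raise ValueError("compound_probability must be in [0, 1]")
        if not 0 <= self.full_colex_probability <= 1:
            raise ValueError("full_colex_probability must be in [0, 1]")
        if self.root_length_range[0] < 5:
            raise ValueError(
                "root_length_range[0] must be >= 5 so planted relations "
                "clear the default thresholds of all three inference kinds"
            )
        if self.n_concepts < 2 or self.n_languages < 1:
            raise ValueError("need >= 2 concepts and >= 1 language")
        if len(self.alphabet) < 4:
            raise ValueError("alphabet too small")


@dataclass
class GroundTruth:
    """The planted concept-level relations of a synthetic wordlist."""

    planted_full: set[frozenset[str]] = field(default_factory=set)
    planted_affix: set[tuple[str, str]] = field(default_factory=set)
    planted_overlap: set[frozenset[str]] = field(default_factory=set)

    def planted(self, kind: str) -> set:
        return {
            "full": self.planted_full,
            "affix": self.planted_affix,
            "overlap": self.planted_overlap,
        }[kind]


def _shared_peripheral(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Longest peripheral substring shared by two token tuples."""
    best = 0
    for length in range(1, min(len(a), len(b)) + 1):
        ends_a = {a[:length], a[len(a) - length:]}
        ends_b = {b[:length], b[len(b) - length:]}
        if ends_a & ends_b:
            best = length
    return best


def _contains(inner: tuple[str, ...], outer: tuple[str, ...]) -> bool:
    """``inner`` occurs at any position of ``outer``."""
    n = len(inner)
    return any(outer[i : i + n] == inner for i in range(len(outer) - n + 1))


def _roots_compatible(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    """Two roots may coexist in one language.

    They must share no peripheral substring of more than one token (which
    covers common prefixes/suffixes and cross prefix/suffix overlaps) and
    neither may occur anywhere inside the other.  Under concatenative
    compounding these conditions rule out *every* accidental full, affix,
    or overlap relation between forms built from distinct root slots, so
    the planted relations are exactly the inferable ones.
    """
    return (
        _shared_peripheral(a, b) <= 1
        and not _contains(a, b)
        and not _contains(b, a)
    )


def _sample_root(
    rng: random.Random, spec: SynthSpec, existing: list[tuple[str, ...]]
) -> tuple[str, ...]:
    lo, hi = spec.root_length_range
    for _ in range(10000):
        root = tuple(rng.choice(spec.alphabet) for _ in range(rng.randint(lo, hi)))
        if all(_roots_compatible(root, other) for other in existing):
            return root
    raise GenerationError(
        "could not sample a collision-free root; enlarge the alphabet or "
        "reduce the root inventory"
    )


def _plan(rng: random.Random, spec: SynthSpec):
    """Global lexicon plan: concept -> root slot(s), plus ground truth."""
    concepts = [f"C{i:03d}" for i in range(spec.n_concepts)]
    slot_of: dict[str, int] = {}  # simple concept -> root slot
    compound_of: dict[str, tuple[int, int]] = {}  # compound concept -> slot pair
    n_slots = 0
    used_pairs: set[tuple[int, int]] = set()

    for concept in concepts:
        simple_so_far = list(slot_of)
        pair: tuple[int, int] | None = None
        if n_slots >= 2 and rng.random() < spec.compound_probability:
            # distinct ordered slot pairs keep compound forms pairwise distinct;
            # when all pairs are taken the concept falls back to a simple root
            free = [
                (i, j)
                for i in range(n_slots)
                for j in range(n_slots)
                if i != j and (i, j) not in used_pairs
            ]
            if free:
                pair = free[rng.randrange(len(free))]
        if pair is not None:
            used_pairs.add(pair)
            compound_of[concept] = pair
        elif simple_so_far and rng.random() < spec.full_colex_probability:
            slot_of[concept] = slot_of[rng.choice(simple_so_far)]
        else:
            if spec.root_inventory_size is not None and n_slots >= spec.root_inventory_size:
                raise GenerationError("root_inventory_size exhausted")
            slot_of[concept] = n_slots
            n_slots += 1

    truth = GroundTruth()
    slot_members: dict[int, list[str]] = {}
    for concept, slot in slot_of.items():
        slot_members.setdefault(slot, []).append(concept)
    for members in slot_members.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                truth.planted_full.add(frozenset((a, b)))
    for concept, (s1, s2) in compound_of.items():
        for member in slot_members[s1] + slot_members[s2]:
            truth.planted_affix.add((member, concept))
    compounds = sorted(compound_of)
    for i, a in enumerate(compounds):
        for b in compounds[i + 1:]:
            if set(compound_of[a]) & set(compound_of[b]):
                truth.planted_overlap.add(frozenset((a, b)))
    return concepts, slot_of, compound_of, n_slots, truth


def generate(spec: SynthSpec) -> tuple[Wordlist, GroundTruth]:
    """Generate a wordlist realising one lexicon plan in every language.

    Deterministic for a fixed ``spec.seed``.  Languages are assigned to
    ``spec.n_families`` families round-robin.
    """
    rng = random.Random(spec.seed)
    concepts, slot_of, compound_of, n_slots, truth = _plan(rng, spec)

    entries: list[FormEntry] = []
    for lang_index in range(spec.n_languages):
        language = f"L{lang_index:02d}"
        family = f"F{lang_index % max(1, spec.n_families):02d}"
        roots: list[tuple[str, ...]] = []
        for _ in range(n_slots):
            roots.append(_sample_root(rng, spec, roots))
        for c_index, concept in enumerate(concepts):
            if concept in compound_of:
                s1, s2 = compound_of[concept]
                tokens = roots[s1] + roots[s2]
            else:
                tokens = roots[slot_of[concept]]
            entries.append(
                FormEntry(
                    entry_id=f"{language}-{c_index:03d}",
                    language_id=language,
                    concept_id=concept,
                    form="".join(tokens),
                    segments=SoundSequence(tokens),
                    family=family,
                )
            )
    wordlist = Wordlist(entries, metadata={"source": "synthetic", "spec": spec})
    return wordlist, truth


def perturb(
    wordlist: Wordlist,
    homophony_rate: float,
    seed: int = 0,
    collision_len: int = 2,
) -> Wordlist:
    """Rewrite a fraction of forms to collide peripherally with others.

    Each selected entry has its first ``collision_len`` tokens replaced by
    the initial tokens of another randomly chosen form of the same
    language, planting accidental shared prefixes — the kind of noise the
    length thresholds exist to suppress.  ``homophony_rate`` 0 returns an
    equal wordlist.
    """
    if not 0 <= homophony_rate <= 1:
        raise ValueError("homophony_rate must be in [0, 1]")
    rng = random.Random(seed)
    new_entries: list[FormEntry] = []
    for language in sorted(wordlist.languages):
        forms = wordlist.language_forms(language)
        for entry in forms:
            if len(forms) > 1 and rng.random() < homophony_rate:
                donor = rng.choice([f for f in forms if f is not entry])
                stolen = donor.segments.tokens[:collision_len]
                rest = entry.segments.tokens[collision_len:]
                tokens = (stolen + rest) or stolen or donor.segments.tokens
                entry = FormEntry(
                    entry_id=entry.entry_id,
                    language_id=entry.language_id,
                    concept_id=entry.concept_id,
                    form="".join(tokens),
                    segments=SoundSequence(tokens),
                    family=entry.family,
                )
            new_entries.append(entry)
    return Wordlist(new_entries, metadata=dict(wordlist.metadata))


def recovery_scores(net: ColexNetwork, truth: GroundTruth) -> tuple[float, float]:
    """Precision and recall of a network's edges against the planted set.

    Directed edges are compared as ordered concept pairs (affix networks),
    undirected ones as unordered pairs.  An empty planted set with no
    inferred edges scores (1.0, 1.0).
    """
    planted = truth.planted(net.kind)
    if net.directed:
        inferred: set = set(net.graph.edges)
    else:
        inferred = {frozenset(edge) for edge in net.graph.edges}
    tp = len(inferred & planted)
    precision = tp / len(inferred) if inferred else 1.0
    recall = tp / len(planted) if planted else 1.0
    return precision, recall
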