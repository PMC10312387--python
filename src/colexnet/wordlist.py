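"""Reading, validation and normalisation of multilingual wordlists.

A *wordlist* is an onomasiological table: one row per word form, indexed by
the concept the form expresses and the language it belongs to.  Forms are
modelled as sequences of sound tokens (segments); partial-colexification
inference operates on those token sequences, never on raw orthography, so
every admitted row must yield a non-empty :class:`SoundSequence`.

Two tabular dialects are supported:

* ``cldf`` — a CLDF-Wordlist-style ``forms.csv`` (comma-separated, columns
  ``ID, Language_ID, Parameter_ID, Form, Segments``, segments
  space-separated);
* ``tsv`` — a plain tab-separated file with ``DOCULECT / CONCEPT / FORM /
  TOKENS`` columns (the common wordlist-TSV convention), remappable via
  ``column_map``.
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: Token inserted by annotators to mark morpheme boundaries inside a
#: segments string.  Boundary markers are not sounds; by default they are
#: stripped before inference so that affix-length thresholds count sounds.
BOUNDARY_MARKER = "+"

_CLDF_COLUMNS = {
    "id": "ID",
    "language": "Language_ID",
    "concept": "Parameter_ID",
    "form": "Form",
    "segments": "Segments",
    "family": "Family",
}
_TSV_COLUMNS = {
    "id": "ID",
    "language": "DOCULECT",
    "concept": "CONCEPT",
    "form": "FORM",
    "segments": "TOKENS",
    "family": "FAMILY",
}


@dataclass(frozen=True, order=True)
class SoundSequence:
    """An ordered, immutable sequence of sound tokens.

    Each token is one segment of a transcribed word form (``"ʃ"``, ``"uː"``,
    or a single orthographic character for toy data).  Tokens may never be
    empty or contain whitespace, because whitespace is the on-disk segment
    separator.
    """

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        for token in self.tokens:
            if not token or any(ch.isspace() for ch in token):
                raise ValueError(f"invalid sound token: {token!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __str__(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True, order=True)
class FormEntry:
    """One row of a wordlist: a form expressing one concept in one language."""

    entry_id: str
    language_id: str
    concept_id: str
    form: str
    segments: SoundSequence
    family: str = ""

    def __post_init__(self) -> None:
        if not self.language_id:
            raise ValueError("language_id must be non-empty")
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")

    @property
    def family_or_language(self) -> str:
        """The family, defaulting to the language itself when unannotated.

        With no family metadata every language counts as its own family,
        which keeps family-based edge weights well defined on toy data.
        """
        return self.family or self.language_id


class Wordlist:
    """A collection of form entries bucketed by language.

    Iteration over languages and over the entries within a language is
    deterministic (sorted by identifier), so that repeated runs over the
    same file build byte-identical networks.
    """

    def __init__(self, entries: Iterable[FormEntry], metadata: dict | None = None):
        self.entries: list[FormEntry] = sorted(
            entries, key=lambda e: (e.language_id, e.entry_id)
        )
        self.metadata: dict = dict(metadata or {})
        self._languages: dict[str, list[FormEntry]] = {}
        for entry in self.entries:
            self._languages.setdefault(entry.language_id, []).append(entry)

    @property
    def languages(self) -> dict[str, list[FormEntry]]:
        return {lang: list(self._languages[lang]) for lang in sorted(self._languages)}

    @property
    def concepts(self) -> list[str]:
        return sorted({e.concept_id for e in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Wordlist):
            return NotImplemented
        return self.entries == other.entries

    def language_forms(self, language_id: str) -> list[FormEntry]:
        """All entries of one language, sorted by entry id."""
        if language_id not in self._languages:
            raise KeyError(f"unknown language: {language_id!r}")
        return list(self._languages[language_id])


def _tokenize(
    form: str, segments_field: str, tokenizer: str, keep_boundaries: bool
) -> tuple[str, ...]:
    if tokenizer == "segments-column":
        tokens = tuple(segments_field.split())
    elif tokenizer == "whitespace":
        tokens = tuple(form.split())
    elif tokenizer == "character":
        tokens = tuple(ch for ch in form if not ch.isspace())
    else:
        raise ConfigurationError(f"unknown tokenizer: {tokenizer!r}")
    if not keep_boundaries:
        tokens = tuple(t for t in tokens if t != BOUNDARY_MARKER)
    return tokens


def read_wordlist(
    path: str | Path,
    dialect: str = "tsv",
    column_map: Mapping[str, str] | None = None,
    tokenizer: str = "segments-column",
    *,
    families: Mapping[str, str] | None = None,
    dedup: bool = True,
    lowercase: bool = False,
    keep_boundaries: bool = False,
) -> Wordlist:
    """Read a tabular wordlist into a :class:`Wordlist`.

    Parameters
    ----------
    path
        The forms table (CSV for ``dialect="cldf"``, TSV otherwise).
    dialect
        ``"cldf"`` or ``"tsv"``; selects delimiter and default column names.
    column_map
        Overrides for the logical column names ``id, language, concept,
        form, segments, family``.  Only ``language, concept, form`` are
        required to resolve; ``id`` falls back to the row number.
    tokenizer
        ``"segments-column"`` (split the segments column on whitespace; the
        default, matching pre-segmented phonetic data), ``"whitespace"``
        (split the form), or ``"character"`` (one token per character, for
        orthographic toy data).
    families
        Optional ``language_id -> family`` mapping; for CLDF input a
        ``languages.csv`` next to the forms table is consulted automatically.
    dedup
        Drop repeated ``(language, concept, form)`` rows (they add no
        evidence and would inflate edge weights).
    lowercase
        Lowercase forms and tokens; needed for orthographic data where
        e.g. a capitalised compound member should match its citation form.
    keep_boundaries
        Keep ``"+"`` morpheme-boundary tokens instead of stripping them.

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    EmptyInputError
        If no row yields an admissible entry.
    """
    path = Path(path)
    if dialect == "cldf":
        defaults, delimiter = _CLDF_COLUMNS, ","
    elif dialect == "tsv":
        defaults, delimiter = _TSV_COLUMNS, "\t"
    else:
        raise ConfigurationError(f"unknown dialect: {dialect!r}")
    columns = {**defaults, **(column_map or {})}

    family_map = dict(families or {})
    if dialect == "cldf" and not family_map:
        family_map = _read_cldf_families(path.parent / "languages.csv")

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: file has no header row")
        for logical in ("language", "concept", "form"):
            if columns[logical] not in reader.fieldnames:
                raise ConfigurationError(
                    f"{path}: required column {columns[logical]!r} "
                    f"(mapped from {logical!r}) not found"
                )
        if tokenizer == "segments-column" and columns["segments"] not in reader.fieldnames:
            raise ConfigurationError(
                f"{path}: tokenizer 'segments-column' needs column "
                f"{columns['segments']!r}"
            )

        entries: list[FormEntry] = []
        seen: set[tuple[str, str, str]] = set()
        dropped = 0
        for number, row in enumerate(reader, start=1):
            entry = _row_to_entry(
                row, number, columns, tokenizer, family_map,
                lowercase=lowercase, keep_boundaries=keep_boundaries,
            )
            if entry is None:
                dropped += 1
                continue
            if dedup:
                key = (entry.language_id, entry.concept_id, entry.form)
                if key in seen:
                    dropped += 1
                    continue
                seen.add(key)
            entries.append(entry)

    if not entries:
        raise EmptyInputError(f"{path}: no admissible rows")
    wordlist = Wordlist(
        entries,
        metadata={
            "source": str(path),
            "dialect": dialect,
            "columns": columns,
            "tokenizer": tokenizer,
            "dropped_rows": dropped,
        },
    )
    logger.info("%s: %d entries, %d dropped rows", path, len(wordlist), dropped)
    for language, forms in wordlist.languages.items():
        logger.info("  %s: %d entries", language, len(forms))
    return wordlist


def _row_to_entry(
    row: Mapping[str, str],
    number: int,
    columns: Mapping[str, str],
    tokenizer: str,
    family_map: Mapping[str, str],
    *,
    lowercase: bool,
    keep_boundaries: bool,
) -> FormEntry | None:
    norm = lambda s: unicodedata.normalize("NFC", (s or "").strip())
    form = norm(row.get(columns["form"], ""))
    language = norm(row.get(columns["language"], ""))
    concept = norm(row.get(columns["concept"], ""))
    if not form or not language or not concept:
        return None
    if lowercase:
        form = form.lower()
    segments_field = norm(row.get(columns["segments"], ""))
    if lowercase:
        segments_field = segments_field.lower()
    tokens = _tokenize(form, segments_field, tokenizer, keep_boundaries)
    if not tokens:
        return None
    entry_id = norm(row.get(columns["id"], "")) or str(number)
    family = family_map.get(language, norm(row.get(columns["family"], "")))
    return FormEntry(
        entry_id=entry_id,
        language_id=language,
        concept_id=concept,
        form=form,
        segments=SoundSequence(tokens),
        family=family,
    )


def _read_cldf_families(path: Path) -> dict[str, str]:
    if not path.exists():
        return {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if not reader.fieldnames or "ID" not in reader.fieldnames:
            return {}
        return {
            row["ID"]: row.get("Family", "") or ""
            for row in reader
            if row.get("ID")
        }


def write_wordlist(wordlist: Wordlist, path: str | Path) -> None:
    """Write a wordlist as TSV (``ID DOCULECT FAMILY CONCEPT FORM TOKENS``).

    Re-reading the file with ``dialect="tsv"`` and the default tokenizer
    reproduces the wordlist entry for entry.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["ID", "DOCULECT", "FAMILY", "CONCEPT", "FORM", "TOKENS"])
        for entry in wordlist.entries:
            writer.writerow(
                [
                    entry.entry_id,
                    entry.language_id,
                    entry.family,
                    entry.concept_id,
                    entry.form,
                    str(entry.segments),
                ]
            )


def language_forms(wordlist: Wordlist, language_id: str) -> list[FormEntry]:
    """Module-level alias for :meth:`Wordlist.language_forms`."""
    return wordlist.language_forms(language_id)
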