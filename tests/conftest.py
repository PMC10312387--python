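"""Shared fixtures: tiny hand-built wordlists with known colexifications."""

from __future__ import annotations

import pytest

from colexnet.wordlist import FormEntry, SoundSequence, Wordlist


def make_entry(
    entry_id: str,
    concept: str,
    form: str,
    language: str = "german",
    family: str = "",
    tokens: tuple[str, ...] | None = None,
) -> FormEntry:
    """A form entry with per-character segmentation unless tokens are given."""
    return FormEntry(
        entry_id=entry_id,
        language_id=language,
        concept_id=concept,
        form=form,
        segments=SoundSequence(tokens if tokens is not None else tuple(form)),
        family=family,
    )


@pytest.fixture
def glove_forms():
    """hand/HAND, schuh/SHOE, handschuh/GLOVE: two planted affix relations."""
    return [
        make_entry("1", "HAND", "hand"),
        make_entry("2", "SHOE", "schuh"),
        make_entry("3", "GLOVE", "handschuh"),
    ]


@pytest.fixture
def earth_forms():
    """Erde/EARTH, Erde/WORLD, Welt/WORLD: one planted full colexification."""
    return [
        make_entry("1", "EARTH", "erde"),
        make_entry("2", "WORLD", "erde"),
        make_entry("3", "WORLD", "welt"),
    ]


@pytest.fixture
def glove_wordlist(glove_forms):
    return Wordlist(glove_forms)


@pytest.fixture
def earth_wordlist(earth_forms):
    return Wordlist(earth_forms)
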