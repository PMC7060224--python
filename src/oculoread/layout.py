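"""Text-line layouts and the experimental letter/word transformations.

A trial is a single line of text (at most 85 character columns, one space
between words).  Five display conditions are supported:

``N``
    normal text (control).
``mL``
    every letter glyph mirrored about its vertical axis; letter order kept.
``mW``
    the whole word mirrored: letter order reversed *and* every glyph mirrored.
``iW``
    letter order reversed, glyphs upright (mimics the letter positions of
    ``mW`` without mirroring).
``sL``
    interior letters scrambled; the first and last letter keep their
    positions, so words shorter than four letters are unchanged.

Glyph mirroring is carried as a boolean flag per letter — the downstream
analyses depend only on letter order and column positions, never on rendered
glyphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "MAX_LINE_CHARS",
    "LayoutWord",
    "TrialLayout",
    "LayoutError",
    "transform_word",
    "build_trial_layout",
    "word_center",
]

CONDITIONS = ("N", "mL", "mW", "iW", "sL")

#: Maximum number of character columns on one displayed line.
MAX_LINE_CHARS = 85


class LayoutError(ValueError):
    """A trial line cannot be laid out (e.g. it overflows the display)."""


def word_center(length: int) -> float:
    """Center of a word on the 1-based letter scale, ``(length + 1) / 2``.

    Fractional for even lengths: a 4-letter word has its center at 2.5.
    """
    if length < 1:
        raise ValueError(f"word length must be >= 1, got {length}")
    return (length + 1) / 2


@dataclass(frozen=True)
class LayoutWord:
    """One word on the display line after the condition transformation.

    ``display_order[i]`` gives the 1-based index of the base letter shown at
    on-screen letter slot ``i + 1``; ``glyph_mirrored[i]`` says whether that
    glyph is reflected about its vertical axis.
    """

    word_index: int
    base_letters: str
    display_order: tuple[int, ...]
    glyph_mirrored: tuple[bool, ...]
    condition: str
    first_char_col: int = 1

    def __post_init__(self) -> None:
        n = len(self.base_letters)
        if n == 0:
            raise ValueError("empty letter sequence")
        if sorted(self.display_order) != list(range(1, n + 1)):
            raise ValueError("display_order is not a permutation of 1..len")
        if len(self.glyph_mirrored) != n:
            raise ValueError("glyph_mirrored length mismatch")

    @property
    def length(self) -> int:
        return len(self.base_letters)

    @property
    def last_char_col(self) -> int:
        return self.first_char_col + self.length - 1

    @property
    def center_col(self) -> float:
        """Column of the word center, ``first_char_col + (len - 1) / 2``."""
        return self.first_char_col + (word_center(self.length) - 1)

    @property
    def displayed_letters(self) -> str:
        """Letter sequence as shown on screen (ignoring glyph mirroring)."""
        return "".join(self.base_letters[i - 1] for i in self.display_order)


def _scramble_interior(
    n: int, rng: np.random.Generator, exclude_identity: bool
) -> tuple[int, ...]:
    # positions 1 and n are fixed points; interior permuted uniformly
    interior = np.arange(2, n)
    if len(interior) < 2:
        return tuple(range(1, n + 1))
    while True:
        perm = rng.permutation(interior)
        if not exclude_identity or not np.array_equal(perm, interior):
            break
    return (1, *map(int, perm), n)


def transform_word(
    letters: str,
    condition: str,
    rng: Optional[np.random.Generator] = None,
    *,
    word_index: int = 0,
    first_char_col: int = 1,
    exclude_identity_scramble: bool = False,
) -> LayoutWord:
    """Apply a display condition to a word.

    Parameters
    ----------
    letters
        The canonical (readable) letter sequence; must be non-empty.
    condition
        One of ``N``, ``mL``, ``mW``, ``iW``, ``sL``.
    rng
        Required for ``sL`` only (the scramble is drawn from it).
    exclude_identity_scramble
        If True, ``sL`` redraws until the interior permutation is not the
        identity (when a non-identity permutation exists).  Off by default:
        a scramble that happens to reproduce the original order is a valid
        draw.
    """
    if not letters:
        raise ValueError("empty letter sequence")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    n = len(letters)
    identity = tuple(range(1, n + 1))
    reversed_ = tuple(range(n, 0, -1))
    if condition == "N":
        order, mirrored = identity, (False,) * n
    elif condition == "mL":
        order, mirrored = identity, (True,) * n
    elif condition == "mW":
        order, mirrored = reversed_, (True,) * n
    elif condition == "iW":
        order, mirrored = reversed_, (False,) * n
    else:  # sL
        if n >= 4:
            if rng is None:
                raise ValueError("condition 'sL' requires a random generator")
            order = _scramble_interior(n, rng, exclude_identity_scramble)
        else:
            order = identity
        mirrored = (False,) * n
    return LayoutWord(
        word_index=word_index,
        base_letters=letters,
        display_order=order,
        glyph_mirrored=mirrored,
        condition=condition,
        first_char_col=first_char_col,
    )


@dataclass(frozen=True)
class TrialLayout:
    """A laid-out trial line: words separated by single spaces, <= 85 columns."""

    trial_id: int
    words: tuple[LayoutWord, ...]
    line_length_chars: int

    def locate(self, col: float) -> Optional[tuple[int, int]]:
        """Map a (possibly fractional) column to ``(word_index, letter_index)``.

        Letter cell *i* of a word covers columns ``[col_i - 0.5, col_i + 0.5)``.
        Returns None for space columns; columns off the line are the caller's
        concern (see :func:`oculoread.preprocess.assign_words`).
        """
        c = int(np.floor(col + 0.5))
        for w in self.words:
            if w.first_char_col <= c <= w.last_char_col:
                return w.word_index, c - w.first_char_col + 1
        return None

    @property
    def n_words(self) -> int:
        return len(self.words)


def build_trial_layout(
    words: Sequence[str],
    condition: str,
    rng: Optional[np.random.Generator] = None,
    *,
    trial_id: int = 0,
    exclude_identity_scramble: bool = False,
) -> TrialLayout:
    """Lay a word list out on one line and apply the condition transformation.

    Words are placed left to right with exactly one space column between
    them; overflowing :data:`MAX_LINE_CHARS` raises :class:`LayoutError`
    naming the offending word.
    """
    if not words:
        raise ValueError("empty word list")
    placed: list[LayoutWord] = []
    col = 1
    for i, letters in enumerate(words, start=1):
        if col + len(letters) - 1 > MAX_LINE_CHARS:
            raise LayoutError(
                f"word {i} ({letters!r}) overflows the {MAX_LINE_CHARS}-column line"
            )
        placed.append(
            transform_word(
                letters,
                condition,
                rng,
                word_index=i,
                first_char_col=col,
                exclude_identity_scramble=exclude_identity_scramble,
            )
        )
        col += len(letters) + 1
    return TrialLayout(
        trial_id=trial_id, words=tuple(placed), line_length_chars=col - 2
    )
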