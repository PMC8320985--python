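"""Core domain model for constrained DNA codeword sets.

A codeword is a fixed-length string over {A, C, G, T}.  Validity of a single
word is governed by a :class:`ConstraintProfile`: an exact GC weight (number
of G/C symbols) and, optionally, the no-runlength rule forbidding identical
adjacent bases.  A *code* is a set of valid words whose pairwise Hamming
distances all reach the profile's minimum distance ``d``.

Bases carry a canonical quaternary digit form (T=0, C=1, G=2, A=3); all
canonical ordering in this package is lexicographic on those digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BASE_TO_DIGIT",
    "DIGIT_TO_BASE",
    "GC_DIGITS",
    "AT_DIGITS",
    "Codeword",
    "ConstraintProfile",
    "CodeSet",
    "InfeasibleProfileError",
    "hamming_distance",
    "gc_count",
    "gc_content",
    "has_no_runlength",
    "is_valid_codeword",
    "min_pairwise_distance",
    "is_valid_code",
    "fitness",
    "coding_rate",
]

#: Canonical base <-> digit mapping.
BASE_TO_DIGIT: dict[str, int] = {"T": 0, "C": 1, "G": 2, "A": 3}
DIGIT_TO_BASE: str = "TCGA"

#: Digits encoding G/C (the "GC class") and A/T.
GC_DIGITS: frozenset[int] = frozenset({1, 2})
AT_DIGITS: frozenset[int] = frozenset({0, 3})


class InfeasibleProfileError(ValueError):
    """Raised when no codeword can satisfy the requested constraints."""


@total_ordering
class Codeword:
    """An immutable DNA word with its canonical digit representation.

    Accepts lowercase input but stores uppercase; any symbol outside
    {A, C, G, T} is rejected (no coercion of N, U or gap characters).
    Ordering is lexicographic on digits, i.e. T < C < G < A.
    """

    __slots__ = ("_bases", "_digits")

    def __init__(self, bases: str) -> None:
        up = str(bases).upper()
        if not up:
            raise ValueError("codeword must be non-empty")
        try:
            digits = tuple(BASE_TO_DIGIT[b] for b in up)
        except KeyError as exc:
            raise ValueError(
                f"invalid symbol {exc.args[0]!r} in codeword {bases!r}; "
                "only A, C, G, T are accepted"
            ) from None
        self._bases = up
        self._digits = digits

    @classmethod
    def from_digits(cls, digits: Iterable[int]) -> "Codeword":
        """Build a word from quaternary digits (T=0, C=1, G=2, A=3)."""
        ds = tuple(int(d) for d in digits)
        if any(d not in (0, 1, 2, 3) for d in ds):
            raise ValueError(f"digits must lie in 0..3, got {ds}")
        return cls("".join(DIGIT_TO_BASE[d] for d in ds))

    @property
    def bases(self) -> str:
        return self._bases

    @property
    def digits(self) -> tuple[int, ...]:
        return self._digits

    def digits_array(self) -> np.ndarray:
        return np.array(self._digits, dtype=np.int8)

    def __len__(self) -> int:
        return len(self._bases)

    def __iter__(self) -> Iterator[str]:
        return iter(self._bases)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Codeword):
            return self._bases == other._bases
        return NotImplemented

    def __lt__(self, other: "Codeword") -> bool:
        if not isinstance(other, Codeword):
            return NotImplemented
        return self._digits < other._digits

    def __hash__(self) -> int:
        return hash(self._bases)

    def __str__(self) -> str:
        return self._bases

    def __repr__(self) -> str:
        return f"Codeword({self._bases!r})"


def _as_codeword(x: "Codeword | str") -> Codeword:
    return x if isinstance(x, Codeword) else Codeword(x)


@dataclass(frozen=True)
class ConstraintProfile:
    """The validity contract (n, d, w, nrl) for a code.

    Parameters
    ----------
    n : codeword length.
    d : minimum Hamming distance required between every unordered pair.
    w : exact GC weight |G| + |C| per word; defaults to ``n // 2``.
    nrl : enforce the no-runlength rule (no identical adjacent bases).
    """

    n: int
    d: int
    w: int = -1  # sentinel; replaced by n // 2 in __post_init__
    nrl: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"codeword length n must be >= 1, got {self.n}")
        if not 1 <= self.d <= self.n:
            raise ValueError(f"distance d must satisfy 1 <= d <= n={self.n}, got {self.d}")
        if self.w == -1:
            object.__setattr__(self, "w", self.n // 2)
        if not 0 <= self.w <= self.n:
            raise ValueError(f"GC weight w must satisfy 0 <= w <= n={self.n}, got {self.w}")

    def check_length(self, word: Codeword) -> None:
        if len(word) != self.n:
            raise ValueError(
                f"codeword length {len(word)} does not match profile length {self.n}"
            )


def hamming_distance(a: "Codeword | str", b: "Codeword | str") -> int:
    """Number of positions at which two equal-length words differ."""
    a, b = _as_codeword(a), _as_codeword(b)
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch: {len(a)} vs {len(b)} ({a.bases!r}, {b.bases!r})"
        )
    return sum(x != y for x, y in zip(a.bases, b.bases))


def gc_count(a: "Codeword | str") -> int:
    """Count of G and C symbols."""
    a = _as_codeword(a)
    return sum(b in "GC" for b in a.bases)


def gc_content(a: "Codeword | str") -> float:
    """GC fraction in [0, 1], derived from the exact count."""
    a = _as_codeword(a)
    return gc_count(a) / len(a)


def has_no_runlength(a: "Codeword | str") -> bool:
    """True iff no two adjacent bases are identical."""
    a = _as_codeword(a)
    s = a.bases
    return all(s[i] != s[i + 1] for i in range(len(s) - 1))


def is_valid_codeword(a: "Codeword | str", profile: ConstraintProfile) -> bool:
    """Per-word validity: exact GC weight and (if enabled) no-runlength."""
    a = _as_codeword(a)
    profile.check_length(a)
    if gc_count(a) != profile.w:
        return False
    if profile.nrl and not has_no_runlength(a):
        return False
    return True


def min_pairwise_distance(words: Sequence["Codeword | str"]) -> int | None:
    """Minimum Hamming distance over all unordered pairs.

    Returns ``None`` (the "no pairs" sentinel) when fewer than two words are
    given; callers must handle the degenerate case explicitly.
    """
    ws = [_as_codeword(w) for w in words]
    if len(ws) < 2:
        return None
    lengths = {len(w) for w in ws}
    if len(lengths) > 1:
        raise ValueError(f"mixed codeword lengths: {sorted(lengths)}")
    mat = np.array([w.digits for w in ws], dtype=np.int8)
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=-1)
    iu = np.triu_indices(len(ws), k=1)
    return int(diff[iu].min())


def fitness(s: "Codeword | str", members: Sequence["Codeword | str"]) -> int:
    """Sum of Hamming distances from ``s`` to every member; 0 for an empty set."""
    s = _as_codeword(s)
    total = 0
    for m in members:
        total += hamming_distance(s, m)
    return total


def coding_rate(M: int, n: int) -> float:
    """Information rate log4(M) / n of a code with M words of length n."""
    if M < 1:
        raise ValueError(f"code size M must be >= 1, got {M}")
    if n < 1:
        raise ValueError(f"word length n must be >= 1, got {n}")
    return math.log(M, 4) / n


@dataclass
class CodeSet:
    """An ordered collection of distinct codewords under one profile."""

    profile: ConstraintProfile
    members: list[Codeword] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = [_as_codeword(m) for m in self.members]
        seen: set[str] = set()
        dedup: list[Codeword] = []
        for m in self.members:
            self.profile.check_length(m)
            if m.bases not in seen:
                seen.add(m.bases)
                dedup.append(m)
        self.members = dedup

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Codeword]:
        return iter(self.members)

    def __contains__(self, word: "Codeword | str") -> bool:
        return _as_codeword(word) in set(self.members)

    def add(self, word: "Codeword | str") -> bool:
        """Append a word if not already present; returns True if added."""
        word = _as_codeword(word)
        self.profile.check_length(word)
        if word in set(self.members):
            return False
        self.members.append(word)
        return True

    def canonical_sorted(self) -> "CodeSet":
        """Copy with members in canonical (digit-lexicographic) order."""
        return CodeSet(self.profile, sorted(self.members))

    def min_pairwise_distance(self) -> int | None:
        return min_pairwise_distance(self.members)

    def is_valid_code(self) -> bool:
        """All members individually valid and every pair at distance >= d.

        Vacuously true for sets of size 0 or 1 (with valid members).
        """
        if not all(is_valid_codeword(m, self.profile) for m in self.members):
            return False
        mpd = self.min_pairwise_distance()
        return mpd is None or mpd >= self.profile.d

    def coding_rate(self) -> float:
        if not self.members:
            raise ValueError("coding rate undefined for an empty code")
        return coding_rate(len(self.members), self.profile.n)

    def digits_matrix(self) -> np.ndarray:
        """Members as an (|S|, n) int8 digit matrix."""
        if not self.members:
            return np.empty((0, self.profile.n), dtype=np.int8)
        return np.array([m.digits for m in self.members], dtype=np.int8)


def is_valid_code(code: CodeSet) -> bool:
    """Functional alias for :meth:`CodeSet.is_valid_code`."""
    return code.is_valid_code()
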