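"""Embedded reference data.

``REFERENCE_WORDS_N9_D6`` is a published example of a 26-word code of length
9 with minimum pairwise distance 6, GC weight 4 and no homopolymers; it is
used as a validation fixture.  The lower-bound tables give published sizes
of codes with w = n // 2 under the no-runlength rule, for the EORS heuristic
and for the altruistic greedy-deletion algorithm it was compared against.
"""

from __future__ import annotations

from .core import CodeSet, ConstraintProfile

__all__ = [
    "REFERENCE_WORDS_N9_D6",
    "REFERENCE_PROFILE_N9_D6",
    "load_reference_code",
    "EORS_LOWER_BOUNDS",
    "ALTRUISTIC_LOWER_BOUNDS",
]

REFERENCE_WORDS_N9_D6: tuple[str, ...] = (
    "ATCTGCTCA", "ATCGAGATG",
    "GTAGTCGAT", "TATCGTAGC",
    "TAGCTAGCT", "TGTCAGCTA",
    "GACTATCGA", "AGTACGTAC",
    "ACACAGTCT", "CATATGACG",
    "GATGTACTC", "GATCACTAG",
    "TAGACTCTG", "TCGTCATGA",
    "AGAGCAGTA", "ATGATGCGA",
    "CTATGACGT", "AGATACAGC",
    "TCACTCATG", "TGCATCTGT",
    "TCTAGAGAG", "GTATCTACG",
    "CACGCATAT", "TCAGATCAC",
    "CTGTATGTC", "CGCAGTATA",
)

REFERENCE_PROFILE_N9_D6 = ConstraintProfile(n=9, d=6, w=4, nrl=True)


def load_reference_code() -> CodeSet:
    """The embedded 26-word reference code with profile (9, 6, 4, nrl)."""
    return CodeSet(REFERENCE_PROFILE_N9_D6, list(REFERENCE_WORDS_N9_D6))


#: Published lower bounds on the maximum code size, keyed by (n, d).
EORS_LOWER_BOUNDS: dict[tuple[int, int], int] = {
    (4, 3): 12,
    (5, 3): 20, (5, 4): 8,
    (6, 3): 55, (6, 4): 21, (6, 5): 8,
    (7, 3): 125, (7, 4): 46, (7, 5): 16, (7, 6): 6,
    (8, 3): 364, (8, 4): 110, (8, 5): 38, (8, 6): 15, (8, 7): 5, (8, 8): 4,
    (9, 3): 737, (9, 4): 226, (9, 5): 71, (9, 6): 26, (9, 7): 11, (9, 8): 5,
    (9, 9): 4,
    (10, 3): 1856, (10, 4): 546, (10, 5): 153, (10, 6): 53, (10, 7): 22,
    (10, 8): 9, (10, 9): 5,
}

ALTRUISTIC_LOWER_BOUNDS: dict[tuple[int, int], int] = {
    (4, 3): 11,
    (5, 3): 17, (5, 4): 7,
    (6, 3): 44, (6, 4): 16, (6, 5): 6,
    (7, 3): 110, (7, 4): 36, (7, 5): 11, (7, 6): 4,
    (8, 3): 289, (8, 4): 86, (8, 5): 29, (8, 6): 9, (8, 7): 4, (8, 8): 4,
    (9, 3): 662, (9, 4): 199, (9, 5): 59, (9, 6): 15, (9, 7): 8, (9, 8): 4,
    (9, 9): 4,
    (10, 3): 1810, (10, 4): 525, (10, 5): 141, (10, 6): 43, (10, 7): 7,
    (10, 8): 5, (10, 9): 4,
}
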