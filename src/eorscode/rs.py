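"""Random-search augmentation of a code set.

Draws random per-word-valid candidates and tests each against the current
set: a candidate conflicting with nobody is inserted; a candidate whose only
conflict is a single member replaces that member (a size-neutral swap that
reshuffles the set out of local optima); anything else is discarded.  The
set therefore never shrinks and stays a valid code after every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CodeSet,
    Codeword,
    ConstraintProfile,
    hamming_distance,
)

__all__ = ["RSParams", "sample_valid_codeword", "conflicts", "rs_augment"]

_GC = np.array([1, 2], dtype=np.int8)
_AT = np.array([0, 3], dtype=np.int8)


@dataclass(frozen=True)
class RSParams:
    """budget: total candidate draws; batch: draws per round; seed: RNG seed."""

    budget: int = 100_000
    batch: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")


def _sample_digits(profile: ConstraintProfile, rng: np.random.Generator) -> np.ndarray:
    """One uniform draw from the valid-word stratum.

    GC positions are placed uniformly among the C(n, w) patterns, letters
    are assigned uniformly within each class, and draws violating the
    no-runlength rule are rejected and redrawn.
    """
    n, w = profile.n, profile.w
    while True:
        digits = _AT[rng.integers(0, 2, size=n)]
        if w:
            pos = rng.choice(n, size=w, replace=False)
            digits[pos] = _GC[rng.integers(0, 2, size=w)]
        if not profile.nrl or n == 1 or (digits[1:] != digits[:-1]).all():
            return digits


def sample_valid_codeword(
    profile: ConstraintProfile, rng: np.random.Generator
) -> Codeword:
    """A random codeword satisfying the GC-weight and no-runlength rules."""
    return Codeword.from_digits(_sample_digits(profile, rng))


def conflicts(s: Codeword | str, code: CodeSet) -> list[Codeword]:
    """Members of the set at Hamming distance < d from ``s``.

    An empty result means ``s`` can be inserted; a member equal to ``s``
    conflicts with it (distance 0), so duplicates are never insertable.
    """
    if not isinstance(s, Codeword):
        s = Codeword(s)
    code.profile.check_length(s)
    return [m for m in code.members if hamming_distance(s, m) < code.profile.d]


def rs_augment(
    start: CodeSet,
    profile: ConstraintProfile,
    params: RSParams,
    rng: np.random.Generator | None = None,
    observer=None,
) -> CodeSet:
    """Expand a valid code set by random candidate draws with the swap rule.

    ``observer``, if given, is called with the working CodeSet after every
    mutation (used by tests to assert validity of intermediate states).
    Returns a new CodeSet at least as large as the input.
    """
    if not start.is_valid_code():
        raise ValueError("input set is not a valid code under its profile")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    d = profile.d
    code = CodeSet(profile, list(start.members))
    matrix = code.digits_matrix()

    drawn = 0
    while drawn < params.budget:
        batch = min(params.batch, params.budget - drawn)
        for _ in range(batch):
            digits = _sample_digits(profile, rng)
            if matrix.shape[0] == 0:
                idx = np.empty(0, dtype=int)
            else:
                dist = (matrix != digits).sum(axis=1)
                idx = np.nonzero(dist < d)[0]
            if idx.size == 0:
                code.members.append(Codeword.from_digits(digits))
                matrix = np.vstack([matrix, digits[None, :]])
            elif idx.size == 1:
                i = int(idx[0])
                code.members[i] = Codeword.from_digits(digits)
                matrix[i] = digits
            else:
                continue
            if observer is not None:
                observer(code)
        drawn += batch
    return code
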