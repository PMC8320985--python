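"""Equilibrium-optimizer stage.

Particles are real "concentration" vectors in [0, 3]^n.  Each vector decodes
to a DNA word by rounding every coordinate to the nearest quaternary digit
and applying a deterministic repair that restores the no-runlength rule and
the exact GC weight.  Particles relax toward an equilibrium pool holding the
four highest-fitness particles plus their coordinate-wise mean; fitness of a
particle is the sum of Hamming distances from its decoded word to the
current code set, so high-fitness particles are the ones far from everything
already accepted.  After every sweep each decoded word that is compatible
with the whole set is inserted, so the set only ever grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AT_DIGITS,
    GC_DIGITS,
    CodeSet,
    Codeword,
    ConstraintProfile,
)

__all__ = [
    "C_MIN",
    "C_MAX",
    "EOParams",
    "Particle",
    "EquilibriumPool",
    "initialize_population",
    "time_parameter",
    "exponential_term",
    "generation_rate",
    "update_concentration",
    "decode_particle",
    "eo_search",
]

C_MIN, C_MAX = 0.0, 3.0

# lower bound for lambda draws: keeps R / (lambda * V) finite
_LAMBDA_EPS = 1e-12


@dataclass(frozen=True)
class EOParams:
    """Optimizer settings (defaults follow the standard EO parameterization)."""

    pop_size: int = 50
    t_max: int = 1000
    a1: float = 2.0
    a2: float = 1.0
    rp: float = 0.5
    v: float = 1.0
    seed: int | None = None
    early_stop: int | None = None  # stop after this many sweeps without insertion

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if not 0.0 <= self.rp <= 1.0:
            raise ValueError("rp must lie in [0, 1]")
        if self.a1 <= 0 or self.a2 <= 0 or self.v <= 0:
            raise ValueError("a1, a2 and v must be positive")


@dataclass
class Particle:
    concentration: np.ndarray
    decoded: Codeword
    fitness_value: int = 0


@dataclass
class EquilibriumPool:
    """Four best particles (by fitness) plus their coordinate-wise mean."""

    best4: list[np.ndarray]
    avg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.avg = np.mean(np.stack(self.best4), axis=0)

    @property
    def candidates(self) -> list[np.ndarray]:
        return [*self.best4, self.avg]

    @classmethod
    def from_particles(cls, particles: Sequence[Particle]) -> "EquilibriumPool":
        order = sorted(
            range(len(particles)),
            key=lambda i: (-particles[i].fitness_value, i),
        )
        top = order[: min(4, len(order))]
        # degenerate small populations repeat the best particle
        while len(top) < 4:
            top.append(top[0])
        return cls([particles[i].concentration.copy() for i in top])


def initialize_population(
    params: EOParams,
    profile: ConstraintProfile,
    rng: np.random.Generator | None = None,
) -> list[Particle]:
    """Uniform random particles: c = c_min + (c_max - c_min) * r, r ~ U[0,1]."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    particles = []
    for _ in range(params.pop_size):
        r = rng.uniform(0.0, 1.0, size=profile.n)
        conc = C_MIN + (C_MAX - C_MIN) * r
        particles.append(Particle(conc, decode_particle(conc, profile)))
    return particles


def time_parameter(iteration: int, params: EOParams) -> float:
    """t = (1 - iter/t_max)^(a2 * iter/t_max), decreasing from 1 to 0."""
    if params.t_max == 0:
        return 1.0
    frac = iteration / params.t_max
    return (1.0 - frac) ** (params.a2 * frac)


def exponential_term(
    lam: np.ndarray, t: float, params: EOParams, r: np.ndarray
) -> np.ndarray:
    """Exploration/exploitation balance term F = a1 sign(r - 0.5) (e^{-lam t} - 1)."""
    return params.a1 * np.sign(r - 0.5) * (np.exp(-lam * t) - 1.0)


def generation_rate(
    lam: np.ndarray,
    c: np.ndarray,
    c_eq: np.ndarray,
    F: np.ndarray,
    r1: float,
    r2: float,
    params: EOParams,
) -> np.ndarray:
    """Production-rate term R = RCP * (c_eq - lam*c) * F, gated by r2 vs RP."""
    rcp = 0.5 * r1 if r2 > params.rp else 0.0
    return rcp * (c_eq - lam * c) * F


def update_concentration(
    particle: Particle,
    pool: EquilibriumPool,
    iteration: int,
    params: EOParams,
    rng: np.random.Generator,
    profile: ConstraintProfile,
) -> Particle:
    """One EO update of a particle's concentration, clamped to [0, 3].

    Draw order (pool pick, lambda, r, r1, r2) is fixed so runs are
    reproducible from the seed alone.
    """
    c = particle.concentration
    c_eq = pool.candidates[int(rng.integers(0, 5))]
    lam = rng.uniform(_LAMBDA_EPS, 1.0, size=c.shape)
    r = rng.uniform(0.0, 1.0, size=c.shape)
    r1 = float(rng.uniform())
    r2 = float(rng.uniform())
    t = time_parameter(iteration, params)
    F = exponential_term(lam, t, params, r)
    R = generation_rate(lam, c, c_eq, F, r1, r2, params)
    new_c = c_eq + (c - c_eq) * F + (R / (lam * params.v)) * (1.0 - F)
    new_c = np.clip(new_c, C_MIN, C_MAX)
    return Particle(new_c, decode_particle(new_c, profile))


# ---------------------------------------------------------------------------
# continuous -> discrete decoding with deterministic repair


def _repair_runlength(digits: np.ndarray, conc: np.ndarray) -> None:
    """Left-to-right scan replacing any digit equal to its predecessor.

    The replacement is the digit (different from both neighbours) closest to
    the original continuous coordinate, ties toward the smaller digit.
    Excluding the right neighbour too means a single pass suffices.
    """
    n = len(digits)
    for i in range(1, n):
        if digits[i] != digits[i - 1]:
            continue
        banned = {int(digits[i - 1])}
        if i + 1 < n:
            banned.add(int(digits[i + 1]))
        allowed = [d for d in range(4) if d not in banned]
        digits[i] = min(allowed, key=lambda d: (abs(d - conc[i]), d))


def _boundary_distance(x: float) -> float:
    # distance from a coordinate to the nearest AT/GC class boundary (0.5, 2.5)
    return min(abs(x - 0.5), abs(x - 2.5))


def _repair_gc_weight(
    digits: np.ndarray, conc: np.ndarray, profile: ConstraintProfile
) -> None:
    """Flip positions between the AT and GC digit classes until the count is w.

    Each step flips the position closest to a class boundary, choosing the
    target-class digit nearest the coordinate and respecting the no-runlength
    rule when enabled.  Every accepted flip moves the count by one, so at
    most n steps run.
    """
    n = len(digits)
    for _ in range(n + 1):
        count = int(np.isin(digits, list(GC_DIGITS)).sum())
        if count == profile.w:
            return
        source = GC_DIGITS if count > profile.w else AT_DIGITS
        target = AT_DIGITS if count > profile.w else GC_DIGITS
        positions = sorted(
            (i for i in range(n) if digits[i] in source),
            key=lambda i: (_boundary_distance(conc[i]), i),
        )
        flipped = False
        for i in positions:
            for d in sorted(target, key=lambda d: (abs(d - conc[i]), d)):
                if profile.nrl:
                    if i > 0 and d == digits[i - 1]:
                        continue
                    if i + 1 < n and d == digits[i + 1]:
                        continue
                digits[i] = d
                flipped = True
                break
            if flipped:
                break
        if not flipped:
            # no single-position flip is legal; rebuild greedily
            digits[:] = _greedy_nearest_valid(conc, profile)
            return


def _greedy_nearest_valid(conc: np.ndarray, profile: ConstraintProfile) -> np.ndarray:
    """Deterministic fallback: build a valid word left to right, choosing at
    each position the feasible digit nearest the coordinate."""
    n = profile.n
    out = np.zeros(n, dtype=np.int8)
    gc_used = 0
    for i in range(n):
        remaining = n - 1 - i
        feasible = []
        for d in sorted(range(4), key=lambda d: (abs(d - conc[i]), d)):
            if profile.nrl and i > 0 and d == out[i - 1]:
                continue
            g = gc_used + (1 if d in GC_DIGITS else 0)
            need = profile.w - g
            if 0 <= need <= remaining:
                feasible.append(d)
                break
        out[i] = feasible[0]
        if out[i] in GC_DIGITS:
            gc_used += 1
    return out


def decode_particle(conc: np.ndarray, profile: ConstraintProfile) -> Codeword:
    """Round each coordinate to the nearest digit (half up) and repair.

    The result always satisfies the per-word constraints; decoding an
    already-valid integer vector is the identity.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (profile.n,):
        raise ValueError(f"expected a length-{profile.n} vector, got shape {conc.shape}")
    digits = np.clip(np.floor(conc + 0.5), 0, 3).astype(np.int8)
    if profile.nrl:
        _repair_runlength(digits, conc)
    _repair_gc_weight(digits, conc, profile)
    return Codeword.from_digits(digits)


# ---------------------------------------------------------------------------
# main search loop


def _fitness_against(matrix: np.ndarray, word_digits: np.ndarray) -> int:
    if matrix.shape[0] == 0:
        return 0
    return int((matrix != word_digits).sum())


def _compatible(matrix: np.ndarray, word_digits: np.ndarray, d: int) -> bool:
    if matrix.shape[0] == 0:
        return True
    return bool(((matrix != word_digits).sum(axis=1) >= d).all())


def eo_search(
    profile: ConstraintProfile,
    params: EOParams,
    rng: np.random.Generator | None = None,
    trajectory: list | None = None,
) -> CodeSet:
    """Grow a valid code set by EO population dynamics.

    Every sweep evaluates fitness against the current set, rebuilds the
    equilibrium pool from the four best particles, updates all particles and
    then greedily inserts every decoded word compatible with the whole set.
    Pass ``trajectory`` (a list) to collect (iteration, best fitness, set
    size) tuples.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    particles = initialize_population(params, profile, rng)

    code = CodeSet(profile)
    matrix = np.empty((0, profile.n), dtype=np.int8)

    def insert(word: Codeword) -> bool:
        nonlocal matrix
        wd = word.digits_array()
        if not _compatible(matrix, wd, profile.d):
            return False
        code.add(word)
        matrix = np.vstack([matrix, wd[None, :]])
        return True

    # seed the set with the best initial decoded word (all fitnesses are 0
    # against an empty set, so ties resolve to the first particle)
    for p in particles:
        p.fitness_value = 0
    insert(particles[0].decoded)

    stale = 0
    for it in range(1, params.t_max + 1):
        for p in particles:
            p.fitness_value = _fitness_against(matrix, p.decoded.digits_array())
        pool = EquilibriumPool.from_particles(particles)
        pool_best = max(p.fitness_value for p in particles)
        particles = [
            update_concentration(p, pool, it, params, rng, profile)
            for p in particles
        ]
        inserted = 0
        for p in particles:
            if insert(p.decoded):
                inserted += 1
        if trajectory is not None:
            trajectory.append((it, pool_best, len(code)))
        stale = 0 if inserted else stale + 1
        if params.early_stop is not None and stale >= params.early_stop:
            break
    return code
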