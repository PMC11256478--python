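"""Seeded random-pedigree generator for tests and benchmarks.

Emulates a livestock-like pedigree: discrete generations of progeny born to
sires and dams drawn from earlier generations, with configurable missing-
parent rates and a small probability of generation overlap (a parent taken
from any earlier generation instead of the immediately previous one). Sex is
assigned at birth with probability 0.5 and fixed thereafter, and sires are
drawn only from males, dams only from females, so the generated pedigree
never violates the no-dual-sex-role invariant.

Output is already chronologically ordered and integer-coded (labels are the
string form of the codes); ``order_and_recode`` is a no-op on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .pedigree import Pedigree


@dataclass
class SimulationConfig:
    """Parameters of the generator.

    Defaults sketch a small herd: a founder cohort followed by a few discrete
    generations, 5% unknown parents per slot (typical of field recording),
    and 10% generation overlap (older sires reused, as with AI bulls).
    """

    n_founders: int = 20
    n_generations: int = 5
    progeny_per_generation: int = 100
    p_missing_sire: float = 0.05
    p_missing_dam: float = 0.05
    p_overlap: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise DomainError("n_founders must be >= 1")
        if self.n_generations < 0:
            raise DomainError("n_generations must be >= 0")
        if self.n_generations > 0 and self.progeny_per_generation < 1:
            raise DomainError("progeny_per_generation must be >= 1")
        for name in ("p_missing_sire", "p_missing_dam", "p_overlap"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {p}")

    @property
    def n_total(self) -> int:
        return self.n_founders + self.n_generations * self.progeny_per_generation


def _draw_parents(
    rng: np.random.Generator,
    size: int,
    pool_prev: np.ndarray,
    pool_all: np.ndarray,
    p_overlap: float,
    p_missing: float,
) -> np.ndarray:
    """Vectorized parent choice for one cohort and one parent slot.

    Scope per progeny: previous generation (prob 1 - p_overlap) or any
    earlier generation. An empty scope is widened to all earlier candidates;
    if none exist at all, the slot is left unknown (deterministic fallback).
    The missingness mask is applied last.
    """
    out = np.zeros(size, dtype=np.int64)
    use_any = rng.random(size) < p_overlap
    missing = rng.random(size) < p_missing
    for mask, pool in ((~use_any, pool_prev if pool_prev.size else pool_all),
                       (use_any, pool_all)):
        k = int(mask.sum())
        if k == 0:
            continue
        if pool.size == 0:
            continue  # founder-ize: stays 0
        out[mask] = pool[rng.integers(0, pool.size, size=k)]
    out[missing] = 0
    return out


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Generate an ordered, validation-clean pedigree from a seeded config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    is_male = np.zeros(n, dtype=bool)

    nf = config.n_founders
    is_male[:nf] = rng.random(nf) < 0.5
    gen_codes: list[np.ndarray] = [np.arange(1, nf + 1, dtype=np.int64)]

    start = nf
    for _ in range(config.n_generations):
        size = config.progeny_per_generation
        codes = np.arange(start + 1, start + size + 1, dtype=np.int64)
        sex = rng.random(size) < 0.5
        prev = gen_codes[-1]
        earlier = np.concatenate(gen_codes)
        prev_m = prev[is_male[prev - 1]]
        all_m = earlier[is_male[earlier - 1]]
        prev_f = prev[~is_male[prev - 1]]
        all_f = earlier[~is_male[earlier - 1]]
        sire[start : start + size] = _draw_parents(
            rng, size, prev_m, all_m, config.p_overlap, config.p_missing_sire
        )
        dam[start : start + size] = _draw_parents(
            rng, size, prev_f, all_f, config.p_overlap, config.p_missing_dam
        )
        is_male[start : start + size] = sex
        gen_codes.append(codes)
        start += size

    labels = tuple(str(i) for i in range(1, n + 1))
    return Pedigree(sire=sire, dam=dam, labels=labels)


def full_sib_line(n_generations: int) -> Pedigree:
    """Deterministic repeated full-sib mating line.

    Two unrelated founders, then each generation one male and one female both
    born to the previous generation's pair. Inbreeding along the line rises
    monotonically toward 1 (F = 0, 0, 1/4, 3/8, 1/2, 19/32, ...).
    """
    if n_generations < 1:
        raise DomainError("n_generations must be >= 1")
    n = 2 + 2 * n_generations
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    pm, pf = 1, 2  # codes of the current breeding pair (male, female)
    for g in range(n_generations):
        i = 2 + 2 * g  # 0-based index of the new male
        sire[i] = sire[i + 1] = pm
        dam[i] = dam[i + 1] = pf
        pm, pf = i + 1, i + 2  # their codes
    labels = tuple(str(i) for i in range(1, n + 1))
    return Pedigree(sire=sire, dam=dam, labels=labels)
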