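import numpy as np
import pytest

from pedkin import (
    Pedigree,
    RawPedigree,
    SimulationConfig,
    classify_sex_roles,
    order_and_recode,
    simulate_pedigree,
)

# Six-animal textbook pedigree: 3 = (1,2), 4 = (1,unknown), 5 = (4,3), 6 = (5,2)
SIX_TRIOS = [
    ("1", "0", "0"),
    ("2", "0", "0"),
    ("3", "1", "2"),
    ("4", "1", "0"),
    ("5", "4", "3"),
    ("6", "5", "2"),
]


@pytest.fixture
def six_raw() -> RawPedigree:
    return RawPedigree(list(SIX_TRIOS))


@pytest.fixture
def six_ped(six_raw) -> Pedigree:
    return order_and_recode(six_raw)


def random_pedigree(seed: int, max_n: int = 200) -> Pedigree:
    """A seeded random pedigree with varied shape, capped at max_n individuals."""
    rng = np.random.default_rng(seed)
    founders = int(rng.integers(2, 21))
    gens = int(rng.integers(1, 9))
    progeny = max(1, int(rng.integers(1, max(2, (max_n - founders) // gens + 1))))
    cfg = SimulationConfig(
        n_founders=founders,
        n_generations=gens,
        progeny_per_generation=progeny,
        p_missing_sire=float(rng.uniform(0, 0.3)),
        p_missing_dam=float(rng.uniform(0, 0.3)),
        p_overlap=float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return simulate_pedigree(cfg)


def role_valid_sets(ped: Pedigree, rng: np.random.Generator, m: int, n: int):
    """Disjoint (set1, set2) for a notdam-notsire query, or None if too small.

    set1 is drawn from non-dams, set2 from non-sires not already in set1.
    """
    sires, dams, neither = classify_sex_roles(ped)
    non_dams = np.array(sorted(sires | neither), dtype=np.int64)
    if non_dams.size < m:
        return None
    set1 = rng.choice(non_dams, size=m, replace=False)
    non_sires = np.array(sorted((dams | neither) - set(set1.tolist())), dtype=np.int64)
    if non_sires.size < n:
        return None
    set2 = rng.choice(non_sires, size=n, replace=False)
    return set1, set2
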