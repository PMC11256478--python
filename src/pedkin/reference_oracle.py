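"""Brute-force numerator relationship matrix by the tabular method.

Independent reference used by the test suite: the full A is built row by row
in pedigree order with the classic recursion

    a(i, j) = 0.5 * (a(j, sire_i) + a(j, dam_i))      for j < i
    a(i, i) = 1 + 0.5 * a(sire_i, dam_i)

with unknown-parent terms contributing 0. This is O(n^2) memory and time, so
it is only meant for small pedigrees (tests cap n at a few hundred).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PedigreeValidationError, UnknownCodeError
from .pedigree import Pedigree

_MAX_DUMP = 500


@dataclass
class FullAMatrix:
    """The full n x n additive (numerator) relationship matrix.

    Symmetric, positive semidefinite; diag(A) = 1 + F.
    """

    A: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0

    def to_csv(self, path: str | Path, ped: Pedigree | None = None) -> None:
        if self.n > _MAX_DUMP:
            raise PedigreeValidationError(
                f"refusing to dump A larger than {_MAX_DUMP} x {_MAX_DUMP}"
            )
        labels = list(ped.labels) if ped is not None else list(range(1, self.n + 1))
        pd.DataFrame(self.A, index=labels, columns=labels).to_csv(path)


def tabular_A(ped: Pedigree) -> FullAMatrix:
    """Full A over an ordered pedigree by the tabular recursion."""
    n = ped.n
    sp, dp = ped.padded_parents()
    # 1-padded workspace: row/column 0 stay zero and absorb unknown parents
    A = np.zeros((n + 1, n + 1), dtype=np.float64)
    for i in range(1, n + 1):
        s, d = sp[i], dp[i]
        row = 0.5 * (A[s, :i] + A[d, :i])
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + 0.5 * A[s, d]
    return FullAMatrix(A=A[1:, 1:])


def recursive_a(ped: Pedigree, i: int, j: int) -> float:
    """Single additive relationship a(i, j) by memoized pairwise recursion.

    Spot-check companion to :func:`tabular_A`: same recursion, evaluated
    lazily for one pair without materializing the matrix. Exact (bitwise)
    agreement with the tabular entry is expected, as both evaluate the same
    expression tree in double precision.
    """
    for c in (i, j):
        if not 1 <= c <= ped.n:
            raise UnknownCodeError(f"code {c} outside 1..{ped.n}")
    sp, dp = ped.padded_parents()
    memo: dict[tuple[int, int], float] = {}

    def a(x: int, y: int) -> float:
        if x == 0 or y == 0:
            return 0.0
        if x > y:
            x, y = y, x
        key = (x, y)
        val = memo.get(key)
        if val is not None:
            return val
        if x == y:
            val = 1.0 + 0.5 * a(int(sp[x]), int(dp[x]))
        else:  # y is the younger of the pair; recurse through its parents
            val = 0.5 * (a(x, int(sp[y])) + a(x, int(dp[y])))
        memo[key] = val
        return val

    return a(int(i), int(j))
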