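"""Inbreeding coefficients and Mendelian-sampling variances.

The inbreeding coefficient F_i of individual i is half the additive
relationship between its parents, F_i = a(s,d)/2, and the diagonal of the
numerator relationship matrix A is 1 + F. The Meuwissen-Luo recursion obtains
F_i from the decomposition A = T D T' by tracing only the ancestors of i, so
the whole vector costs far less than building A.

The Mendelian-sampling variance d_i = diag(D)_i depends only on how many
parents of i are known and on their inbreeding:

    both known      d = 0.5  - 0.25 (F_s + F_d)
    one known       d = 0.75 - 0.25 F_known
    none known      d = 1

Because d is a deterministic function of parental F, a previously computed
(f, d) pair for the first k individuals of an *unchanged* ordered pedigree
lets the recursion resume at k+1 and reproduce the from-scratch result
bitwise. A trio checksum sidecar makes silent pedigree edits detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import meuwissen_luo
from .errors import AlignmentError, DomainError
from .pedigree import Pedigree


@dataclass
class InbreedingResult:
    """Aligned vectors of inbreeding coefficients and Mendelian-sampling variances.

    ``f[i-1]`` and ``d[i-1]`` belong to the individual with code i of the
    pedigree the result was computed on. Founders have F = 0 and d = 1;
    1 + f is the diagonal of A.
    """

    f: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.f.shape != self.d.shape:
            raise AlignmentError("f and d must have the same length")

    @property
    def n(self) -> int:
        return self.f.shape[0]

    def to_dataframe(self, ped: Pedigree | None = None) -> pd.DataFrame:
        ids = list(ped.labels) if ped is not None else list(range(1, self.n + 1))
        return pd.DataFrame({"id": ids, "f": self.f, "d": self.d})


def mendelian_sampling_d(
    f_sire: float | None = None, f_dam: float | None = None
) -> float:
    """Mendelian-sampling variance of a progeny given parental inbreeding.

    ``None`` marks an unknown parent, which contributes as an unrelated,
    non-inbred founder.
    """
    for fp in (f_sire, f_dam):
        if fp is not None and not 0.0 <= fp < 1.0:
            raise DomainError(f"inbreeding coefficient {fp} outside [0, 1)")
    if f_sire is None and f_dam is None:
        return 1.0
    if f_sire is None or f_dam is None:
        known = f_sire if f_dam is None else f_dam
        return 0.75 - 0.25 * known
    return 0.5 - 0.25 * (f_sire + f_dam)


def _d_from_f(sp: np.ndarray, dp: np.ndarray, fpad: np.ndarray, k: int) -> np.ndarray:
    """Vectorized d for codes 1..k given complete parental f (padded arrays)."""
    s, t = sp[1 : k + 1], dp[1 : k + 1]
    fs, ft = fpad[s], fpad[t]  # fpad[0] == 0 handles unknowns
    both = (s > 0) & (t > 0)
    one = (s > 0) ^ (t > 0)
    return np.where(both, 0.5 - 0.25 * (fs + ft), np.where(one, 0.75 - 0.25 * (fs + ft), 1.0))


def compute_inbreeding(
    ped: Pedigree,
    f_prefix: np.ndarray | None = None,
    d_prefix: np.ndarray | None = None,
) -> InbreedingResult:
    """Meuwissen-Luo inbreeding coefficients, optionally resumed from a prefix.

    Parameters
    ----------
    ped
        Ordered pedigree (parents precede progeny).
    f_prefix
        Inbreeding coefficients of the first k coded individuals, taken
        verbatim. The pedigree's first k trios must be unchanged since they
        were computed; see :func:`trio_checksum`.
    d_prefix
        Mendelian-sampling variances matching ``f_prefix``; requires
        ``f_prefix`` and the same length. When absent, d over the prefix is
        recomputed from the parental f (cheap).

    Returns
    -------
    InbreedingResult
        Both f and d for all n individuals. The result is identical whether
        or not prefixes were supplied (for prefixes that match a from-scratch
        run on the same pedigree).
    """
    n = ped.n
    if d_prefix is not None and f_prefix is None:
        raise AlignmentError("d_prefix requires f_prefix")
    fpad = np.zeros(n + 1, dtype=np.float64)
    dpad = np.ones(n + 1, dtype=np.float64)
    k = 0
    if f_prefix is not None:
        f_prefix = np.asarray(f_prefix, dtype=np.float64)
        if f_prefix.ndim != 1 or f_prefix.shape[0] > n:
            raise AlignmentError(
                f"f_prefix length {f_prefix.shape[0]} exceeds pedigree size {n}"
            )
        if f_prefix.size and (f_prefix.min() < 0.0 or f_prefix.max() >= 1.0):
            raise DomainError("f_prefix values must lie in [0, 1)")
        k = f_prefix.shape[0]
        fpad[1 : k + 1] = f_prefix
        if d_prefix is not None:
            d_prefix = np.asarray(d_prefix, dtype=np.float64)
            if d_prefix.shape != f_prefix.shape:
                raise AlignmentError("d_prefix must match f_prefix in length")
            if d_prefix.size and (d_prefix.min() <= 0.0 or d_prefix.max() > 1.0):
                raise DomainError("d_prefix values must lie in (0, 1]")
            dpad[1 : k + 1] = d_prefix
        else:
            sp, dp = ped.padded_parents()
            dpad[1 : k + 1] = _d_from_f(sp, dp, fpad, k)
    sp, dp = ped.padded_parents()
    meuwissen_luo(sp, dp, fpad, dpad, k)
    return InbreedingResult(f=fpad[1:], d=dpad[1:])


def ne_from_delta_f(delta_f: float) -> float:
    """Effective population size from the per-generation inbreeding rate.

    Ne = 1 / (2 ΔF): the size of an idealized population with the same rate
    of inbreeding. ΔF must be strictly positive.
    """
    if not delta_f > 0:
        raise DomainError(f"delta_f must be > 0, got {delta_f}")
    return 1.0 / (2.0 * delta_f)


# ---------------------------------------------------------------------------
# coefficient files + prefix checksum
# ---------------------------------------------------------------------------

def trio_checksum(ped: Pedigree, k: int | None = None) -> str:
    """SHA-256 over the first k label trios; identifies the covered prefix."""
    k = ped.n if k is None else k
    if not 0 <= k <= ped.n:
        raise AlignmentError(f"checksum length {k} outside 0..{ped.n}")
    h = hashlib.sha256()
    for i, trio in enumerate(ped.trios()):
        if i >= k:
            break
        h.update(("|".join(trio) + "\n").encode())
    return h.hexdigest()


def write_coefficients(
    path: str | Path,
    ped: Pedigree,
    result: InbreedingResult,
    include_d: bool = False,
    sidecar: bool = True,
) -> None:
    """Export f (and optionally d) as CSV in pedigree order, full precision.

    A ``<path>.checksum`` sidecar records the trio checksum of the covered
    prefix so a later resume can detect pedigree edits.
    """
    if result.n != ped.n:
        raise AlignmentError("result length does not match pedigree")
    df = result.to_dataframe(ped)
    if not include_d:
        df = df[["id", "f"]]
    df.to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {"n_records": ped.n, "trio_sha256": trio_checksum(ped)}
        Path(str(path) + ".checksum").write_text(json.dumps(meta) + "\n")


def read_coefficients(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Read a coefficient CSV back as (ids, f, d-or-None)."""
    df = pd.read_csv(path, dtype={"id": str})
    f = df["f"].to_numpy(dtype=np.float64)
    d = df["d"].to_numpy(dtype=np.float64) if "d" in df.columns else None
    return df["id"].tolist(), f, d


def prefix_matches(ped: Pedigree, sidecar_path: str | Path) -> bool:
    """True if the pedigree's leading trios still match an exported sidecar."""
    meta = json.loads(Path(sidecar_path).read_text())
    k = int(meta["n_records"])
    if k > ped.n:
        return False
    return trio_checksum(ped, k) == meta["trio_sha256"]
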