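"""Numerator relationship coefficients between two sets via dummy progenies.

The additive relationship between two individuals is twice the inbreeding
coefficient of their (possibly hypothetical) progeny. For two disjoint sets
of m and n individuals, one terminal dummy progeny per pair is introduced and
its inbreeding coefficient computed; the m x n block R of A then satisfies

    R = 2 P1' diag(F_d) P2

with P1, P2 the mn x m and mn x n parent-incidence matrices. Because every
dummy has exactly one parent in each set, the product collapses to placing
2 F_d[p] in the cell of pair p — the direct fill used here.

Dummies are terminal and mutually unrelated, so they can be evaluated in
batches of any size over ``pair_order`` without changing a single bit of the
result relative to appending all mn of them to the pedigree at once; batching
bounds peak memory for large queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._kernels import dummy_inbreeding
from .errors import AlignmentError, DisjointnessError, RoleError, UnknownCodeError
from .inbreeding import InbreedingResult, compute_inbreeding
from .pedigree import Pedigree, classify_sex_roles

RelType = Literal["notdam-notsire", "sire-sire", "dam-dam"]

DUMMY_PREFIX = "~dummy"


@dataclass
class DummyDesign:
    """The m x n grid of dummy progenies for a pairwise relationship query.

    Pairs are enumerated set1-major: for each s in set1, for each t in set2.
    ``pair_sire[p]``/``pair_dam[p]`` are the parent codes of dummy p in that
    order (set1 fills the sire slot, set2 the dam slot — immaterial to the
    result since a(s, t) is symmetric, fixed for determinism).
    """

    set1: np.ndarray  # m codes, order preserved
    set2: np.ndarray  # n codes

    def __post_init__(self) -> None:
        self.set1 = np.asarray(self.set1, dtype=np.int64)
        self.set2 = np.asarray(self.set2, dtype=np.int64)

    @property
    def m(self) -> int:
        return self.set1.shape[0]

    @property
    def n(self) -> int:
        return self.set2.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.m * self.n

    @property
    def pair_sire(self) -> np.ndarray:
        return np.repeat(self.set1, self.n)

    @property
    def pair_dam(self) -> np.ndarray:
        return np.tile(self.set2, self.m)

    @property
    def p1_index(self) -> np.ndarray:
        """Column index into set1 for each dummy (row of P1 with the 1)."""
        return np.repeat(np.arange(self.m), self.n)

    @property
    def p2_index(self) -> np.ndarray:
        return np.tile(np.arange(self.n), self.m)

    def pair_order(self) -> Iterator[tuple[int, int]]:
        for s in self.set1:
            for t in self.set2:
                yield int(s), int(t)

    def P1(self) -> sp.csr_matrix:
        """The mn x m 0/1 parent-incidence matrix for set1."""
        mn = self.n_pairs
        return sp.csr_matrix(
            (np.ones(mn), (np.arange(mn), self.p1_index)), shape=(mn, self.m)
        )

    def P2(self) -> sp.csr_matrix:
        """The mn x n 0/1 parent-incidence matrix for set2."""
        mn = self.n_pairs
        return sp.csr_matrix(
            (np.ones(mn), (np.arange(mn), self.p2_index)), shape=(mn, self.n)
        )


@dataclass
class RelationshipBlock:
    """An m x n off-diagonal block of A plus the dummy inbreeding behind it."""

    R: np.ndarray
    F_d: np.ndarray
    design: DummyDesign

    def to_long_dataframe(self, ped: Pedigree) -> pd.DataFrame:
        """Long format: one row per pair (id1, id2, relationship, dummy F)."""
        id1 = [ped.label(c) for c in self.design.pair_sire]
        id2 = [ped.label(c) for c in self.design.pair_dam]
        return pd.DataFrame(
            {
                "id1": id1,
                "id2": id2,
                "relationship": self.R[self.design.p1_index, self.design.p2_index],
                "dummy_inbreeding": self.F_d,
            }
        )

    def to_matrix_dataframe(self, ped: Pedigree) -> pd.DataFrame:
        return pd.DataFrame(
            self.R,
            index=[ped.label(c) for c in self.design.set1],
            columns=[ped.label(c) for c in self.design.set2],
        )


def _check_query(
    ped: Pedigree,
    set1: Sequence[int],
    set2: Sequence[int],
    rel_type: RelType,
) -> DummyDesign:
    s1 = np.asarray(list(set1), dtype=np.int64)
    s2 = np.asarray(list(set2), dtype=np.int64)
    if s1.size == 0 or s2.size == 0:
        raise DisjointnessError("set1 and set2 must be non-empty")
    for name, s in (("set1", s1), ("set2", s2)):
        bad = s[(s < 1) | (s > ped.n)]
        if bad.size:
            raise UnknownCodeError(f"{name}: codes {bad.tolist()} outside 1..{ped.n}")
        if np.unique(s).size != s.size:
            raise DisjointnessError(f"{name} contains duplicate ids")
    overlap = np.intersect1d(s1, s2)
    if overlap.size:
        raise DisjointnessError(
            f"set1 and set2 overlap: {overlap.tolist()} (the two sets must be disjoint)"
        )
    sires, dams, _ = classify_sex_roles(ped)
    if rel_type == "notdam-notsire":
        bad1 = sorted(set(s1.tolist()) & dams)
        bad2 = sorted(set(s2.tolist()) & sires)
        if bad1:
            raise RoleError(f"type notdam-notsire: set1 members are dams: {bad1}")
        if bad2:
            raise RoleError(f"type notdam-notsire: set2 members are sires: {bad2}")
    elif rel_type == "sire-sire":
        bad = sorted((set(s1.tolist()) | set(s2.tolist())) - sires)
        if bad:
            raise RoleError(f"type sire-sire: non-sire members: {bad}")
    elif rel_type == "dam-dam":
        bad = sorted((set(s1.tolist()) | set(s2.tolist())) - dams)
        if bad:
            raise RoleError(f"type dam-dam: non-dam members: {bad}")
    else:
        raise RoleError(f"unknown relationship type {rel_type!r}")
    return DummyDesign(set1=s1, set2=s2)


def make_dummies(
    ped: Pedigree,
    set1: Sequence[int],
    set2: Sequence[int],
    rel_type: RelType = "notdam-notsire",
) -> tuple[Pedigree, DummyDesign]:
    """Append one terminal dummy progeny per (set1, set2) pair to the pedigree.

    Dummies follow all real animals in pair order (set1-major); real trios are
    unchanged. Sets must be disjoint, duplicate-free and satisfy the sex-role
    constraint of ``rel_type`` (checked against the pedigree's parent columns).
    """
    design = _check_query(ped, set1, set2, rel_type)
    mn = design.n_pairs
    sire = np.concatenate([ped.sire, design.pair_sire])
    dam = np.concatenate([ped.dam, design.pair_dam])
    labels = list(ped.labels)
    existing = set(labels)
    k = 0
    for _ in range(mn):
        k += 1
        while f"{DUMMY_PREFIX}{k}" in existing:
            k += 1
        labels.append(f"{DUMMY_PREFIX}{k}")
    extended = Pedigree(sire=sire, dam=dam, labels=tuple(labels))
    return extended, design


def assemble_R_from_Fd(design: DummyDesign, F_d: np.ndarray) -> RelationshipBlock:
    """Form R by placing 2 F_d[p] directly in the cell of each pair.

    Equals the explicit product 2 P1' diag(F_d) P2 — every dummy has exactly
    one parent per set, so each product cell receives a single term.
    """
    F_d = np.asarray(F_d, dtype=np.float64)
    if F_d.shape != (design.n_pairs,):
        raise AlignmentError(
            f"F_d length {F_d.shape} does not match {design.n_pairs} pairs"
        )
    R = np.empty((design.m, design.n), dtype=np.float64)
    R[design.p1_index, design.p2_index] = 2.0 * F_d
    return RelationshipBlock(R=R, F_d=F_d, design=design)


def calc_relationships(
    ped: Pedigree,
    set1: Sequence[int],
    set2: Sequence[int],
    rel_type: RelType = "notdam-notsire",
    f_prefix: np.ndarray | None = None,
    d_prefix: np.ndarray | None = None,
    batch_size: int | None = None,
) -> RelationshipBlock:
    """Relationship block R between two disjoint sets of real individuals.

    Inbreeding over the real pedigree is computed first (resuming from
    ``f_prefix``/``d_prefix`` when given — the prefixes may cover at most the
    real animals); each dummy's inbreeding coefficient is then evaluated in
    batches over pair order. Results are independent of the prefixes and of
    ``batch_size`` (default: one set1 row, i.e. len(set2) dummies at a time).
    """
    design = _check_query(ped, set1, set2, rel_type)
    base = compute_inbreeding(ped, f_prefix=f_prefix, d_prefix=d_prefix)
    F_d = dummy_inbreeding_for_design(ped, base, design, batch_size=batch_size)
    return assemble_R_from_Fd(design, F_d)


def dummy_inbreeding_for_design(
    ped: Pedigree,
    base: InbreedingResult,
    design: DummyDesign,
    batch_size: int | None = None,
) -> np.ndarray:
    """F of every dummy in pair order, given complete real-animal f and d."""
    if base.n != ped.n:
        raise AlignmentError("base result length does not match pedigree")
    if batch_size is None:
        batch_size = design.n
    if batch_size < 1:
        raise AlignmentError(f"batch_size must be >= 1, got {batch_size}")
    sp_, dp_ = ped.padded_parents()
    fpad = np.concatenate([np.zeros(1), base.f])
    dpad = np.concatenate([np.ones(1), base.d])
    ps = design.pair_sire
    pt = design.pair_dam
    F_d = np.empty(design.n_pairs, dtype=np.float64)
    for lo in range(0, design.n_pairs, batch_size):
        hi = min(lo + batch_size, design.n_pairs)
        dummy_inbreeding(sp_, dp_, fpad, dpad, ps[lo:hi], pt[lo:hi], F_d[lo:hi])
    return F_d
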