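"""Pedigree reading, validation, ordering, recoding and subsetting.

A pedigree is a table of trios (individual, sire, dam) with unknown parents
coded 0. The kinship kernels require a *chronologically ordered* pedigree —
parents appear before progeny — with individuals recoded 1..n; this module is
the only place where ordering and recoding happen, so the resume contract of
:mod:`pedkin.inbreeding` (prefix vectors aligned to codes 1..k) is always
meaningful.
"""

from __future__ import annotations

import csv
import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import (
    CycleError,
    DomainError,
    OrderingError,
    PedigreeParseError,
    PedigreeValidationError,
    UnknownCodeError,
)

MISSING = "0"
"""Missing-parent sentinel on the label side."""


# ---------------------------------------------------------------------------
# raw (unordered, label-based) pedigrees
# ---------------------------------------------------------------------------

@dataclass
class RawPedigree:
    """An unordered pedigree of string-labelled trios.

    ``records`` holds (individual, sire, dam) label triples; unknown parents
    are the string ``"0"``. Construction normalizes empty parent fields to the
    sentinel but performs no structural validation — that is :func:`validate`'s
    job, so that problems can be *reported* rather than raised one at a time.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        norm = []
        for rec in self.records:
            ind, sire, dam = (str(x).strip() for x in rec[:3])
            if ind == MISSING or ind == "":
                raise DomainError(
                    "individual id may not be empty or equal the missing-parent "
                    f"sentinel {MISSING!r}"
                )
            norm.append((ind, sire or MISSING, dam or MISSING))
        self.records = norm

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.records)


def read_pedigree(
    path: str | Path,
    delimiter: str | None = None,
    has_header: bool = False,
) -> RawPedigree:
    """Read a pedigree CSV/TSV into a :class:`RawPedigree`.

    Parameters
    ----------
    path
        File with at least three columns: individual, sire, dam. Extra
        columns are ignored. Unknown parents are ``0`` or empty.
    delimiter
        Field separator; ``None`` infers ``'\\t'`` for ``.tsv``/``.txt``
        files and ``','`` otherwise.
    has_header
        Skip the first row when true.

    Raises
    ------
    PedigreeParseError
        On a row with fewer than three fields, naming the line.
    PedigreeValidationError
        On duplicate individual ids.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if has_header and lineno == 1:
                continue
            if not row or all(not f.strip() for f in row):
                continue  # blank line
            if len(row) < 3:
                raise PedigreeParseError(
                    f"{path}: line {lineno}: expected at least 3 columns, got {len(row)}"
                )
            ind = row[0].strip()
            if ind in seen:
                raise PedigreeValidationError(
                    f"{path}: line {lineno}: duplicate individual id {ind!r}"
                )
            seen.add(ind)
            records.append((ind, row[1], row[2]))
    return RawPedigree(records)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    kind: str      # cycle | self-parent | dual-sex-role | undeclared-parent | duplicate-id
    ids: tuple[str, ...]

    def __str__(self) -> str:
        return f"[{self.severity}] {self.kind}: {', '.join(self.ids)}"


@dataclass
class PedigreeIssueReport:
    """Findings of :func:`validate`; empty iff the pedigree is clean."""

    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:  # truthy iff anything was found
        return bool(self.issues)

    def raise_on_errors(self) -> None:
        if self.errors:
            kinds = {i.kind for i in self.errors}
            msg = "; ".join(str(i) for i in self.errors)
            if "cycle" in kinds:
                raise CycleError(msg)
            raise PedigreeValidationError(msg)


def validate(raw: RawPedigree) -> PedigreeIssueReport:
    """Check a raw pedigree against the invariants the algorithms assume.

    Errors: duplicate ids, self-parenting, ids used as both sire and dam,
    cycles (an individual its own ancestor). Warnings: parents never declared
    as individuals (they become implicit founders during ordering).
    """
    report = PedigreeIssueReport()
    declared = [r[0] for r in raw]
    declared_set = set()
    dups = sorted({i for i in declared if i in declared_set or declared_set.add(i)})
    # note: the walrus-free one-liner above relies on set.add returning None
    if dups:
        report.issues.append(Issue("error", "duplicate-id", tuple(dups)))

    sires = {s for _, s, _ in raw if s != MISSING}
    dams = {d for _, _, d in raw if d != MISSING}
    dual = sorted(sires & dams)
    if dual:
        report.issues.append(Issue("error", "dual-sex-role", tuple(dual)))

    selfp = sorted({i for i, s, d in raw if i == s or i == d})
    if selfp:
        report.issues.append(Issue("error", "self-parent", tuple(selfp)))

    undeclared = sorted((sires | dams) - declared_set)
    if undeclared:
        report.issues.append(Issue("warning", "undeclared-parent", tuple(undeclared)))

    # cycle detection: Kahn's algorithm over parent -> child edges
    children: dict[str, list[str]] = {}
    indeg: dict[str, int] = {i: 0 for i in declared_set}
    for ind, s, d in raw:
        for p in (s, d):
            if p != MISSING and p != ind and p in declared_set:
                children.setdefault(p, []).append(ind)
                indeg[ind] += 1
    queue = [i for i in declared_set if indeg[i] == 0]
    removed = 0
    while queue:
        node = queue.pop()
        removed += 1
        for child in children.get(node, ()):
            indeg[child] -= 1
            if indeg[child] == 0:
                queue.append(child)
    if removed < len(declared_set):
        stuck = sorted(i for i, k in indeg.items() if k > 0)
        report.issues.append(Issue("error", "cycle", tuple(stuck)))
    return report


# ---------------------------------------------------------------------------
# ordered, integer-coded pedigrees
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """A chronologically ordered, integer-coded pedigree.

    ``sire``/``dam`` are int64 arrays of length n holding parent *codes*
    (1-based; 0 = unknown) with the invariant sire[i-1] < i and dam[i-1] < i
    for code i — parents always precede progeny. ``labels[c-1]`` is the
    original label of code c and ``id_map`` the inverse.

    The no-dual-sex-role invariant is enforced at validation time on input
    pedigrees but deliberately *not* here: extended pedigrees carrying dummy
    progenies of same-sex pairs (``sire-sire``/``dam-dam`` queries) violate it
    by construction.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: tuple[str, ...]
    id_map: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.ascontiguousarray(self.sire, dtype=np.int64)
        self.dam = np.ascontiguousarray(self.dam, dtype=np.int64)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeValidationError("sire/dam/labels length mismatch")
        codes = np.arange(1, n + 1)
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            if n and (arr.min(initial=0) < 0 or not np.all(arr < codes)):
                raise PedigreeValidationError(
                    f"{name} codes must be 0 (unknown) or precede their progeny"
                )
        self.id_map = {lab: c for c, lab in enumerate(self.labels, start=1)}
        if len(self.id_map) != n:
            raise PedigreeValidationError("labels are not unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def code(self, label: str) -> int:
        try:
            return self.id_map[label]
        except KeyError:
            raise UnknownCodeError(f"unknown individual label {label!r}") from None

    def label(self, code: int) -> str:
        if not 1 <= code <= self.n:
            raise UnknownCodeError(f"code {code} outside 1..{self.n}")
        return self.labels[code - 1]

    def padded_parents(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent arrays padded with a leading 0 so code c indexes position c."""
        zero = np.zeros(1, dtype=np.int64)
        return np.concatenate([zero, self.sire]), np.concatenate([zero, self.dam])

    def trios(self) -> Iterator[tuple[str, str, str]]:
        """Yield label trios, unknown parents as the sentinel."""
        for i in range(self.n):
            s, d = self.sire[i], self.dam[i]
            yield (
                self.labels[i],
                self.labels[s - 1] if s else MISSING,
                self.labels[d - 1] if d else MISSING,
            )

    def to_raw(self) -> RawPedigree:
        return RawPedigree(list(self.trios()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.trios()), columns=["individual", "sire", "dam"])


def order_and_recode(raw: RawPedigree, strict: bool = False) -> Pedigree:
    """Topologically order and integer-recode a raw pedigree.

    Founders come first; ties are broken by original input order (stable), and
    parents never declared as individuals are inserted as implicit founders
    immediately before their first mention. With ``strict=True`` an input whose
    row order already violates parent-before-progeny raises
    :class:`OrderingError` instead of being silently reordered.
    """
    report = validate(raw)
    report.raise_on_errors()

    declared = {ind: idx for idx, (ind, _, _) in enumerate(raw)}
    first_mention: dict[str, int] = {}
    for idx, (_, s, d) in enumerate(raw):
        for p in (s, d):
            if p != MISSING and p not in declared and p not in first_mention:
                first_mention[p] = idx

    if strict:
        for idx, (ind, s, d) in enumerate(raw):
            for p in (s, d):
                if p != MISSING and p in declared and declared[p] >= idx:
                    raise OrderingError(
                        f"strict: parent {p!r} of {ind!r} does not precede it"
                    )

    # node sort keys: real record i -> (i, 1); implicit founder first seen in
    # record i -> (i, 0), i.e. just before the record that mentions it
    key = {ind: (idx, 1) for ind, idx in declared.items()}
    key.update({p: (idx, 0) for p, idx in first_mention.items()})
    parents: dict[str, tuple[str, str]] = {p: (MISSING, MISSING) for p in first_mention}
    parents.update({ind: (s, d) for ind, s, d in raw})

    children: dict[str, list[str]] = {}
    indeg = {node: 0 for node in key}
    for ind, (s, d) in parents.items():
        for p in (s, d):
            if p != MISSING:
                children.setdefault(p, []).append(ind)
                indeg[ind] += 1

    heap = [(key[n], n) for n, k in indeg.items() if k == 0]
    heapq.heapify(heap)
    order: list[str] = []
    while heap:
        _, node = heapq.heappop(heap)
        order.append(node)
        for child in children.get(node, ()):
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(heap, (key[child], child))
    if len(order) < len(key):  # unreachable after validate, but cheap to keep
        raise CycleError("pedigree contains a cycle; no chronological order exists")

    code = {lab: c for c, lab in enumerate(order, start=1)}
    sire = np.zeros(len(order), dtype=np.int64)
    dam = np.zeros(len(order), dtype=np.int64)
    for lab, (s, d) in parents.items():
        i = code[lab] - 1
        sire[i] = code[s] if s != MISSING else 0
        dam[i] = code[d] if d != MISSING else 0
    return Pedigree(sire=sire, dam=dam, labels=tuple(order))


def extract_ancestors(ped: Pedigree, focal: Iterable[int]) -> Pedigree:
    """Subset a pedigree to ``focal`` individuals plus all their ancestors.

    The subset is re-recoded 1..m with the original relative order preserved,
    so inbreeding computed on the subset matches the full pedigree exactly for
    every retained individual (the ancestor closure is self-contained).
    """
    focal = list(focal)
    for c in focal:
        if not 1 <= int(c) <= ped.n:
            raise UnknownCodeError(f"code {c} outside 1..{ped.n}")
    sp, dp = ped.padded_parents()
    keep: set[int] = set()
    stack = [int(c) for c in focal]
    while stack:
        c = stack.pop()
        if c in keep:
            continue
        keep.add(c)
        if sp[c]:
            stack.append(int(sp[c]))
        if dp[c]:
            stack.append(int(dp[c]))
    old = sorted(keep)
    newcode = {c: i + 1 for i, c in enumerate(old)}
    sire = np.array([newcode[int(sp[c])] if sp[c] else 0 for c in old], dtype=np.int64)
    dam = np.array([newcode[int(dp[c])] if dp[c] else 0 for c in old], dtype=np.int64)
    labels = tuple(ped.labels[c - 1] for c in old)
    return Pedigree(sire=sire, dam=dam, labels=labels)


def classify_sex_roles(
    ped: Pedigree,
) -> tuple[frozenset[int], frozenset[int], frozenset[int]]:
    """Partition codes into (sires, dams, neither) by parent-column usage."""
    sires = frozenset(int(c) for c in ped.sire[ped.sire > 0])
    dams = frozenset(int(c) for c in ped.dam[ped.dam > 0])
    neither = frozenset(range(1, ped.n + 1)) - sires - dams
    return sires, dams, neither


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path: str | Path, delimiter: str = ",") -> None:
    """Write label trios in the same three-column format accepted on input."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerows(ped.trios())


def write_id_map(ped: Pedigree, path: str | Path, delimiter: str = ",") -> None:
    """Write the (original label, integer code) correspondence."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["label", "code"])
        for c, lab in enumerate(ped.labels, start=1):
            writer.writerow([lab, c])
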