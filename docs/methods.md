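# Methods

## Model

For an ordered pedigree (parents precede progeny, individuals coded 1..n,
unknown parents 0), the numerator relationship matrix **A** collects the
additive genetic relationships a(i, j) — twice the kinship (coancestry)
coefficients — with diagonal a(i, i) = 1 + F_i. Founders are taken as
non-inbred and mutually unrelated; an unknown parent contributes as an
unrelated, non-inbred founder. These are the standard base-population
assumptions of pedigree BLUP; everything below is conditional on them.

### Inbreeding: Meuwissen–Luo

With **A** = **TDT**′ (T unit lower-triangular, D diagonal), the diagonal
element of **A** is a quadratic form in one column of T:

    1 + F_i = Σ_j L_j² d_j      over i and its ancestors j,  L_i = 1.

`compute_inbreeding` evaluates this per individual: starting from 0.5 on each
known parent, ancestor coefficients L are accumulated downward (0.5·L_j to
each known parent of j) while ancestors are processed youngest-first —
largest code first — so each L_j is final exactly once. The Mendelian-sampling
variance is

    d_i = 0.5  − 0.25 (F_s + F_d)   both parents known
    d_i = 0.75 − 0.25 F_known       one parent known
    d_i = 1                         founder,

so 0.25 < d ≤ 1 always, and d is a deterministic function of parental F.
The ancestor set is collected by a stack traversal with stamped visited
flags, then sorted descending; workspace arrays are reused across
individuals. The inner loops are JIT-compiled (numba), which is what makes
the half-million-animal runs in the test suite take seconds.

**Resume semantics.** f (and optionally d) for the first k coded individuals
are accepted verbatim and the recursion starts at k+1. When d is not
supplied it is recomputed from the parental f in one vectorized pass.
Because the resumed run executes the identical instruction sequence from k+1
on, it reproduces the from-scratch result *bitwise* — asserted, not just to
tolerance, in the tests. The contract requires the first k trios to be
unchanged; the library cannot verify that from the vectors alone, so
coefficient exports carry a SHA-256 checksum sidecar over the covered trios
(`prefix_matches` detects edits). Coefficients are exported at full double
precision (`%.17g`), so a write/read round trip is exact.

### Relationships between two sets: dummy progenies

a(s, t) = 2 F_X for any progeny X of s and t. For disjoint sets of m and n
individuals, one *terminal* dummy progeny per pair is introduced (pair order:
set1-major) and its F computed; the block of **A** is

    R = 2 P₁′ diag(F_d) P₂,

with P₁, P₂ the mn×m and mn×n parent-incidence matrices. Since each dummy
has exactly one parent per set, every cell of the product receives a single
term, and `assemble_R_from_Fd` places 2·F_d[p] directly — the equality with
the explicit sparse product is a property test, not an assumption.

Three query types mirror the sex-role constraints: `notdam-notsire`
(default; set1 free of dams, set2 free of sires), `sire-sire`, `dam-dam`.
Same-sex pairs cannot have a real progeny, but the dummy is hypothetical, so
the query is well-defined; set1 conventionally fills the sire slot
(immaterial — a(s, t) is symmetric — but fixed for determinism). Sets must
be disjoint and duplicate-free; self-relationships are 1 + F from the
inbreeding module, not a query.

**Batching.** Dummies are terminal and mutually unrelated, so their F values
are independent: the pair kernel evaluates them in configurable batches over
pair order (default: one set1 row, n dummies) against the *real* pedigree
arrays, without materializing the mn extended records. The result is
bit-identical to appending all dummies and running the full recursion — the
monolithic path is kept in the code (`make_dummies` + `compute_inbreeding`)
and compared bitwise in the tests. Peak memory of a query is therefore
O(n_real + batch), not O(n_real + m·n).

### Other quantities

- Effective population size Ne = 1/(2ΔF), ΔF > 0. Estimating ΔF from a time
  series of mean F is left to the caller.
- `extract_ancestors` returns the upward closure of a focal set, re-recoded
  with relative order preserved. Because the closure is self-contained and
  ancestor processing order is preserved, inbreeding on the subset equals
  the full-pedigree values bitwise.

## Reference oracle

`tabular_A` builds the full **A** by the tabular recursion in pedigree order
(a(i, j) = ½(a(j, s_i) + a(j, d_i)), a(i, i) = 1 + ½ a(s_i, d_i)); it shares
no code with the kernel and is the independent reference in every
equivalence test (tolerance 1e-12). `recursive_a` is a memoized pairwise
evaluation of the same recursion for spot checks without the n² matrix. Both
are O(n²) or worse by design and capped at a few hundred individuals in
tests. Wright's path-counting formula is not implemented as a second oracle:
path enumeration with common-ancestor corrections is error-prone and adds no
verification power over the recursion.

## Pedigree handling

Input is CSV/TSV trios with arbitrary string labels; 0 or an empty field
means unknown. Validation reports (rather than raises) duplicate ids,
self-parenting, ids used as both sire and dam (hard error — the query types
presuppose consistent sex roles), cycles, and parents never declared as
individuals; the last are *warnings* and become implicit founders, inserted
immediately before their first mention, since real pedigrees routinely omit
founder rows. Ordering is a stable topological sort (ties by input order),
so codes — and hence the f/d prefix alignment — are deterministic. `strict`
mode instead fails when the input rows are not already parent-before-progeny:
the resume contract is only meaningful under a fixed order, so reordering is
always an explicit step, never implicit inside a kernel.

## Simulator

`simulate_pedigree` emulates a livestock-like population: a founder cohort,
then discrete generations whose sires are drawn from earlier males and dams
from earlier females (sex assigned at birth with probability 0.5 and fixed,
so dual-role violations cannot arise). Parameters, with defaults: 20
founders, 5 generations × 100 progeny, 5% missing probability per parent
slot (typical of field recording), 10% generation overlap (a parent drawn
from any earlier generation — reused older sires, as with AI bulls). An
empty eligible pool is widened to all earlier candidates, then the slot is
left unknown (deterministic fallback). A single seeded generator drives all
draws; identical configs give identical pedigrees. `full_sib_line` is a
deterministic preset of repeated full-sib mating whose F climbs
monotonically toward 1 (0, 1/4, 3/8, 1/2, 19/32, ...), used to exercise deep
inbreeding.

What the simulator does **not** emulate: selection, assortative or avoidance
mating, unbalanced family sizes beyond uniform parent reuse, overlapping
birth records within a generation, or recording errors other than missing
parents. Passing tests therefore demonstrate algorithmic correctness on
structurally realistic pedigrees, not robustness to the messiness of raw
field data (which the validation layer is for).

## Scale choices and numerical notes

- Oracle-equivalence tests run 200 seeded random pedigrees capped at n = 200
  (the oracle is O(n²)); resume invariance runs 20 pedigrees at every split
  point. The scaled engineering check uses a 500,000-animal pedigree
  (100,000 founders + 8 generations × 50,000 — shallow, commercial-dairy-like
  depth) with a 100×100 query in batches of 1,000, asserted to stay under a
  256 MB peak of Python allocations (tracemalloc, measured over the query
  only); batched-vs-monolithic bitwise agreement is asserted on a
  10,000-animal pedigree.
- All coefficients are double precision throughout; no rounding on export.
  F and d values on bounded-depth pedigrees are dyadic rationals well within
  double range, which is why bitwise assertions (resume, batching, subset,
  set-swap transpose) are meaningful.
- Degenerate inputs: empty pedigree files yield empty results; a pedigree of
  one founder gives F = 0, d = 1; queries reject empty, overlapping or
  duplicated sets, and unknown ids, with specific exceptions the CLI maps to
  exit codes (2 validation, 3 I/O, 4 alignment/domain).

## API notes

The library's `compute_inbreeding` always returns both f and d (computing d
is free — the recursion needs it anyway); the `--export-d` switch on the CLI
controls whether d is written, mirroring the common convention of returning
either the f vector or the (f, d) pair. The `pedkin` command is a thin layer
over the library; every run logs its resolved configuration and the package
version, and identical configurations on identical inputs produce
byte-identical outputs.

## Known limitations

- No unknown-parent groups, genetic groups, or multi-breed handling; no
  inverse of **A** (Henderson/Quaas rules) and no genomic relationships.
- The resume checksum detects edits only within the covered prefix; changes
  *appended* after the prefix are, by design, exactly what resume is for.
- `recursive_a` uses Python recursion and is intended for small pedigrees;
  depth is bounded by pedigree length.
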