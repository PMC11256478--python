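# pedkin

Pedigree-based inbreeding and numerator relationship coefficients for
conservation and breeding programs.

Monitoring the rate of inbreeding and planning matings that keep it low
requires two quantities per pedigreed population: the inbreeding coefficient
F of every individual, and the additive (numerator) relationship coefficient
a(i, j) between candidate pairs. `pedkin` computes both from a plain
three-column pedigree (individual, sire, dam; unknown parents coded 0):

- **Inbreeding** by the Meuwissen–Luo algorithm, which obtains each F from
  the decomposition **A** = **TDT**′ by tracing only the individual's
  ancestors — no n×n matrix is ever built. The Mendelian-sampling variances
  **d** = diag(**D**) come out for free, and the computation can be
  *resumed*: given f (and optionally d) for the first k individuals of an
  unchanged ordered pedigree, only the new animals are processed, with a
  checksum sidecar to detect pedigree edits.
- **Relationships between two sets** via dummy progenies: the relationship
  coefficient between two individuals is twice the inbreeding coefficient of
  their (possibly hypothetical) progeny, a(s, t) = 2 F_X. One terminal dummy
  per pair is introduced — whether or not the pair has a real progeny, and
  even when it could not (same sex) — and the m×n block of **A** is
  **R** = 2 **P**₁′ diag(**F**_d) **P**₂, filled directly from the dummy
  inbreeding vector. Dummies are evaluated in batches, so peak memory stays
  bounded for large m·n.
- Supporting tools: pedigree validation/ordering/recoding, ancestor-traced
  subsetting, sex-role classification, effective population size
  Ne = 1/(2ΔF), a seeded pedigree simulator, and a brute-force tabular-method
  oracle for verification.

## Worked example

The classic six-animal pedigree (3 = 1×2, 4 = 1×unknown, 5 = 4×3, 6 = 5×2):

```python
from pedkin import RawPedigree, order_and_recode, compute_inbreeding, calc_relationships

ped = order_and_recode(RawPedigree([
    ("1","0","0"), ("2","0","0"), ("3","1","2"),
    ("4","1","0"), ("5","4","3"), ("6","5","2"),
]))
res = compute_inbreeding(ped)
print(res.f)   # [0.    0.    0.    0.    0.125 0.125]
print(res.d)   # [1.      1.      0.5     0.75    0.5     0.46875]

block = calc_relationships(ped, set1=[1, 4], set2=[3, 6])
print(block.F_d)  # [0.25    0.125   0.125   0.15625]
print(block.R)    # [[0.5    0.25  ]
                  #  [0.25   0.3125]]
```

Animals 5 and 6 are inbred (F = 1/8 each; e.g. 6's parents 5 and 2 are
related through 2). The four dummy progenies of the {1,4}×{3,6} query have
inbreeding (1/4, 1/8, 1/8, 5/32); doubling them gives the relationship block
R — for instance a(4, 6) = 2·5/32 = 0.3125.

The same is available from a shell:

```sh
pedkin inbreeding --pedigree ped.csv --export-d --out f.csv
pedkin relate --pedigree ped.csv --set1 s1.txt --set2 s2.txt --out rel.csv
pedkin subset --pedigree ped.csv --ids focal.txt --out sub.csv
pedkin simulate --founders 100 --generations 5 --progeny 500 --seed 1 --out sim.csv
```

`relate` writes long-format rows `id1,id2,relationship,dummy_inbreeding`;
`--f`/`--d` accept previously exported coefficient files to skip recomputing
the real population.

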