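# partialalign

Smith–Waterman **partial alignment** for locating large deletions in
DNA queries.

A read that spans a kilobase-scale deletion maps to two distant loci of
its reference. A single Smith–Waterman (SW) local alignment cannot
bridge them — an affine gap of length *L* costs `open + (L−1)·extend`,
far more than the matches beyond the breakpoint can repay — so the
classical alignment misplaces the deletion boundary. This package
splits the query into a *former* and a *latter* part, aligns each part
separately against the full reference, and reads the deletion off the
two mappings: former part mapped to `[a, b]`, latter part to `[c, d]`
with `b < c` implies a deleted interval `[b+1, c−1]` of length
`c − b − 1`.

Two split searches are provided, plus the classical baseline:

* **IncrementalPartialAlign** — scan former-part lengths one base at a
  time from `min_length` upward until the part's *similarity ratio*
  (identical matches / full part length) first drops below a threshold;
  linear in the boundary position.
* **BinaryPartialAlign** — start from an equal split and move the split
  point by halving steps `k_i = floor(l_query / 2^(i+1))`, lengthening
  whichever part currently aligns better, until both parts clear the
  threshold; logarithmic in the query length.
* **Classical SW** — one whole-query alignment; the boundary estimate
  is the number of query bases it consumes.

A benchmarking harness generates two-fragment "deleted" queries from a
reference and aggregates, per query-length bin, the estimated deletion
position error (EDPE, in bp) of all three methods.

Intended users: wet-lab and bioinformatics researchers screening reads
or assembled fragments for large structural deletions, and anyone who
needs a small, deterministic, fully scripted reimplementation of the
partial-alignment strategy for comparison studies.

## Worked example

```python
from partialalign import (ScoringScheme, binary_partial_align,
                          worked_example_analog)

scheme = ScoringScheme.blosum62()
reference, query, truth = worked_example_analog(seed=1)   # 500 bp reference,
# 40 bp query = exact unique 27 + 13 bp fragments, >= 100 bp apart

res = binary_partial_align(query, reference, threshold=0.9,
                           min_length=20, scheme=scheme)
print([s.former_length for s in res.trace])   # [20, 30, 25, 27]
print(res.boundary_estimate)                  # 27
print(res.deletion_ref_start, res.deletion_ref_end, res.deletion_length)
# 77 232 156   (for seed 1: deleted interval [b+1, c-1], length c-b-1)
```

The split trace is the method's signature behaviour: from the 20/20
split the former half aligns perfectly (ratio 1.0) while the latter
half straddles the breakpoint (ratio 13/20), so the former part grows
by `floor(40/4) = 10`; at 30/10 the former part's ratio is exactly
27/30 = 0.9 — *not* strictly above the 0.9 threshold — so the latter
part grows by 5; at 25/15 the former part is clean again and grows by
2, landing on 27/13 where both parts align perfectly: boundary 27,
position error 0 bp. The classical baseline on the same query consumes
39–40 bases, an error of 12–13 bp.

The same is available from the shell:

```bash
partialalign make-ref --length 20000 --seed 1 -o ref.fa
partialalign find-deletion query.fa ref.fa --method binary -o result.tsv
partialalign simulate --synthetic-ref 20000 --seed 1 --n-per-bin 20 \
    --substitution-rate 0.01 --out-summary summary.tsv --out-queries queries.tsv
```

`simulate` reproduces the benchmark design: nine query-length bins
(100–199 … 900–999 bp), random two-fragment queries, per-bin mean ± SD
EDPE per method. On a 20 kb synthetic reference with 20 queries per bin
and a 1% substitution rate, mean EDPE orders
**binary ≤ incremental ≤ classical SW in every bin** (asserted by the
test suite), with the classical baseline's error growing to hundreds of
bp in the longest bins while the binary strategy stays lowest.

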