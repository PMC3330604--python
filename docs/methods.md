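# Methods

## Problem

A sequencing read that spans a large deletion maps to two distant loci
of the reference. A single Smith–Waterman (SW) local alignment cannot
bridge them: a gap of length *L* costs `open + (L−1)·extend`, so for a
kilobase-scale deletion the penalty dwarfs any match reward and the
optimal local alignment either stops near the breakpoint or absorbs a
ragged mix of gaps and chance matches past it. The position error this
induces — the absolute difference, in bases, between the estimated and
the true breakpoint within the query — is the EDPE (estimated deletion
position error) that all methods here are measured by.

The remedy is *partial alignment*: split the query at a candidate
breakpoint into a **former** and a **latter** part, align each part
separately against the full reference, and accept the split when both
parts align well. If the former part maps to reference interval
`[a, b]` and the latter to `[c, d]` with `b < c`, the deleted interval
is `[b+1, c−1]` with length `c − b − 1`.

## Acceptance statistic: the similarity ratio

Each part alignment is scored by its **similarity ratio**: the number
of identically matched bases divided by the *full* length of the part
(not by the aligned span). A part "aligns well" when its ratio is
**strictly above** a user threshold. Strictness matters: in the
published 40-bp demonstration the 30-base former part has exactly 27
matches, ratio 27/30 = 0.9, and the search is only correct if 0.9 does
*not* count as above a 0.9 threshold. For the same reason thresholds
are compared as exact rationals (a threshold written `0.9` means
exactly 9/10; match counts are integers), so binary floating point can
never flip a boundary case.

## The two split searches

Both strategies take the same four inputs: query, reference, similarity
ratio threshold, and minimum sequence length. Both begin with one
whole-query SW run; if its ratio is above the threshold the query is
reported as containing no deletion.

**IncrementalPartialAlign** scans former-part lengths
`L = min_length, min_length+1, …`, each time aligning `query[1..L]`,
until the ratio first falls strictly below the threshold at some `L*`.
The boundary estimate is `L* − 1` (the last length that still aligned
acceptably). The remaining latter part `query[L*..]` is then aligned
and the deletion called from the two mappings. The scan may run past
`l_query − min_length`: the minimum length bounds only where the scan
*starts* (the published 40-bp example, min_length 20, stops at
`L* = 28`, leaving a 12-base latter part). Cost is linear in the
boundary position.

Implementation note: the SW matrix of `query[1..L]` is the top `L`-row
slice of the full query's matrix, so the scan is computed with one
shared matrix fill; the per-prefix optimum, tie-breaking and traceback
are identical to independent SW runs (asserted by test), and `sw_calls`
counts the logical invocations.

**BinaryPartialAlign** starts from the equal split
`former = floor(l_query/2)` and iterates: align both parts; if both
ratios are above the threshold, stop and report the split; otherwise
lengthen the part with the larger ratio (ties lengthen the former part)
by the halving step

```
k_i = floor(l_query / 2^(i+1)),   i = 1, 2, …
```

and continue. When `k_i` reaches 0, or a clamped move makes no
progress, the best split seen so far — the one maximizing
min(former ratio, latter ratio) — is reported with a `not_converged`
status. Intermediate parts may drop below `min_length` (the published
trace visits 30/10 and 25/15 with min_length 20); parts are clamped to
at least one base. Cost is logarithmic in the query length.

The classical baseline ("sw") estimates the boundary as the number of
query bases consumed by the one whole-query alignment.

## Alignment engine

Affine-gap local alignment is computed by a Gotoh three-matrix DP
(numba-compiled, float32; every cell value is an exact multiple of 0.5
far inside float32's exact range, so traceback equality tests are
exact). Deterministic tie-breaks, chosen because the original report
is silent on them: among equal-scoring end cells the smallest
(ref_end, query_end) lexicographically; during traceback diagonal over
gap-in-reference over gap-in-query, and gaps are closed as early as
possible. Coordinates in all reports are 1-based inclusive.

Scoring defaults reproduce the original tool: BLOSUM62 (its alphabet
contains A/C/G/T, so it is usable on DNA) with gap open 10 and gap
extend 0.5. A match +5 / mismatch −4 nucleotide matrix is bundled as
the alternative (`--matrix nuc`). `N` is scored 0 against everything —
it is an ambiguity placeholder in DNA, not asparagine — regardless of
the N row a protein matrix supplies.

Two consequences of this scoring are worth knowing. Uniform random DNA
has a *positive* expected BLOSUM62 self-score (+0.75/base), so chance
local alignments extend through unrelated sequence and the classical
baseline often consumes nearly the whole query — the large baseline
EDPE values the benchmark reports are a property of the scoring scheme,
faithfully reproduced, not an artifact. Second, with the cheap 0.5
extension, a large-deletion bridge is profitable whenever the smaller
fragment scores more than `open + (deletion−1)·extend`; the benchmark's
default minimum deletion of 1000 keeps bridging rare for queries under
1 kb on a 20 kb reference.

## Default parameters

| parameter | default | role |
|---|---|---|
| threshold | 0.9 | minimum acceptable similarity ratio per part (strict) |
| min_length | 20 bp | starting former length / initial split bound |
| gap open / extend | 10 / 0.5 | affine penalty magnitudes |
| matrix | BLOSUM62 | substitution scores |
| min_fragment | 20 bp | smallest planted fragment in simulations |
| min_deletion | 1000 bp | smallest planted deletion in simulations |

The threshold the original study used is not recorded. Analysis of its
worked example brackets it: the incremental scan returns boundary 27
only if the threshold exceeds 27/28 ≈ 0.964, while 0.9 makes the scan
overshoot deliberately (ratio `β/L` stays above 0.9 until `L ≈ β/0.9`).
The package default stays at 0.9; tests that reproduce the worked
example's incremental result use 0.97 and say so.

## What exact recovery can and cannot mean

For queries made of two *exact, unique* reference fragments whose
junction-flanking bases disagree (the generator's `guards=True` mode),
the incremental scan provably recovers the boundary exactly at a
threshold just under 1 (0.999 in the tests): every prefix up to the
boundary scores ratio exactly 1, and the first prefix past it cannot —
the flanking base disagrees and a one-base gap detour costs 10, more
than any single match can repay.

The binary search has no such guarantee. Its step schedule
`floor(l_query/2^(i+1))` is a fixed halving walk, not an interval
bisection; integer floors leave some offsets from `l_query/2` exactly
unreachable (for a 100-bp query starting at 50 with steps 25, 12, 6, 3,
1, a true boundary of 49 is never visited). At looser thresholds it
also stops at the first split whose two ratios clear the threshold,
which is generally near but not at the boundary. Both effects are
consistent with the original benchmark, which reports nonzero mean EDPE
for the binary strategy throughout while still finding it the most
accurate of the three. Tests therefore assert exact recovery for the
incremental scan, and for the binary search assert the trace dynamics
plus a majority exact-recovery rate rather than universality.

## The synthetic benchmark

The harness plants two-fragment queries in a reference: total length
uniform in a bin, split uniformly into two fragments of at least
`min_fragment`, former placed uniformly, latter uniformly among
downstream positions leaving at least `min_deletion` bases (the former
fragment is always upstream, so planted truths always have `b < c`).
An optional i.i.d. substitution rate (default 0) perturbs the query.
EDPE is computed per query and method against the planted boundary;
when a method reports no split boundary the whole-query alignment span
is used as its estimate, like the classical baseline. Per-bin means
use the sample standard deviation (n−1; reported as 0 for n = 1).
Wall-clock per query is recorded only on request so that same-seed
reruns are byte-identical.

The default acceptance-scale run uses the nine published length bins
(100–199 … 900–999), 20 queries per bin, a 20 kb uniform reference and
a 1% substitution rate — sizes chosen so the whole benchmark completes
in minutes on one core while leaving dozens of queries per comparison.
What it emulates is the *design* of the original experiment (random
two-fragment queries from a fixed reference, EDPE per length bin); what
it does not emulate is real mtDNA base composition and repeat
structure, the original's unknown threshold, or its absolute EDPE
values — so passing the ordering check (binary ≤ incremental ≤
classical in every bin) supports the methods' ranking, not the original
table's exact numbers.

The worked-example analog (`worked_example_analog`) rebuilds the 40-bp
demonstration on a seeded 500-bp uniform reference: exact unique 27+13
fragments at least 100 bp apart, with the construction verified by SW
runs (retrying deterministically) so that the visited splits behave as
published. For every seed it reproduces the split trace
20/20 → 30/10 → 25/15 → 27/13 and boundary 27.

## Degenerate inputs and conventions

* Queries shorter than `2·min_length`, thresholds outside (0, 1], and
  infeasible generator constraints raise a parameter error naming the
  violated bound.
* A part with no positive-scoring cell yields an "empty" alignment
  (ratio 0); searches treat it as a failed part, never crash.
* Latter part mapping at or before the former part's end: status
  `discordant_mapping` (order reversed) or `no_deletion_between_parts`
  (adjacent); no deletion interval is invented.
* If the very first scanned prefix is already below threshold the
  incremental search reports `not_converged` (there is no last
  acceptable length).

## Known limitations

* One breakpoint per query: multi-deletion queries are out of scope, as
  are insertions and read-mapper (SAM/BAM) integration.
* The similarity ratio saturates for gap-rich chance alignments under
  cheap gap extension (see above); interpreting absolute ratios
  requires keeping the scoring scheme in mind.
* The binary search inherits the published schedule's unreachable
  offsets; exact breakpoint recovery is a property of the incremental
  scan only.
* BLOSUM62-on-DNA is reproduced for fidelity, not recommended: the
  `nuc` matrix is the sensible choice for new nucleotide work.
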