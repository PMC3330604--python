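"""Shared fixtures and independent scoring oracles.

The oracles deliberately avoid the package's Gotoh recurrences: one is
an explicit-gap-length DP (every gap length tried directly), one is
Biopython's PairwiseAligner, and one is a tiny exhaustive path
enumerator.  All three are used only to check scores.
"""

import numpy as np
import pytest

from partialalign import ScoringScheme, Sequence

BASES = "ACGT"


@pytest.fixture(scope="session")
def blosum():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def nuc_scheme():
    return ScoringScheme.from_name("nuc")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def sw_score_explicit(q: str, r: str, scheme: ScoringScheme) -> float:
    """Explicit-gap-length local-alignment DP: a gap of length g is tried
    directly at cost open + (g-1)*extend, with no affine bookkeeping."""
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(q), len(r)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v = H[i - 1][j - 1] + scheme.score(q[i - 1], r[j - 1])
            for g in range(1, j + 1):
                v = max(v, H[i][j - g] - (go + (g - 1) * ge))
            for g in range(1, i + 1):
                v = max(v, H[i - g][j] - (go + (g - 1) * ge))
            v = max(v, 0.0)
            H[i][j] = v
            best = max(best, v)
    return best


def sw_score_biopython(q: str, r: str, scheme: ScoringScheme) -> float:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    arr = substitution_matrices.Array(alphabet=scheme.alphabet, dims=2)
    for a in scheme.alphabet:
        for b in scheme.alphabet:
            arr[a, b] = scheme.score(a, b)
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return float(aligner.score(q, r))


def _affine_alignment_score(columns, scheme: ScoringScheme) -> float:
    score = 0.0
    gap_side = None  # None | "q" | "r"
    for qc, rc in columns:
        if qc is None:
            score -= scheme.gap_open if gap_side != "q" else scheme.gap_extend
            gap_side = "q"
        elif rc is None:
            score -= scheme.gap_open if gap_side != "r" else scheme.gap_extend
            gap_side = "r"
        else:
            score += scheme.score(qc, rc)
            gap_side = None
    return score


def sw_score_exhaustive(q: str, r: str, scheme: ScoringScheme) -> float:
    """Enumerate every gapped alignment of every substring pair (feasible
    only for very short sequences)."""
    n, m = len(q), len(r)
    best = 0.0

    def rec(i, j, columns):
        nonlocal best
        if columns:
            best = max(best, _affine_alignment_score(columns, scheme))
        if i < n and j < m:
            rec(i + 1, j + 1, columns + [(q[i], r[j])])
        if columns:  # leading gaps never help a local alignment
            if i < n:
                rec(i + 1, j, columns + [(q[i], None)])
            if j < m:
                rec(i, j + 1, columns + [(None, r[j])])

    for i0 in range(n):
        for j0 in range(m):
            rec(i0, j0, [])
    return best


@pytest.fixture(scope="session")
def oracles():
    return {
        "explicit": sw_score_explicit,
        "biopython": sw_score_biopython,
        "exhaustive": sw_score_exhaustive,
    }


def pick_clean_two_fragment_ref(seed_start: int, ref_len: int, f1: tuple[int, int],
                                f2: tuple[int, int]) -> tuple[Sequence, str, str, int]:
    """Find a seeded uniform reference in which the two 1-based fragment
    intervals are unique substrings with mismatched junction-flanking
    bases; returns (reference, frag1, frag2, seed_used)."""
    from partialalign import synthetic_reference

    for seed in range(seed_start, seed_start + 100):
        ref = synthetic_reference(ref_len, seed)
        s = ref.residues
        a = s[f1[0] - 1:f1[1]]
        b = s[f2[0] - 1:f2[1]]
        if s.count(a) != 1 or s.count(b) != 1:
            continue
        if s[f1[1]] == b[0] or s[f2[0] - 2] == a[-1]:
            continue
        return ref, a, b, seed
    raise AssertionError("no clean seed found")
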