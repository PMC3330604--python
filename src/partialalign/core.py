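"""Partial sequence alignment for locating large deletions.

A query read that spans a large deletion cannot be placed by a single
Smith-Waterman (SW) local alignment: the optimal local alignment either
stops at the breakpoint or absorbs a ragged mix of gaps and chance
matches, so the estimated deletion position carries a large error
(EDPE, estimated deletion position error, in bp).  This module
implements the two split-search strategies built on top of SW that
divide the query into a "former" part (before the breakpoint) and a
"latter" part (after it), align each part to the full reference
separately, and read the deleted reference interval off the two
mappings:

* ``incremental_partial_align`` scans former-part lengths one base at a
  time, starting from a minimum length, until the part's similarity
  ratio drops below a threshold (IncrementalPartialAlign);
* ``binary_partial_align`` starts from an equal split and moves the
  split point by halving steps ``k_i = floor(l_query / 2**(i+1))``,
  lengthening whichever part currently aligns better, until both parts
  align above the threshold (BinaryPartialAlign).

If the former part maps to reference interval ``[a, b]`` and the latter
part to ``[c, d]`` with ``b < c``, the deleted interval is
``[b + 1, c - 1]`` and its length is ``c - b - 1``.

The similarity ratio of an alignment is the fraction of bases of the
full query (part) that are matched identically in its best local
alignment -- the denominator is the sequence length, not the aligned
span.  "Above the threshold" is a strict comparison throughout, which
is what makes the published 40-bp worked example (split trace
20/20 -> 30/10 -> 25/15 -> 27/13) come out right: at the 30/10 split
the former part has ratio exactly 27/30 = 0.9 and must count as *not*
above a 0.9 threshold.

A benchmarking harness (`run_benchmark`) generates two-fragment
"deleted" queries from a reference and aggregates EDPE per query-length
bin for the classical single-SW baseline and the two split strategies.
"""

from __future__ import annotations

import io
import json
import logging
import time
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence as TSequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from numba import njit

logger = logging.getLogger("partialalign")

# ---------------------------------------------------------------------------
# Defaults (scoring scheme of the original tool: BLOSUM62, affine gaps
# open 10 / extend 0.5; a gap of length L costs open + (L-1)*extend).
# ---------------------------------------------------------------------------

DEFAULT_MATRIX = "blosum62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_THRESHOLD = 0.9
DEFAULT_MIN_LENGTH = 20
DEFAULT_MIN_FRAGMENT = 20
DEFAULT_MIN_DELETION = 1000

RESULT_TSV_VERSION = "partialalign-tsv-v1"

METHOD_SW = "sw"
METHOD_INCREMENTAL = "incremental"
METHOD_BINARY = "binary"
METHODS = (METHOD_SW, METHOD_INCREMENTAL, METHOD_BINARY)

# status values carried by PartialAlignmentResult
STATUS_DELETION = "deletion"
STATUS_BASELINE = "sw_baseline"
STATUS_NO_DELETION = "no_deletion"
STATUS_ADJACENT = "no_deletion_between_parts"
STATUS_DISCORDANT = "discordant_mapping"
STATUS_NOT_CONVERGED = "not_converged"


class PartialAlignError(Exception):
    """Base class for errors raised by this package."""


class MatrixFormatError(PartialAlignError):
    """Malformed substitution-matrix text (carries a line number)."""


class AlignmentInputError(PartialAlignError):
    """A sequence cannot be scored under the active scheme."""


class ParameterError(PartialAlignError):
    """Infeasible or inconsistent parameters."""


class NoDeletionBetweenParts(PartialAlignError):
    """The two part mappings are adjacent or overlapping: no deleted
    interval lies between them."""


# ---------------------------------------------------------------------------
# Sequences and FASTA I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sequence:
    """A named residue string (query or reference), stored uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParameterError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def prefix(self, length: int) -> "Sequence":
        """First ``length`` residues, 1-based inclusive."""
        return Sequence(f"{self.id}[1..{length}]", self.residues[:length])

    def suffix_from(self, start: int) -> "Sequence":
        """Residues from 1-based position ``start`` to the end."""
        return Sequence(f"{self.id}[{start}..{len(self)}]", self.residues[start - 1:])


def read_fasta(path: Union[str, Path]) -> list[Sequence]:
    """Read a (multi-record) FASTA file; residues are uppercased on load."""
    path = Path(path)
    records = [Sequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParameterError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[Sequence], path: Union[str, Path], width: int = 70) -> None:
    """Write records wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Substitution matrices and scoring scheme
# ---------------------------------------------------------------------------


def parse_substitution_matrix(text: str) -> dict[tuple[str, str], float]:
    """Parse a whitespace-delimited NCBI/EMBOSS-style matrix.

    The first non-comment line is the header row of symbols; each
    following line is a row label plus one score per header symbol.
    Lines starting with ``#`` are ignored.  The matrix must be square,
    complete and symmetric.
    """
    header: list[str] = []
    matrix: dict[tuple[str, str], float] = {}
    row_labels: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not header:
            if any(len(tok) != 1 for tok in fields):
                raise MatrixFormatError(f"line {lineno}: header symbols must be single characters")
            header = [tok.upper() for tok in fields]
            continue
        label = fields[0].upper()
        if len(label) != 1:
            raise MatrixFormatError(f"line {lineno}: row label {fields[0]!r} is not a single symbol")
        values = fields[1:]
        if len(values) != len(header):
            raise MatrixFormatError(
                f"line {lineno}: expected {len(header)} scores for row {label!r}, got {len(values)}"
            )
        row_labels.append(label)
        for col, tok in zip(header, values):
            try:
                matrix[(label, col)] = float(tok)
            except ValueError as exc:
                raise MatrixFormatError(f"line {lineno}: bad score {tok!r}") from exc
    if not header:
        raise MatrixFormatError("line 1: no header row found")
    if sorted(row_labels) != sorted(header):
        raise MatrixFormatError(
            f"row labels {row_labels} do not cover the header symbols {header}"
        )
    for a in header:
        for b in header:
            if matrix[(a, b)] != matrix[(b, a)]:
                raise MatrixFormatError(
                    f"matrix is asymmetric: score({a},{b})={matrix[(a, b)]} "
                    f"!= score({b},{a})={matrix[(b, a)]}"
                )
    return matrix


def load_substitution_matrix(text: str) -> dict[tuple[str, str], float]:
    """Alias for :func:`parse_substitution_matrix` (text contents in)."""
    return parse_substitution_matrix(text)


def builtin_matrix_text(name: str) -> str:
    """Return the packaged matrix text for ``blosum62`` or ``nuc``."""
    fname = {"blosum62": "BLOSUM62.txt", "nuc": "NUC.txt"}.get(name.lower())
    if fname is None:
        raise ParameterError(f"unknown builtin matrix {name!r} (choose blosum62 or nuc)")
    return resources.files("partialalign").joinpath("data", fname).read_text()


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalty magnitudes.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the
    first gap column pays the opening penalty only).  'N' residues are
    scored 0 against everything, regardless of any 'N' row in the file
    (BLOSUM62's N is asparagine, not an ambiguous nucleotide).
    """

    matrix: dict[tuple[str, str], float]
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ParameterError(
                f"require gap_open >= gap_extend >= 0, got {self.gap_open}, {self.gap_extend}"
            )
        symbols = sorted({a for a, _ in self.matrix})
        for a, b in self.matrix:
            if self.matrix[(a, b)] != self.matrix[(b, a)]:
                raise ParameterError(f"matrix is asymmetric at ({a},{b})")
        if "N" not in symbols:
            symbols.append("N")
        self._alphabet = "".join(symbols)
        self._index = {c: i for i, c in enumerate(self._alphabet)}
        arr = np.zeros((len(symbols), len(symbols)), dtype=np.float32)
        for (a, b), v in self.matrix.items():
            arr[self._index[a], self._index[b]] = v
        n = self._index["N"]
        arr[n, :] = 0.0  # neutral ambiguity code
        arr[:, n] = 0.0
        self._array = arr

    @property
    def alphabet(self) -> str:
        return self._alphabet

    def score(self, a: str, b: str) -> float:
        if "N" in (a, b):
            return 0.0
        return self.matrix[(a, b)]

    def encode(self, seq: Sequence) -> np.ndarray:
        out = np.empty(len(seq), dtype=np.int8)
        for i, c in enumerate(seq.residues):
            idx = self._index.get(c)
            if idx is None:
                raise AlignmentInputError(
                    f"residue {c!r} at position {i + 1} of {seq.id!r} "
                    f"is not scoreable under the active matrix (alphabet {self._alphabet})"
                )
            out[i] = idx
        return out

    @classmethod
    def from_text(cls, text: str, gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND) -> "ScoringScheme":
        return cls(parse_substitution_matrix(text), gap_open, gap_extend)

    @classmethod
    def from_name(cls, name_or_path: str = DEFAULT_MATRIX,
                  gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND) -> "ScoringScheme":
        """Builtin name (``blosum62``, ``nuc``) or a path to a matrix file."""
        if name_or_path.lower() in ("blosum62", "nuc"):
            text = builtin_matrix_text(name_or_path)
        else:
            text = Path(name_or_path).read_text()
        return cls.from_text(text, gap_open, gap_extend)

    @classmethod
    def blosum62(cls, gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> "ScoringScheme":
        return cls.from_name("blosum62", gap_open, gap_extend)


# ---------------------------------------------------------------------------
# Smith-Waterman kernels (Gotoh affine-gap DP, float32; all cell values
# are exact multiples of 0.5 well inside float32's exact-integer range,
# so equality tests in the traceback are exact).
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_matrices(q, r, sub, go, ge):
    n = q.shape[0]
    m = r.shape[0]
    NEG = np.float32(-1e30)
    H = np.zeros((n + 1, m + 1), np.float32)
    E = np.full((n + 1, m + 1), NEG, np.float32)  # gap in query row (consumes reference)
    F = np.full((n + 1, m + 1), NEG, np.float32)  # gap in reference row (consumes query)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            t = E[i, j - 1] - ge
            if t > e:
                e = t
            E[i, j] = e
            f = H[i - 1, j] - go
            t = F[i - 1, j] - ge
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, r[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _argmax_cell(H, rows):
    # Deterministic tie-break: among equal maxima pick the smallest
    # (ref_end, query_end) lexicographically.
    best = np.float32(0.0)
    bi = 0
    bj = 0
    m = H.shape[1] - 1
    for j in range(1, m + 1):
        for i in range(1, rows + 1):
            v = H[i, j]
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _traceback(H, E, F, q, r, sub, go, ge, i, j):
    """Trace one optimal path from H cell (i, j) back to its local start.

    Returns (qa, ra, matches, i0, j0): qa/ra hold 0-based residue indices
    into query/reference, -1 marking a gap, emitted in reverse order;
    the alignment covers query[i0+1..i], reference[j0+1..j] (1-based).

    Tie-breaks: diagonal over gap-in-reference over gap-in-query; a gap
    is closed as soon as the scores allow it.
    """
    cap = i + j + 2
    qa = np.empty(cap, np.int32)
    ra = np.empty(cap, np.int32)
    k = 0
    matches = 0
    state = 0  # 0 = H, 1 = E (gap in query row), 2 = F (gap in reference row)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == np.float32(0.0):
                break
            if h == H[i - 1, j - 1] + sub[q[i - 1], r[j - 1]]:
                qa[k] = i - 1
                ra[k] = j - 1
                if q[i - 1] == r[j - 1]:
                    matches += 1
                k += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:
            qa[k] = i - 1
            ra[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:
            qa[k] = -1
            ra[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    return qa[:k], ra[:k], matches, i, j


@njit(cache=True)
def _prefix_scan(q, r, sub, go, ge, min_len, max_len, threshold):
    """Evaluate SW alignments of query prefixes of length min_len..max_len.

    The DP matrix of a prefix is the top slice of the full matrix, so one
    incremental fill serves every prefix; per-prefix optima and match
    counts are identical to independent SW runs (same tie-breaks).

    Stops at the first prefix whose similarity ratio (matches / prefix
    length) falls strictly below the threshold, given as an integer
    rational ``(numerator, denominator)`` so the strict comparison is
    exact.  Returns
    (n_evaluated, stopped, scores, matches, qs, qe, rs, re) where arrays
    are indexed by L - min_len for the evaluated prefixes.
    """
    m = r.shape[0]
    NEG = np.float32(-1e30)
    H = np.zeros((max_len + 1, m + 1), np.float32)
    E = np.full((max_len + 1, m + 1), NEG, np.float32)
    F = np.full((max_len + 1, m + 1), NEG, np.float32)
    count = max_len - min_len + 1
    scores = np.zeros(count, np.float32)
    matches_arr = np.zeros(count, np.int64)
    qs_arr = np.zeros(count, np.int64)
    qe_arr = np.zeros(count, np.int64)
    rs_arr = np.zeros(count, np.int64)
    re_arr = np.zeros(count, np.int64)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    thr_num = np.int64(threshold[0])
    thr_den = np.int64(threshold[1])
    n_eval = 0
    stopped = False
    for i in range(1, max_len + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            t = E[i, j - 1] - ge
            if t > e:
                e = t
            E[i, j] = e
            f = H[i - 1, j] - go
            t = F[i - 1, j] - ge
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, r[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
        # fold row i into the running argmax (smallest (j, i) on ties:
        # an equal value in a later row never displaces the incumbent,
        # a strictly smaller column does)
        for j in range(1, m + 1):
            v = H[i, j]
            if v > best or (v == best and v > np.float32(0.0) and j < bj):
                best = v
                bi = i
                bj = j
        if i < min_len:
            continue
        idx = i - min_len
        if best > np.float32(0.0):
            qa, ra, matches, i0, j0 = _traceback(H, E, F, q, r, sub, go, ge, bi, bj)
            scores[idx] = best
            matches_arr[idx] = matches
            qs_arr[idx] = i0 + 1
            qe_arr[idx] = bi
            rs_arr[idx] = j0 + 1
            re_arr[idx] = bj
        n_eval = idx + 1
        # exact rational comparison: matches / L < thr_num / thr_den
        if matches_arr[idx] * thr_den < thr_num * i:
            stopped = True
            break
    return n_eval, stopped, scores, matches_arr, qs_arr, qe_arr, rs_arr, re_arr


# ---------------------------------------------------------------------------
# Local alignment API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    """One Smith-Waterman result.  Coordinates are 1-based inclusive.

    ``similarity_ratio`` divides the identity count by the *full* length
    of the query sequence that was aligned, not by the aligned span.
    An all-zero score (no positive-scoring cell) yields an "empty"
    alignment with ``matches == 0`` and zeroed coordinates.
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    aligned_query: str
    aligned_ref: str
    score: float
    matches: int
    similarity_ratio: float

    @property
    def is_empty(self) -> bool:
        return self.matches == 0 and self.score == 0.0

    @property
    def query_span(self) -> int:
        """Number of query bases consumed by the alignment."""
        if self.is_empty:
            return 0
        return self.query_end - self.query_start + 1


def smith_waterman(query: Sequence, reference: Sequence,
                   scheme: Optional[ScoringScheme] = None) -> LocalAlignment:
    """Optimal local alignment of ``query`` against ``reference``.

    Affine gap scoring: a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  Ties are broken
    deterministically (see :class:`LocalAlignment` and the traceback
    kernel).  Raises :class:`AlignmentInputError` for residues absent
    from the scheme's alphabet.
    """
    scheme = scheme or ScoringScheme.blosum62()
    q = scheme.encode(query)
    r = scheme.encode(reference)
    go = np.float32(scheme.gap_open)
    ge = np.float32(scheme.gap_extend)
    H, E, F = _fill_matrices(q, r, scheme._array, go, ge)
    best, bi, bj = _argmax_cell(H, len(q))
    if best <= 0.0:
        return LocalAlignment(0, 0, 0, 0, "", "", 0.0, 0, 0.0)
    qa, ra, matches, i0, j0 = _traceback(H, E, F, q, r, scheme._array, go, ge, bi, bj)
    alpha = scheme.alphabet
    aq = "".join("-" if x < 0 else alpha[q[x]] for x in qa[::-1])
    ar = "".join("-" if x < 0 else alpha[r[x]] for x in ra[::-1])
    return LocalAlignment(
        query_start=i0 + 1, query_end=int(bi),
        ref_start=j0 + 1, ref_end=int(bj),
        aligned_query=aq, aligned_ref=ar,
        score=float(best), matches=int(matches),
        similarity_ratio=matches / len(query),
    )


def similarity_ratio(alignment: LocalAlignment, query_length: int) -> float:
    """Fraction of the full query matched identically: matches / query_length."""
    if query_length < 1:
        raise ParameterError(f"query_length must be >= 1, got {query_length}")
    if alignment.matches > query_length:
        raise ParameterError(
            f"inconsistent inputs: {alignment.matches} matches for a "
            f"query of length {query_length}"
        )
    return alignment.matches / query_length


def classical_sw_boundary(query: Sequence, reference: Sequence,
                          scheme: Optional[ScoringScheme] = None) -> int:
    """Baseline deletion-position estimate from one whole-query SW run:
    the number of query bases consumed by the optimal local alignment."""
    return smith_waterman(query, reference, scheme).query_span


# ---------------------------------------------------------------------------
# Deletion calling and EDPE
# ---------------------------------------------------------------------------


class Deletion(NamedTuple):
    start: int  # b + 1
    end: int    # c - 1
    length: int  # c - b - 1


def call_deletion(former_ref_end: int, latter_ref_start: int) -> Deletion:
    """Deleted reference interval between the two part mappings.

    With the former part ending at reference base ``b`` and the latter
    part starting at ``c`` (1-based), the deletion is ``[b+1, c-1]`` of
    length ``c - b - 1``.  Raises :class:`NoDeletionBetweenParts` when
    the mappings are adjacent or out of order (``c <= b + 1``).
    """
    b, c = former_ref_end, latter_ref_start
    if c <= b + 1:
        raise NoDeletionBetweenParts(
            f"no deletion between parts: former ends at {b}, latter starts at {c}"
        )
    return Deletion(b + 1, c - 1, c - b - 1)


def edpe(estimated_boundary: int, true_boundary: int) -> int:
    """Estimated deletion position error, |estimated - true|, in bp."""
    return abs(int(estimated_boundary) - int(true_boundary))


def step_size(query_length: int, iteration: int) -> int:
    """Split-shift step of the binary strategy: floor(l_query / 2**(i+1)).

    Returns 0 once the floor reaches 0, which signals termination.
    """
    if iteration < 1:
        raise ParameterError(f"iteration must be >= 1, got {iteration}")
    return query_length // (2 ** (iteration + 1))


# ---------------------------------------------------------------------------
# Split-search strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitState:
    """One visited former/latter split (lengths sum to the query length).

    ``step`` is the shift computed *at* this iteration (1 for the
    incremental scan); a ratio is ``None`` if that part was not aligned
    at this split.
    """

    iteration: int
    former_length: int
    latter_length: int
    step: int
    former_ratio: Optional[float]
    latter_ratio: Optional[float]


@dataclass
class PartialAlignmentResult:
    """Outcome of one deletion search on a single query."""

    method: str
    query_id: str
    query_length: int
    status: str
    no_deletion: bool
    sw_calls: int
    full_ratio: Optional[float] = None
    full_alignment: Optional[LocalAlignment] = None
    boundary_estimate: Optional[int] = None
    former: Optional[LocalAlignment] = None
    latter: Optional[LocalAlignment] = None
    deletion_ref_start: Optional[int] = None
    deletion_ref_end: Optional[int] = None
    deletion_length: Optional[int] = None
    trace: list[SplitState] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.status in (STATUS_DELETION, STATUS_NO_DELETION,
                               STATUS_ADJACENT, STATUS_DISCORDANT)

    def fallback_boundary(self) -> int:
        """Boundary estimate with the classical-SW fallback: when the
        search produced no split boundary, use the query bases consumed
        by the whole-query alignment."""
        if self.boundary_estimate is not None:
            return self.boundary_estimate
        if self.full_alignment is not None:
            return self.full_alignment.query_span
        return 0

    def to_row(self) -> dict:
        f, l = self.former, self.latter
        return {
            "query_id": self.query_id,
            "method": self.method,
            "status": self.status,
            "query_length": self.query_length,
            "boundary": self.boundary_estimate,
            "a": f.ref_start if f else None,
            "b": f.ref_end if f else None,
            "c": l.ref_start if l else None,
            "d": l.ref_end if l else None,
            "deletion_start": self.deletion_ref_start,
            "deletion_end": self.deletion_ref_end,
            "deletion_length": self.deletion_length,
            "former_ratio": round(f.similarity_ratio, 6) if f else None,
            "latter_ratio": round(l.similarity_ratio, 6) if l else None,
            "full_ratio": round(self.full_ratio, 6) if self.full_ratio is not None else None,
            "sw_calls": self.sw_calls,
        }

    def to_json_dict(self) -> dict:
        d = self.to_row()
        d["trace"] = [
            {
                "iteration": s.iteration,
                "former_length": s.former_length,
                "latter_length": s.latter_length,
                "step": s.step,
                "former_ratio": s.former_ratio,
                "latter_ratio": s.latter_ratio,
            }
            for s in self.trace
        ]
        return d


def _threshold_fraction(threshold: float) -> Fraction:
    """Interpret a threshold at its printed decimal value (0.9 means
    exactly 9/10), so that strict above/below comparisons against exact
    match ratios are not distorted by binary floating point."""
    return Fraction(str(threshold))


def _check_split_params(query: Sequence, threshold: float, min_length: int) -> None:
    if min_length < 1:
        raise ParameterError(f"min_length must be >= 1, got {min_length}")
    if 2 * min_length > len(query):
        raise ParameterError(
            f"query {query.id!r} of length {len(query)} is shorter than "
            f"2 * min_length = {2 * min_length}"
        )
    if not (0 < threshold <= 1):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")


def _finish_with_parts(res: PartialAlignmentResult, boundary: int,
                       former: LocalAlignment, latter: LocalAlignment,
                       converged: bool) -> PartialAlignmentResult:
    """Fill boundary/deletion fields from the two part alignments."""
    res.boundary_estimate = boundary
    res.former = former
    res.latter = latter
    if former.is_empty or latter.is_empty:
        res.status = STATUS_NOT_CONVERGED
        return res
    b, c = former.ref_end, latter.ref_start
    try:
        deletion = call_deletion(b, c)
    except NoDeletionBetweenParts:
        if converged:
            res.status = STATUS_DISCORDANT if c <= b else STATUS_ADJACENT
        else:
            res.status = STATUS_NOT_CONVERGED
        return res
    res.deletion_ref_start = deletion.start
    res.deletion_ref_end = deletion.end
    res.deletion_length = deletion.length
    res.status = STATUS_DELETION if converged else STATUS_NOT_CONVERGED
    return res


def incremental_partial_align(query: Sequence, reference: Sequence,
                              threshold: float = DEFAULT_THRESHOLD,
                              min_length: int = DEFAULT_MIN_LENGTH,
                              scheme: Optional[ScoringScheme] = None) -> PartialAlignmentResult:
    """IncrementalPartialAlign: scan former-part lengths one base at a time.

    After a whole-query alignment (no deletion if its similarity ratio is
    strictly above ``threshold``), former-part lengths
    L = min_length, min_length + 1, ... are aligned until the ratio first
    drops strictly below ``threshold`` at some L*; the boundary estimate
    is L* - 1 (the last length that still aligned acceptably), and the
    remaining latter part is aligned to call the deletion.

    The prefix alignments are computed with a shared DP fill that yields
    results identical to independent SW runs; ``sw_calls`` counts the
    logical SW invocations (one per evaluated prefix, plus the full-query
    and latter-part runs).
    """
    scheme = scheme or ScoringScheme.blosum62()
    _check_split_params(query, threshold, min_length)
    thr = _threshold_fraction(threshold)
    lq = len(query)
    res = PartialAlignmentResult(
        method=METHOD_INCREMENTAL, query_id=query.id, query_length=lq,
        status=STATUS_NO_DELETION, no_deletion=False, sw_calls=0,
    )
    full = smith_waterman(query, reference, scheme)
    res.sw_calls += 1
    res.full_ratio = full.similarity_ratio
    res.full_alignment = full
    if Fraction(full.matches, lq) > thr:
        res.no_deletion = True
        return res

    q = scheme.encode(query)
    r = scheme.encode(reference)
    # the former part may grow until only one base is left for the latter
    # part: the published 40-bp example (min_length 20) stops at L* = 28,
    # past l_query - min_length, so min_length bounds only the start
    max_len = lq - 1
    n_eval, stopped, scores, matches, qs, qe, rs, re = _prefix_scan(
        q, r, scheme._array, np.float32(scheme.gap_open), np.float32(scheme.gap_extend),
        min_length, max_len, (thr.numerator, thr.denominator),
    )
    res.sw_calls += int(n_eval)
    for idx in range(n_eval):
        L = min_length + idx
        res.trace.append(SplitState(
            iteration=idx + 1, former_length=L, latter_length=lq - L, step=1,
            former_ratio=float(matches[idx]) / L, latter_ratio=None,
        ))
    if not stopped:
        # every prefix in range aligned acceptably: no deletion found
        res.no_deletion = True
        return res
    l_star = min_length + n_eval - 1
    boundary = l_star - 1
    if boundary < 1:
        # the very first prefix was already below threshold and no former
        # part can be reported; flag rather than raise
        res.status = STATUS_NOT_CONVERGED
        return res
    # the prefix at `boundary` was already evaluated during the scan; this
    # re-derivation only materializes its aligned strings
    former = smith_waterman(query.prefix(boundary), reference, scheme)
    latter = smith_waterman(query.suffix_from(boundary + 1), reference, scheme)
    res.sw_calls += 1
    return _finish_with_parts(res, boundary, former, latter, converged=True)


def binary_partial_align(query: Sequence, reference: Sequence,
                         threshold: float = DEFAULT_THRESHOLD,
                         min_length: int = DEFAULT_MIN_LENGTH,
                         scheme: Optional[ScoringScheme] = None) -> PartialAlignmentResult:
    """BinaryPartialAlign: move the split point by halving steps.

    Starting from an equal split, each iteration aligns both parts; the
    search terminates when both similarity ratios are strictly above
    ``threshold``, otherwise it lengthens the part with the larger ratio
    (ties lengthen the former part) by ``step_size(l_query, i)`` and
    increments ``i``.  When the step reaches 0, or a move makes no
    progress, the best split seen so far -- the one maximizing
    min(former_ratio, latter_ratio) -- is reported with a
    ``not_converged`` status.

    ``min_length`` bounds the initial split and the input precondition
    only; intermediate splits may evaluate shorter parts, exactly as in
    the published 40-bp trace (20/20 -> 30/10 -> 25/15 -> 27/13).
    """
    scheme = scheme or ScoringScheme.blosum62()
    _check_split_params(query, threshold, min_length)
    thr = _threshold_fraction(threshold)
    lq = len(query)
    res = PartialAlignmentResult(
        method=METHOD_BINARY, query_id=query.id, query_length=lq,
        status=STATUS_NO_DELETION, no_deletion=False, sw_calls=0,
    )
    full = smith_waterman(query, reference, scheme)
    res.sw_calls += 1
    res.full_ratio = full.similarity_ratio
    res.full_alignment = full
    if Fraction(full.matches, lq) > thr:
        res.no_deletion = True
        return res

    f = lq // 2
    f = min(max(f, min_length), lq - min_length)
    i = 1
    best_min = Fraction(-1)
    best: Optional[tuple[int, LocalAlignment, LocalAlignment]] = None
    while True:
        former = smith_waterman(query.prefix(f), reference, scheme)
        latter = smith_waterman(query.suffix_from(f + 1), reference, scheme)
        res.sw_calls += 2
        fr = Fraction(former.matches, f)
        lr = Fraction(latter.matches, lq - f)
        k = step_size(lq, i)
        res.trace.append(SplitState(
            iteration=i, former_length=f, latter_length=lq - f, step=k,
            former_ratio=float(fr), latter_ratio=float(lr),
        ))
        if min(fr, lr) > best_min:
            best_min = min(fr, lr)
            best = (f, former, latter)
        if fr > thr and lr > thr:
            return _finish_with_parts(res, f, former, latter, converged=True)
        if k == 0:
            break
        f_new = f + k if fr >= lr else f - k
        f_new = min(max(f_new, 1), lq - 1)
        if f_new == f:
            break  # clamped move makes no progress
        f = f_new
        i += 1
    assert best is not None
    return _finish_with_parts(res, best[0], best[1], best[2], converged=False)


def find_deletion(query: Sequence, reference: Sequence, method: str = METHOD_BINARY,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_length: int = DEFAULT_MIN_LENGTH,
                  scheme: Optional[ScoringScheme] = None) -> PartialAlignmentResult:
    """Dispatch one query to a deletion-search method (``sw`` is the
    classical whole-query baseline: boundary only, no deletion interval)."""
    if method == METHOD_INCREMENTAL:
        return incremental_partial_align(query, reference, threshold, min_length, scheme)
    if method == METHOD_BINARY:
        return binary_partial_align(query, reference, threshold, min_length, scheme)
    if method == METHOD_SW:
        full = smith_waterman(query, reference, scheme)
        res = PartialAlignmentResult(
            method=METHOD_SW, query_id=query.id, query_length=len(query),
            status=STATUS_BASELINE, no_deletion=False, sw_calls=1,
            full_ratio=full.similarity_ratio, full_alignment=full,
            boundary_estimate=full.query_span,
        )
        return res
    raise ParameterError(f"unknown method {method!r}; choose one of {METHODS}")


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "query_id", "method", "status", "query_length", "boundary",
    "a", "b", "c", "d", "deletion_start", "deletion_end", "deletion_length",
    "former_ratio", "latter_ratio", "full_ratio", "sw_calls",
]


def results_to_tsv(results: Iterable[PartialAlignmentResult],
                   header_comments: Iterable[str] = ()) -> str:
    buf = io.StringIO()
    buf.write(f"# {RESULT_TSV_VERSION}\n")
    for c in header_comments:
        buf.write(f"# {c}\n")
    frame = pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)
    frame.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def results_to_json(results: Iterable[PartialAlignmentResult]) -> str:
    return json.dumps([r.to_json_dict() for r in results], indent=2)


# ---------------------------------------------------------------------------
# Synthetic data: references and two-fragment "deleted" queries
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def synthetic_reference(length: int, seed: int, id: str = "synthetic_ref") -> Sequence:
    """Uniform i.i.d. A/C/G/T sequence from a seeded generator."""
    if length < 1:
        raise ParameterError(f"reference length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length)
    return Sequence(id, "".join(_BASES[i] for i in idx))


@dataclass(frozen=True)
class QueryTruth:
    """Ground truth for a simulated two-fragment query (1-based reference
    coordinates).  ``true_boundary`` is the former fragment's length;
    ``true_deletion_length`` applies the deletion-interval formula to the
    planted coordinates."""

    former_ref_start: int
    former_ref_end: int
    latter_ref_start: int
    latter_ref_end: int
    true_boundary: int
    true_deletion_length: int


def _rng_from(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_query(reference: Sequence, length_range: tuple[int, int],
               min_fragment: int = DEFAULT_MIN_FRAGMENT,
               min_deletion: int = DEFAULT_MIN_DELETION,
               rng: Union[int, np.random.Generator] = 0,
               substitution_rate: float = 0.0,
               guards: bool = False,
               query_id: str = "query") -> tuple[Sequence, QueryTruth]:
    """Concatenate two reference fragments into one "deleted" query.

    The total query length is drawn uniformly from ``length_range``, split
    uniformly into two fragment lengths each >= ``min_fragment``; the
    former fragment is placed uniformly and the latter uniformly among
    downstream positions leaving a gap >= ``min_deletion`` (the former
    fragment is always upstream, so the truth always has b < c).

    ``substitution_rate`` mutates query bases i.i.d. after extraction
    (robustness testing; fragments are exact copies by default).

    ``guards=True`` retries the placement (deterministically) until both
    fragments occur exactly once in the reference and the bases flanking
    the junction disagree with their query-side counterparts
    (``ref[b+1] != query[boundary+1]`` and ``ref[c-1] != query[boundary]``),
    so the planted boundary is the unique exactly-recoverable answer.
    """
    rng = _rng_from(rng)
    lo, hi = length_range
    if lo > hi or lo < 2 * min_fragment:
        raise ParameterError(
            f"length_range {length_range} infeasible: need lo <= hi and lo >= "
            f"2 * min_fragment = {2 * min_fragment}"
        )
    R = len(reference)
    total = int(rng.integers(lo, hi + 1))
    former_len = int(rng.integers(min_fragment, total - min_fragment + 1))
    latter_len = total - former_len
    span_needed = total + min_deletion
    if R < span_needed:
        raise ParameterError(
            f"reference of length {R} cannot host a {total} bp query plus a "
            f"deletion >= {min_deletion} (needs >= {span_needed})"
        )
    ref = reference.residues
    for _ in range(1000):
        s1 = int(rng.integers(0, R - span_needed + 1))  # 0-based former start
        e1 = s1 + former_len  # 0-based exclusive
        s2 = int(rng.integers(e1 + min_deletion, R - latter_len + 1))
        frag1 = ref[s1:e1]
        frag2 = ref[s2:s2 + latter_len]
        if guards:
            if ref.count(frag1) != 1 or ref.count(frag2) != 1:
                continue
            if ref[e1] == frag2[0]:  # former mapping could extend right
                continue
            if ref[s2 - 1] == frag1[-1]:  # latter mapping could extend left
                continue
        break
    else:
        raise ParameterError("could not place guarded fragments; reference too repetitive")
    qstr = frag1 + frag2
    if substitution_rate > 0:
        chars = list(qstr)
        for i in range(len(chars)):
            if rng.random() < substitution_rate:
                chars[i] = _BASES[(_BASES.index(chars[i]) + int(rng.integers(1, 4))) % 4]
        qstr = "".join(chars)
    truth = QueryTruth(
        former_ref_start=s1 + 1, former_ref_end=e1,
        latter_ref_start=s2 + 1, latter_ref_end=s2 + latter_len,
        true_boundary=former_len,
        true_deletion_length=(s2 + 1) - e1 - 1,
    )
    return Sequence(query_id, qstr), truth


def worked_example_analog(seed: int, ref_length: int = 500,
                          former_len: int = 27, latter_len: int = 13,
                          min_deletion: int = 100,
                          scheme: Optional[ScoringScheme] = None,
                          ) -> tuple[Sequence, Sequence, QueryTruth]:
    """Synthetic analog of the 40-bp worked example: a seeded uniform
    reference and a query of two exact unique fragments (27 + 13 bp by
    default) separated by at least ``min_deletion`` bases.

    The construction is verified by actual SW runs so that the splits the
    search strategies visit behave as in the published example: fragments
    are unique in the reference, junction-flanking bases disagree, query
    prefixes one and three bases past the true boundary pick up no extra
    matches, and the latter-part alignments at the visited splits gain no
    chance matches that would lift their similarity ratio over the
    threshold.  Attempts are retried deterministically until the contract
    holds, so for every seed the returned query reproduces the
    20/20 -> 30/10 -> 25/15 -> 27/13 trace at threshold 0.9 (and boundary
    recovery by the incremental scan at thresholds up to 27/28).
    Returns (reference, query, truth).
    """
    scheme = scheme or ScoringScheme.blosum62()
    total = former_len + latter_len
    span_needed = total + min_deletion
    if ref_length < span_needed:
        raise ParameterError(
            f"reference of {ref_length} bp cannot host {total} bp of fragments "
            f"plus a deletion >= {min_deletion}"
        )
    for attempt in range(500):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        ref_str = "".join(_BASES[i] for i in rng.integers(0, 4, ref_length))
        ref = Sequence("synthetic_ref", ref_str)
        s1 = int(rng.integers(0, ref_length - span_needed + 1))
        e1 = s1 + former_len
        s2 = int(rng.integers(e1 + min_deletion, ref_length - latter_len + 1))
        frag1 = ref_str[s1:e1]
        frag2 = ref_str[s2:s2 + latter_len]
        if ref_str.count(frag1) != 1 or ref_str.count(frag2) != 1:
            continue
        if ref_str[e1] == frag2[0] or ref_str[s2 - 1] == frag1[-1]:
            continue
        query = Sequence("worked_example_query", frag1 + frag2)
        truth = QueryTruth(
            former_ref_start=s1 + 1, former_ref_end=e1,
            latter_ref_start=s2 + 1, latter_ref_end=s2 + latter_len,
            true_boundary=former_len,
            true_deletion_length=(s2 + 1) - e1 - 1,
        )
        # prefixes just past the boundary must not gain chance matches
        # (fixes the ratio sequence 27/28, 27/30 the searches rely on)
        ok = all(
            smith_waterman(query.prefix(L), ref, scheme).matches == former_len
            for L in (former_len + 1, former_len + 3)
        )
        if ok:
            # latter parts at the visited splits: no chance matches that
            # would lift the ratio above the threshold (13/20 split), and
            # none at all two bases before the boundary (25/15 split)
            half = total // 2
            near = smith_waterman(query.suffix_from(former_len - 1), ref, scheme)
            far = smith_waterman(query.suffix_from(half + 1), ref, scheme)
            ok = (near.matches == latter_len
                  and Fraction(far.matches, total - half) <= _threshold_fraction(DEFAULT_THRESHOLD))
        if ok:
            full = smith_waterman(query, ref, scheme)
            ok = Fraction(full.matches, total) <= _threshold_fraction(DEFAULT_THRESHOLD)
        if ok:
            return ref, query, truth
    raise ParameterError("could not construct a worked-example analog (seed exhausted)")


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethodStats:
    """Per-bin EDPE and runtime summary for one method.  Runtime fields
    are informational and excluded from equality so that identical seeds
    compare equal."""

    mean_edpe: float
    sd_edpe: float
    total_sw_calls: int
    mean_runtime_ms: float = field(compare=False, default=0.0)
    sd_runtime_ms: float = field(compare=False, default=0.0)


@dataclass(frozen=True)
class BinStats:
    bin_low: int
    bin_high: int
    n: int
    methods: tuple[tuple[str, MethodStats], ...]

    def stats(self, method: str) -> MethodStats:
        return dict(self.methods)[method]


def _mean_sd(values: TSequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0  # single-sample convention
    return mean, sd


def run_benchmark(reference: Sequence, bins: TSequence[tuple[int, int]],
                  n_per_bin: int,
                  methods: TSequence[str] = METHODS,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_length: int = DEFAULT_MIN_LENGTH,
                  min_fragment: int = DEFAULT_MIN_FRAGMENT,
                  min_deletion: int = DEFAULT_MIN_DELETION,
                  scheme: Optional[ScoringScheme] = None,
                  seed: int = 0,
                  substitution_rate: float = 0.0,
                  guards: bool = False,
                  include_runtime: bool = False,
                  ) -> tuple[list[BinStats], pd.DataFrame]:
    """Simulated-deletion benchmark: per bin, generate ``n_per_bin``
    two-fragment queries, run each requested method, and aggregate EDPE
    (mean and sample standard deviation) per bin and method.

    Boundary estimates fall back to the whole-query alignment span when a
    method reports no split boundary (``no_deletion``/degenerate cases),
    mirroring the classical baseline.  Fully reproducible from ``seed``;
    per-query wall-clock is recorded only when ``include_runtime``.
    """
    scheme = scheme or ScoringScheme.blosum62()
    for m in methods:
        if m not in METHODS:
            raise ParameterError(f"unknown method {m!r}")
    rng = np.random.default_rng(seed)
    rows = []
    bin_stats: list[BinStats] = []
    for (lo, hi) in bins:
        per_method: dict[str, dict[str, list]] = {
            m: {"edpe": [], "runtime": [], "calls": []} for m in methods
        }
        for qi in range(n_per_bin):
            query, truth = make_query(
                reference, (lo, hi), min_fragment=min_fragment,
                min_deletion=min_deletion, rng=rng,
                substitution_rate=substitution_rate, guards=guards,
                query_id=f"bin{lo}-{hi}_q{qi}",
            )
            row = {
                "bin_low": lo, "bin_high": hi, "query_id": query.id,
                "query_length": len(query), "true_boundary": truth.true_boundary,
                "true_deletion_length": truth.true_deletion_length,
            }
            for m in methods:
                t0 = time.perf_counter()
                result = find_deletion(query, reference, method=m,
                                       threshold=threshold, min_length=min_length,
                                       scheme=scheme)
                dt_ms = (time.perf_counter() - t0) * 1e3
                err = edpe(result.fallback_boundary(), truth.true_boundary)
                per_method[m]["edpe"].append(err)
                per_method[m]["runtime"].append(dt_ms)
                per_method[m]["calls"].append(result.sw_calls)
                row[f"{m}_edpe"] = err
                row[f"{m}_boundary"] = result.fallback_boundary()
                row[f"{m}_status"] = result.status if not result.no_deletion else STATUS_NO_DELETION
                row[f"{m}_sw_calls"] = result.sw_calls
                if include_runtime:
                    row[f"{m}_runtime_ms"] = round(dt_ms, 3)
            rows.append(row)
        stats = []
        for m in methods:
            me, se = _mean_sd(per_method[m]["edpe"])
            mr, sr = _mean_sd(per_method[m]["runtime"])
            stats.append((m, MethodStats(
                mean_edpe=me, sd_edpe=se,
                total_sw_calls=int(sum(per_method[m]["calls"])),
                mean_runtime_ms=mr, sd_runtime_ms=sr,
            )))
        bin_stats.append(BinStats(bin_low=lo, bin_high=hi, n=n_per_bin,
                                  methods=tuple(stats)))
        logger.info("bin %d-%d done (%d queries)", lo, hi, n_per_bin)
    return bin_stats, pd.DataFrame(rows)


def benchmark_summary_frame(bin_stats: TSequence[BinStats],
                            include_runtime: bool = False) -> pd.DataFrame:
    rows = []
    for bs in bin_stats:
        for m, st in bs.methods:
            row = {
                "bin_low": bs.bin_low, "bin_high": bs.bin_high, "n": bs.n,
                "method": m,
                "mean_edpe": round(st.mean_edpe, 4),
                "sd_edpe": round(st.sd_edpe, 4),
                "total_sw_calls": st.total_sw_calls,
            }
            if include_runtime:
                row["mean_runtime_ms"] = round(st.mean_runtime_ms, 3)
                row["sd_runtime_ms"] = round(st.sd_runtime_ms, 3)
            rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path: Union[str, Path],
              header_comments: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with ``#`` header comment lines (used to
    record seeds and parameters in benchmark outputs)."""
    with open(path, "w") as fh:
        fh.write(f"# {RESULT_TSV_VERSION}\n")
        for c in header_comments:
            fh.write(f"# {c}\n")
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pretty-printing (CLI convenience)
# ---------------------------------------------------------------------------


def format_alignment(aln: LocalAlignment, width: int = 60) -> str:
    """Human-readable pairwise alignment block with match bars."""
    if aln.is_empty:
        return "(empty alignment)\n"
    bars = "".join("|" if a == b and a != "-" else " "
                   for a, b in zip(aln.aligned_query, aln.aligned_ref))
    out = []
    for i in range(0, len(bars), width):
        out.append(f"query {aln.aligned_query[i:i + width]}")
        out.append(f"      {bars[i:i + width]}")
        out.append(f"ref   {aln.aligned_ref[i:i + width]}")
        out.append("")
    out.append(f"score {aln.score:g}  matches {aln.matches}  "
               f"query [{aln.query_start},{aln.query_end}]  "
               f"ref [{aln.ref_start},{aln.ref_end}]")
    return "\n".join(out) + "\n"
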