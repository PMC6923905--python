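"""Accuracy metrics: correction gain, N50, and alignment statistics.

The gain of a corrector over one read compares the set of real sequencing
errors E_m (known exactly here from the simulator's logs) with the set of
errors remaining after correction E_r (extracted from a global alignment of
the corrected read against its true source interval):

    TP = |E_m \\ E_r|    errors successfully removed
    FP = |E_r \\ E_m|    true bases wrongly changed
    FN = |E_r  ∩ E_m|    errors still present
    gain = (TP - FP) / (TP + FN)

Error sets are keyed by (reference coordinate, error type) with indel
positions normalized by left-shifting gaps, so the set algebra is
well-defined. Two alignment engines are available: an exact affine-free
Needleman-Wunsch with configurable scores and deterministic tie-breaking
(the reference implementation, vectorized row by row), and edlib's banded
unit-cost aligner for long sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .errors import DataError, ParameterError
from .simulate import ErrorLog, SUB, INS, DEL

# traceback codes
_DIAG, _UP, _LEFT = 0, 1, 2

# edit operation codes used in AlignmentResult.ops:
#   ("match"|"mismatch", ref_index, read_index)
#   ("del", ref_index, None)   reference base absent from the read
#   ("ins", ref_index, read_index)  read base inserted before ref_index


@dataclass
class AlignmentResult:
    score: float
    ops: list[tuple[str, int | None, int | None]]
    identity: float
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int

    @property
    def columns(self) -> int:
        return len(self.ops)


def global_align(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment of read ``b`` to reference ``a``.

    Linear gap penalty. Ties are broken deterministically, preferring
    match/mismatch over a deletion (gap in the read) over an insertion (gap
    in the reference). Identity is matches over alignment columns.
    """
    if not a or not b:
        raise ParameterError("global_align requires two non-empty sequences")
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    jcol = np.arange(m + 1, dtype=np.float64)
    prev = gap * jcol  # H[0, :]
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr[0, 1:] = _LEFT
    for i in range(1, n + 1):
        sub_scores = np.where(bb == aa[i - 1], match, mismatch)
        diag = prev[:-1] + sub_scores
        up = prev[1:] + gap
        best_nl = np.maximum(diag, up)  # best without a left move, cols 1..m
        # fold in left moves: H[i,j] = max over j' <= j of best_nl-chain + gaps;
        # with a linear gap this is a running max of (value - gap*j) + gap*j
        cell0 = prev[0] + gap  # H[i, 0]
        shifted = np.concatenate(([cell0], best_nl)) - gap * jcol
        run = np.maximum.accumulate(shifted)
        cur = run + gap * jcol
        row_ptr = np.where(
            cur[1:] == diag, _DIAG, np.where(cur[1:] == up, _UP, _LEFT)
        )
        ptr[i, 1:] = row_ptr
        ptr[i, 0] = _UP
        cur[0] = cell0
        prev = cur
    score = float(prev[m])

    ops: list[tuple[str, int | None, int | None]] = []
    i, j = n, m
    n_match = n_mismatch = n_ins = n_del = 0
    while i > 0 or j > 0:
        move = ptr[i, j]
        if i > 0 and j > 0 and move == _DIAG:
            i -= 1
            j -= 1
            if a[i] == b[j]:
                ops.append(("match", i, j))
                n_match += 1
            else:
                ops.append(("mismatch", i, j))
                n_mismatch += 1
        elif i > 0 and (move == _UP or j == 0):
            i -= 1
            ops.append(("del", i, None))
            n_del += 1
        else:
            j -= 1
            ops.append(("ins", i, j))
            n_ins += 1
    ops.reverse()
    identity = n_match / len(ops) if ops else 0.0
    return AlignmentResult(
        score=score,
        ops=ops,
        identity=identity,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_ins=n_ins,
        n_del=n_del,
    )


def _edlib_ops(a: str, b: str) -> tuple[list[tuple[str, int | None, int | None]], int]:
    """Edit operations of read b vs reference a from edlib's unit-cost path."""
    res = edlib.align(b, a, mode="NW", task="path")
    cigar = res["cigar"]
    ops: list[tuple[str, int | None, int | None]] = []
    i = j = 0
    num = ""
    n_match = 0
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch == "=":
            for _ in range(length):
                ops.append(("match", i, j))
                i += 1
                j += 1
                n_match += 1
        elif ch == "X":
            for _ in range(length):
                ops.append(("mismatch", i, j))
                i += 1
                j += 1
        elif ch == "D":  # target (reference) base absent from query (read)
            for _ in range(length):
                ops.append(("del", i, None))
                i += 1
        elif ch == "I":  # query (read) base absent from target (reference)
            for _ in range(length):
                ops.append(("ins", i, j))
                j += 1
        else:
            raise DataError(f"unexpected CIGAR op {ch!r}")
    return ops, n_match


def align_identity(a: str, b: str, engine: str = "edlib") -> float:
    """Fraction of matching columns in a global alignment of b against a."""
    if engine == "edlib":
        ops, n_match = _edlib_ops(a, b)
        return n_match / len(ops) if ops else 0.0
    return global_align(a, b).identity


def _left_shift_events(
    a: str, b: str, ops: list[tuple[str, int | None, int | None]]
) -> list[tuple[int, str]]:
    """Per-base error events with indel gap runs shifted maximally left.

    Returns (reference position, type) pairs; an insertion is anchored at
    the index of the reference base it precedes, matching the simulator's
    convention.
    """
    events: list[tuple[int, str]] = []
    idx = 0
    n_ops = len(ops)
    while idx < n_ops:
        op, i, j = ops[idx]
        if op == "match":
            idx += 1
            continue
        if op == "mismatch":
            events.append((i, SUB))
            idx += 1
            continue
        if op == "del":
            run = idx
            while run < n_ops and ops[run][0] == "del":
                run += 1
            lo, hi = i, ops[run - 1][1] + 1  # deleted ref slice a[lo:hi]
            while lo > 0 and a[lo - 1] == a[hi - 1]:
                lo -= 1
                hi -= 1
            events.extend((p, DEL) for p in range(lo, hi))
            idx = run
            continue
        # insertion run: read slice b[u:v] inserted before reference index p
        run = idx
        while run < n_ops and ops[run][0] == "ins":
            run += 1
        p = i
        u, v = j, ops[run - 1][2] + 1
        while p > 0 and u > 0 and a[p - 1] == b[v - 1]:
            p -= 1
            u -= 1
            v -= 1
        events.extend((p, INS) for _ in range(v - u))
        idx = run
    return events


def error_set_from_truth(log: ErrorLog) -> set[tuple[int, str]]:
    """E_m: the read's true errors keyed by (reference coordinate, type)."""
    return {(pos, etype) for pos, etype, _, _ in log.events}


def error_set_from_alignment(
    read_seq: str, ref_interval: str, ref_offset: int = 0, engine: str = "edlib"
) -> set[tuple[int, str]]:
    """E_r: errors remaining in a read, from global alignment to its source.

    ``ref_offset`` shifts interval-local coordinates into full-reference
    coordinates so the result is directly comparable with
    :func:`error_set_from_truth`.
    """
    if not read_seq or not ref_interval:
        raise ParameterError("alignment requires non-empty sequences")
    if engine == "edlib":
        ops, _ = _edlib_ops(ref_interval, read_seq)
    elif engine == "nw":
        ops = global_align(ref_interval, read_seq).ops
    else:
        raise ParameterError(f"unknown alignment engine {engine!r}")
    events = _left_shift_events(ref_interval, read_seq, ops)
    return {(ref_offset + pos, etype) for pos, etype in events}


@dataclass
class GainStats:
    TP: int
    FP: int
    FN: int
    gain: float
    degenerate: bool = False  # TP + FN == 0: gain is a sentinel, not Eq-defined


def compute_gain(E_m: set, E_r: set) -> GainStats:
    """Gain = (TP - FP) / (TP + FN) from the two error sets.

    TP = |E_m \\ E_r|, FP = |E_r \\ E_m|, FN = |E_r ∩ E_m|. When the read had
    no real errors (TP + FN == 0) the ratio is undefined; the result is
    flagged degenerate and reported as 1.0 for FP == 0 and -1.0 otherwise.
    """
    TP = len(E_m - E_r)
    FP = len(E_r - E_m)
    FN = len(E_r & E_m)
    if TP + FN > 0:
        return GainStats(TP, FP, FN, (TP - FP) / (TP + FN))
    return GainStats(TP, FP, FN, 1.0 if FP == 0 else -1.0, degenerate=True)


def n50(lengths) -> int:
    """The largest L such that reads of length >= L hold half of all bases."""
    arr = sorted(lengths, reverse=True)
    if not arr:
        raise ParameterError("n50 of an empty length list")
    if any(x <= 0 for x in arr):
        raise ParameterError("lengths must be positive")
    half = sum(arr) / 2
    acc = 0
    for x in arr:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def aligned_fraction(
    reads,
    ref: str,
    logs: dict[str, ErrorLog],
    min_identity: float = 0.7,
    engine: str = "edlib",
) -> tuple[float, float]:
    """(% aligned reads, % aligned bases) against true source intervals.

    A read counts as aligned when its global alignment to the reference
    interval it was simulated from reaches at least ``min_identity``.
    """
    n_reads = 0
    n_aligned = 0
    bases = 0
    aligned_bases = 0
    for rec in reads:
        log = logs.get(rec.id)
        if log is None:
            raise DataError(f"no truth interval for read {rec.id!r}")
        interval = ref[log.start : log.end]
        ident = align_identity(interval, rec.sequence, engine=engine)
        n_reads += 1
        bases += len(rec.sequence)
        if ident >= min_identity:
            n_aligned += 1
            aligned_bases += len(rec.sequence)
    if n_reads == 0:
        raise ParameterError("no reads to evaluate")
    return 100.0 * n_aligned / n_reads, 100.0 * aligned_bases / bases
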