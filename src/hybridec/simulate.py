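"""Synthetic references and reads with exact, replayable error logs.

The generator exists so every correction stage can be exercised against
known ground truth. A random reference (optionally with an injected repeat
to create branching in the de Bruijn graph) is sampled into short reads
with i.i.d. substitution errors, emulating Illumina data (~1% errors,
substitution-dominated), and into long reads with i.i.d. insertion,
deletion and substitution events, emulating PacBio-class data (~13% errors,
indel-dominated; default profile ins 6% / del 5% / sub 2%). Every emitted
read carries an :class:`ErrorLog` whose edits replay exactly onto the
reference interval, so the true error set of each read is known without any
mapping step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dbg import revcomp
from .errors import DataError, ParameterError
from .io_formats import ReadRecord, _open_text

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
# substitution table: row = original base index, columns = the 3 other bases
_OTHER = {b: [c for c in _BASES if c != b] for b in _BASES}

SUB, INS, DEL = "sub", "ins", "del"

DEFAULT_LONG_INS = 0.06
DEFAULT_LONG_DEL = 0.05
DEFAULT_LONG_SUB = 0.02
DEFAULT_SHORT_SUB = 0.01


@dataclass
class ErrorLog:
    """Ground-truth edit list tying one read to its reference interval.

    Events are ``(ref_pos, type, ref_base, read_base)`` in generation order;
    an insertion at ``ref_pos`` inserts *before* the reference base at that
    position and consumes no reference base. Replaying the events over
    ``ref[start:end]`` (then reverse-complementing when ``strand == '-'``)
    reproduces the read exactly.
    """

    read_id: str
    start: int
    end: int
    strand: str = "+"
    events: list[tuple[int, str, str, str]] = field(default_factory=list)

    def replay(self, ref: str) -> str:
        out: list[str] = []
        ptr = self.start
        for pos, etype, ref_base, read_base in self.events:
            if not self.start <= pos <= self.end:
                raise DataError(
                    f"{self.read_id}: event at {pos} outside interval "
                    f"[{self.start}, {self.end})"
                )
            if pos < ptr:
                raise DataError(f"{self.read_id}: events out of order at {pos}")
            out.append(ref[ptr:pos])
            ptr = pos
            if etype == INS:
                out.append(read_base)
            elif etype == DEL:
                if ref[pos] != ref_base:
                    raise DataError(
                        f"{self.read_id}: deletion ref base mismatch at {pos}"
                    )
                ptr += 1
            elif etype == SUB:
                if ref[pos] != ref_base:
                    raise DataError(
                        f"{self.read_id}: substitution ref base mismatch at {pos}"
                    )
                out.append(read_base)
                ptr += 1
            else:
                raise DataError(f"{self.read_id}: unknown event type {etype!r}")
        out.append(ref[ptr : self.end])
        seq = "".join(out)
        return revcomp(seq) if self.strand == "-" else seq


def simulate_reference(
    length: int,
    gc: float = 0.5,
    seed: int | None = None,
    repeat_length: int = 0,
    repeat_copies: int = 2,
) -> str:
    """An i.i.d. random reference with the requested GC fraction.

    When ``repeat_length > 0`` a substring of that length is copied to
    ``repeat_copies - 1`` additional non-overlapping loci, creating exact
    repeats that make the de Bruijn graph branch.
    """
    if length < 1:
        raise ParameterError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ParameterError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    seq = arr.tobytes().decode()
    if repeat_length:
        if repeat_copies < 2:
            raise ParameterError("repeat_copies must be >= 2 when injecting a repeat")
        if repeat_length * repeat_copies > length:
            raise ParameterError("repeat does not fit in the reference")
        # partition the reference into repeat_copies equal blocks and plant
        # one copy at a random offset inside each block
        block = length // repeat_copies
        src_off = int(rng.integers(0, block - repeat_length + 1))
        unit = seq[src_off : src_off + repeat_length]
        chars = list(seq)
        for i in range(1, repeat_copies):
            off = i * block + int(rng.integers(0, block - repeat_length + 1))
            chars[off : off + repeat_length] = unit
        seq = "".join(chars)
    return seq


def simulate_short_reads(
    ref: str,
    read_len: int = 100,
    coverage: float = 50.0,
    sub_rate: float = DEFAULT_SHORT_SUB,
    seed: int | None = None,
) -> tuple[list[ReadRecord], list[ErrorLog]]:
    """Uniformly placed short reads from both strands with i.i.d. substitutions.

    ``ceil(coverage * len(ref) / read_len)`` reads are drawn. Errors are
    logged in forward-interval coordinates; a minus-strand read is the
    reverse complement of its edited interval.
    """
    if read_len > len(ref):
        raise ParameterError("read_len exceeds reference length")
    if not 0.0 <= sub_rate < 1.0:
        raise ParameterError(f"sub_rate must be in [0, 1), got {sub_rate}")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * len(ref) / read_len)
    starts = rng.integers(0, len(ref) - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[ReadRecord] = []
    logs: list[ErrorLog] = []
    for i in range(n_reads):
        start = int(starts[i])
        strand = "-" if strands[i] else "+"
        template = ref[start : start + read_len]
        log = ErrorLog(f"sr_{i:07d}", start, start + read_len, strand)
        if sub_rate > 0:
            mask = rng.random(read_len) < sub_rate
            if mask.any():
                chars = list(template)
                picks = rng.integers(0, 3, size=int(mask.sum()))
                for j, p in zip(np.flatnonzero(mask), picks):
                    old = chars[j]
                    new = _OTHER[old][p]
                    chars[j] = new
                    log.events.append((start + int(j), SUB, old, new))
                template = "".join(chars)
        seq = revcomp(template) if strand == "-" else template
        reads.append(ReadRecord(id=log.read_id, sequence=seq))
        logs.append(log)
    return reads, logs


def simulate_long_reads(
    ref: str,
    mean_len: int = 5000,
    coverage: float = 10.0,
    ins_rate: float = DEFAULT_LONG_INS,
    del_rate: float = DEFAULT_LONG_DEL,
    sub_rate: float = DEFAULT_LONG_SUB,
    seed: int | None = None,
    length_sigma: float = 0.15,
) -> tuple[list[ReadRecord], list[ErrorLog]]:
    """Long reads with i.i.d. insertion/deletion/substitution events.

    Interval lengths are lognormal around ``mean_len`` (geometric sd
    ``exp(length_sigma)``), clipped to the reference. Reads are sampled from
    both strands but emitted on the forward strand of their interval, so
    the error log coordinates are directly comparable with alignment-derived
    error sets; the originating strand is recorded for bookkeeping. Each
    per-base event rate must be below 0.5.
    """
    if mean_len > len(ref):
        raise ParameterError("mean_len exceeds reference length")
    for name, rate in (("ins", ins_rate), ("del", del_rate), ("sub", sub_rate)):
        if not 0.0 <= rate < 0.5:
            raise ParameterError(f"{name}_rate must be in [0, 0.5), got {rate}")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * len(ref) / mean_len)
    reads: list[ReadRecord] = []
    logs: list[ErrorLog] = []
    for i in range(n_reads):
        length = int(round(rng.lognormal(math.log(mean_len), length_sigma)))
        length = max(50, min(length, len(ref)))
        start = int(rng.integers(0, len(ref) - length + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        log = ErrorLog(f"lr_{i:05d}", start, start + length, "+")
        ins_mask = rng.random(length) < ins_rate
        # one categorical draw per base so that deletions and substitutions
        # are mutually exclusive yet each occurs at exactly its nominal rate
        u = rng.random(length)
        del_mask = u < del_rate
        sub_mask = (u >= del_rate) & (u < del_rate + sub_rate)
        ins_picks = rng.integers(0, 4, size=length)
        sub_picks = rng.integers(0, 3, size=length)
        out: list[str] = []
        for j in range(length):
            pos = start + j
            base = ref[pos]
            if ins_mask[j]:
                new = _BASES[ins_picks[j]]
                out.append(new)
                log.events.append((pos, INS, "", new))
            if del_mask[j]:
                log.events.append((pos, DEL, base, ""))
            elif sub_mask[j]:
                new = _OTHER[base][sub_picks[j]]
                out.append(new)
                log.events.append((pos, SUB, base, new))
            else:
                out.append(base)
        seq = "".join(out)
        if not seq:
            continue  # vanishingly unlikely: every base deleted
        log.strand_sampled = strand  # informational only
        reads.append(ReadRecord(id=log.read_id, sequence=seq))
        logs.append(log)
    return reads, logs


# -- truth table serialization ---------------------------------------------

_TRUTH_HEADER = "#read_id\tstart\tend\tstrand\tevents"


def write_truth(logs: list[ErrorLog], path: str | Path) -> None:
    """Write error logs as TSV: one read per line, events comma-joined."""
    with _open_text(path, "wt") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for log in logs:
            ev = ",".join(
                f"{pos}:{etype}:{rb or '.'}:{qb or '.'}"
                for pos, etype, rb, qb in log.events
            )
            fh.write(f"{log.read_id}\t{log.start}\t{log.end}\t{log.strand}\t{ev}\n")


def read_truth(path: str | Path) -> dict[str, ErrorLog]:
    """Inverse of :func:`write_truth`, keyed by read id."""
    logs: dict[str, ErrorLog] = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TRUTH_HEADER:
            raise DataError(f"{path}: unrecognized truth table header")
        for line in fh:
            read_id, start, end, strand, ev = line.rstrip("\n").split("\t")
            log = ErrorLog(read_id, int(start), int(end), strand)
            if ev:
                for item in ev.split(","):
                    pos, etype, rb, qb = item.split(":")
                    log.events.append(
                        (int(pos), etype, "" if rb == "." else rb, "" if qb == "." else qb)
                    )
            logs[read_id] = log
    return logs
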