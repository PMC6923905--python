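"""Substitution error correction via fragment skew statistics and voting.

Long reads are cut into non-overlapping fragments of roughly short-read
length. Within a fragment the k-mer coverages are summarized by Pearson's
median skew coefficient, 3*(mean - median)/std: a fragment whose coverages
are balanced has near-zero skew and is accepted as true; a fragment that is
uniformly low-coverage reflects a genuinely low-coverage genomic region and
is also accepted (the key protection over tools that flag every
low-coverage k-mer as an error); only fragments dominated by high-coverage
k-mers with a few low-coverage outliers are classified as erroneous. Error
positions are localized where every overlapping in-fragment window is
low-coverage, and each flagged base is re-voted: the base is substituted
with each nucleotide in turn and accepted only when all windows covering
the position meet the coverage threshold for the fragment's coverage class
(high- and low-coverage areas of the genome get separate thresholds).
Substitution correction never changes read length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dbg import DeBruijnGraph, kmer_coverages
from .errors import ParameterError
from .io_formats import ReadRecord

DEFAULT_FRAG_LEN = 100
DEFAULT_SKEW_LOW = -0.3
DEFAULT_SKEW_HIGH = 0.3
# a fragment counts as "mostly low-coverage" when its median is below this
# fraction of the spectrum median; sampling noise places clean fragments'
# medians close to the spectrum median, so the cutoff must sit well below it
DEFAULT_LOW_MEDIAN_FACTOR = 0.5

KLASS_TRUE_BALANCED = "true_balanced"
KLASS_TRUE_LOW = "true_low"
KLASS_ERROR_HIGH = "error_high"
KLASS_ERROR_LOW = "error_low"
KLASS_IGNORED_TAIL = "ignored_tail"


@dataclass
class FragmentStats:
    """Per-fragment k-mer coverage vector with summary statistics."""

    read_id: str
    start: int
    end: int  # base coordinates, 0-based half-open
    coverages: np.ndarray | None = None  # windows fully inside the fragment
    mean: float = 0.0
    median: float = 0.0
    std: float = 0.0
    skew: float = 0.0
    klass: str | None = None


@dataclass
class SubstCorrectionReport:
    read_id: str
    n_fragments: int = 0
    n_error_fragments: int = 0
    n_positions_flagged: int = 0
    n_positions_corrected: int = 0
    # (position, old base, new base or None when no candidate qualified)
    edits: list[tuple[int, str, str | None]] = field(default_factory=list)
    skipped: bool = False


def fragment_read(read: ReadRecord, frag_len: int, k: int = 2) -> list[FragmentStats]:
    """Cut a read into consecutive non-overlapping fragments.

    A final fragment shorter than ``frag_len`` is labeled ``ignored_tail``
    and excluded from classification and correction, as it is too short to
    gather coverage statistics from.
    """
    if frag_len < k:
        raise ParameterError(f"frag_len {frag_len} must be >= k ({k})")
    seq_len = len(read.sequence)
    frags: list[FragmentStats] = []
    pos = 0
    while pos + frag_len <= seq_len:
        frags.append(FragmentStats(read.id, pos, pos + frag_len))
        pos += frag_len
    if pos < seq_len:
        frags.append(
            FragmentStats(read.id, pos, seq_len, klass=KLASS_IGNORED_TAIL)
        )
    return frags


def pearson_median_skew(coverages) -> float:
    """Pearson's median skew coefficient, 3*(mean - median)/std.

    Uses the population standard deviation (the fragment's windows are the
    whole population of interest); returns 0 when the standard deviation is
    zero.
    """
    cov = np.asarray(coverages, dtype=float)
    if cov.size == 0:
        raise ParameterError("cannot compute skew of an empty coverage vector")
    std = float(np.std(cov))
    if std == 0.0:
        return 0.0
    return 3.0 * (float(np.mean(cov)) - float(np.median(cov))) / std


def fill_fragment_stats(
    frag: FragmentStats, sequence: str, graph: DeBruijnGraph
) -> FragmentStats:
    """Fill coverages (windows fully inside the fragment) and summary stats."""
    k = graph.k
    cov = kmer_coverages(graph, sequence[frag.start : frag.end])
    frag.coverages = cov
    if cov.size:
        frag.mean = float(np.mean(cov))
        frag.median = float(np.median(cov))
        frag.std = float(np.std(cov))
        frag.skew = pearson_median_skew(cov)
    return frag


def classify_fragment(
    frag: FragmentStats,
    skew_low: float = DEFAULT_SKEW_LOW,
    skew_high: float = DEFAULT_SKEW_HIGH,
    graph_median: float = 0.0,
    low_median_factor: float = DEFAULT_LOW_MEDIAN_FACTOR,
) -> str:
    """Assign the fragment's coverage class from its skew and median.

    A fragment whose median coverage sits well below the spectrum median
    (below ``low_median_factor`` times it) and whose skew is within the
    accepted interval or negative is a genuinely low-coverage region
    (true_low, never an error). Otherwise a skew inside
    [skew_low, skew_high] means a balanced, error-free fragment
    (true_balanced); anything else is erroneous, split into error_high /
    error_low by comparing the fragment median against the spectrum median.
    """
    if frag.klass == KLASS_IGNORED_TAIL:
        return frag.klass
    if frag.coverages is None:
        raise ParameterError("fragment stats not filled; call fill_fragment_stats")
    in_interval = skew_low <= frag.skew <= skew_high
    if frag.median < low_median_factor * graph_median and (
        in_interval or frag.skew < 0
    ):
        frag.klass = KLASS_TRUE_LOW
    elif in_interval:
        frag.klass = KLASS_TRUE_BALANCED
    elif frag.median > graph_median:
        frag.klass = KLASS_ERROR_HIGH
    else:
        frag.klass = KLASS_ERROR_LOW
    return frag.klass


def locate_error_positions(
    read: ReadRecord | str,
    frag: FragmentStats,
    graph: DeBruijnGraph,
    tau_low: int,
) -> list[int]:
    """Base positions inside an error fragment consistent with a substitution.

    A window (k-mer fully inside the fragment) is an *error window* when its
    coverage is below ``tau_low``. A base position is flagged when at least
    one in-fragment window overlaps it and every such window is an error
    window: for an isolated substitution with full context this intersection
    is exactly one base; near fragment edges the intersection widens and all
    candidate positions are returned (the voting step resolves them).
    """
    if frag.klass not in (KLASS_ERROR_HIGH, KLASS_ERROR_LOW):
        raise ParameterError(f"fragment class {frag.klass!r} is not an error class")
    if frag.coverages is None:
        raise ParameterError("fragment stats not filled; call fill_fragment_stats")
    k = graph.k
    cov = frag.coverages
    n_win = cov.size
    if n_win == 0:
        return []
    err = cov < tau_low
    if not err.any():
        return []
    # prefix sums of non-error windows for O(1) "all windows in range are
    # error" queries
    ok_prefix = np.concatenate(([0], np.cumsum(~err)))
    positions: list[int] = []
    for p in range(frag.start, frag.end):
        rel = p - frag.start
        lo = max(0, rel - k + 1)
        hi = min(rel, n_win - 1)
        if lo > hi:
            continue
        if ok_prefix[hi + 1] - ok_prefix[lo] == 0:
            positions.append(p)
    return positions


def vote_base(
    read: ReadRecord | str, pos: int, graph: DeBruijnGraph, threshold: int
) -> str | None:
    """Majority vote over the k-mers covering one base position.

    Each nucleotide is substituted at ``pos`` in turn and the coverage of
    every k-mer window overlapping the position (clipped to the read) is
    looked up. A candidate qualifies only when all those coverages are at
    least ``threshold``; among qualifying candidates the one maximizing the
    minimum window coverage wins, ties broken alphabetically. Returns None
    when no candidate qualifies (the base is left unchanged).
    """
    seq = read if isinstance(read, str) else read.sequence
    if not 0 <= pos < len(seq):
        raise ParameterError(f"position {pos} outside read of length {len(seq)}")
    k = graph.k
    lo = max(0, pos - k + 1)
    hi = min(pos, len(seq) - k)
    if lo > hi:
        return None  # read shorter than k: no window covers the position
    best: tuple[int, str] | None = None
    for base in "ACGT":
        min_cov = None
        for w in range(lo, hi + 1):
            window = seq[w:pos] + base + seq[pos + 1 : w + k]
            c = graph.coverage(window)
            if c < threshold:
                min_cov = None
                break
            if min_cov is None or c < min_cov:
                min_cov = c
        if min_cov is None:
            continue
        if best is None or min_cov > best[0]:
            best = (min_cov, base)
    return best[1] if best else None


def correct_read_substitutions(
    read: ReadRecord,
    graph: DeBruijnGraph,
    frag_len: int = DEFAULT_FRAG_LEN,
    skew_low: float = DEFAULT_SKEW_LOW,
    skew_high: float = DEFAULT_SKEW_HIGH,
    tau_low: int = 3,
    thresh_high: int = 1,
    thresh_low: int = 1,
    graph_median: float | None = None,
) -> tuple[str, SubstCorrectionReport]:
    """Locate and vote-correct substitution errors in one read.

    Fragments are classified, error positions located only within error
    fragments, and each flagged base re-voted with ``thresh_high`` in
    high-coverage fragments and ``thresh_low`` in low-coverage ones.
    Accepted edits are applied immediately, so later windows see earlier
    corrections. The output always has the same length as the input.
    """
    report = SubstCorrectionReport(read_id=read.id)
    seq = read.sequence
    if len(seq) < frag_len:
        report.skipped = True
        return seq, report
    if graph_median is None:
        graph_median = graph.spectrum_median(mode="instances")
    frags = fragment_read(read, frag_len, k=graph.k)
    report.n_fragments = len(frags)
    for frag in frags:
        if frag.klass == KLASS_IGNORED_TAIL:
            continue
        fill_fragment_stats(frag, seq, graph)
        klass = classify_fragment(frag, skew_low, skew_high, graph_median)
        if klass not in (KLASS_ERROR_HIGH, KLASS_ERROR_LOW):
            continue
        report.n_error_fragments += 1
        threshold = thresh_high if klass == KLASS_ERROR_HIGH else thresh_low
        positions = locate_error_positions(seq, frag, graph, tau_low)
        report.n_positions_flagged += len(positions)
        for pos in positions:
            new = vote_base(seq, pos, graph, threshold)
            old = seq[pos]
            if new is not None and new != old:
                seq = seq[:pos] + new + seq[pos + 1 :]
                report.n_positions_corrected += 1
                report.edits.append((pos, old, new))
            else:
                report.edits.append((pos, old, None))
    return seq, report
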