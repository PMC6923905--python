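"""Coverage-annotated de Bruijn graph built from short reads.

Every vertex is a k-mer carrying its occurrence count across the whole
short-read set (its *coverage*) plus the single-character encodings of its
in- and out-edges: a character appended to the (k-1)-suffix of a vertex
names a successor k-mer, one prepended to the (k-1)-prefix names a
predecessor. By default k-mers are strand-canonicalized (a k-mer and its
reverse complement are merged into the lexicographically smaller of the
two), because short reads sample both genome strands; ``canonical=False``
gives literal single-strand counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import EmptyGraphError, ParameterError
from .io_formats import ReadRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")

DEFAULT_K = 21


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def canonicalize(kmer: str) -> str:
    """The lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerVertex:
    kmer: str
    count: int = 0
    in_edges: set[str] = field(default_factory=set)
    out_edges: set[str] = field(default_factory=set)


def extract_kmers(sequence: str, k: int) -> list[tuple[int, str]]:
    """All (position, k-mer) windows whose characters are all in {A,C,G,T}.

    Windows containing any other character (e.g. N) are omitted. Returns an
    empty list when the sequence is shorter than k.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    out: list[tuple[int, str]] = []
    last_bad = -1
    for i, ch in enumerate(sequence):
        if ch not in _ACGT:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            out.append((i - k + 1, sequence[i - k + 1 : i + 1]))
    return out


class DeBruijnGraph:
    """k-mer hash map with counts and single-character edge sets.

    Lookup is a plain dict access, i.e. expected O(1). Equality compares k,
    strand mode, vertices (counts and edge sets) and the instance total.
    """

    def __init__(self, k: int, canonical: bool = True):
        if k < 2:
            raise ParameterError(f"k must be >= 2, got {k}")
        self.k = k
        self.canonical = canonical
        self.vertices: dict[str, KmerVertex] = {}
        self.total_instances = 0

    def __len__(self) -> int:
        return len(self.vertices)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DeBruijnGraph):
            return NotImplemented
        return (
            self.k == other.k
            and self.canonical == other.canonical
            and self.total_instances == other.total_instances
            and self.vertices == other.vertices
        )

    # -- construction -----------------------------------------------------

    def _vertex(self, stored_kmer: str) -> KmerVertex:
        v = self.vertices.get(stored_kmer)
        if v is None:
            v = KmerVertex(kmer=stored_kmer)
            self.vertices[stored_kmer] = v
        return v

    def add_read(self, sequence: str) -> int:
        """Count all valid k-mer windows of one read and record adjacencies.

        Returns the number of windows added.
        """
        k = self.k
        windows = extract_kmers(sequence, k)
        if not windows:
            return 0
        if self.canonical:
            rc_seq = revcomp(sequence)
            n = len(sequence)
            stored = []
            for pos, kmer in windows:
                rck = rc_seq[n - pos - k : n - pos]
                if kmer <= rck:
                    stored.append((pos, kmer, False))
                else:
                    stored.append((pos, rck, True))
            for pos, skmer, flipped in stored:
                self._vertex(skmer).count += 1
            # adjacency u -> v between consecutive windows; recorded in the
            # canonical orientation of each endpoint
            for (pu, su, fu), (pv, sv, fv) in zip(stored, stored[1:]):
                if pv != pu + 1:
                    continue
                c_out = sequence[pu + k]  # last char of v
                c_in = sequence[pu]  # first char of u
                u = self.vertices[su]
                if fu:
                    u.in_edges.add(complement(c_out))
                else:
                    u.out_edges.add(c_out)
                v = self.vertices[sv]
                if fv:
                    v.out_edges.add(complement(c_in))
                else:
                    v.in_edges.add(c_in)
        else:
            for pos, kmer in windows:
                self._vertex(kmer).count += 1
            for (pu, ku), (pv, kv) in zip(windows, windows[1:]):
                if pv != pu + 1:
                    continue
                self.vertices[ku].out_edges.add(kv[-1])
                self.vertices[kv].in_edges.add(ku[0])
        self.total_instances += len(windows)
        return len(windows)

    # -- queries -----------------------------------------------------------

    def _check_len(self, kmer: str) -> None:
        if len(kmer) != self.k:
            raise ParameterError(
                f"k-mer length {len(kmer)} does not match graph k={self.k}"
            )

    def __contains__(self, kmer: str) -> bool:
        return self.coverage(kmer) > 0

    def coverage(self, kmer: str) -> int:
        """Occurrence count of a k-mer; 0 if absent (or containing non-ACGT)."""
        self._check_len(kmer)
        key = canonicalize(kmer) if self.canonical else kmer
        v = self.vertices.get(key)
        return v.count if v is not None else 0

    def _neighbor_chars(self, kmer: str, outgoing: bool) -> list[str]:
        key = canonicalize(kmer) if self.canonical else kmer
        v = self.vertices.get(key)
        if v is None:
            raise KeyError(f"k-mer {kmer!r} not in graph")
        if not self.canonical or key == kmer:
            chars = set(v.out_edges if outgoing else v.in_edges)
            if self.canonical and kmer == revcomp(kmer):
                # palindromic vertex: both orientations coincide
                other = v.in_edges if outgoing else v.out_edges
                chars |= {complement(c) for c in other}
        else:
            # the query orientation is the reverse complement of the stored one
            other = v.in_edges if outgoing else v.out_edges
            chars = {complement(c) for c in other}
        return sorted(chars)

    def successors(self, kmer: str) -> list[tuple[str, int]]:
        """Neighbor k-mers reachable by appending one character, with coverage."""
        self._check_len(kmer)
        return [
            (nbr, self.coverage(nbr))
            for c in self._neighbor_chars(kmer, outgoing=True)
            if (nbr := kmer[1:] + c)
        ]

    def predecessors(self, kmer: str) -> list[tuple[str, int]]:
        """Neighbor k-mers reachable by prepending one character, with coverage."""
        self._check_len(kmer)
        return [
            (nbr, self.coverage(nbr))
            for c in self._neighbor_chars(kmer, outgoing=False)
            if (nbr := c + kmer[:-1])
        ]

    def spectrum_median(self, mode: str = "distinct") -> float:
        """Median coverage of the k-mer spectrum.

        ``mode="distinct"`` takes the median over the counts of distinct
        stored k-mers; ``mode="instances"`` weights each k-mer by its own
        count (the median coverage of a randomly drawn k-mer *instance*,
        which tracks the sequencing depth of the genome). An even number of
        values yields the arithmetic mean of the two middle ones.
        """
        if not self.vertices:
            raise EmptyGraphError("cannot take the median of an empty spectrum")
        counts = np.fromiter(
            (v.count for v in self.vertices.values()), dtype=np.int64
        )
        if mode == "distinct":
            return float(np.median(counts))
        if mode == "instances":
            counts.sort()
            cum = np.cumsum(counts)
            total = int(cum[-1])
            # median of the multiset where count c contributes c copies of c
            lo = int(counts[np.searchsorted(cum, (total + 1) // 2)])
            hi = int(counts[np.searchsorted(cum, total // 2 + 1)])
            return (lo + hi) / 2
        raise ParameterError(f"unknown spectrum median mode {mode!r}")


def build_graph(
    short_reads: Iterable[ReadRecord | str],
    k: int = DEFAULT_K,
    canonical: bool = True,
) -> DeBruijnGraph:
    """Build the coverage-annotated de Bruijn graph from short reads.

    Vertex counts equal the multiset counts of (canonicalized) k-mers over
    all reads; edge sets record every adjacency observed within a read.
    Raises :class:`EmptyGraphError` when no read yields a single valid
    window.
    """
    graph = DeBruijnGraph(k=k, canonical=canonical)
    for rec in short_reads:
        seq = rec if isinstance(rec, str) else rec.sequence
        graph.add_read(seq)
    if not graph.vertices:
        raise EmptyGraphError(
            f"no read contained a valid window of length k={k}; "
            "correction cannot proceed"
        )
    return graph


def kmer_coverages(graph: DeBruijnGraph, sequence: str) -> np.ndarray:
    """Coverage of every k-mer window of a sequence, as an int array.

    Windows containing non-ACGT characters get coverage 0. The array has
    ``len(sequence) - k + 1`` entries (empty for sequences shorter than k).
    """
    k = graph.k
    n = len(sequence) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    cov = np.zeros(n, dtype=np.int64)
    get = graph.vertices.get
    if graph.canonical:
        rc_seq = revcomp(sequence)
        m = len(sequence)
        for i in range(n):
            kmer = sequence[i : i + k]
            rck = rc_seq[m - i - k : m - i]
            v = get(kmer if kmer <= rck else rck)
            if v is not None:
                cov[i] = v.count
    else:
        for i in range(n):
            v = get(sequence[i : i + k])
            if v is not None:
                cov[i] = v.count
    return cov
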