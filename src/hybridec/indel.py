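"""Indel error correction by local assembly in the de Bruijn graph.

A long read is partitioned, in k-mer index space, into *strong* regions
(every k-mer has coverage >= tau in the short-read graph) and *weak* regions
(coverage < tau), the latter presumed to contain indel errors. Each weak
region flanked by strong regions on both sides is replaced by the spelling
of the widest path -- the path maximizing its minimum k-mer coverage --
between the last k-mer of the left strong region and the first k-mer of the
right strong region. Shortest-path (BFS) and greedy max-coverage traversals
are provided as ablation alternatives. Nothing is ever trimmed: a region
with no usable path, or a weak region at a read end, is left unchanged.

The search functions only require ``graph.coverage(node)`` and
``graph.successors(node)``, so they work on any vertex-weighted adjacency
structure, not just a de Bruijn graph.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

from .dbg import DeBruijnGraph, kmer_coverages
from .errors import HybridecError, ParameterError
from .io_formats import ReadRecord

DEFAULT_TAU = 3
DEFAULT_MAX_LEN_FACTOR = 2.0
DEFAULT_BRANCHING = 100


@dataclass
class RegionAnnotation:
    """A maximal strong or weak interval of a read, in k-mer index space.

    ``start``/``end`` are 0-based half-open; index i refers to the k-mer
    starting at base i.
    """

    read_id: str
    start: int
    end: int
    label: str  # "strong" | "weak"


@dataclass
class AssemblyPath:
    """A walk in the graph: consecutive k-mers overlap by k-1 characters."""

    kmers: tuple[str, ...]
    width: int

    @property
    def length(self) -> int:
        return len(self.kmers)

    def spell(self) -> str:
        return spell_path(self)


@dataclass
class RegionOutcome:
    start: int
    end: int
    outcome: str  # "replaced" | "no_path" | "tip" | "boundary_missing"
    replacement_length: int | None = None  # bases, including both boundary k-mers
    path_width: int | None = None


@dataclass
class IndelCorrectionReport:
    read_id: str
    n_weak_regions: int = 0
    n_replaced: int = 0
    n_unchanged: int = 0
    skipped_short: bool = False
    outcomes: list[RegionOutcome] = field(default_factory=list)


def partition_read(
    read: ReadRecord, graph: DeBruijnGraph, tau: int
) -> list[RegionAnnotation]:
    """Run-length partition of a read into alternating strong/weak regions.

    k-mer index i is weak iff the coverage of the window starting at base i
    is below tau. Reads shorter than k yield an empty list (the caller
    passes such reads through untouched).
    """
    if tau < 1:
        raise ParameterError(f"tau must be >= 1, got {tau}")
    cov = kmer_coverages(graph, read.sequence)
    regions: list[RegionAnnotation] = []
    n = len(cov)
    if n == 0:
        return regions
    start = 0
    weak = bool(cov[0] < tau)
    for i in range(1, n):
        w = bool(cov[i] < tau)
        if w != weak:
            regions.append(
                RegionAnnotation(read.id, start, i, "weak" if weak else "strong")
            )
            start, weak = i, w
    regions.append(RegionAnnotation(read.id, start, n, "weak" if weak else "strong"))
    return regions


def _check_endpoints(graph, source: str, dest: str) -> tuple[int, int]:
    cov_s = graph.coverage(source)
    cov_d = graph.coverage(dest)
    if cov_s <= 0:
        raise KeyError(f"source {source!r} not in graph")
    if cov_d <= 0:
        raise KeyError(f"destination {dest!r} not in graph")
    return cov_s, cov_d


def widest_path(graph, source: str, dest: str, max_len: int) -> AssemblyPath | None:
    """Maximum-bottleneck path of at most ``max_len`` vertices.

    Returns a path from source to dest maximizing the minimum vertex
    coverage along it (endpoints included); among equal-width paths, one of
    minimal length. Implemented as a best-first search ordered by
    (width desc, length asc, path lex) -- the bottleneck analogue of
    Dijkstra -- with Pareto pruning on (width, length) labels per vertex,
    which keeps optimality because a walk's width never increases as it
    grows. Returns None when no path within the length bound exists.
    """
    if max_len < 1:
        raise ParameterError(f"max_len must be >= 1, got {max_len}")
    cov_s, _ = _check_endpoints(graph, source, dest)
    if source == dest:
        return AssemblyPath(kmers=(source,), width=cov_s)
    # heap entries: (-width, length, path tuple)
    heap: list[tuple[int, int, tuple[str, ...]]] = [(-cov_s, 1, (source,))]
    labels: dict[str, list[tuple[int, int]]] = {source: [(cov_s, 1)]}
    while heap:
        neg_w, length, path = heapq.heappop(heap)
        width = -neg_w
        node = path[-1]
        if node == dest:
            return AssemblyPath(kmers=path, width=width)
        if length >= max_len:
            continue
        for nbr, cov in graph.successors(node):
            w2 = min(width, cov)
            l2 = length + 1
            existing = labels.setdefault(nbr, [])
            if any(lw >= w2 and ll <= l2 for lw, ll in existing):
                continue
            existing[:] = [(lw, ll) for lw, ll in existing if not (lw <= w2 and ll >= l2)]
            existing.append((w2, l2))
            heapq.heappush(heap, (-w2, l2, path + (nbr,)))
    return None


def shortest_path(graph, source: str, dest: str, max_len: int) -> AssemblyPath | None:
    """Minimum-length path (unweighted BFS) of at most ``max_len`` vertices.

    The path width is still computed and reported for diagnostics.
    Deterministic: neighbors are expanded in lexicographic order, so the
    first path reaching the destination is the lexicographically smallest
    among the shortest.
    """
    if max_len < 1:
        raise ParameterError(f"max_len must be >= 1, got {max_len}")
    cov_s, _ = _check_endpoints(graph, source, dest)
    if source == dest:
        return AssemblyPath(kmers=(source,), width=cov_s)
    queue: deque[tuple[str, ...]] = deque([(source,)])
    visited = {source}
    while queue:
        path = queue.popleft()
        if len(path) >= max_len:
            continue
        for nbr, cov in graph.successors(path[-1]):
            if nbr in visited:
                continue
            new = path + (nbr,)
            if nbr == dest:
                width = min(graph.coverage(x) for x in new)
                return AssemblyPath(kmers=new, width=width)
            visited.add(nbr)
            queue.append(new)
    return None


def greedy_path(
    graph,
    source: str,
    dest: str,
    b: int = DEFAULT_BRANCHING,
    max_len: int | None = None,
) -> AssemblyPath | None:
    """Greedy max-coverage descent with bounded backtracking.

    From each vertex the neighbor with the maximum coverage is tried first
    (ties broken lexicographically). After ``b`` successive vertices from
    the source without reaching the destination the branch is abandoned and
    the search backtracks; a vertex is never visited twice, so the search
    aborts once every successor reachable from the source has been tried.
    """
    if b < 1:
        raise ParameterError(f"branching factor must be >= 1, got {b}")
    cov_s, _ = _check_endpoints(graph, source, dest)
    if source == dest:
        return AssemblyPath(kmers=(source,), width=cov_s)
    # cap on total path vertices: b successors beyond the source, and never
    # more than the caller's length bound
    limit = b + 1 if max_len is None else min(b + 1, max_len)
    visited = {source}

    # iterative DFS; stack holds (path, iterator over ordered neighbors)
    def ordered(node: str):
        return iter(sorted(graph.successors(node), key=lambda t: (-t[1], t[0])))

    stack: list[tuple[tuple[str, ...], object]] = [((source,), ordered(source))]
    while stack:
        path, it = stack[-1]
        descended = False
        for nbr, _cov in it:
            if nbr in visited:
                continue
            visited.add(nbr)
            new = path + (nbr,)
            if nbr == dest:
                if len(new) <= limit:
                    width = min(graph.coverage(x) for x in new)
                    return AssemblyPath(kmers=new, width=width)
                continue
            if len(new) < limit:
                stack.append((new, ordered(nbr)))
                descended = True
                break
            # depth-limited dead end: try the next sibling
        if not descended:
            stack.pop()
    return None


def spell_path(path: AssemblyPath) -> str:
    """Concatenate a k-mer walk into its spelled sequence.

    The first k-mer followed by the last character of each subsequent k-mer;
    consecutive k-mers must overlap by k-1 characters.
    """
    kmers = path.kmers
    if not kmers:
        raise HybridecError("cannot spell an empty path")
    first = kmers[0]
    parts = [first]
    for prev, cur in zip(kmers, kmers[1:]):
        if prev[1:] != cur[:-1]:
            raise HybridecError(
                f"path k-mers {prev!r} -> {cur!r} do not overlap by k-1"
            )
        parts.append(cur[-1])
    return "".join(parts)


_SEARCHES = {"widest": "widest", "shortest": "shortest", "greedy": "greedy"}


def correct_read_indels(
    read: ReadRecord,
    graph: DeBruijnGraph,
    tau: int = DEFAULT_TAU,
    search: str = "widest",
    max_len_factor: float = DEFAULT_MAX_LEN_FACTOR,
    b: int = DEFAULT_BRANCHING,
) -> tuple[str, IndelCorrectionReport]:
    """Replace each internally-flanked weak region of one read.

    For a weak region spanning k-mer indices [ws, we) the source is the
    k-mer at index ws-1 (the last k-mer of the left strong region) and the
    destination the k-mer at index we (the first of the right strong
    region); the spelled path replaces the read bases [ws-1, we+k), which
    include both boundary k-mers verbatim, so strong-region bases are
    preserved bit-identically. The search is capped at
    ceil(max_len_factor * (weak span in k-mers + 2)) path vertices. Weak
    regions at read extremities, or with no qualifying path, are left
    unchanged -- never trimmed. Every input read yields exactly one output
    read.
    """
    if search not in _SEARCHES:
        raise ParameterError(f"unknown search strategy {search!r}")
    if max_len_factor <= 0:
        raise ParameterError(f"max_len_factor must be > 0, got {max_len_factor}")
    k = graph.k
    report = IndelCorrectionReport(read_id=read.id)
    seq = read.sequence
    if len(seq) < k:
        report.skipped_short = True
        return seq, report
    regions = partition_read(read, graph, tau)
    weak = [r for r in regions if r.label == "weak"]
    report.n_weak_regions = len(weak)
    n_kmers = len(seq) - k + 1

    planned: list[tuple[RegionOutcome, str | None]] = []
    for region in weak:
        ws, we = region.start, region.end
        if ws == 0 or we == n_kmers:
            planned.append((RegionOutcome(ws, we, "tip"), None))
            continue
        source = seq[ws - 1 : ws - 1 + k]
        dest = seq[we : we + k]
        span = we - ws
        max_len = math.ceil(max_len_factor * (span + 2))
        try:
            if search == "widest":
                path = widest_path(graph, source, dest, max_len)
            elif search == "shortest":
                path = shortest_path(graph, source, dest, max_len)
            else:
                path = greedy_path(graph, source, dest, b=b, max_len=max_len)
        except KeyError:
            planned.append((RegionOutcome(ws, we, "boundary_missing"), None))
            continue
        if path is None:
            planned.append((RegionOutcome(ws, we, "no_path"), None))
            continue
        spelled = spell_path(path)
        planned.append(
            (
                RegionOutcome(
                    ws,
                    we,
                    "replaced",
                    replacement_length=len(spelled),
                    path_width=path.width,
                ),
                spelled,
            )
        )

    # Apply replacements right-to-left so earlier coordinates stay valid.
    # Adjacent replacements can overlap within a short shared strong region,
    # but the overlapping bases are the boundary k-mers, which both the read
    # and every spelled path contain verbatim, so the splices agree.
    for outcome, spelled in reversed(planned):
        if spelled is None:
            continue
        a = outcome.start - 1
        bpos = outcome.end + k
        seq = seq[:a] + spelled + seq[bpos:]

    report.outcomes = [o for o, _ in planned]
    report.n_replaced = sum(1 for o, s in planned if s is not None)
    report.n_unchanged = report.n_weak_regions - report.n_replaced
    return seq, report
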