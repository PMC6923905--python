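"""Shared fixtures and oracles for the test suite."""

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import settings

from hybridec import ReadRecord, build_graph
from hybridec.simulate import simulate_reference, simulate_short_reads

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


class VertexGraph:
    """Minimal vertex-weighted adjacency structure for path-search tests.

    Exposes the same ``coverage`` / ``successors`` interface as the de
    Bruijn graph, so the search algorithms can be exercised on arbitrary
    topologies that would be awkward to realize with overlapping k-mers.
    """

    def __init__(self, coverages: dict, edges):
        self.cov = dict(coverages)
        self.adj = defaultdict(list)
        for u, v in edges:
            if v not in self.adj[u]:
                self.adj[u].append(v)
        for u in self.adj:
            self.adj[u].sort()

    def coverage(self, node):
        return self.cov.get(node, 0)

    def successors(self, node):
        return [(v, self.cov[v]) for v in self.adj[node]]


def enumerate_simple_paths(graph: VertexGraph, source, dest, max_len):
    """All simple paths from source to dest with at most max_len vertices."""
    paths = []

    def dfs(path):
        node = path[-1]
        if node == dest:
            paths.append(tuple(path))
            return
        if len(path) >= max_len:
            return
        for nbr, _ in graph.successors(node):
            if nbr not in path:
                path.append(nbr)
                dfs(path)
                path.pop()

    dfs([source])
    return paths


def random_vertex_graph(rng: np.random.Generator, max_nodes=8):
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [chr(ord("a") + i) for i in range(n)]
    density = rng.uniform(0.3, 0.7)
    cov = {v: int(rng.integers(1, 11)) for v in nodes}
    edges = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and rng.random() < density
    ]
    return VertexGraph(cov, edges), nodes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_reference():
    """A 2 kb repeat-free reference used by several correction fixtures."""
    return simulate_reference(2000, seed=11)


@pytest.fixture(scope="session")
def tiny_graph(tiny_reference):
    """Clean 30x short-read graph (k=15) over the tiny reference."""
    reads, _ = simulate_short_reads(
        tiny_reference, read_len=100, coverage=30, sub_rate=0.0, seed=12
    )
    return build_graph(reads, k=15)


def brute_force_kmer_counts(reads, k, canonical):
    """Independent multiset counter over all valid windows of all reads."""
    from hybridec.dbg import revcomp

    counts = defaultdict(int)
    total = 0
    for rec in reads:
        seq = rec.sequence if isinstance(rec, ReadRecord) else rec
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            if canonical:
                w = min(w, revcomp(w))
            counts[w] += 1
            total += 1
    return counts, total
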