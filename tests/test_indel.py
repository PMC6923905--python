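"""Region partitioning, path searches and indel repair of long reads."""

import pytest

from hybridec import (
    ParameterError,
    ReadRecord,
    build_graph,
    correct_read_indels,
    greedy_path,
    partition_read,
    shortest_path,
    spell_path,
    widest_path,
)
from hybridec.errors import HybridecError
from hybridec.indel import AssemblyPath
from conftest import VertexGraph, enumerate_simple_paths, random_vertex_graph


# -- partitioning -------------------------------------------------------------


def test_partition_all_strong(tiny_graph, tiny_reference):
    read = ReadRecord("r", tiny_reference[200:400])
    regions = partition_read(read, tiny_graph, tau=1)
    assert [r.label for r in regions] == ["strong"]
    assert (regions[0].start, regions[0].end) == (0, 200 - tiny_graph.k + 1)


def test_partition_all_weak(tiny_graph):
    read = ReadRecord("r", "A" * 60)  # homopolymer absent from the reference
    regions = partition_read(read, tiny_graph, tau=1)
    assert [r.label for r in regions] == ["weak"]


def test_partition_run_length_encoding(tiny_graph, tiny_reference):
    """Coverage pattern strong/weak/strong maps to three tiling regions."""
    k = tiny_graph.k
    seq = tiny_reference[300:340]
    # corrupt the middle so a block of windows disappears from the graph
    seq = seq[:20] + "A" * 4 + seq[24:]
    read = ReadRecord("r", seq)
    cov = [tiny_graph.coverage(seq[i : i + k]) for i in range(len(seq) - k + 1)]
    expected = []
    lab = lambda c: "weak" if c < 1 else "strong"
    start = 0
    for i in range(1, len(cov)):
        if lab(cov[i]) != lab(cov[start]):
            expected.append((start, i, lab(cov[start])))
            start = i
    expected.append((start, len(cov), lab(cov[start])))
    got = [(r.start, r.end, r.label) for r in partition_read(read, tiny_graph, 1)]
    assert got == expected
    assert got[0][2] == "strong" and got[1][2] == "weak"


def test_partition_monotone_in_tau(tiny_graph, tiny_reference, rng):
    seq = list(tiny_reference[500:700])
    for p in rng.integers(10, 190, size=4):
        seq[p] = "ACGT"[(("ACGT".index(seq[p])) + 1) % 4]
    read = ReadRecord("r", "".join(seq))
    weak_sets = []
    for tau in (1, 2, 5, 20, 100):
        regions = partition_read(read, tiny_graph, tau)
        weak = {
            i for r in regions if r.label == "weak" for i in range(r.start, r.end)
        }
        weak_sets.append(weak)
    for a, b in zip(weak_sets, weak_sets[1:]):
        assert a <= b


def test_short_read_yields_no_regions(tiny_graph):
    assert partition_read(ReadRecord("r", "ACGT"), tiny_graph, 1) == []


# -- path searches on constructed graphs --------------------------------------


def diamond_graph():
    """Short low-coverage branch (s-x-d) vs long high-coverage branch."""
    cov = {"s": 9, "x": 1, "p": 8, "q": 7, "d": 9}
    edges = [("s", "x"), ("x", "d"), ("s", "p"), ("p", "q"), ("q", "d")]
    return VertexGraph(cov, edges)


def test_widest_path_identity_and_linear_chain():
    g = VertexGraph({"A": 5, "B": 2, "C": 7}, [("A", "B"), ("B", "C")])
    p = widest_path(g, "A", "A", max_len=5)
    assert p.kmers == ("A",) and p.width == 5
    p = widest_path(g, "A", "C", max_len=5)
    assert p.kmers == ("A", "B", "C") and p.width == 2


def test_widest_vs_shortest_on_diamond():
    g = diamond_graph()
    w = widest_path(g, "s", "d", max_len=8)
    s = shortest_path(g, "s", "d", max_len=8)
    assert w.kmers == ("s", "p", "q", "d") and w.width == 7
    assert s.kmers == ("s", "x", "d") and s.width == 1
    assert w.width >= s.width


def test_shortest_path_identity_and_disconnected():
    g = VertexGraph({"a": 1, "b": 1}, [])
    p = shortest_path(g, "a", "a", max_len=3)
    assert p.kmers == ("a",)
    assert shortest_path(g, "a", "b", max_len=5) is None
    assert widest_path(g, "a", "b", max_len=5) is None


def test_absent_endpoints_raise_lookup_error():
    g = VertexGraph({"a": 1}, [])
    with pytest.raises(KeyError):
        widest_path(g, "a", "zz", max_len=3)
    with pytest.raises(KeyError):
        shortest_path(g, "zz", "a", max_len=3)
    with pytest.raises(KeyError):
        greedy_path(g, "zz", "a")


def test_widest_path_respects_length_bound():
    g = diamond_graph()
    # only the 3-vertex branch fits in max_len=3
    p = widest_path(g, "s", "d", max_len=3)
    assert p.kmers == ("s", "x", "d") and p.width == 1


def test_greedy_linear_chain_matches_widest():
    g = VertexGraph({"A": 5, "B": 2, "C": 7}, [("A", "B"), ("B", "C")])
    p = greedy_path(g, "A", "C")
    assert p.kmers == ("A", "B", "C") and p.width == 2


def test_greedy_backtracks_from_high_coverage_dead_end():
    # greedy prefers t (cov 9) which dead-ends; backtracking finds s-x-d
    cov = {"s": 5, "t": 9, "x": 2, "d": 5}
    edges = [("s", "t"), ("s", "x"), ("x", "d")]
    g = VertexGraph(cov, edges)
    p = greedy_path(g, "s", "d", b=10)
    assert p is not None and p.kmers == ("s", "x", "d")


def test_greedy_exhaustion_returns_none():
    cov = {"s": 5, "t": 9, "u": 8, "d": 5}
    edges = [("s", "t"), ("t", "u")]
    g = VertexGraph(cov, edges)
    assert greedy_path(g, "s", "d", b=10) is None


def test_greedy_branching_factor_limits_depth():
    # chain of 6 vertices; b=3 allows only 3 vertices beyond the source
    nodes = list("abcdef")
    cov = {n: 5 for n in nodes}
    edges = list(zip(nodes, nodes[1:]))
    g = VertexGraph(cov, edges)
    assert greedy_path(g, "a", "f", b=3) is None
    assert greedy_path(g, "a", "f", b=10) is not None


def test_path_searches_match_enumeration_oracle(rng):
    """Widest width, shortest length and greedy reachability against
    exhaustive simple-path enumeration on small random graphs."""
    max_len = 8
    n_disconnected = 0
    for _ in range(60):
        g, nodes = random_vertex_graph(rng)
        source, dest = rng.choice(nodes, size=2, replace=False)
        paths = enumerate_simple_paths(g, source, dest, max_len)
        w = widest_path(g, source, dest, max_len)
        s = shortest_path(g, source, dest, max_len)
        gr = greedy_path(g, source, dest, b=100, max_len=max_len)
        if not paths:
            n_disconnected += 1
            assert w is None and s is None and gr is None
            continue
        best_width = max(min(g.coverage(v) for v in p) for p in paths)
        min_len = min(len(p) for p in paths)
        assert w.width == best_width
        assert w.width == min(g.coverage(v) for v in w.kmers)
        best_len_at_width = min(
            len(p)
            for p in paths
            if min(g.coverage(v) for v in p) == best_width
        )
        assert w.length == best_len_at_width
        assert s.length == min_len
        assert gr is not None  # reachable => greedy finds some path
        assert w.width >= s.width and w.width >= gr.width
    assert n_disconnected < 30


# -- spelling and read correction ---------------------------------------------


def test_spell_path_examples():
    assert spell_path(AssemblyPath(("ACG", "CGT"), 1)) == "ACGT"
    assert spell_path(AssemblyPath(("ACG",), 1)) == "ACG"
    with pytest.raises(HybridecError):
        spell_path(AssemblyPath(("ACG", "GGG"), 1))


def test_spell_path_round_trip_on_read_windows(tiny_reference):
    seq = tiny_reference[50:90]
    k = 7
    kmers = tuple(seq[i : i + k] for i in range(len(seq) - k + 1))
    assert spell_path(AssemblyPath(kmers, 1)) == seq


def test_correct_read_identity_when_no_weak_regions(tiny_graph, tiny_reference):
    read = ReadRecord("r", tiny_reference[400:700])
    out, rep = correct_read_indels(read, tiny_graph, tau=1)
    assert out == read.sequence
    assert rep.n_weak_regions == 0


def test_correct_read_repairs_planted_deletion(tiny_graph, tiny_reference):
    truth = tiny_reference[600:900]
    corrupted = truth[:150] + truth[151:]  # one deleted base
    out, rep = correct_read_indels(ReadRecord("r", corrupted), tiny_graph, tau=1)
    assert out == truth
    assert rep.n_replaced == rep.n_weak_regions == 1


def test_correct_read_repairs_planted_insertion_and_substitution(
    tiny_graph, tiny_reference
):
    truth = tiny_reference[0:400]
    corrupted = truth[:100] + "T" + truth[100:250] + (
        "A" if truth[250] != "A" else "C"
    ) + truth[251:]
    out, rep = correct_read_indels(ReadRecord("r", corrupted), tiny_graph, tau=1)
    assert out == truth
    assert rep.n_replaced == 2


def test_weak_region_at_read_tip_left_unchanged(tiny_graph, tiny_reference):
    truth = tiny_reference[100:300]
    corrupted = "TTTTTTTT" + truth[8:]  # corrupt the left tip
    out, rep = correct_read_indels(ReadRecord("r", corrupted), tiny_graph, tau=1)
    assert out == corrupted
    assert rep.n_unchanged == rep.n_weak_regions == 1
    assert rep.outcomes[0].outcome == "tip"


def test_unbridgeable_weak_region_left_unchanged(tiny_graph, tiny_reference):
    """When the gap spans sequence absent from the graph and no alternative
    path exists within the length bound, the read is left untouched."""
    truth = tiny_reference[300:600]
    foreign = "A" * 50  # not bridgeable: creates a huge weak region
    corrupted = truth[:120] + foreign + truth[170:]
    out, rep = correct_read_indels(
        ReadRecord("r", corrupted), tiny_graph, tau=1, max_len_factor=0.2
    )
    assert out == corrupted
    assert rep.n_unchanged == rep.n_weak_regions


def test_read_shorter_than_k_passes_through(tiny_graph):
    out, rep = correct_read_indels(ReadRecord("r", "ACGT"), tiny_graph)
    assert out == "ACGT"
    assert rep.skipped_short


def test_no_trimming_every_read_yields_one_output(tiny_graph, tiny_reference, rng):
    """Output length is never below input length minus the total weak span."""
    k = tiny_graph.k
    for start in (0, 310, 777):
        truth = tiny_reference[start : start + 250]
        chars = list(truth)
        del chars[60]
        del chars[130]
        corrupted = "".join(chars)
        read = ReadRecord("r", corrupted)
        regions = partition_read(read, tiny_graph, 3)
        weak_span = sum(r.end - r.start for r in regions if r.label == "weak")
        out, _ = correct_read_indels(read, tiny_graph, tau=3)
        assert len(out) >= len(corrupted) - weak_span
        assert isinstance(out, str) and len(out) > 0


def test_strong_region_bases_preserved(tiny_graph, tiny_reference):
    truth = tiny_reference[900:1200]
    corrupted = truth[:140] + truth[141:]
    read = ReadRecord("r", corrupted)
    k = tiny_graph.k
    regions = partition_read(read, tiny_graph, tau=3)
    out, rep = correct_read_indels(read, tiny_graph, tau=3)
    for region, outcome in zip(
        [r for r in regions if r.label == "weak"], rep.outcomes
    ):
        assert (region.start, region.end) == (outcome.start, outcome.end)
    shift = 0
    for r in regions:
        if r.label == "strong":
            frag = corrupted[r.start : r.end + k - 1]
            assert out[r.start + shift : r.end + k - 1 + shift] == frag
        else:
            outcome = next(
                o for o in rep.outcomes if (o.start, o.end) == (r.start, r.end)
            )
            if outcome.outcome == "replaced":
                old_span = (r.end + k) - (r.start - 1)
                shift += outcome.replacement_length - old_span


def test_unknown_search_strategy_rejected(tiny_graph):
    with pytest.raises(ParameterError):
        correct_read_indels(ReadRecord("r", "ACGT" * 20), tiny_graph, search="astar")
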