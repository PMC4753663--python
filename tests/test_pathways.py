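import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermnet.pathways import (
    Pathway,
    PathwayLibrary,
    enrich_type,
    map_compounds,
    ora_fisher,
    pathway_impact,
    results_frame,
)


def exact_upper_tail(x, n, K, N):
    """Rational hypergeometric upper tail, independent of scipy."""
    total = Fraction(0)
    for k in range(x, min(n, K) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
    return total


def chain(*nodes):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(zip(nodes[:-1], nodes[1:]))
    return g


@pytest.fixture
def toy_library():
    p1 = Pathway("p1", "chain", frozenset("abc"), chain("a", "b", "c"))
    p2 = Pathway("p2", "pair", frozenset("cd"), chain("c", "d"))
    return PathwayLibrary([p1, p2])


class TestOraFisher:
    def test_minimum_overlap_gives_one(self):
        assert ora_fisher(0, 5, 4, 10) == pytest.approx(1.0)

    def test_enumerated_example(self):
        # N=10, K=4, n=5, x=4 -> C(4,4)C(6,1)/C(10,5) = 6/252
        assert ora_fisher(4, 5, 4, 10) == pytest.approx(6 / 252, abs=1e-14)
        # brute-force enumeration over all C(10,5) draws
        hits = sum(
            1 for draw in itertools.combinations(range(10), 5) if sum(i < 4 for i in draw) >= 4
        )
        assert ora_fisher(4, 5, 4, 10) == pytest.approx(hits / comb(10, 5), abs=1e-14)

    def test_extreme_tail_exact_rational(self):
        assert ora_fisher(10, 10, 10, 100) == pytest.approx(1 / comb(100, 10), rel=1e-10)

    def test_matches_rational_oracle_small_sweep(self):
        for N in (5, 9, 14):
            for K in range(N + 1):
                for n in range(N + 1):
                    for x in range(max(0, n + K - N), min(n, K) + 1):
                        assert ora_fisher(x, n, K, N) == pytest.approx(
                            float(exact_upper_tail(x, n, K, N)), abs=1e-12
                        )

    def test_monotone_in_x(self):
        N, K, n = 30, 12, 10
        ps = [ora_fisher(x, n, K, N) for x in range(0, min(n, K) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(5, 3, 4, 10), (1, 11, 4, 10), (0, 3, 11, 10), (-1, 3, 4, 10)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            ora_fisher(*args)


class TestPathwayImpact:
    def test_chain_out_degrees(self):
        g = chain("a", "b", "c")
        assert [g.out_degree(u) for u in "abc"] == [1, 1, 0]
        assert pathway_impact(g, {"a"}) == pytest.approx(0.5)

    def test_all_hits_gives_one(self):
        assert pathway_impact(chain("a", "b", "c"), {"a", "b", "c"}) == pytest.approx(1.0)

    def test_empty_hits_zero(self):
        assert pathway_impact(chain("a", "b", "c"), set()) == 0.0

    def test_zero_total_centrality(self):
        g = nx.DiGraph()
        g.add_nodes_from("ab")
        assert pathway_impact(g, {"a"}) == 0.0

    def test_monotone_in_hits_random_dags(self):
        for s in range(100):
            rng = np.random.default_rng(s)
            n = int(rng.integers(3, 10))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for a in range(n):
                for b in range(a + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(a, b)
            nodes = list(range(n))
            small = set(rng.choice(nodes, size=n // 2, replace=False).tolist())
            big = small | {int(rng.choice(nodes))}
            assert pathway_impact(g, big) >= pathway_impact(g, small) - 1e-12

    def test_permutation_invariant_to_labels(self, rng):
        g = chain(0, 1, 2, 3)
        mapping = {0: "w", 1: "x", 2: "y", 3: "z"}
        h = nx.relabel_nodes(g, mapping)
        assert pathway_impact(g, {0, 2}) == pytest.approx(pathway_impact(h, {"w", "y"}))

    def test_betweenness_mode(self):
        g = chain("a", "b", "c")
        assert 0.0 <= pathway_impact(g, {"b"}, centrality="betweenness") <= 1.0

    def test_unknown_hits_rejected(self):
        with pytest.raises(ValueError):
            pathway_impact(chain("a", "b"), {"zzz"})


class TestMapCompounds:
    def test_disjoint_query_all_unmapped(self, toy_library):
        mapped, unmapped = map_compounds(["x", "y"], toy_library)
        assert mapped == set() and unmapped == ["x", "y"]

    def test_duplicates_collapse(self, toy_library):
        mapped, unmapped = map_compounds(["a", "A", "a"], toy_library)
        assert mapped == {"a"} and unmapped == []

    def test_case_insensitive_roundtrip(self, rng):
        ids = [f"C{n:05d}x" for n in range(20)]
        lib = {i.upper() for i in ids}
        scrambled = ["".join(ch.upper() if rng.random() < 0.5 else ch.lower() for ch in i) for i in ids]
        mapped, unmapped = map_compounds(scrambled, lib)
        assert mapped == lib and unmapped == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_compounds(["a"], set())


class TestEnrichType:
    def test_query_equals_background_nothing_passes(self, toy_library):
        bg = {"a", "b", "c", "d"}
        results = enrich_type(bg, toy_library, bg)
        assert all(r.p == pytest.approx(1.0) for r in results)
        assert not any(r.passes_filter for r in results)

    def test_singleton_pathways_closed_form(self):
        lib = PathwayLibrary([Pathway(f"s{i}", f"s{i}", frozenset({f"c{i}"})) for i in range(6)])
        bg = {f"c{i}" for i in range(6)}
        results = enrich_type({"c0", "c1"}, lib, bg)
        for r in results:
            assert r.x == 1
            assert r.p == pytest.approx(r.n / r.N, abs=1e-12)

    def test_planted_pathway_ranks_first_and_passes(self):
        bg = {f"c{i}" for i in range(97)}
        planted = Pathway("planted", "planted", frozenset(f"c{i}" for i in range(10)),
                          chain(*[f"c{i}" for i in range(10)]))
        decoy = Pathway("decoy", "decoy", frozenset(f"c{i}" for i in range(50, 58)))
        lib = PathwayLibrary([decoy, planted])
        query = {f"c{i}" for i in range(8)} | {f"c{i}" for i in range(60, 72)}  # 8/10 planted hits
        results = enrich_type(query, lib, bg)
        assert results[0].pathway_id == "planted"
        assert results[0].passes_filter
        expected = float(exact_upper_tail(8, 20, 10, 97))
        assert results[0].p == pytest.approx(expected, rel=1e-10)

    def test_empty_query_warns(self, toy_library):
        with pytest.warns(UserWarning, match="empty mapped query"):
            assert enrich_type(set(), toy_library, {"a", "b", "c", "d"}) == []

    def test_members_outside_background_rejected(self, toy_library):
        with pytest.raises(ValueError, match="outside the background"):
            enrich_type({"zzz"}, toy_library, {"a"})

    def test_results_frame_has_fdr_column(self, toy_library):
        bg = {"a", "b", "c", "d"}
        df = results_frame(enrich_type({"a", "c"}, toy_library, bg))
        assert "fdr" in df.columns and df["p"].is_monotonic_increasing


class TestLibraryIO:
    def test_gmt_sif_roundtrip(self, tmp_path, toy_library):
        gmt, sif = tmp_path / "lib.gmt", tmp_path / "lib.sif"
        toy_library.write_gmt(gmt)
        toy_library.write_sif(sif)
        back = PathwayLibrary.read(gmt, sif)
        for orig, re in zip(toy_library, back):
            assert orig.id == re.id and orig.name == re.name
            assert orig.compounds == re.compounds
            assert set(orig.graph.edges) == set(re.graph.edges)
            assert set(orig.graph.nodes) == set(re.graph.nodes)

    def test_graph_nodes_must_be_members(self):
        g = chain("a", "q")
        with pytest.raises(ValueError, match="outside compound set"):
            Pathway("p", "p", frozenset("ab"), g)

    def test_duplicate_ids_rejected(self):
        p = Pathway("p", "p", frozenset("ab"))
        with pytest.raises(ValueError, match="duplicate"):
            PathwayLibrary([p, Pathway("p", "other", frozenset("cd"))])


@settings(max_examples=50, deadline=None)
@given(data=st.data())
def test_ora_monotone_property(data):
    N = data.draw(st.integers(4, 25))
    K = data.draw(st.integers(1, N))
    n = data.draw(st.integers(1, N))
    lo, hi = max(0, n + K - N), min(n, K)
    x = data.draw(st.integers(lo, hi))
    p = ora_fisher(x, n, K, N)
    assert 0.0 < p <= 1.0
    if x > lo:
        assert ora_fisher(x - 1, n, K, N) >= p - 1e-15
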