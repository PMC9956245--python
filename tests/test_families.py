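"""Family rule boundaries, clustering vs a BFS oracle, planted recovery."""

import numpy as np
import pytest

from sympan.align import LocalHit
from sympan.families import (HomologyEdge, all_vs_all_edges, build_families,
                             edge_test, presence_matrix, weighted_similarity)
from sympan.records import StrainInfo


def make_hit(qspan, sspan, sim, ident=None):
    n = qspan[1] - qspan[0]
    return LocalHit("A", "B", 100, 1e-10, qspan, sspan,
                    sim if ident is None else ident, sim, n_columns=n)


class TestEdgeRule:
    def test_qualifying_pair_yields_edge(self):
        hits = [make_hit((0, 85), (0, 85), sim=0.60)]
        edge = edge_test(hits, 100, 100)
        assert edge is not None
        assert edge.coverage_a == pytest.approx(0.85)
        assert edge.similarity == pytest.approx(0.60)

    def test_coverage_exactly_080_passes(self):
        # "at least 80%" is inclusive
        assert edge_test([make_hit((0, 80), (0, 80), sim=0.6)], 100, 100)

    def test_coverage_below_080_on_either_side_fails(self):
        assert edge_test([make_hit((0, 79), (0, 85), sim=0.6)], 100, 100) is None
        assert edge_test([make_hit((0, 85), (0, 79), sim=0.6)], 100, 100) is None

    def test_similarity_exactly_050_fails(self):
        # "over 50%" is strict
        assert edge_test([make_hit((0, 90), (0, 90), sim=0.50)], 100, 100) is None
        assert edge_test([make_hit((0, 90), (0, 90), sim=0.51)], 100, 100)

    def test_no_hits_no_edge(self):
        assert edge_test([], 100, 100) is None

    def test_multi_hsp_coverage_union_and_weighted_similarity(self):
        # two HSPs jointly reach 80% coverage; similarity is length-weighted
        hits = [make_hit((0, 50), (0, 50), sim=0.80),
                make_hit((50, 80), (50, 80), sim=0.40)]
        edge = edge_test(hits, 100, 100)
        assert edge is not None
        assert edge.similarity == pytest.approx((0.8 * 50 + 0.4 * 30) / 80)
        assert weighted_similarity(hits) == edge.similarity


def bfs_components(nodes, edges):
    """Independent connected-components oracle."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            n = queue.pop()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(adj[n] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def he(a, b):
    return HomologyEdge(a, b, 0.9, 0.9, 0.8, 1e-20)


class TestBuildFamilies:
    def test_no_edges_gives_singletons(self):
        loci = [("s1", f"L{i}") for i in range(5)]
        fams = build_families([], loci)
        assert len(fams) == 5
        assert all(len(f.members) == 1 for f in fams)

    def test_chain_merges_transitively(self):
        loci = [("s1", "A"), ("s2", "B"), ("s3", "C")]
        fams = build_families([he("A", "B"), he("B", "C")], loci)
        assert len(fams) == 1
        assert fams[0].family_id == "A"
        assert fams[0].loci() == {"A", "B", "C"}

    def test_unknown_locus_rejected(self):
        with pytest.raises(ValueError, match="unknown locus"):
            build_families([he("A", "Z")], [("s1", "A")])

    def test_duplicate_locus_universe_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_families([], [("s1", "A"), ("s2", "A")])

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 25))
            nodes = [f"L{i:02d}" for i in range(n)]
            pairs = {tuple(sorted(rng.choice(n, 2, replace=False)))
                     for _ in range(rng.integers(0, 2 * n))}
            edges = [he(nodes[i], nodes[j]) for i, j in pairs]
            fams = build_families(edges, [("s", x) for x in nodes])
            assert {f.loci() for f in fams} == \
                bfs_components(nodes, [(nodes[i], nodes[j]) for i, j in pairs])

    def test_partition_covers_every_locus_once(self, small_panel, small_result):
        panel, _ = small_panel
        seen = [l for f in small_result.families for _, l in f.members]
        assert sorted(seen) == sorted(r.locus_id for r in panel.all_records())

    def test_planted_families_recovered_exactly(self, small_panel, small_result):
        _, truth = small_panel
        got = {frozenset(l for _, l in f.members) for f in small_result.families}
        assert got == truth.as_member_sets()

    def test_raising_similarity_threshold_only_refines(self, small_panel,
                                                       blosum62, params):
        panel, _ = small_panel
        loci = [(r.strain_id, r.locus_id) for r in panel.all_records()]
        loose = build_families(
            all_vs_all_edges(panel, blosum62, params, min_similarity=0.50), loci)
        strict = build_families(
            all_vs_all_edges(panel, blosum62, params, min_similarity=0.80), loci)
        loose_sets = [f.loci() for f in loose]
        for fam in strict:
            assert any(fam.loci() <= big for big in loose_sets)


class TestPresenceMatrix:
    META = {"s1": StrainInfo("s1", "Ia", "Sp-")}

    def test_singletons_give_unit_matrix(self):
        fams = build_families([], [("s1", f"L{i}") for i in range(3)])
        pm = presence_matrix(fams, self.META)
        assert pm.counts.shape == (3, 1)
        assert (pm.counts["s1"] == 1).all()

    def test_paralogs_counted_per_copy(self):
        fams = build_families([he("A", "B")], [("s1", "A"), ("s1", "B")])
        pm = presence_matrix(fams, self.META)
        assert pm.counts.loc["A", "s1"] == 2

    def test_column_sums_equal_proteome_sizes(self, small_panel, small_result):
        panel, _ = small_panel
        sums = small_result.matrix.counts.sum(axis=0)
        for strain in panel.strain_ids:
            assert sums[strain] == panel.n_proteins(strain)

    def test_missing_strain_metadata_rejected(self):
        fams = build_families([], [("s2", "A")])
        with pytest.raises(ValueError, match="missing from metadata"):
            presence_matrix(fams, self.META)
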