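"""BBH edges, triangle clustering, in-paralogs, redundancy filter, PSSM rescue."""

import numpy as np
import pandas as pd
import pytest

from viropan import bbh_edges, build_clusters, pssm_rescue, redundancy_filter
from viropan.cluster import (
    ROLE_INPARALOG,
    ROLE_ORPHAN,
    ROLE_ORTHOLOG,
    cog_triangles,
    detect_inparalogs,
    global_identity,
    separate_orphans,
)
from viropan.simulate import mutate_sequence, random_protein

from oracles import brute_force_bbh, brute_force_triangle_clusters, random_hit_table


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "bitscore", "qgenome", "sgenome",
                       "evalue", "qcov", "scov"]
    )


class TestBBHEdges:
    def test_mutual_pair_gives_one_edge(self):
        hits = _hits([
            ("a", "b", 50.0, "g1", "g2", 1e-9, 1.0, 1.0),
            ("b", "a", 50.0, "g2", "g1", 1e-9, 1.0, 1.0),
        ])
        edges = bbh_edges(hits)
        assert len(edges) == 1
        assert tuple(edges.iloc[0][["protein_a", "protein_b"]]) == ("a", "b")

    def test_one_directional_best_is_not_an_edge(self):
        # b is a's best, but b's best in g1 is c
        hits = _hits([
            ("a", "b", 50.0, "g1", "g2", 1e-9, 1.0, 1.0),
            ("b", "a", 50.0, "g2", "g1", 1e-9, 1.0, 1.0),
            ("b", "c", 80.0, "g2", "g1", 1e-9, 1.0, 1.0),
            ("c", "b", 80.0, "g1", "g2", 1e-9, 1.0, 1.0),
        ])
        edges = bbh_edges(hits)
        pairs = set(map(tuple, edges[["protein_a", "protein_b"]].to_numpy()))
        assert pairs == {("b", "c")}

    def test_matches_double_loop_oracle_on_random_tables(self, rng):
        for _ in range(50):
            hits, _ = random_hit_table(rng, n_proteins=int(rng.integers(4, 13)))
            edges = bbh_edges(hits)
            got = {frozenset(p) for p in edges[["protein_a", "protein_b"]].to_numpy()}
            assert got == brute_force_bbh(hits)


class TestCogTriangles:
    def test_single_triangle_clusters_three_proteins(self):
        hits = _hits([
            (a, b, 50.0, ga, gb, 1e-9, 1.0, 1.0)
            for (a, ga), (b, gb) in [
                (("p1", "g1"), ("p2", "g2")), (("p2", "g2"), ("p1", "g1")),
                (("p1", "g1"), ("p3", "g3")), (("p3", "g3"), ("p1", "g1")),
                (("p2", "g2"), ("p3", "g3")), (("p3", "g3"), ("p2", "g2")),
            ]
        ])
        clusters = cog_triangles(bbh_edges(hits), {"p1": "g1", "p2": "g2", "p3": "g3"})
        assert clusters == [{"p1", "p2", "p3"}]

    def test_isolated_pair_forms_no_triangle(self):
        hits = _hits([
            ("a", "b", 50.0, "g1", "g2", 1e-9, 1.0, 1.0),
            ("b", "a", 50.0, "g2", "g1", 1e-9, 1.0, 1.0),
        ])
        assert cog_triangles(bbh_edges(hits), {"a": "g1", "b": "g2"}) == []

    def test_matches_enumeration_and_merge_oracle(self, rng):
        # fewer graphs here than the acceptance sweep, same property
        for _ in range(100):
            hits, genome_of = random_hit_table(rng, n_proteins=int(rng.integers(6, 13)))
            edges = bbh_edges(hits)
            got = sorted(
                (frozenset(c) for c in cog_triangles(edges, genome_of)), key=min
            )
            edge_set = {
                frozenset(p) for p in edges[["protein_a", "protein_b"]].to_numpy()
            }
            assert got == brute_force_triangle_clusters(edge_set, genome_of)


class TestInparalogsAndOrphans:
    def test_one_protein_per_genome_means_no_inparalogs(self, small_family_membership):
        singles = small_family_membership.groupby(
            ["cluster_id", "genome_id"]
        ).filter(lambda g: len(g) == 1)
        assert (singles["role"] != ROLE_INPARALOG).all()

    def test_paralog_rate_one_gives_one_inparalog_per_incidence(self):
        from viropan import FamilySpec, all_vs_all, generate_family

        spec = FamilySpec(n_genomes=4, n_core=3, n_shell=0, n_cloud=0,
                          paralog_rate=1.0, divergence=0.1, seed=13)
        proteomes, truth = generate_family(spec)
        mem = build_clusters(all_vs_all(proteomes), proteomes)
        per_cluster = mem[mem["role"] == ROLE_INPARALOG].groupby("cluster_id").size()
        occ = mem.groupby("cluster_id")["genome_id"].nunique()
        assert len(per_cluster) == 3
        assert all(per_cluster[c] == occ[c] for c in per_cluster.index)

    def test_tied_scores_pick_lexicographically_smallest_ortholog(self):
        mem = pd.DataFrame({
            "cluster_id": ["c1"] * 3,
            "protein_id": ["a2", "a1", "b1"],
            "genome_id": ["g1", "g1", "g2"],
            "role": [ROLE_ORTHOLOG] * 3,
        })
        hits = _hits([
            ("a1", "b1", 50.0, "g1", "g2", 1e-9, 1.0, 1.0),
            ("a2", "b1", 50.0, "g1", "g2", 1e-9, 1.0, 1.0),
        ])
        out = detect_inparalogs(mem, hits).set_index("protein_id")["role"]
        assert out["a1"] == ROLE_ORTHOLOG
        assert out["a2"] == ROLE_INPARALOG

    def test_every_protein_clustered_exactly_once(
        self, small_family, small_family_membership
    ):
        _, proteomes, truth = small_family
        assert sorted(small_family_membership["protein_id"]) == \
            sorted(truth["protein_id"])

    def test_orphan_singletons_have_orphan_role(self, small_family_membership):
        orphans = separate_orphans(small_family_membership)
        assert (orphans["role"] == ROLE_ORPHAN).all()


class TestRedundancyFilter:
    def test_identical_pair_keeps_one(self, rng):
        seq = random_protein(100, rng)
        assert redundancy_filter([("s1", seq), ("s2", seq)]) == ["s1"]

    def test_identity_exactly_at_threshold_keeps_both(self):
        a = "ACDEFGHIKL"
        b = "ACDEFGHIWW"  # 8/10 identical -> exactly 0.80, strict "greater than"
        assert global_identity(a, b) == pytest.approx(0.80)
        assert len(redundancy_filter([("s1", a), ("s2", b)])) == 2

    def test_idempotent_on_its_own_output(self, rng):
        base = [random_protein(80, rng) for _ in range(5)]
        seqs = [(f"s{i}", s) for i, s in enumerate(base)]
        seqs += [
            (f"d{i}", mutate_sequence(s, 0.1, 0.0, seed=i))
            for i, s in enumerate(base)
        ]
        retained = redundancy_filter(seqs)
        lookup = dict(seqs)
        again = redundancy_filter([(i, lookup[i]) for i in retained])
        assert again == retained

    def test_no_retained_pair_exceeds_threshold(self, rng):
        base = random_protein(120, rng)
        seqs = [
            (f"v{i}", mutate_sequence(base, d, 0.0, seed=i))
            for i, d in enumerate([0.0, 0.05, 0.1, 0.3, 0.5])
        ]
        retained = redundancy_filter(seqs)
        lookup = dict(seqs)
        for i, x in enumerate(retained):
            for y in retained[i + 1:]:
                assert global_identity(lookup[x], lookup[y]) <= 0.80


class TestPssmRescue:
    @pytest.fixture(scope="class")
    def cluster_members(self):
        rng = np.random.default_rng(99)
        ancestor = random_protein(140, rng)
        return [
            (f"m{i}", mutate_sequence(ancestor, 0.1, 0.0, seed=i)) for i in range(5)
        ], ancestor

    def test_single_member_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="single-member"):
            pssm_rescue([("m0", random_protein(50, rng))], [])

    def test_own_member_passes_cutoff(self, cluster_members):
        members, _ = cluster_members
        res = pssm_rescue(members, [members[0]])
        assert bool(res["rescued"].iloc[0])

    def test_false_positive_rate_bounded(self, cluster_members):
        members, _ = cluster_members
        rng = np.random.default_rng(7)
        decoys = [(f"r{i}", random_protein(140, rng)) for i in range(100)]
        res = pssm_rescue(members, decoys)
        assert res["rescued"].mean() <= 0.05

    def test_distant_member_recovered(self, cluster_members):
        members, ancestor = cluster_members
        distant = mutate_sequence(ancestor, 0.45, 0.0, seed=1234)
        res = pssm_rescue(members, [("far", distant)])
        assert bool(res["rescued"].iloc[0])
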