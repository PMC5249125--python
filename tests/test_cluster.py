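import itertools

import networkx as nx
import numpy as np
import pytest

from barcodeaudit import (
    DistanceMatrix,
    bootstrap_supports,
    discordance_report,
    distance_matrix,
    nj_tree,
    rsl_cluster,
    species_cohesion,
)
from barcodeaudit.simulate import SimulationConfig, simulate_library

from conftest import make_library


def dm(ids, d):
    d = np.asarray(d, float)
    return DistanceMatrix(list(ids), d, np.ones_like(d, dtype=np.int64))


def random_additive_matrix(rng, n):
    """Random unrooted binary tree with positive branch lengths -> path
    distance matrix (the additive oracle for NJ)."""
    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n)]
    g.add_edge(leaves[0], "x0", length=rng.uniform(0.5, 2))
    g.add_edge(leaves[1], "x0", length=rng.uniform(0.5, 2))
    g.add_edge(leaves[2], "x0", length=rng.uniform(0.5, 2))
    nxt = 1
    for leaf in leaves[3:]:
        u, v = list(g.edges)[rng.integers(len(g.edges))]
        data = g.edges[u, v]
        mid = f"x{nxt}"
        nxt += 1
        split = rng.uniform(0.2, 0.8) * data["length"]
        g.remove_edge(u, v)
        g.add_edge(u, mid, length=split)
        g.add_edge(mid, v, length=data["length"] - split)
        g.add_edge(mid, leaf, length=rng.uniform(0.5, 2))
    d = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            d[i, j] = paths[a][b]
    splits = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(
            x for x in nx.node_connected_component(h, u) if x.startswith("L")
        )
        if len(side) >= 2 and len(side) <= n - 2:
            if leaves[0] in side:
                side = frozenset(leaves) - side
            splits.add(side)
    return leaves, d, splits


class TestNeighbourJoining:
    def test_three_taxa_closed_form_lengths(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> vA=1, vB=2, vC=3
        t = nj_tree(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        lengths = {
            leaf: t.graph.edges[leaf, nb]["length"]
            for leaf in "ABC"
            for nb in t.graph.neighbors(leaf)
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2),(C:3,D:4)) with internal edge 1
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = nj_tree(dm("ABCD", d))
        assert t.internal_bipartitions() == {frozenset({"C", "D"})}
        lengths = sorted(
            round(dd["length"], 6) for _, _, dd in t.graph.edges(data=True)
        )
        assert lengths == [1.0, 1.0, 2.0, 3.0, 4.0]

    def test_recovers_random_additive_trees(self, rng):
        for n in (5, 8, 12):
            leaves, d, true_splits = random_additive_matrix(rng, n)
            t = nj_tree(dm(leaves, d))
            assert t.internal_bipartitions() == true_splits

    def test_matches_independent_nj_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        leaves, d, _ = random_additive_matrix(rng, 7)
        d = (d + d.T) / 2  # remove float asymmetry from path sums
        ours = nj_tree(dm(leaves, d)).internal_bipartitions()
        sk_tree = skbio_nj(SkbioDM(d, ids=leaves))
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if leaves[0] in side:
                side = frozenset(leaves) - side
            if 2 <= len(side) <= len(leaves) - 2:
                theirs.add(side)
        assert ours == theirs

    def test_zero_distance_pair_joined_first(self):
        d = [[0, 0, 5, 6], [0, 0, 6, 7], [5, 6, 0, 2], [6, 7, 2, 0]]
        t = nj_tree(dm("ABCD", d))
        assert frozenset({"C", "D"}) in t.internal_bipartitions()

    def test_order_invariance(self, rng):
        leaves, d, _ = random_additive_matrix(rng, 6)
        perm = list(rng.permutation(len(leaves)))
        t1 = nj_tree(dm(leaves, d))
        t2 = nj_tree(dm([leaves[i] for i in perm], d[np.ix_(perm, perm)]))
        assert t1.internal_bipartitions() == t2.internal_bipartitions()

    def test_fewer_than_three_is_error(self):
        with pytest.raises(ValueError):
            nj_tree(dm("AB", [[0, 1], [1, 0]]))


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(
        self, two_species_library
    ):
        t = bootstrap_supports(two_species_library, n_reps=1, seed=1)
        sups = [
            d["support"]
            for _, _, d in t.graph.edges(data=True)
            if d.get("support") is not None
        ]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_is_bit_identical(self, two_species_library):
        t1 = bootstrap_supports(two_species_library, n_reps=25, seed=7)
        t2 = bootstrap_supports(two_species_library, n_reps=25, seed=7)
        s1 = sorted(
            d.get("support")
            for _, _, d in t1.graph.edges(data=True)
            if d.get("support") is not None
        )
        s2 = sorted(
            d.get("support")
            for _, _, d in t2.graph.edges(data=True)
            if d.get("support") is not None
        )
        assert s1 == s2

    def test_well_separated_species_get_high_support(self):
        lib, _ = simulate_library(
            SimulationConfig(seed=5, n_species=2, n_specimens=8)
        )
        t = bootstrap_supports(lib, n_reps=100, seed=5)
        coh = species_cohesion(t, lib.labels())
        for info in coh.values():
            assert info["cohesive"] and info["support"] >= 80

    def test_identical_sequences_are_handled(self):
        lib = make_library(["ACGTAC" * 10] * 4)
        t = bootstrap_supports(lib, n_reps=5, seed=1)
        assert set(t.leaves()) == {"S1", "S2", "S3", "S4"}


class TestCohesion:
    def test_two_clean_species_both_cohesive(self, two_species_library):
        t = nj_tree(distance_matrix(two_species_library))
        coh = species_cohesion(t, two_species_library.labels())
        assert all(info["cohesive"] for info in coh.values())

    def test_mislabelled_specimen_breaks_cohesion(self):
        # beta clade is two cherries ((S4,S5),(S6,S7)); labelling the
        # cherry member S4 as alpha leaves neither label monophyletic
        base_a, base_b = "ACGTAC" * 10, "TGCATG" * 10
        base_b2 = "AA" + base_b[2:]
        lib = make_library(
            [base_a, base_a, base_a, base_b, base_b, base_b2, base_b2],
            labels=["Genus alpha"] * 3 + ["Genus beta"] * 4,
        )
        labels = lib.labels()
        labels["S4"] = "Genus alpha"
        t = nj_tree(distance_matrix(lib))
        coh = species_cohesion(t, labels)
        assert not coh["Genus alpha"]["cohesive"]
        assert not coh["Genus beta"]["cohesive"]

    def test_singleton_cohesive_by_convention(self):
        lib = make_library(
            ["ACGTAC" * 5, "ACGAAC" * 5, "TGCATG" * 5],
            labels=["Genus alpha", "Genus alpha", "Genus beta"],
        )
        coh = species_cohesion(nj_tree(distance_matrix(lib)), lib.labels())
        assert coh["Genus beta"]["cohesive"] and coh["Genus beta"]["support"] is None


def brute_force_single_linkage(ids, d, threshold):
    """Connected components of the <=threshold graph (the stage-1 oracle)."""
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j in itertools.combinations(range(len(ids)), 2):
        if not np.isnan(d[i, j]) and d[i, j] <= threshold:
            g.add_edge(ids[i], ids[j])
    return {frozenset(c) for c in nx.connected_components(g)}


class TestRslCluster:
    def test_two_species_split_at_default_threshold(self):
        lib, _ = simulate_library(
            SimulationConfig(seed=2, n_species=2, n_specimens=6)
        )
        otus = rsl_cluster(distance_matrix(lib))
        assert len(otus) == 2

    def test_chain_within_twice_threshold_stays_merged(self):
        d = np.array(
            [[0, 0.02, 0.04], [0.02, 0, 0.02], [0.04, 0.02, 0]]
        )
        otus = rsl_cluster(dm("ABC", d), threshold=0.022)
        assert len(otus) == 1

    def test_excessive_diameter_triggers_refinement(self):
        # A-B and C-D tight; B-C linked at 0.02 but A-D at 0.06 (> 2x0.022)
        d = np.array(
            [
                [0, 0.002, 0.020, 0.060],
                [0.002, 0, 0.018, 0.058],
                [0.020, 0.018, 0, 0.002],
                [0.060, 0.058, 0.002, 0],
            ]
        )
        refined = rsl_cluster(dm("ABCD", d), threshold=0.022, refine=True)
        unrefined = rsl_cluster(dm("ABCD", d), threshold=0.022, refine=False)
        assert len(unrefined) == 1
        assert {frozenset(o.members) for o in refined} == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }

    def test_stage1_equals_connectivity_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 40))
            d = rng.uniform(0, 0.1, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            ids = [f"S{i}" for i in range(n)]
            otus = rsl_cluster(dm(ids, d), threshold=0.022, refine=False)
            assert {frozenset(o.members) for o in otus} == (
                brute_force_single_linkage(ids, d, 0.022)
            )

    def test_order_invariance(self, rng):
        n = 20
        d = rng.uniform(0, 0.1, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"S{i:02d}" for i in range(n)]
        perm = list(rng.permutation(n))
        a = rsl_cluster(dm(ids, d))
        b = rsl_cluster(dm([ids[i] for i in perm], d[np.ix_(perm, perm)]))
        assert {frozenset(o.members) for o in a} == {
            frozenset(o.members) for o in b
        }

    def test_sibling_pair_below_threshold_merges_into_one_otu(self):
        lib, _ = simulate_library(
            SimulationConfig(
                seed=13,
                n_species=4,
                n_specimens=6,
                sibling_pairs=[(0, 1, 0.017)],
            )
        )
        otus = rsl_cluster(distance_matrix(lib))
        labels = lib.labels()
        otus, frame = discordance_report(otus, labels)
        merged = [o for o in otus if len(o.taxon_variation) == 2]
        assert len(merged) == 1
        assert set(merged[0].taxon_variation) == {
            "Genus1 species1",
            "Genus1 species2",
        }
        assert merged[0].status == "discordant"


class TestDiscordanceReport:
    def test_uniform_otu_is_concordant(self):
        from barcodeaudit import OtuCluster

        otus = [OtuCluster("OTU_0001", [f"S{i}" for i in range(5)])]
        labels = {f"S{i}": "Genus alpha" for i in range(5)}
        otus, frame = discordance_report(otus, labels)
        assert otus[0].status == "concordant"
        assert frame.rank_of_conflict[0] == ""

    def test_interim_mixture_is_discordant_pre_review(self):
        from barcodeaudit import OtuCluster

        members = [f"S{i}" for i in range(10)]
        labels = {m: "Genus alpha" for m in members[:8]}
        labels.update({m: "Genus sp." for m in members[8:]})
        otus, frame = discordance_report([OtuCluster("OTU_0001", members)], labels)
        assert otus[0].status == "discordant"
        assert frame.rank_of_conflict[0] == "Species"
        assert frame.taxon_variation[0] == "Genus alpha[8], Genus sp.[2]"

    def test_cross_genus_conflict_ranks_as_genus(self):
        from barcodeaudit import OtuCluster

        labels = {"S1": "Prionace glauca", "S2": "Carcharhinus brevipinna"}
        otus, frame = discordance_report([OtuCluster("O1", ["S1", "S2"])], labels)
        assert frame.rank_of_conflict[0] == "Genus"

    def test_taxonomy_table_elevates_to_family(self):
        from barcodeaudit import OtuCluster

        labels = {"S1": "Squalus acanthias", "S2": "Centrophorus uyato"}
        taxonomy = {"Squalus": "Squalidae", "Centrophorus": "Centrophoridae"}
        _, frame = discordance_report(
            [OtuCluster("O1", ["S1", "S2"])], labels, taxonomy=taxonomy
        )
        assert frame.rank_of_conflict[0] == "Family"

    def test_singleton_status(self):
        from barcodeaudit import OtuCluster

        otus, _ = discordance_report(
            [OtuCluster("O1", ["S1"])], {"S1": "Genus alpha"}
        )
        assert otus[0].status == "singleton"
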