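"""K2P matrices, neighbor joining, bootstrap, and SSP screening."""

import numpy as np
import pytest

from its2dist import (
    Alignment,
    SeqStructRecord,
    SimConfig,
    bootstrap_support,
    distance_matrix_k2p,
    k2p_distance,
    ml_distance_dna,
    nj_tree,
    screen_genus,
)
from its2dist.distance import count_patterns
from its2dist.simulate import mask_from_structure, simulate_genus


from conftest import random_additive_tree


def seq_pair_alignment(n_ts, n_tv, n_same):
    a = ["A"] * (n_same + n_ts + n_tv)
    b = ["A"] * n_same + ["G"] * n_ts + ["C"] * n_tv
    filler = "C" * len(a)
    return Alignment((
        SeqStructRecord("x", "".join(a), "." * len(a)),
        SeqStructRecord("y", "".join(b), "." * len(a)),
        SeqStructRecord("z", filler, "." * len(a)),
    ))


class TestK2PMatrix:
    def test_identical_records_zero_matrix(self):
        rec = "GGAACC"
        aln = Alignment(tuple(
            SeqStructRecord(f"r{i}", rec, "......") for i in range(3)
        ))
        D = distance_matrix_k2p(aln)
        assert np.allclose(D, 0.0)

    def test_closed_form_entry(self):
        aln = seq_pair_alignment(n_ts=10, n_tv=5, n_same=85)
        D = distance_matrix_k2p(aln)
        assert D[0, 1] == pytest.approx(k2p_distance(0.10, 0.05), abs=1e-12)
        assert D[0, 1] == pytest.approx(0.170181, abs=1e-6)

    def test_matches_ml_k2p_per_pair(self):
        aln = seq_pair_alignment(n_ts=7, n_tv=3, n_same=90)
        D = distance_matrix_k2p(aln)
        pair = Alignment((aln[0], aln[1]))
        counts = count_patterns(pair, mask_from_structure("." * aln.columns), 7)
        ml = ml_distance_dna(counts, "K2P").gd
        assert D[0, 1] == pytest.approx(ml, abs=1e-6)

    def test_saturation_marked_infinite(self):
        aln = seq_pair_alignment(n_ts=45, n_tv=10, n_same=45)
        D = distance_matrix_k2p(aln)
        assert np.isinf(D[0, 1])
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(D, [r.id for r in aln.records])

    def test_global_complete_deletion(self):
        aln = Alignment((
            SeqStructRecord("a", "GGAA", "...."),
            SeqStructRecord("b", "GG-A", "...."),
            SeqStructRecord("c", "GGAA", "...."),
        ))
        D = distance_matrix_k2p(aln)  # column 2 dropped for ALL pairs
        assert np.allclose(D, 0.0)


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {tree.leaf_name[n]: list(tree.adj[n].values())[0]
                   for n in tree.leaf_name}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_exact_recovery(self):
        # tree ((t0:1, t1:2):5, t2:3, t3:4) — additive matrix by hand
        D = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], dtype=float)
        tree = nj_tree(D, ["t0", "t1", "t2", "t3"])
        assert frozenset({"t2", "t3"}) in tree.splits()
        all_lengths = sorted(
            length for n, nbrs in tree.adj.items() for m, length in nbrs.items() if n < m
        )
        assert np.allclose(all_lengths, [1, 2, 3, 4, 5])

    def test_additive_matrices_recovered_exactly(self, rng):
        """NJ is exact on additive matrices (topology and branch lengths)."""
        for _ in range(20):
            n = int(rng.integers(5, 9))
            D, _, true_splits = random_additive_tree(rng, n)
            tree = nj_tree(D, [f"t{k}" for k in range(n)])
            assert set(tree.splits().keys()) == true_splits
            # round trip: path distances on the recovered tree match D
            for i in range(n):
                for j in range(i + 1, n):
                    assert _tree_distance(tree, f"t{i}", f"t{j}") == pytest.approx(
                        D[i, j], abs=1e-9
                    )

    def test_label_permutation_gives_isomorphic_tree(self, rng):
        D, _, true_splits = random_additive_tree(rng, 6)
        labels = [f"t{k}" for k in range(6)]
        perm = rng.permutation(6)
        Dp = D[np.ix_(perm, perm)]
        tree_p = nj_tree(Dp, [labels[k] for k in perm])
        assert set(tree_p.splits().keys()) == true_splits

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        """Independent NJ oracle from scikit-bio on a noisy matrix."""
        skbio = pytest.importorskip("skbio")
        n = 6
        D, _, _ = random_additive_tree(rng, n)
        D += rng.uniform(0, 0.05, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"t{k}" for k in range(n)]
        ours = nj_tree(D, labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, labels))
        their_splits = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                if "t0" in side:
                    side = frozenset(labels) - side
                their_splits.add(side)
        assert set(ours.splits().keys()) == their_splits


def _tree_distance(tree, a, b):
    ids = {v: k for k, v in tree.leaf_name.items()}
    start, goal = ids[a], ids[b]
    seen = {start}
    stack = [(start, 0.0)]
    while stack:
        node, d = stack.pop()
        if node == goal:
            return d
        for nb, length in tree.adj[node].items():
            if nb not in seen:
                seen.add(nb)
                stack.append((nb, d + length))
    raise AssertionError("disconnected tree")


@pytest.fixture(scope="module")
def genus_alignment():
    cfg = SimConfig(seed=5, t_total=0.08, t_within=0.004, n_individuals=3)
    return simulate_genus(cfg, 2)


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self, genus_alignment):
        aln, _ = genus_alignment
        tree = bootstrap_support(aln, replicates=1, seed=0)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_same_seed_is_bitwise_reproducible(self, genus_alignment):
        aln, _ = genus_alignment
        t1 = bootstrap_support(aln, replicates=25, seed=123)
        t2 = bootstrap_support(aln, replicates=25, seed=123)
        assert t1.supports == t2.supports

    def test_deep_split_gets_high_support(self, genus_alignment):
        aln, species_map = genus_alignment
        tree = bootstrap_support(aln, replicates=100, seed=1)
        side = tree.normalize_split(frozenset(species_map["sp01"]))
        assert tree.supports[side] >= 95.0


class TestScreenGenus:
    def test_textbook_two_clades(self, genus_alignment):
        aln, species_map = genus_alignment
        tree = bootstrap_support(aln, replicates=100, seed=2)
        res = screen_genus(tree, species_map)
        assert res.resolution == 1.0
        assert res.passes
        assert len(res.ssps) == 1
        assert {res.ssps[0].species_a, res.ssps[0].species_b} == {"sp01", "sp02"}

    def test_polyphyletic_species_score_zero(self, genus_alignment):
        aln, species_map = genus_alignment
        tree = bootstrap_support(aln, replicates=50, seed=3)
        # scramble the species map so each 'species' straddles both clades
        mixed = {
            "mixA": [species_map["sp01"][0], species_map["sp02"][0]],
            "mixB": [species_map["sp01"][1], species_map["sp02"][1]],
        }
        res = screen_genus(tree, mixed)
        assert res.resolution == 0.0
        assert res.ssps == []

    def test_three_species_give_exactly_one_ssp(self):
        """Two sisters plus an outgroup: the outgroup cannot join an SSP."""
        cfg = SimConfig(seed=9, t_total=0.12, t_within=0.004, n_individuals=3)
        aln, species_map = simulate_genus(cfg, 3)
        tree = bootstrap_support(aln, replicates=100, seed=4)
        res = screen_genus(tree, species_map)
        assert len(res.ssps) == 1
        ssp = res.ssps[0]
        assert ssp.support > 50.0
        assert ssp.species_a in res.identified
        assert ssp.species_b in res.identified
        # the reported pair is the closest pair of species clades
        def mean_dist(a, b):
            ds = [tree.leaf_distance(x, y)
                  for x in species_map[a] for y in species_map[b]]
            return sum(ds) / len(ds)

        pairs = [("sp01", "sp02"), ("sp01", "sp03"), ("sp02", "sp03")]
        closest = min(pairs, key=lambda p: mean_dist(*p))
        assert {ssp.species_a, ssp.species_b} == set(closest)

    def test_single_individual_species_excluded(self, genus_alignment):
        aln, species_map = genus_alignment
        tree = bootstrap_support(aln, replicates=50, seed=5)
        smap = dict(species_map)
        smap["lonely"] = [species_map["sp01"][0]]
        res = screen_genus(tree, smap)
        assert "lonely" in res.excluded_single_individual

    def test_leaf_order_invariance(self, genus_alignment):
        aln, species_map = genus_alignment
        perm = Alignment(tuple(reversed(aln.records)))
        t1 = bootstrap_support(aln, replicates=50, seed=6)
        t2 = bootstrap_support(perm, replicates=50, seed=6)
        r1 = screen_genus(t1, species_map)
        r2 = screen_genus(t2, species_map)
        assert r1.resolution == r2.resolution
        assert {(s.species_a, s.species_b) for s in r1.ssps} == {
            (s.species_a, s.species_b) for s in r2.ssps
        }

    def test_needs_two_species(self, genus_alignment):
        _, species_map = genus_alignment
        with pytest.raises(ValueError):
            screen_genus(
                bootstrap_support(genus_alignment[0], replicates=5, seed=7),
                {"sp01": species_map["sp01"]},
            )
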