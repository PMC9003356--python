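"""Pairwise ML distances: closed forms, grid-search oracle, invariants."""

import numpy as np
import pytest

from its2dist import (
    Alignment,
    ConsensusStructure,
    RnaModelNotApplicableError,
    SaturationError,
    SeqStructRecord,
    UndefinedRatioError,
    build_model,
    count_patterns,
    gd_ratio,
    jc_distance,
    k2p_distance,
    ml_distance_dna,
    ml_distance_mixed,
    p_distance,
    partition_alignment,
)
from its2dist.distance import (
    DistanceResult,
    changes_per_event,
    fit_model_to_counts,
    pair_log_likelihood,
)
from its2dist.models import free_param_names


def counts_from(seq_a, seq_b, structure, space=7):
    from its2dist.simulate import mask_from_structure

    aln = Alignment((SeqStructRecord("a", seq_a, structure),
                     SeqStructRecord("b", seq_b, structure)))
    return count_patterns(aln, mask_from_structure(structure), space=space)


def k2p_counts(n_same=85, n_ts=10, n_tv=5):
    C = np.zeros((4, 4), dtype=int)
    C[0, 0] = n_same - 60
    C[1, 1] = C[2, 2] = C[3, 3] = 20
    C[0, 2] = n_ts - 5
    C[1, 3] = 5
    C[0, 1] = n_tv - 2
    C[2, 3] = 2
    return C


class TestCountPatterns:
    def test_identical_sequences_count_on_diagonal(self):
        c = counts_from("GGAACC", "GGAACC", "((..))")
        assert np.trace(c.loop_counts) == c.n_loop == 2
        assert np.trace(c.stem_counts) == c.n_stempairs == 2
        assert c.stem_nt_diff == 0

    def test_gap_drops_whole_pair_column(self):
        # record b is gapped at stem column 4: pair (1,4) unscorable,
        # pair (0,5) kept, loop columns unaffected
        from its2dist.simulate import mask_from_structure

        structure = "((..))"
        aln = Alignment((
            SeqStructRecord("a", "GGAACC", structure),
            SeqStructRecord("b", "GGAA-C", "....-."),
        ))
        c = count_patterns(aln, mask_from_structure(structure), space=7)
        assert c.n_stempairs == 1
        assert c.n_loop == 2
        # dropped pair contributes nowhere, including the unfolded DNA counts
        assert c.nt_counts_all.sum() == c.n_loop + 2 * c.n_stempairs

    def test_loop_mismatch_lands_in_off_diagonal_cell(self):
        c = counts_from("GGAACC", "GGGACC", "((..))")
        assert c.loop_counts[0, 2] == 1  # A vs G at a loop column

    def test_mask_length_mismatch_rejected(self):
        from its2dist.simulate import mask_from_structure
        aln = Alignment((SeqStructRecord("a", "GGAACC", "((..))"),
                         SeqStructRecord("b", "GGAACC", "((..))")))
        with pytest.raises(ValueError, match="mask"):
            count_patterns(aln, mask_from_structure("(..)"), 7)


class TestPDistance:
    def test_identical_is_zero(self):
        assert p_distance(counts_from("GGAACC", "GGAACC", "((..))")) == 0.0

    def test_mixed_position_counting(self):
        # 100 loop sites, 10 differ; 50 stem pairs, 5 one-sided changes
        c = counts_from(
            "A" * 100 + "G" * 50 + "C" * 50,
            "G" * 10 + "A" * 90 + "G" * 45 + "A" * 5 + "C" * 50,
            "." * 100 + "(" * 50 + ")" * 50,
        )
        assert c.n_loop == 100 and c.n_stempairs == 50
        assert p_distance(c) == pytest.approx((10 + 5) / 200)


class TestClosedForms:
    def test_k2p_ml_matches_closed_form(self):
        t, _, _, conv = fit_model_to_counts(k2p_counts(), "K2P")
        assert conv
        assert t == pytest.approx(k2p_distance(0.10, 0.05), abs=1e-4)
        assert t == pytest.approx(0.170181, abs=1e-4)

    def test_jc_ml_matches_closed_form(self):
        C = np.zeros((4, 4), dtype=int)
        C[0, 0] = 80
        C[0, 1], C[0, 2], C[0, 3] = 7, 7, 6
        t, _, _, _ = fit_model_to_counts(C, "JC69")
        assert t == pytest.approx(jc_distance(0.20), abs=1e-4)
        assert t == pytest.approx(0.232616, abs=1e-4)

    def test_saturated_closed_form_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(0.45, 0.10)
        with pytest.raises(SaturationError):
            jc_distance(0.80)


class TestMlDistanceDna:
    def test_identical_sequences_give_zero(self):
        c = counts_from("GGAACC", "GGAACC", "((..))")
        assert ml_distance_dna(c, "K2P").gd == pytest.approx(0.0, abs=1e-6)

    def test_swapping_sequences_leaves_distance_unchanged(self):
        c1 = counts_from("GGAACC", "GCUACC", "((..))")
        c2 = counts_from("GCUACC", "GGAACC", "((..))")
        d1 = ml_distance_dna(c1, "K2P").gd
        d2 = ml_distance_dna(c2, "K2P").gd
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_extra_difference_never_decreases_distance(self):
        base = fit_model_to_counts(k2p_counts(), "JC69")[0]
        more = fit_model_to_counts(k2p_counts(n_same=84, n_tv=6), "JC69")[0]
        assert more > base

    def test_saturation_flagged_not_silently_capped(self):
        C = np.full((4, 4), 25, dtype=int)  # uniform: no signal, lnL flat/increasing
        res_t, _, _, conv = fit_model_to_counts(C, "JC69", cap=10.0)
        # at uniform counts the likelihood is maximised at infinite distance
        assert not conv and res_t == 10.0

    def test_non_nucleotide_model_rejected(self):
        c = counts_from("GGAACC", "GGAACC", "((..))")
        with pytest.raises(ValueError):
            ml_distance_dna(c, "RNA7G")


class TestGridOracle:
    @pytest.mark.parametrize("name,space", [("RNA7G", 7), ("RNA16", 16)])
    def test_optimizer_matches_dense_grid(self, rng, name, space):
        """Spot check of the brute-force oracle (full version in acceptance)."""
        from conftest import grid_argmax, random_pattern_counts

        for _ in range(5):
            model, C = random_pattern_counts(rng, name, space)
            t_grid = grid_argmax(C, model)
            t_opt, _, _, _ = fit_model_to_counts(
                C, name, pi=model.pi, init_params=dict(model.params.values),
                estimate_params=False, cap=5.0,
            )
            assert t_opt == pytest.approx(t_grid, abs=2e-4)


class TestMlDistanceMixed:
    def test_identical_sequences_give_zero(self):
        c = counts_from("GGAACC", "GGAACC", "((..))")
        res = ml_distance_mixed(c, "JC69", "RNA7G")
        assert res.gd == pytest.approx(0.0, abs=1e-6)

    def test_no_stem_variation_reduces_to_loop_term(self):
        structure = "." * 100 + "(" * 50 + ")" * 50
        a = "A" * 100 + "G" * 50 + "C" * 50
        b = "G" * 20 + "A" * 80 + "G" * 50 + "C" * 50  # 20 loop diffs, stems equal
        c = counts_from(a, b, structure)
        res = ml_distance_mixed(c, "JC69", "RNA7G")
        assert res.t_stem == pytest.approx(0.0, abs=1e-6)
        expected = 100 * res.t_loop / (100 + 50)
        assert res.gd == pytest.approx(expected, rel=1e-6)

    def test_empty_partition_raises_not_applicable(self):
        c = counts_from("GGCC", "GGCC", "(())")  # no loop columns
        with pytest.raises(RnaModelNotApplicableError):
            ml_distance_mixed(c, "JC69", "RNA7G")

    def test_wrong_state_space_rejected(self):
        c = counts_from("GGAACC", "GGAACC", "((..))", space=16)
        with pytest.raises(ValueError, match="state space"):
            ml_distance_mixed(c, "JC69", "RNA7G")

    def test_changes_per_event_is_one_for_single_sub_presets(self):
        assert changes_per_event(build_model("RNA7G", {"alpha": 3.0})) == pytest.approx(1.0)
        assert changes_per_event(build_model("RNA16")) == pytest.approx(1.0)

    def test_changes_per_event_above_one_with_double_moves(self):
        m = build_model("RNA7A")  # all 21 exchangeabilities = 1, doubles included
        assert changes_per_event(m) > 1.0


class TestGdRatio:
    def _result(self, gd):
        return DistanceResult(gd=gd, lnl=-1.0, model="K2P", converged=True)

    def test_equal_distances_give_one(self):
        assert gd_ratio(self._result(0.02), self._result(0.02)) == 1.0

    def test_arithmetic(self):
        assert gd_ratio(self._result(0.01), self._result(0.02)) == 0.5

    def test_zero_dna_distance_undefined(self):
        with pytest.raises(UndefinedRatioError):
            gd_ratio(self._result(0.01), self._result(0.0))

    def test_falls_below_one_at_threefold_stem_rate(self):
        """With stems evolving 3x faster than loops, the paired-site distance
        is the smaller one in the large-site limit (moderate divergence)."""
        from its2dist import SimConfig
        from its2dist.simulate import mask_from_structure, simulate_sister_pair

        for s in range(2):
            cfg = SimConfig(
                seed=s, t_total=0.1, t_within=0.001, rate_ratio=3.0,
                stem_lengths=(1000, 1500, 3500, 700),
                loop_lengths=(1000, 1200, 1100, 1400, 1200, 1600, 1000, 800, 400),
            )
            aln, _ = simulate_sister_pair(cfg)
            c = count_patterns(aln, mask_from_structure(aln[0].structure), 7)
            ratio = gd_ratio(
                ml_distance_mixed(c, "HKY85", "RNA7G"),
                ml_distance_dna(c, "HKY85"),
            )
            assert ratio < 1.0
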