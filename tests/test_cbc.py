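"""CBC/hemi-CBC counting and raw stem/loop substitution rates."""

import itertools

import pytest

from its2dist import (
    Alignment,
    ConsensusStructure,
    SeqStructRecord,
    UndefinedRatioError,
    count_cbc,
    substitution_rates,
    variable_site_table,
)
from its2dist.cbc import classify_pair_change
from its2dist.simulate import mask_from_structure

PAIRING = {"AU", "UA", "GC", "CG", "GU", "UG"}
HAIRPIN = ConsensusStructure(frozenset({(0, 3)}))


def pair_records(di_a, di_b):
    """Two records aligned on a single consensus pair (columns 0 and 3)."""
    return (
        SeqStructRecord("a", di_a[0] + "AA" + di_a[1], "(..)"),
        SeqStructRecord("b", di_b[0] + "AA" + di_b[1], "(..)"),
    )


class TestCountCbc:
    def test_au_to_gc_is_cbc(self):
        a, b = pair_records("AU", "GC")
        assert count_cbc(a, b, HAIRPIN).cbc == 1

    def test_au_to_gu_is_hemi(self):
        a, b = pair_records("AU", "GU")
        counts = count_cbc(a, b, HAIRPIN)
        assert (counts.cbc, counts.hemi_cbc) == (0, 1)

    def test_identity_counts_nothing(self):
        a, b = pair_records("AU", "AU")
        counts = count_cbc(a, b, HAIRPIN)
        assert (counts.cbc, counts.hemi_cbc) == (0, 0)
        assert counts.compared_pairs == 1

    def test_change_into_mismatch_excluded(self):
        a, b = pair_records("AU", "GA")  # one side changed, pairing lost
        counts = count_cbc(a, b, HAIRPIN)
        assert (counts.cbc, counts.hemi_cbc) == (0, 0)

    def test_gapped_pair_is_unscorable(self):
        a = SeqStructRecord("a", "AAAU", "(..)")
        b = SeqStructRecord("b", "-AAU", "...." )
        counts = count_cbc(a, b, HAIRPIN)
        assert counts.unscorable_pairs == 1
        assert counts.compared_pairs == 0

    def test_symmetric_in_sequences(self):
        for di_a, di_b in [("AU", "GC"), ("GU", "GC"), ("AA", "GC"), ("UG", "CG")]:
            a, b = pair_records(di_a, di_b)
            assert count_cbc(a, b, HAIRPIN) == count_cbc(b, a, HAIRPIN)

    def test_full_truth_table_over_all_256_transitions(self):
        """Exhaustive check of every ordered dinucleotide combination against
        an independently coded truth table."""
        nts = "ACGU"
        for x1, y1, x2, y2 in itertools.product(nts, repeat=4):
            s1, s2 = x1 + y1, x2 + y2
            # independent oracle, straight from the definition:
            both_pairing = s1 in PAIRING and s2 in PAIRING
            n_diff = (x1 != x2) + (y1 != y2)
            expect_cbc = 1 if (both_pairing and n_diff == 2) else 0
            expect_hemi = 1 if (both_pairing and n_diff == 1) else 0
            a, b = pair_records(s1, s2)
            counts = count_cbc(a, b, HAIRPIN)
            assert counts.cbc == expect_cbc, (s1, s2)
            assert counts.hemi_cbc == expect_hemi, (s1, s2)

    def test_classify_matches_wobble_intermediate_path(self):
        # the two-step CBC pathway: AU -> GU (hemi) -> GC (hemi); AU -> GC (cbc)
        assert classify_pair_change("AU", "GU") == "hemi"
        assert classify_pair_change("GU", "GC") == "hemi"
        assert classify_pair_change("AU", "GC") == "cbc"


class TestSubstitutionRates:
    def test_no_variation_gives_zero_rates_and_undefined_ratio(self):
        rec = SeqStructRecord("a", "GGAACC", "((..))")
        aln = Alignment((rec, SeqStructRecord("b", rec.sequence, rec.structure)))
        rates = substitution_rates(aln, mask_from_structure("((..))"))
        assert rates.srs == rates.srl == 0.0
        with pytest.raises(UndefinedRatioError):
            rates.ratio
        assert rates.ratio_or_none is None

    def test_rate_arithmetic(self):
        # 40 stem columns with 4 differing, 100 loop columns with 5 differing
        structure = "(" * 20 + "." * 100 + ")" * 20
        a = "G" * 20 + "A" * 100 + "C" * 20
        b = "A" * 2 + "G" * 18 + "C" * 5 + "A" * 95 + "C" * 18 + "G" * 2
        aln = Alignment((SeqStructRecord("a", a, structure),
                         SeqStructRecord("b", b, structure)))
        rates = substitution_rates(aln, mask_from_structure(structure))
        assert rates.srs == pytest.approx(0.10)
        assert rates.srl == pytest.approx(0.05)
        assert rates.ratio == pytest.approx(2.0)

    def test_all_stem_variation_loops_constant(self):
        structure = "((..))"
        aln = Alignment((SeqStructRecord("a", "GGAACC", structure),
                         SeqStructRecord("b", "CCAAGG", structure)))
        rates = substitution_rates(aln, mask_from_structure(structure))
        assert rates.srs == 1.0
        with pytest.raises(UndefinedRatioError):
            rates.ratio

    def test_agrees_with_variable_site_table_on_pairs(self):
        structure = "(" * 5 + "." * 8 + ")" * 5
        a = "GGGGG" + "AAAAAAAA" + "CCCCC"
        b = "AGGGG" + "GGAAAAAA" + "CCCCU"
        aln = Alignment((SeqStructRecord("a", a, structure),
                         SeqStructRecord("b", b, structure)))
        mask = mask_from_structure(structure)
        rates = substitution_rates(aln, mask)
        table = variable_site_table(aln, mask)
        assert rates.srs == table["stem_variable"] / table["stem_columns"]
        assert rates.srl == table["loop_variable"] / table["loop_columns"]


class TestVariableSiteTable:
    def test_invariant_alignment(self):
        rec = SeqStructRecord("a", "GGAACC", "((..))")
        aln = Alignment((rec, SeqStructRecord("b", rec.sequence, rec.structure),
                         SeqStructRecord("c", rec.sequence, rec.structure)))
        t = variable_site_table(aln, mask_from_structure("((..))"))
        assert t["stem_variable"] == t["loop_variable"] == 0

    def test_single_variable_loop_column(self):
        aln = Alignment((SeqStructRecord("a", "GGAACC", "((..))"),
                         SeqStructRecord("b", "GGAACC", "((..))"),
                         SeqStructRecord("c", "GGGACC", "((..))")))
        t = variable_site_table(aln, mask_from_structure("((..))"))
        assert t["loop_variable"] == 1

    def test_gap_column_with_one_state_not_variable(self):
        aln = Alignment((SeqStructRecord("a", "GGAACC", "((..))"),
                         SeqStructRecord("b", "GG-ACC", "((..))"),
                         SeqStructRecord("c", "GGAACC", "((..))")))
        t = variable_site_table(aln, mask_from_structure("((..))"))
        assert t["loop_variable"] == 0


class TestCbcIncreasesWithStemDivergence:
    def test_rank_correlation_with_t_stem(self):
        """Expected CBC count rises monotonically with stem divergence."""
        from scipy.stats import spearmanr

        from its2dist import ConsensusStructure, SimConfig, count_cbc, simulate_sister_pair
        from its2dist.simulate import mask_from_structure

        grid = [0.02, 0.1, 0.3, 0.6, 1.0]
        means = []
        for k, t in enumerate(grid):
            vals = []
            for s in range(8):
                cfg = SimConfig(seed=1000 * k + s, t_total=t, t_within=0.001,
                                rate_ratio=2.0)
                aln, _ = simulate_sister_pair(cfg)
                mask = mask_from_structure(aln[0].structure)
                cons = ConsensusStructure(frozenset(mask.stem_pairs))
                vals.append(count_cbc(aln[0], aln[1], cons).cbc)
            means.append(sum(vals) / len(vals))
        rho, _ = spearmanr(grid, means)
        assert rho > 0.9
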