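"""Tests for tolerance, percentile-rank, alignment and divergence profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dropdms import (
    PositionMap,
    align_positions,
    coefficient_difference_matrix,
    divergence_profile,
    msa_tolerance,
    percentile_rank,
    site_tolerance,
)
from dropdms.profiles import ToleranceProfile, moving_average, site_divergence_significance
from dropdms.pu import CoefficientTable


def _coefs(entries):
    """entries: list of (position, ref, alt, beta)."""
    idx = pd.MultiIndex.from_tuples([(p, r, a) for p, r, a, _ in entries],
                                    names=["position", "ref", "alt"])
    return CoefficientTable(pd.DataFrame({"beta": [b for *_, b in entries]},
                                         index=idx))


def _profile(values, start=1):
    df = pd.DataFrame(
        {"mean_abs_coefficient": values,
         "n_mutations": [1] * len(values)},
        index=pd.Index(range(start, start + len(values)), name="position"),
    )
    return ToleranceProfile(df=df)


class TestSiteTolerance:
    def test_mean_absolute_value_per_position(self):
        prof = site_tolerance(_coefs([(5, "A", "V", -1.0), (5, "A", "G", 1.0)]))
        assert prof.df.loc[5, "mean_abs_coefficient"] == pytest.approx(1.0)
        assert prof.df.loc[5, "n_mutations"] == 2

    def test_zero_coefficients_give_zero_tolerance(self):
        prof = site_tolerance(_coefs([(3, "W", "C", 0.0), (3, "W", "R", 0.0)]))
        assert prof.df.loc[3, "mean_abs_coefficient"] == 0.0

    def test_global_sign_flip_invariance(self):
        entries = [(1, "A", "V", -2.0), (2, "C", "G", 0.5), (2, "C", "W", -1.5)]
        flipped = [(p, r, a, -b) for p, r, a, b in entries]
        pd.testing.assert_frame_equal(site_tolerance(_coefs(entries)).df,
                                      site_tolerance(_coefs(flipped)).df)

    def test_positions_without_data_are_absent(self):
        prof = site_tolerance(_coefs([(1, "A", "V", 1.0), (9, "L", "P", 2.0)]))
        assert list(prof.positions) == [1, 9]


class TestPercentileRank:
    def test_strictly_increasing_profile_tops_at_100(self):
        prof = percentile_rank(_profile([0.1, 0.5, 1.0, 2.0]))
        assert prof.df["percentile_rank"].iloc[-1] == pytest.approx(100.0)

    def test_tied_values_get_average_ranks(self):
        # {1,2,2,3}: average ranks {1, 2.5, 2.5, 4} / 4 * 100
        prof = percentile_rank(_profile([1.0, 2.0, 2.0, 3.0]))
        assert list(prof.df["percentile_rank"]) == pytest.approx(
            [25.0, 62.5, 62.5, 100.0])

    def test_constant_profile_shares_one_average_rank(self):
        # all four positions tie at average rank 2.5 -> 62.5 under rank/n*100
        prof = percentile_rank(_profile([1.0, 1.0, 1.0, 1.0]))
        assert list(prof.df["percentile_rank"]) == pytest.approx([62.5] * 4)

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ranks_bounded_and_monotone_invariant(self, values):
        prof = percentile_rank(_profile(values))
        ranks = prof.df["percentile_rank"].to_numpy()
        assert (ranks >= 0).all() and (ranks <= 100).all()
        # a strictly monotone transform of the tolerances preserves the ranks
        # (power-of-two scaling is exact in floats, so ties are preserved)
        transformed = percentile_rank(_profile([4.0 * v for v in values]))
        assert np.allclose(ranks, transformed.df["percentile_rank"].to_numpy())


class TestAlignPositions:
    def test_identical_sequences_give_identity_map(self):
        seq = "MDDASNMRW"
        pmap = align_positions(seq, seq)
        assert pmap.pairs == [(i, i) for i in range(1, len(seq) + 1)]

    def test_indel_shifts_downstream_positions(self):
        a = "MAGWCDEKLH"
        b = "MAGCDEKLH"  # W deleted
        pmap = align_positions(a, b)
        mapping = pmap.a_to_b()
        assert mapping[2] == 2
        assert mapping[10] == 9

    def test_offsets_convert_to_canonical_numbering(self):
        pmap = align_positions("MKL", "MKL", offset_a=100, offset_b=200)
        assert pmap.pairs[0] == (101, 201)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="monotone"):
            PositionMap(pairs=[(2, 1), (1, 2)])


class TestDivergence:
    def test_identical_profiles_give_zero_everywhere(self):
        prof = _profile([1.0, 2.0, 3.0, 4.0, 5.0])
        pmap = PositionMap(pairs=[(i, i) for i in range(1, 6)])
        div = divergence_profile(prof, prof, pmap, window=3)
        assert np.allclose(div.df["delta"], 0.0)
        assert np.allclose(div.df["smoothed_delta"], 0.0)

    def test_constant_delta_is_smoothing_invariant(self):
        a = _profile([2.0, 3.0, 4.0, 5.0, 6.0])
        b = _profile([1.0, 2.0, 3.0, 4.0, 5.0])
        pmap = PositionMap(pairs=[(i, i) for i in range(1, 6)])
        div = divergence_profile(a, b, pmap, window=3)
        assert np.allclose(div.df["smoothed_delta"], 1.0)

    def test_hand_convolution_with_truncated_edges(self):
        assert list(moving_average(np.array([0, 0, 3, 0, 0.0]), 3)) == pytest.approx(
            [0.0, 1.0, 1.0, 1.0, 0.0])

    def test_even_window_rejected(self):
        prof = _profile([1.0, 2.0, 3.0])
        pmap = PositionMap(pairs=[(i, i) for i in range(1, 4)])
        with pytest.raises(ValueError, match="odd"):
            divergence_profile(prof, prof, pmap, window=4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(70)
        a = _profile(rng.random(12))
        b = _profile(rng.random(12))
        pmap = PositionMap(pairs=[(i, i) for i in range(1, 13)])
        ab = divergence_profile(a, b, pmap, window=5)
        ba = divergence_profile(b, a, pmap, window=5)
        assert np.allclose(ab.df["delta"], -ba.df["delta"])
        assert np.allclose(ab.df["smoothed_delta"], -ba.df["smoothed_delta"])

    def test_planted_intolerant_block_produces_positive_peak(self):
        base = np.full(40, 0.5)
        spiked = base.copy()
        spiked[15:20] += 3.0  # mutations matter much more in A here
        a, b = _profile(spiked), _profile(base)
        pmap = PositionMap(pairs=[(i, i) for i in range(1, 41)])
        div = divergence_profile(a, b, pmap, window=5)
        sm = div.df["smoothed_delta"]
        assert sm.loc[16:19].min() > 0.5
        assert abs(sm.loc[1:10]).max() < 1e-12

    def test_twin_screens_diverge_less_at_higher_depth(self):
        # two screens generated from the same truth should agree better as
        # read depth grows
        from dropdms import (FeatureMatrix, PULogisticModel, ScreenConfig,
                             apply_count_threshold, assign_ground_truth,
                             build_count_table, generate_reads,
                             simulate_droplet_sort, simulate_epcr_library,
                             CodingSequence)
        from dropdms.calling import call_reads

        ref = CodingSequence("twin", "ATGGCTTGGGATCGTAAAGAACATTTGGGTGTTACCATCAGCTAC"
                                     "CCGGACTTCAACCTGGCAGTGAGAGAGCTCATTGGCTGCCATAAA")
        lib = simulate_epcr_library(ref, 1500, 4.0, seed=71)
        rng = np.random.default_rng(72)
        keys = sorted({s for v in lib.variants for s in v.aa_substitutions})
        truth = {k: float(rng.normal(0, 1.5)) for k in keys}
        lib = assign_ground_truth(lib, truth, 0.25, seed=73)

        def screen_profile(depth, seed):
            inp, srt, _ = simulate_droplet_sort(lib, ScreenConfig(seed=seed),
                                                n_droplets=40_000)
            ir = generate_reads(inp, depth, 0.001, seed=seed + 1)
            sr = generate_reads(srt, depth, 0.001, seed=seed + 2)
            tab = apply_count_threshold(build_count_table(ir, sr, ref), 10)
            fm = FeatureMatrix.from_read_calls(call_reads(ir, ref),
                                               call_reads(sr, ref),
                                               tab.substitutions)
            res = PULogisticModel(fm, 0.25).fit(compute_se=False)
            return percentile_rank(site_tolerance(res.coefficient_table()))

        gaps = {}
        for depth in (2000, 20_000):
            pa = screen_profile(depth, 80)
            pb = screen_profile(depth, 90)
            shared = pa.df.index.intersection(pb.df.index)
            pmap = PositionMap(pairs=[(i, i) for i in shared])
            div = divergence_profile(pa, pb, pmap, window=5)
            gaps[depth] = float(np.abs(div.df["smoothed_delta"]).mean())
        assert gaps[20_000] < gaps[2000]


class TestMsaTolerance:
    def _alignment(self, columns):
        """columns: list of per-column residue strings (one char per seq)."""
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        n = len(columns[0])
        seqs = ["".join(col[i] for col in columns) for i in range(n)]
        return MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=f"seq{i}") for i, s in enumerate(seqs)]
        )

    def test_conserved_column_scores_zero(self):
        aln = self._alignment(["AAAAA", "CCCCC", "ADHKW"])
        prof = msa_tolerance(aln, "seq0")
        assert prof.df.loc[1, "mean_abs_coefficient"] == 0.0
        assert prof.df.loc[2, "mean_abs_coefficient"] == 0.0
        assert prof.df.loc[3, "mean_abs_coefficient"] > 0.5

    def test_uniform_column_is_maximal(self):
        # 20 sequences, each a distinct residue in column 2
        residues = "ACDEFGHIKLMNPQRSTVWY"
        aln = self._alignment(["A" * 20, residues])
        prof = msa_tolerance(aln, "seq0")
        assert prof.df.loc[2, "mean_abs_coefficient"] == pytest.approx(1.0)

    def test_hand_entropy_two_thirds_one_third(self):
        # column 2 composition is 2/3 A, 1/3 V (6 sequences: A,A,A,A,V,V)
        aln = self._alignment(["AAAAAA", "AAAAVV"])
        prof = msa_tolerance(aln, "seq0")
        h = -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3))
        assert prof.df.loc[2, "mean_abs_coefficient"] == pytest.approx(
            h / math.log(20), rel=1e-12)

    def test_gappy_columns_omitted_and_ref_gaps_skipped(self):
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq("MA-W"), id="ref"),
            SeqRecord(Seq("MA-W"), id="s1"),
            SeqRecord(Seq("M--W"), id="s2"),
            SeqRecord(Seq("M--W"), id="s3"),
            SeqRecord(Seq("M--W"), id="s4"),
        ]
        prof = msa_tolerance(MultipleSeqAlignment(recs), "ref")
        # ref position 2 ('A' column) has 4/5 gaps -> omitted; gap column not
        # a ref position at all
        assert list(prof.df.index) == [1, 3]

    def test_missing_reference_rejected(self):
        aln = self._alignment(["AAAAA", "CCCCC"])
        with pytest.raises(ValueError, match="not found"):
            msa_tolerance(aln, "nope")


class TestDifferenceMatrix:
    def test_identical_tables_identity_map_all_zero(self):
        t = _coefs([(1, "A", "V", 1.0), (2, "C", "G", -2.0)])
        pmap = PositionMap(pairs=[(1, 1), (2, 2)])
        mat = coefficient_difference_matrix(t, t, pmap)
        assert np.allclose(mat.fillna(0).to_numpy(), 0.0)

    def test_missing_in_either_is_absent_not_zero(self):
        a = _coefs([(1, "A", "V", 1.0), (2, "C", "G", 2.0)])
        b = _coefs([(1, "A", "V", 0.5)])
        pmap = PositionMap(pairs=[(1, 1), (2, 2)])
        mat = coefficient_difference_matrix(a, b, pmap)
        assert mat.loc[1, "V"] == pytest.approx(0.5)
        assert (2, "G") not in mat.stack().index

    def test_hand_subtraction_across_aligned_positions(self):
        a = _coefs([(10, "A", "V", 1.0), (11, "C", "G", -1.0), (12, "D", "E", 2.0)])
        b = _coefs([(20, "S", "V", 0.5), (21, "T", "G", 1.0), (22, "E", "E", -1.0)])
        pmap = PositionMap(pairs=[(10, 20), (11, 21), (12, 22)])
        mat = coefficient_difference_matrix(a, b, pmap)
        assert mat.loc[10, "V"] == pytest.approx(0.5)
        assert mat.loc[11, "G"] == pytest.approx(-2.0)
        assert mat.loc[12, "E"] == pytest.approx(3.0)


class TestSignificance:
    def test_planted_site_difference_detected(self):
        rng = np.random.default_rng(74)
        a_entries, b_entries = [], []
        alts = "VGLIPKR"
        for pos in range(1, 11):
            for alt in alts:
                a_beta = rng.normal(0, 0.2) + (4.0 if pos == 5 else 0.0)
                a_entries.append((pos, "A", alt, a_beta))
                b_entries.append((pos, "A", alt, rng.normal(0, 0.2)))
        pmap = PositionMap(pairs=[(i, i) for i in range(1, 11)])
        res = site_divergence_significance(_coefs(a_entries), _coefs(b_entries),
                                           pmap, n_permutations=500, seed=75)
        assert bool(res.loc[5, "significant"])
        assert res["delta"].idxmax() == 5
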