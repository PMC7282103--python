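"""Variation statistics: polymorphic sites, p-distances, Pi, windows, slicing."""

import numpy as np
import pytest

import barcodescreen as bs
from conftest import brute_force_pi


class TestCountPolymorphicSites:
    def test_identical_sequences(self, make_alignment):
        aln = make_alignment(["ACGT" * 25] * 3)
        assert bs.count_polymorphic_sites(aln) == (0, 0.0)

    def test_two_sites_in_ten_columns(self, make_alignment):
        aln = make_alignment(["AAAAAAAAAA", "AAATAAATAA"])
        assert bs.count_polymorphic_sites(aln) == (2, 20.0)

    def test_gapped_columns_excluded_by_default(self, make_alignment):
        #          polymorphic v        v gap-containing polymorphic column
        aln = make_alignment(["ACGTAAAAAC", "AAGTAAAAA-"])
        assert bs.count_polymorphic_sites(aln)[0] == 1
        # the flag re-admits columns that still vary among unambiguous bases
        aln2 = make_alignment(["ACGTAAAAAC", "AAGTAAAA-G"])
        assert bs.count_polymorphic_sites(aln2, count_gapped_columns=True)[0] == 2

    def test_invariant_to_row_order_and_duplication(self, make_alignment):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT-N"), size=60)) for _ in range(4)]
        base = bs.count_polymorphic_sites(make_alignment(seqs))
        shuffled = bs.count_polymorphic_sites(make_alignment(seqs[::-1]))
        duplicated = bs.count_polymorphic_sites(make_alignment(seqs + [seqs[0]],
                                                ids=list("abcde")))
        assert base == shuffled == duplicated


class TestPairwiseDivergence:
    def test_identical_pair(self, make_alignment):
        dm = bs.pairwise_divergence(make_alignment(["ACGTACGT"] * 2))
        assert dm.pair("s1", "s2") == (0.0, 0)

    def test_pairwise_deletion_denominator(self, make_alignment):
        # length 10, one substitution, two gap columns -> p = 1/8
        aln = make_alignment(["ACGTACGTAC", "ACTTAC--AC"])
        p, diff = dm_pair = bs.pairwise_divergence(aln).pair("s1", "s2")
        assert diff == 1
        assert p == pytest.approx(1 / 8)

    def test_low_p_with_one_difference(self, make_alignment):
        # a pair may round to p = 0 at 2 significant figures while diff = 1
        aln = make_alignment(["A" * 1000, "A" * 999 + "C"])
        p, diff = bs.pairwise_divergence(aln).pair("s1", "s2")
        assert diff == 1
        assert 0 < p < 0.005

    def test_exactness_and_symmetry_on_random_alignments(self, make_alignment):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            seqs = ["".join(rng.choice(list("ACGTN-"), size=40)) for _ in range(n)]
            dm = bs.pairwise_divergence(make_alignment(seqs))
            assert np.allclose(np.nan_to_num(dm.p), np.nan_to_num(dm.p.T))
            for i in range(n):
                for j in range(i + 1, n):
                    kept = sum(
                        a in "ACGT" and b in "ACGT" for a, b in zip(seqs[i], seqs[j])
                    )
                    diff = sum(
                        a in "ACGT" and b in "ACGT" and a != b
                        for a, b in zip(seqs[i], seqs[j])
                    )
                    assert dm.diff_counts[i, j] == diff
                    if kept:
                        assert dm.p[i, j] == pytest.approx(diff / kept)

    def test_all_gap_pair_is_undefined(self, make_alignment):
        dm = bs.pairwise_divergence(make_alignment(["----", "ACGT", "ACGA"],
                                                   ids=list("abc")))
        assert np.isnan(dm.p[0, 1])


class TestNucleotideDiversity:
    def test_identical_pair_is_zero(self, make_alignment):
        assert bs.nucleotide_diversity(make_alignment(["ACGTACGTAC"] * 2)) == 0.0

    def test_single_pair_closed_form(self, make_alignment):
        aln = make_alignment(["ACGTACGTAC", "ACGTACGTAT"])
        assert bs.nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_four_sequences_equal_mean_of_six_pairs(self, make_alignment):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "AAAAAAATTT"]
        aln = make_alignment(seqs)
        assert bs.nucleotide_diversity(aln) == pytest.approx(brute_force_pi(seqs))

    def test_matches_brute_force_oracle(self, make_alignment):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            seqs = ["".join(rng.choice(list("ACGTN-"), size=30)) for _ in range(n)]
            aln = make_alignment(seqs)
            expected = brute_force_pi(seqs)
            got = bs.nucleotide_diversity(aln)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


class TestSlidingWindow:
    def test_identical_sequences_flat_profile(self, make_alignment):
        aln = make_alignment(["A" * 2500] * 3)
        profile = bs.sliding_window_pi(aln, window=1000, step=300)
        assert all(pi == 0 for _, _, pi in profile.windows)

    def test_window_start_grid_and_partial_tail(self, make_alignment):
        aln = make_alignment(["A" * 2500] * 2)
        profile = bs.sliding_window_pi(aln, window=1000, step=300)
        starts = [s for s, _, _ in profile.windows]
        assert starts == [0, 300, 600, 900, 1200, 1500, 1800]
        # tail window [1800, 2500) spans 700 >= step, so it is retained
        assert profile.windows[-1][:2] == (1800, 2500)

    def test_argmax_overlaps_planted_divergent_block(self, make_alignment):
        rng = np.random.default_rng(3)
        a = rng.choice(list("ACGT"), size=5000)
        b = a.copy()
        idx = rng.choice(np.arange(2000, 3000), size=120, replace=False)
        b[idx] = [{"A": "C", "C": "G", "G": "T", "T": "A"}[x] for x in b[idx]]
        aln = make_alignment(["".join(a), "".join(b)])
        s, e, _ = bs.sliding_window_pi(aln, 1000, 300).argmax_window()
        assert s < 3000 and e > 2000

    def test_window_larger_than_alignment_warns_single_window(self, make_alignment):
        aln = make_alignment(["ACGTACGTAC"] * 2)
        with pytest.warns(UserWarning, match="window"):
            profile = bs.sliding_window_pi(aln, window=50, step=10)
        assert profile.windows[0][:2] == (0, 10)
        assert len(profile.windows) == 1

    def test_partition_mean_equals_whole_alignment_pi(self, make_alignment):
        # step == window tiles the columns; on gap-free data the
        # length-weighted window mean is the whole-alignment Pi
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=900)) for _ in range(4)]
        aln = make_alignment(seqs)
        profile = bs.sliding_window_pi(aln, window=300, step=300)
        weighted = sum((e - s) * pi for s, e, pi in profile.windows) / 900
        assert weighted == pytest.approx(bs.nucleotide_diversity(aln))


class TestHypervariableRegions:
    def _profile(self, pis, window=100, step=50):
        windows = []
        for k, pi in enumerate(pis):
            windows.append((k * step, k * step + window, pi))
        return bs.SlidingWindowProfile(window_length=window, step=step, windows=windows)

    def test_flat_profile_yields_nothing(self):
        assert bs.extract_hypervariable_regions(self._profile([0.0] * 6)) == []

    def test_two_disjoint_blocks_merge_into_two_regions(self):
        pis = [0.001, 0.004, 0.005, 0.001, 0.001, 0.006, 0.004, 0.001]
        regions = bs.extract_hypervariable_regions(self._profile(pis))
        assert len(regions) == 2
        assert regions[0] == (50, 200, 0.005)
        assert regions[1] == (250, 400, 0.006)

    def test_threshold_is_half_the_observed_maximum(self):
        # default 0.003 is just above half of the 0.0059 profile ceiling
        pis = [0.0059, 0.0029, 0.0031]
        regions = bs.extract_hypervariable_regions(self._profile(pis, step=100))
        assert [r[2] for r in regions] == [0.0059, 0.0031]


class TestSliceAndIrRemoval:
    def test_identity_slice(self, scaled_dataset):
        aln = scaled_dataset.alignment
        out = bs.slice_region(aln, (0, aln.length))
        assert out.length == aln.length and out.ids == aln.ids

    def test_named_slice_sets_region_name(self, make_alignment):
        aln = make_alignment(["ACGTACGTAC"] * 2)
        out = bs.slice_region(aln, bs.Annotation("ndhF", 2, 8))
        assert out.length == 6 and out.region_name == "ndhF"

    def test_reversed_coordinates_error(self, make_alignment):
        aln = make_alignment(["ACGTACGTAC"] * 2)
        with pytest.raises(ValueError):
            bs.slice_region(aln, (8, 2))

    def test_remove_one_ir_lengths(self, scaled_dataset):
        aln = scaled_dataset.alignment
        record = aln.to_records()[0]
        structure = bs.analyze_structure(record, min_ir_length=100)
        core = bs.remove_one_ir(aln, structure)
        assert core.length == aln.length - structure.ir_length
        # a second application no longer tiles: error
        with pytest.raises(ValueError, match="tile"):
            bs.remove_one_ir(core, structure)

    def test_remove_one_ir_on_record(self, scaled_dataset):
        record = scaled_dataset.alignment.to_records()[0]
        structure = bs.analyze_structure(record, min_ir_length=100)
        out = bs.remove_one_ir(record, structure)
        assert len(out.sequence) == len(record.sequence) - structure.ir_length


class TestConcatenation:
    def test_missing_accession_dropped_with_warning(self, make_alignment, caplog):
        a = make_alignment(["ACGT", "AGGT", "ACGA"], ids=["x", "y", "z"])
        b = make_alignment(["TTTT", "TTTA"], ids=["x", "y"])
        with caplog.at_level("WARNING"):
            combined = bs.concatenate_alignments([a, b])
        assert combined.ids == ["x", "y"]
        assert combined.length == 8
        assert "z" in caplog.text
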