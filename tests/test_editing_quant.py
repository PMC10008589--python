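import math

import numpy as np
import pandas as pd
import pytest

from dartvadar.editing_quant import (
    bin_by_marker,
    fold_change,
    logo_matrix,
    pileup,
    topology_ratios,
)

REF = ("amp", "ACGTAACGGT")  # A at 0, 4, 5


class TestPileup:
    def test_identical_reads_have_zero_editing(self):
        table = pileup([REF[1]] * 10, REF, min_depth=5)
        frac = table.editing_fraction
        for pos in (0, 4, 5):
            assert frac[pos] == 0.0
        assert np.isnan(frac[1])  # non-A reference position

    def test_hand_counted_fraction(self):
        reads = [REF[1]] * 7 + ["ACGTGACGGT"] * 3  # G at position 4 in 3/10 reads
        table = pileup(reads, REF, min_depth=5)
        assert table.editing_fraction[4] == pytest.approx(0.3)
        assert table.editing_fraction[0] == 0.0
        assert table.counts[4, 0] == 7 and table.counts[4, 2] == 3

    def test_counts_conserve_read_bases(self):
        reads = [REF[1]] * 7 + ["ACGTGACGGT"] * 3
        table = pileup(reads, REF, min_depth=1)
        assert table.counts.sum() == sum(len(r) for r in reads)
        assert (table.counts.sum(axis=1) == table.depth).all()

    def test_invariant_to_read_order_and_chunking(self):
        rng = np.random.default_rng(0)
        reads = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(20)]
        reads = [r for r in reads]  # some will be discarded identically either way
        a = pileup(reads, REF, min_depth=1, max_mismatch_frac=1.0)
        b = pileup(list(reversed(reads)), REF, min_depth=1, max_mismatch_frac=1.0)
        c1 = pileup(reads[:7], REF, min_depth=1, max_mismatch_frac=1.0)
        c2 = pileup(reads[7:], REF, min_depth=1, max_mismatch_frac=1.0)
        assert (a.counts == b.counts).all()
        assert (a.counts == c1.counts + c2.counts).all()

    def test_short_read_placed_at_best_offset(self):
        # unique 4-mer from positions 4..8 of the reference
        table = pileup(["AACG"], REF, min_depth=1)
        assert table.counts[4, 0] == 1 and table.counts[7, 2] == 1
        assert table.depth.sum() == 4

    def test_mismatch_ceiling_discards_noise_reads(self):
        with pytest.warns(UserWarning, match="no usable reads"):
            table = pileup(["TTTTTTTTTT"], REF, min_depth=1, max_mismatch_frac=0.2)
        assert table.n_discarded == 1 and table.n_reads == 0
        assert table.counts.sum() == 0

    def test_min_depth_masks_fraction(self):
        table = pileup([REF[1]] * 3, REF, min_depth=100)
        assert np.isnan(table.editing_fraction[0])

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="no usable reads"):
            table = pileup([], REF, min_depth=1)
        assert table.counts.sum() == 0

    def test_fastq_file_input(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("".join(f"@r{i}\n{REF[1]}\n+\n{'I' * 10}\n" for i in range(5)))
        table = pileup(fq, REF, min_depth=1)
        assert table.n_reads == 5
        assert table.editing_fraction[0] == 0.0


class TestPileupSam:
    def _write_sam(self, path, records):
        header = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:amp\tLN:10\n"
        path.write_text(header + "".join(records))

    def test_forward_and_reverse_records_counted(self, tmp_path):
        sam = tmp_path / "a.sam"
        # SEQ is stored reference-oriented, also for flag-16 records
        recs = [
            f"r1\t0\tamp\t1\t60\t10M\t*\t0\t0\t{REF[1]}\t*\n",
            f"r2\t16\tamp\t1\t60\t10M\t*\t0\t0\tACGTGACGGT\t*\n",
        ]
        self._write_sam(sam, recs)
        table = pileup(sam, REF, min_depth=1)
        assert table.n_reads == 2
        assert table.counts[4, 0] == 1 and table.counts[4, 2] == 1
        assert table.editing_fraction[4] == pytest.approx(0.5)

    def test_partial_alignment_uses_reference_coordinates(self, tmp_path):
        sam = tmp_path / "a.sam"
        self._write_sam(sam, ["r1\t0\tamp\t5\t60\t4M\t*\t0\t0\tAACG\t*\n"])
        table = pileup(sam, REF, min_depth=1)
        assert table.counts[4, 0] == 1 and table.depth.sum() == 4

    def test_wrong_reference_name_is_an_error(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:other\tLN:10\n")
        with pytest.raises(ValueError, match="not found in SAM header"):
            pileup(sam, REF)


class TestLogoMatrix:
    def test_unedited_sample_is_point_mass_on_reference(self):
        table = pileup([REF[1]] * 10, REF, min_depth=1)
        logo = logo_matrix(table)
        for pos, base in enumerate(REF[1]):
            assert logo.loc[pos, base] == 1.0
            assert logo.loc[pos].sum() == pytest.approx(1.0)

    def test_edited_position_splits_a_and_g(self):
        reads = [REF[1]] * 7 + ["ACGTGACGGT"] * 3
        logo = logo_matrix(pileup(reads, REF, min_depth=1), window=(3, 6))
        assert logo.loc[4, "A"] == pytest.approx(0.7)
        assert logo.loc[4, "G"] == pytest.approx(0.3)
        assert list(logo.index) == [3, 4, 5]

    def test_rows_sum_to_one_or_are_missing(self):
        table = pileup(["AACG"], REF, min_depth=1)  # covers positions 4..7 only
        logo = logo_matrix(table)
        sums = logo.sum(axis=1, skipna=False)
        covered = ~sums.isna()
        assert sums[covered].apply(lambda v: math.isclose(v, 1.0)).all()
        assert logo.loc[0].isna().all()  # zero-depth column -> missing marker

    def test_window_bounds_checked(self):
        table = pileup([REF[1]], REF, min_depth=1)
        with pytest.raises(ValueError):
            logo_matrix(table, window=(5, 50))


class TestBinByMarker:
    def test_half_log_bins_anchored_at_one(self):
        df, excluded = bin_by_marker([1.0, 3.5, 10.0], log10_bin_width=0.5)
        assert excluded == 0
        assert list(df["bin"]) == [0, 1, 2]
        assert df["bin_lo"].tolist() == pytest.approx([1.0, 10 ** 0.5, 10.0])
        assert df["bin_hi"].tolist() == pytest.approx([10 ** 0.5, 10.0, 10 ** 1.5])

    def test_equal_intensities_share_one_bin(self):
        df, _ = bin_by_marker([7.0] * 50)
        assert df["bin"].nunique() == 1

    def test_non_positive_cells_excluded_and_counted(self):
        df, excluded = bin_by_marker([5.0, 0.0, -2.0])
        assert excluded == 2 and len(df) == 1

    def test_bad_width(self):
        with pytest.raises(ValueError):
            bin_by_marker([1.0], log10_bin_width=0)


class TestFoldChange:
    def test_identical_populations_give_unity(self):
        cells = [10.0, 100.0, 1000.0]
        r = fold_change(cells, cells, n_boot=200, seed=1)
        assert r.fold_change == pytest.approx(1.0)
        assert r.ci95[0] <= 1.0 <= r.ci95[1]

    def test_closed_form_geometric_means(self):
        r = fold_change([10.0, 1000.0], [1.0, 100.0], n_boot=100, seed=1)
        assert r.geo_mean_on == pytest.approx(100.0)
        assert r.geo_mean_off == pytest.approx(10.0)
        assert r.fold_change == pytest.approx(10.0)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        on = rng.lognormal(3.0, 1.0, 500)
        off = rng.lognormal(1.0, 1.0, 500)
        r = fold_change(on, off, seed=5)
        assert r.ci95[0] <= r.fold_change <= r.ci95[1]

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(4)
        on = rng.lognormal(3.0, 1.0, 100)
        off = rng.lognormal(1.0, 1.0, 100)
        fwd = fold_change(on, off, n_boot=10, seed=0).fold_change
        rev = fold_change(off, on, n_boot=10, seed=0).fold_change
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (100, 4000):
            rng = np.random.default_rng(7)
            on = rng.lognormal(3.0, 1.0, n)
            off = rng.lognormal(1.0, 1.0, n)
            r = fold_change(on, off, seed=11)
            widths.append(r.ci95[1] - r.ci95[0])
        assert widths[1] < widths[0]

    def test_non_positive_intensity_is_an_error(self):
        with pytest.raises(ValueError, match="non-positive"):
            fold_change([1.0, 0.0], [1.0], n_boot=10, seed=0)
        with pytest.raises(ValueError):
            fold_change([], [1.0])


class TestTopologyRatios:
    def test_identical_results_give_zero_ratios(self):
        r = fold_change([10.0, 1000.0], [1.0, 100.0], n_boot=10, seed=0)
        out = topology_ratios(r, r)
        assert out["log10_fold_change_ratio"] == 0.0
        assert out["log10_basal_ratio"] == 0.0
        assert not out["better_with_autocatalysis"]

    def test_eightfold_improvement_is_log10_8(self):
        ol = fold_change([10.0], [10.0], n_boot=10, seed=0)  # FC 1
        cl = fold_change([80.0], [10.0], n_boot=10, seed=0)  # FC 8
        out = topology_ratios(cl, ol)
        assert out["log10_fold_change_ratio"] == pytest.approx(math.log10(8), abs=1e-12)
        assert out["better_with_autocatalysis"]

    def test_background_reduction_gives_negative_basal_ratio(self):
        cl = fold_change([100.0], [2.0], n_boot=10, seed=0)
        ol = fold_change([100.0], [20.0], n_boot=10, seed=0)
        out = topology_ratios(cl, ol)
        assert out["log10_basal_ratio"] == pytest.approx(-1.0)
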