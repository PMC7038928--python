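"""Window tiling, winscore peak calling, merge/split and ratio quantification."""

import numpy as np
import pandas as pd
import pytest

from m6acomod.peaks import (
    call_peaks,
    make_windows,
    metagene_profile,
    peak_ratios,
    rpkm,
    union_merge_split,
    winscore,
)


class TestMakeWindows:
    def test_single_exon_tiling(self):
        win = make_windows({"g": ("chr1", "+", [(0, 250)])})
        assert list(zip(win["sstart"], win["send"])) == [(0, 100), (50, 150), (100, 200), (150, 250)]
        assert (win["gstart"] == win["sstart"]).all()

    def test_exact_window_length_gene(self):
        win = make_windows({"g": ("chr1", "+", [(0, 100)])})
        assert len(win) == 1 and win["length"].iat[0] == 100

    def test_short_gene_keeps_true_length(self):
        win = make_windows({"g": ("chr1", "+", [(0, 60)])})
        assert len(win) == 1 and win["length"].iat[0] == 60

    def test_junction_spanning_window(self):
        # two 60-bp exons: spliced length 120 -> windows 0-100 (crosses the
        # junction) and 50-120 (terminal, 70 bp)
        win = make_windows({"g": ("chr1", "+", [(0, 60), (260, 320)])})
        assert list(zip(win["sstart"], win["send"])) == [(0, 100), (50, 120)]
        assert win["gstart"].iat[0] == 0 and win["gend"].iat[0] == 300
        assert win["length"].iat[1] == 70

    def test_minus_strand_projection(self):
        # on '-', spliced position 0 is the highest genomic coordinate
        win = make_windows({"g": ("chr1", "-", [(0, 150)])})
        assert win["gstart"].iat[0] == 50 and win["gend"].iat[0] == 150

    def test_tiling_covers_every_base(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            total = int(rng.integers(100, 2000))
            win = make_windows({"g": ("chr1", "+", [(0, total)])})
            cov = np.zeros(total, dtype=int)
            for _, row in win.iterrows():
                cov[row["sstart"] : row["send"]] += 1
            assert (cov >= 1).all()
            # interior bases fall in exactly 2 windows for step = length/2
            assert (cov[100 : max((total - 100) // 50 * 50, 100)] <= 2).all()

    def test_empty_gene_skipped(self, caplog):
        win = make_windows({"g": ("chr1", "+", []), "h": ("chr1", "+", [(0, 100)])})
        assert list(win["gene_id"].unique()) == ["h"]


class TestScores:
    @pytest.mark.parametrize(
        "count,lib,length,expected",
        [(0, 1e7, 100, 0.0), (50, 1e7, 100, 50.0), (1, 1e9, 1000, 0.001)],
    )
    def test_rpkm_formula(self, count, lib, length, expected):
        assert rpkm(count, lib, length) == pytest.approx(expected)

    def test_winscore_symmetry_and_boundary(self):
        assert winscore(3.0, 3.0) == 1.0
        assert winscore(5.0, 2.0) == pytest.approx(2.0)  # not > 2: no peak
        assert winscore(7.0, 2.0) == pytest.approx(8.0 / 3.0)

    def test_winscore_monotonicity(self):
        ip = np.linspace(0, 50, 20)
        assert (np.diff(winscore(ip, 5.0)) > 0).all()
        assert (np.diff(winscore(5.0, ip)) < 0).all()


class TestCallPeaks:
    def test_all_zero_counts_yield_no_peaks(self, single_gene_windows):
        from conftest import make_count_table

        table = make_count_table(single_gene_windows, np.zeros(4), np.zeros(4))
        assert not call_peaks(table).to_numpy().any()

    def test_enriched_window_called_and_threshold_respected(self, single_gene_windows):
        from conftest import make_count_table

        # RPKM = count * 1e9/(1e7*100) = count; window 1: IP RPKM 30, input 5
        ip = [5, 30, 5, 5]
        inp = [5, 5, 5, 5]
        table = make_count_table(single_gene_windows, ip, inp)
        called = call_peaks(table)
        assert called["s1"].tolist() == [False, True, False, False]
        assert not call_peaks(table, threshold=10).to_numpy().any()


def _called_frame(windows, idx):
    called = pd.DataFrame(False, index=windows.index, columns=["s1"])
    called.iloc[idx, 0] = True
    return called


class TestUnionMergeSplit:
    def test_single_window_peak(self, single_gene_windows):
        peaks = union_merge_split(single_gene_windows, _called_frame(single_gene_windows, [1]))
        assert len(peaks) == 1
        assert peaks.iloc[0]["member_windows"] == "gA:1"

    def test_run_of_seven_splits_five_plus_two(self):
        win = make_windows({"g": ("chr1", "+", [(0, 500)])})  # 9 windows
        peaks = union_merge_split(win, _called_frame(win, list(range(7))))
        sizes = [len(m.split(",")) for m in peaks["member_windows"]]
        assert sizes == [5, 2]
        assert list(peaks.index) == ["g.1", "g.2"]

    def test_gap_breaks_contiguity(self, single_gene_windows):
        peaks = union_merge_split(single_gene_windows, _called_frame(single_gene_windows, [0, 2]))
        assert len(peaks) == 2

    def test_union_across_samples_order_independent(self, single_gene_windows):
        win = single_gene_windows
        a = pd.DataFrame({"s1": [True, False, False, False], "s2": [False, True, False, False]}, index=win.index)
        b = a[["s2", "s1"]]
        pa = union_merge_split(win, a)
        pb = union_merge_split(win, b)
        pd.testing.assert_frame_equal(pa, pb)
        # idempotence: re-merging the union changes nothing
        again = union_merge_split(win, a.any(axis=1).to_frame("u"))
        pd.testing.assert_frame_equal(pa, again)

    def test_never_merges_across_genes(self):
        win = make_windows({"a": ("chr1", "+", [(0, 100)]), "b": ("chr1", "+", [(100, 200)])})
        peaks = union_merge_split(win, pd.DataFrame(True, index=win.index, columns=["s1"]))
        assert len(peaks) == 2

    def test_foreign_grid_rejected(self, single_gene_windows):
        other = make_windows({"g": ("chr1", "+", [(0, 250)])})
        with pytest.raises(ValueError, match="grid"):
            union_merge_split(single_gene_windows, pd.DataFrame(True, index=other.index, columns=["s1"]))


class TestPeakRatios:
    def test_ratio_without_pseudocount_and_na_rule(self, single_gene_windows):
        from conftest import make_count_table

        # window RPKMs equal counts with these library sizes
        table = make_count_table(single_gene_windows, [12, 12, 0, 0], [6, 4, 5, 5])
        peaks = union_merge_split(single_gene_windows, _called_frame(single_gene_windows, [0]))
        r = peak_ratios(peaks, table)
        assert r.iloc[0, 0] == pytest.approx(2.0)
        peaks2 = union_merge_split(single_gene_windows, _called_frame(single_gene_windows, [1]))
        assert np.isnan(peak_ratios(peaks2, table).iloc[0, 0])  # input RPKM 4 < 5

    def test_merged_peak_takes_max_over_windows(self, single_gene_windows):
        from conftest import make_count_table

        table = make_count_table(single_gene_windows, [8, 10, 14, 0], [10, 4, 10, 10])
        peaks = union_merge_split(single_gene_windows, _called_frame(single_gene_windows, [0, 1, 2]))
        # window ratios: 0.8, missing (input < 5), 1.4 -> max 1.4
        assert peak_ratios(peaks, table).iloc[0, 0] == pytest.approx(1.4)
        # brute-force recomputation
        from m6acomod.peaks import window_rpkms

        ip, inp = window_rpkms(table)
        w = ip / inp.where(inp >= 5)
        assert peak_ratios(peaks, table).iloc[0, 0] == w.iloc[:3, 0].max()

    def test_all_windows_missing_gives_missing(self, single_gene_windows):
        from conftest import make_count_table

        table = make_count_table(single_gene_windows, [9, 9, 9, 9], [1, 1, 1, 1])
        peaks = union_merge_split(single_gene_windows, _called_frame(single_gene_windows, [0, 1]))
        assert peak_ratios(peaks, table).isna().all().all()


class TestMetagene:
    @pytest.mark.parametrize(
        "center_sstart,expected_bin",
        [
            (0, 0),  # first nt of the 5'UTR
            (250, 15),  # CDS bin 5: floor((250-100)/300*10)
            (399, 19),  # last CDS nt stays in CDS
        ],
    )
    def test_center_bin_assignment(self, toy_model, center_sstart, expected_bin):
        peaks = pd.DataFrame(
            {"gene_id": ["gA"], "sstart": [center_sstart], "send": [center_sstart]}, index=["p1"]
        )
        prof = metagene_profile(peaks, {"gA": toy_model}, normalize="none")
        assert prof["density"].to_numpy().nonzero()[0].tolist() == [expected_bin]

    def test_outside_transcript_skipped(self, toy_model):
        peaks = pd.DataFrame({"gene_id": ["gA"], "sstart": [900], "send": [920]}, index=["p1"])
        prof = metagene_profile(peaks, {"gA": toy_model}, normalize="none")
        assert prof["density"].sum() == 0

    def test_region_normalization_uniform_density(self, toy_model):
        # peaks uniform over the whole transcript -> near-flat normalized curve
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 600, size=3000)
        peaks = pd.DataFrame({"gene_id": "gA", "sstart": pos, "send": pos})
        prof = metagene_profile(peaks, {"gA": toy_model})
        assert prof["density"].std() / prof["density"].mean() < 0.15
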