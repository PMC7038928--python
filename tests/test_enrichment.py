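"""Interval overlap, IUPAC motif matching, chi-square enrichment, BH and tiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6acomod.enrichment import (
    Motif,
    bh_fdr,
    chi_square_enrichment,
    integrate_calls,
    motif_flags,
    motif_proximity_profile,
    overlap_flags,
)


def peaks_df(intervals):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "strand": st_} for c, s, e, st_ in intervals],
        index=[f"p{i}" for i in range(len(intervals))],
    )


class TestOverlapFlags:
    def test_one_bp_overlap_counts_abutment_does_not(self):
        peaks = peaks_df([("chr1", 100, 200, "+"), ("chr1", 100, 200, "+")])
        clip = pd.DataFrame([{"chrom": "chr1", "start": 199, "end": 250, "strand": "+"}])
        assert overlap_flags(peaks.iloc[[0]], clip).iloc[0]
        clip2 = pd.DataFrame([{"chrom": "chr1", "start": 200, "end": 250, "strand": "+"}])
        assert not overlap_flags(peaks.iloc[[0]], clip2).iloc[0]

    def test_empty_clip_and_strand_awareness(self):
        peaks = peaks_df([("chr1", 100, 200, "+")])
        assert not overlap_flags(peaks, pd.DataFrame(columns=["chrom", "start", "end", "strand"])).any()
        clip = pd.DataFrame([{"chrom": "chr1", "start": 150, "end": 160, "strand": "-"}])
        assert not overlap_flags(peaks, clip).iloc[0]
        assert overlap_flags(peaks, clip, stranded=False).iloc[0]

    def test_symmetric_in_query_direction(self):
        rng = np.random.default_rng(0)
        a = peaks_df([("chr1", int(s), int(s) + 80, "+") for s in rng.integers(0, 5000, 30)])
        b = peaks_df([("chr1", int(s), int(s) + 120, "+") for s in rng.integers(0, 5000, 30)])
        fa = overlap_flags(a, b)
        fb = overlap_flags(b, a)
        assert fa.any() == fb.any()
        # pairwise symmetry by brute force
        for _, pa in a.iterrows():
            hit = any(min(pa["end"], pb["end"]) - max(pa["start"], pb["start"]) >= 1 for _, pb in b.iterrows())
            assert hit == fa.loc[pa.name]

    def test_malformed_interval_rejected(self):
        peaks = peaks_df([("chr1", 100, 200, "+")])
        clip = pd.DataFrame([{"chrom": "chr1", "start": 250, "end": 250, "strand": "+"}])
        with pytest.raises(ValueError, match="row"):
            overlap_flags(peaks, clip)


class TestMotifFlags:
    @pytest.mark.parametrize(
        "seq,consensus,expected",
        [
            ("GGACT", "DRACH", True),
            ("GGGCT", "DRACH", False),
            ("TTTTT", "NNN", True),
            ("AC", "NNN", False),  # motif longer than sequence
            ("GGACU", "DRACH", True),  # U treated as T
        ],
    )
    def test_iupac_matching(self, seq, consensus, expected):
        flags = motif_flags(pd.Series([seq]), Motif("x", consensus))
        assert bool(flags.iloc[0]) is expected

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            Motif("x", "DRAXH")


class TestChiSquare:
    def _oracle(self, a, b, c, d):
        n = a + b + c + d
        return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))

    def test_worked_table_matches_closed_form(self):
        mf = np.repeat([True, False], [30, 20])
        bf = np.repeat([True, False], [100, 400])
        chi2, p, table, enriched = chi_square_enrichment(mf, bf)
        assert chi2 == pytest.approx(self._oracle(30, 20, 100, 400), abs=1e-10)
        assert p < 1e-9 and enriched

    @given(
        st.integers(2, 80), st.integers(2, 80), st.integers(2, 400), st.integers(2, 400)
    )
    @settings(max_examples=100, deadline=None)
    def test_random_tables_match_closed_form(self, a, b, c, d):
        mf = np.repeat([True, False], [a, b])
        bf = np.repeat([True, False], [c, d])
        chi2, p, table, _ = chi_square_enrichment(mf, bf)
        if p < 1.0 or chi2 > 0:
            assert chi2 == pytest.approx(self._oracle(a, b, c, d), abs=1e-8)

    def test_equal_fractions_independent(self):
        mf = np.repeat([True, False], [10, 10])
        bf = np.repeat([True, False], [50, 50])
        chi2, p, _, enriched = chi_square_enrichment(mf, bf)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert not enriched

    def test_depletion_flagged_as_not_enriched(self):
        mf = np.repeat([True, False], [2, 48])
        bf = np.repeat([True, False], [100, 100])
        chi2, p, _, enriched = chi_square_enrichment(mf, bf)
        assert p < 0.01 and not enriched

    def test_tiny_expected_counts_give_p_one(self):
        mf = np.array([True] + [False] * 4)
        bf = np.array([False] * 5)
        _, p, _, _ = chi_square_enrichment(mf, bf)
        assert p == 1.0


class TestBhFdr:
    def test_small_examples(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(1, 100))
            p = rng.random(m)
            q = bh_fdr(p)
            order = np.argsort(p)
            brute = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                js = np.arange(rank, m + 1)
                brute[idx] = min(1.0, np.min(np.sort(p)[js - 1] * m / js))
            assert np.allclose(q, brute, atol=1e-12)
            assert (q >= p - 1e-15).all()


class TestIntegrateCalls:
    def _corr(self, rows):
        return pd.DataFrame(rows, columns=["rbp_id", "module_id", "r_full", "p_jack", "significant"])

    def _enr(self, rows):
        df = pd.DataFrame(rows, columns=["rbp_id", "module_id", "evidence", "q", "enriched"])
        return df

    def test_same_module_required_for_high_confidence(self):
        corr = self._corr([("A", 1, 0.9, 1e-5, True), ("B", 1, 0.8, 1e-4, True)])
        enr = self._enr([("A", 1, "clip", 0.01, True), ("B", 2, "clip", 0.001, True)])
        calls = integrate_calls(corr, enr).set_index("rbp_id")
        assert calls.loc["A", "tier"] == "high_confidence"
        assert calls.loc["B", "tier"] == "low_confidence"

    def test_depleted_or_weak_enrichment_stays_low(self):
        corr = self._corr([("A", 1, 0.9, 1e-5, True)])
        enr = self._enr([("A", 1, "clip", 0.01, False), ("A", 1, "motif", 0.2, True)])
        calls = integrate_calls(corr, enr).set_index("rbp_id")
        assert calls.loc["A", "tier"] == "low_confidence"

    def test_unevaluable_flag_without_binding_data(self):
        corr = self._corr([("A", 1, 0.9, 1e-5, True)])
        calls = integrate_calls(corr, self._enr([])).set_index("rbp_id")
        assert calls.loc["A", "tier"] == "low_confidence"
        assert bool(calls.loc["A", "unevaluable"])

    def test_non_significant_rbps_absent(self):
        corr = self._corr([("A", 1, 0.1, 0.9, False)])
        assert integrate_calls(corr, self._enr([])).empty


class TestMotifProximity:
    def test_planted_fixed_offset_is_the_mode(self):
        rng = np.random.default_rng(2)
        seqs = []
        for _ in range(60):
            bg = "".join(rng.choice(list("CG"), size=200))  # no spurious matches
            # anchor GGACT center 102.5, motif TGCATG center 133 -> distance 30.5
            s = bg[:100] + "GGACT" + bg[105:130] + "TGCATG" + bg[136:]
            seqs.append(s)
        hist = motif_proximity_profile(pd.Series(seqs), Motif("x", "TGCATG"), max_offset=100)
        assert int(np.argmax(hist)) == pytest.approx(30, abs=1)

    def test_sequences_without_anchor_contribute_nothing(self):
        seqs = pd.Series(["".join("CG" * 100)])
        hist = motif_proximity_profile(pd.Series(seqs), Motif("x", "TGCATG"))
        assert hist.sum() == 0
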