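import math

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from asquant.quantify import (
    BedGraphError,
    ComparisonThresholds,
    EventQuant,
    chi2_2x2,
    compare_event,
    coverage_from_bam,
    coverage_from_bedgraph,
    quantify_event,
    run_comparison,
    write_bedgraph,
)

from conftest import make_se_event, make_transcript, uniform_track
from oracles import chi2_closed_form, chi2_pvalue_erfc


class TestBedGraph:
    def test_single_interval(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t10\t5\n")
        track = coverage_from_bedgraph(str(path))
        assert track.depth("chr1", 0, 10).tolist() == [5] * 10
        assert track.depth("chr1", 10, 12).tolist() == [0, 0]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text("")
        assert coverage_from_bedgraph(str(path)).chrom_names() == set()

    def test_overlap_rejected_naming_line(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t10\t5\nchr1\t5\t15\t3\n")
        with pytest.raises(BedGraphError, match="line 2"):
            coverage_from_bedgraph(str(path))

    def test_round_trip(self, tmp_path, sim_small):
        original = coverage_from_bedgraph(sim_small.coverage_a)
        out = tmp_path / "rt.bedgraph"
        write_bedgraph(original, str(out))
        back = coverage_from_bedgraph(str(out))
        for chrom in original.chrom_names():
            a, b = original.depths[chrom], back.depths[chrom]
            n = min(len(a), len(b))
            assert np.array_equal(a[:n], b[:n])
            assert not a[n:].any() and not b[n:].any()


def _write_bam(path, reads, chrom_len=1000):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": chrom_len}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (pos, cigar, flag) in enumerate(reads):
            read = pysam.AlignedSegment()
            read.query_name = f"r{i}"
            read.reference_id = 0
            read.reference_start = pos
            read.flag = flag
            read.mapping_quality = 60
            read.cigartuples = cigar
            length = sum(n for op, n in cigar if op in (0, 7, 8))
            read.query_sequence = "N" * length
            bam.write(read)
    pysam.sort("-o", str(path), str(path))
    pysam.index(str(path))


class TestBamCoverage:
    def test_simple_read(self, tmp_path):
        path = tmp_path / "a.bam"
        _write_bam(path, [(100, [(0, 50)], 0)])
        track = coverage_from_bam(str(path))
        arr = track.depths["chr1"]
        assert arr[100:150].tolist() == [1] * 50
        assert arr.sum() == 50

    def test_split_read_skips_gap(self, tmp_path):
        path = tmp_path / "a.bam"
        _write_bam(path, [(0, [(0, 20), (3, 100), (0, 30)], 0)])
        arr = coverage_from_bam(str(path)).depths["chr1"]
        assert arr[0:20].tolist() == [1] * 20
        assert arr[20:120].sum() == 0
        assert arr[120:150].tolist() == [1] * 30

    def test_secondary_and_duplicate_excluded(self, tmp_path):
        path = tmp_path / "a.bam"
        _write_bam(path, [(0, [(0, 10)], 0), (0, [(0, 10)], 256), (0, [(0, 10)], 1024)])
        assert coverage_from_bam(str(path)).depths["chr1"].sum() == 10

    def test_missing_index_instructs(self, tmp_path):
        path = tmp_path / "a.bam"
        _write_bam(path, [(0, [(0, 10)], 0)])
        (tmp_path / "a.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="samtools index"):
            coverage_from_bam(str(path))

    def test_matches_simulator_bedgraph(self, tmp_path):
        from asquant.simulate import SimConfig, simulate_dataset

        res = simulate_dataset(
            SimConfig(seed=2, n_se=2, n_mxe=1, n_a5ss=1, n_a3ss=1, make_bam=True),
            str(tmp_path),
        )
        bg = coverage_from_bedgraph(res.coverage_a)
        bam = coverage_from_bam(res.bam_a)
        a = bg.depths["chrS"]
        b = bam.depths["chrS"]
        n = min(len(a), len(b))
        assert np.array_equal(a[:n], b[:n]) and not b[n:].any()


class TestChi2:
    def test_identical_rows_give_zero(self):
        assert chi2_2x2(50, 50, 50, 50) == (0.0, 1.0)

    def test_textbook_value(self):
        chi2, p = chi2_2x2(10, 90, 30, 70)
        assert chi2 == pytest.approx(12.5, abs=1e-12)
        assert p == pytest.approx(4.0695e-4, rel=1e-3)

    def test_zero_margin_returns_no_evidence(self):
        assert chi2_2x2(0, 0, 5, 10) == (0.0, 1.0)
        assert chi2_2x2(0, 5, 0, 10) == (0.0, 1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(-1, 2, 3, 4)

    @given(st.tuples(*[st.integers(0, 1000)] * 4))
    @settings(max_examples=200, derandomize=True)
    def test_matches_closed_form_and_scipy(self, table):
        a, b, c, d = table
        chi2, p = chi2_2x2(a, b, c, d)
        assert chi2 == pytest.approx(chi2_closed_form(a, b, c, d), abs=1e-9)
        assert p == pytest.approx(chi2_pvalue_erfc(chi2), abs=1e-12)
        obs = np.array([[a, b], [c, d]])
        if obs.sum(0).min() > 0 and obs.sum(1).min() > 0:
            ref = chi2_contingency(obs, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.tuples(*[st.integers(0, 500)] * 4), st.integers(1, 7))
    @settings(max_examples=100, derandomize=True)
    def test_swap_invariance_and_count_scaling(self, table, k):
        a, b, c, d = table
        chi2, p = chi2_2x2(a, b, c, d)
        for swapped in (chi2_2x2(c, d, a, b), chi2_2x2(b, a, d, c)):
            assert swapped[0] == pytest.approx(chi2, rel=1e-12, abs=1e-12)
            assert swapped[1] == pytest.approx(p, rel=1e-12, abs=1e-15)
        chi2_k, _ = chi2_2x2(k * a, k * b, k * c, k * d)
        assert chi2_k == pytest.approx(k * chi2, rel=1e-9, abs=1e-9)

    def test_pvalue_monotone_in_statistic(self):
        from scipy.stats import chi2 as chi2_dist

        xs = np.linspace(0, 30, 200)
        ps = chi2_dist.sf(xs, 1)
        assert ps[0] == 1.0
        assert (np.diff(ps) <= 0).all()


class TestQuantifyEvent:
    def _gene(self):
        t1 = make_transcript([(0, 100), (200, 300), (400, 500)], tid="t1")
        t2 = make_transcript([(0, 100), (400, 500)], tid="t2")
        ev = make_se_event((200, 300), (0, 100), (400, 500))
        return ev, {"t1": t1, "t2": t2}

    def test_mean_coverage_arithmetic(self):
        ev, txs = self._gene()
        track = uniform_track(600, [(0, 100, 60), (200, 300, 30), (400, 500, 60)])
        q = quantify_event(ev, txs, track)
        assert (q.n, q.N) == (30.0, 60.0)
        assert q.ratio == pytest.approx(1 / 3)
        assert (q.affected_len, q.rest_len) == (100, 200)

    def test_zero_coverage_gives_missing_ratio(self):
        ev, txs = self._gene()
        q = quantify_event(ev, txs, uniform_track(600, []))
        assert (q.n, q.N) == (0.0, 0.0)
        assert math.isnan(q.ratio)

    def test_raw_ratio_definition(self):
        ev, txs = self._gene()
        track = uniform_track(600, [(0, 100, 60), (200, 300, 30), (400, 500, 60)])
        q = quantify_event(ev, txs, track, ratio_def="raw")
        assert q.ratio == pytest.approx(0.5)

    def test_single_exon_host_skipped_with_warning(self, caplog):
        # affected exon spans the whole single-exon transcript: no rest
        from asquant.gene_models import ASEvent, GenomicInterval

        tx = make_transcript([(200, 300)], tid="t1")
        ev = make_se_event((200, 300), (0, 100), (400, 500))
        with caplog.at_level("WARNING"):
            assert quantify_event(ev, {"t1": tx}, uniform_track(600, [])) is None
        assert "no rest exons" in caplog.text

    def test_mxe_partner_excluded_from_rest(self):
        from asquant.gene_models import GenomicInterval, make_event

        t1 = make_transcript([(0, 100), (200, 300), (600, 700)], tid="t1")
        t2 = make_transcript([(0, 100), (400, 500), (600, 700)], tid="t2")
        ev = make_event(
            "MXE", "g1",
            [GenomicInterval("chr1", 200, 300), GenomicInterval("chr1", 400, 500)],
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 600, 700),
            "t1", "t2",
        )
        track = uniform_track(
            800, [(0, 100, 50), (200, 300, 40), (400, 500, 10), (600, 700, 50)]
        )
        q = quantify_event(ev, {"t1": t1, "t2": t2}, track)
        assert (q.n, q.N) == (40.0, 50.0)  # partner's depth plays no role in N
        assert q.rest_len == 200

    def test_ratio_recovers_simulated_psi(self, tmp_path):
        from asquant.simulate import SimConfig, simulate_dataset

        res = simulate_dataset(
            SimConfig(seed=9, n_se=10, n_mxe=0, n_a5ss=0, n_a3ss=0,
                      depth=100.0, psi_a=0.8, psi_b=0.8),
            str(tmp_path),
        )
        track = coverage_from_bedgraph(res.coverage_a)
        ratios = [
            quantify_event(ev, res.transcripts, track).ratio for ev in res.events
        ]
        assert np.mean(ratios) == pytest.approx(0.8 / 1.8, abs=0.01)


class TestCompareEvent:
    def _quant(self, eid, n, N):
        ratio = n / (n + N) if n + N else math.nan
        return EventQuant(eid, n, N, ratio, 100, 200)

    def test_strong_shift_is_significant(self):
        comp = compare_event(self._quant("e", 80, 100), self._quant("e", 20, 100))
        assert comp.chi2 == pytest.approx(25.0, abs=1e-9)
        assert comp.pvalue == pytest.approx(5.733e-7, rel=1e-3)
        assert comp.dratio == pytest.approx(80 / 180 - 20 / 120, abs=1e-12)
        assert comp.significant and comp.direction == "a_higher"

    def test_identical_quants_not_significant(self):
        comp = compare_event(self._quant("e", 50, 50), self._quant("e", 50, 50))
        assert (comp.chi2, comp.pvalue) == (0.0, 1.0)
        assert comp.dratio == 0.0 and not comp.significant

    def test_small_effect_filtered_despite_small_pvalue(self):
        comp = compare_event(self._quant("e", 3000, 7000), self._quant("e", 2800, 7200))
        assert comp.pvalue <= 0.1
        assert abs(comp.dratio) <= 0.1
        assert not comp.significant

    def test_low_coverage_flagged_not_significant(self):
        comp = compare_event(self._quant("e", 0, 0), self._quant("e", 50, 50))
        assert comp.low_coverage and not comp.significant
        assert comp.direction == "undefined"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ComparisonThresholds(p_max=0)
        with pytest.raises(ValueError):
            ComparisonThresholds(dratio_min=1.0)


class TestRunComparison:
    def test_empty_event_list(self, sim_small):
        track = coverage_from_bedgraph(sim_small.coverage_a)
        df, summary = run_comparison([], sim_small.transcripts, track, track)
        assert len(df) == 0
        assert summary["n_significant"] == 0
        assert all(v == 0 for v in summary["per_etype"].values())

    def test_self_comparison_yields_nothing_significant(self, sim_small):
        track = coverage_from_bedgraph(sim_small.coverage_a)
        df, summary = run_comparison(
            sim_small.events, sim_small.transcripts, track, track
        )
        assert len(df) == len(sim_small.events)
        assert summary["n_significant"] == 0
        assert (df["dratio"] == 0).all()

    def test_repeated_runs_identical(self, sim_small):
        ta = coverage_from_bedgraph(sim_small.coverage_a)
        tb = coverage_from_bedgraph(sim_small.coverage_b)
        df1, s1 = run_comparison(sim_small.events, sim_small.transcripts, ta, tb)
        df2, s2 = run_comparison(sim_small.events, sim_small.transcripts, ta, tb)
        assert df1.equals(df2) and s1 == s2
        assert df1["event_id"].is_monotonic_increasing

    def test_bh_correction_adds_padj(self, sim_small):
        ta = coverage_from_bedgraph(sim_small.coverage_a)
        tb = coverage_from_bedgraph(sim_small.coverage_b)
        df, _ = run_comparison(
            sim_small.events, sim_small.transcripts, ta, tb, bh_correction=True
        )
        assert "padj" in df.columns
        assert (df["padj"] >= df["pvalue"] - 1e-15).all()
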