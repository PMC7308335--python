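import numpy as np
import pytest

from repscan import enrichment_pipeline as ep
from repscan import motif_engine as me
from repscan import synthetic_data as sd
from repscan.io_core import Region, RunConfig
from repscan.motif_engine import MotifHit
from tests.conftest import make_region


@pytest.fixture(scope="module")
def toy_genome():
    genome, _ = sd.simulate_genome(sd.GenomeSimParams(length=20_000, seed=50))
    return genome


class TestEndRegions:
    def test_region_arithmetic(self, toy_genome):
        regions = ep.build_deletion_end_regions([("chrS", 1000, 2000)], toy_genome)
        five, three = regions
        assert (five.start, five.end) == (993, 1060)
        assert (three.start, three.end) == (1940, 2007)
        assert len(five) == len(three) == 67
        assert five.border_position == 1000 and three.border_position == 2000
        assert five.role == "deletion_5prime_end"

    def test_56_deletions_give_112_regions(self, toy_genome):
        dels = [("chrS", 200 * i + 1000, 200 * i + 1100) for i in range(56)]
        regions = ep.build_deletion_end_regions(
            [("chrS", s, e) for _, s, e in dels], toy_genome)
        assert len(regions) == 112

    def test_short_deletion_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="deletion 0"):
            ep.build_deletion_end_regions([("chrS", 100, 150)], toy_genome)

    def test_chromosome_edge_clipped_and_flagged(self, toy_genome):
        (five, _) = ep.build_deletion_end_regions([("chrS", 3, 500)], toy_genome)[:2]
        assert five.start == 0
        assert "clipped" in five.name


def _hits_region(seq, hept_offsets, region=None):
    region = region or make_region(seq)
    hepts = [MotifHit(o, o + 7, "+", 0.9, "heptamer_D3", region)
             for o in hept_offsets]
    return ep.RegionHits(region, hepts, [], [], [])


class TestWindows:
    seq = "A" * 67

    def test_single_hit_window(self):
        hits = _hits_region(self.seq, [20])
        (w,) = ep.extract_heptamer_windows(hits, flank=7)
        assert (w.start, w.end) == (13, 34)

    def test_overlapping_windows_merge(self):
        hits = _hits_region(self.seq, [20, 25])
        (w,) = ep.extract_heptamer_windows(hits, flank=7)
        assert (w.start, w.end) == (13, 39)
        assert len(w.contributing_hits) == 2

    def test_clipping_at_region_edge(self):
        hits = _hits_region(self.seq, [2])
        (w,) = ep.extract_heptamer_windows(hits, flank=7)
        assert (w.start, w.end) == (0, 16)

    def test_merged_windows_are_disjoint(self, rng):
        offsets = sorted(set(rng.integers(0, 60, size=12).tolist()))
        hits = _hits_region(self.seq, offsets)
        windows = ep.extract_heptamer_windows(hits, flank=7)
        for a, b in zip(windows, windows[1:]):
            assert a.end <= b.start
        # idempotence: every contributing hit is inside exactly one window
        assert sum(len(w.contributing_hits) for w in windows) == len(offsets)


class TestRunx1Overlap:
    def test_four_nt_overlap_positive(self):
        hits = _hits_region("A" * 67, [17])
        windows = ep.extract_heptamer_windows(hits, flank=7)
        runx1 = [MotifHit(10, 21, "-", 0.9, "RUNX1_core11", hits.region)]
        n, pos, detail = ep.count_runx1_overlaps(windows, runx1, 4)
        assert (n, pos) == (1, 1)
        assert detail[0]["best_overlap"] == 4

    def test_three_nt_overlap_negative(self):
        hits = _hits_region("A" * 67, [17])
        windows = ep.extract_heptamer_windows(hits, flank=7)
        runx1 = [MotifHit(10, 20, "-", 0.9, "RUNX1_core11", hits.region)]
        n, pos, _ = ep.count_runx1_overlaps(windows, runx1, 4)
        assert (n, pos) == (1, 0)

    def test_no_runx1_hits(self):
        hits = _hits_region("A" * 67, [17, 40])
        windows = ep.extract_heptamer_windows(hits, flank=7)
        assert ep.count_runx1_overlaps(windows, [], 4)[1] == 0


class TestEnrichment:
    def test_observed_equals_expected(self):
        res = ep.enrichment(10, 40, 250, 1000)
        assert res.fold == pytest.approx(1.0)
        assert res.z == 0.0

    def test_reh_like_numbers_with_binomial_sd(self):
        res = ep.enrichment(15, 30, 7600, 30_000)
        assert res.expected == pytest.approx(7.6)
        assert res.fold == pytest.approx(15 / 7.6)
        sd_b = np.sqrt(30 * 7.6 / 30 * (1 - 7.6 / 30))
        assert res.z == pytest.approx((15 - 7.6 - 0.5) / sd_b)
        assert res.p_binomial == pytest.approx(0.0034, abs=5e-4)

    def test_zero_background_rate_degenerate(self):
        res = ep.enrichment(3, 10, 0, 1000)
        assert np.isnan(res.fold)
        assert res.p_binomial == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ep.enrichment(1, 0, 1, 10)

    @pytest.mark.parametrize("observed,n,bp,bt", [
        (15, 30, 250, 1000), (16, 40, 5000, 20000), (30, 60, 3000, 10000),
    ])
    def test_analytic_vs_resampling_agree(self, observed, n, bp, bt):
        ana = ep.enrichment(observed, n, bp, bt, method="analytic")
        res = ep.enrichment(observed, n, bp, bt, method="resampling",
                            n_resamples=20_000, seed=7)
        assert ana.expected >= 5
        assert abs(ana.z - res.z) < 0.3
        lo, hi = sorted([ana.p_binomial, res.p_binomial])
        assert hi <= max(2.0 * lo, 1e-3)


class TestSpatial:
    def _region_with(self, insert, offset, border_at_start=True):
        # low-complexity background with no chance heptamer/RUNX1 matches
        seq = ("TTGA" * 17)[:67]
        seq = seq[:offset] + insert + seq[offset + len(insert):]
        border = 1000 if border_at_start else 1067
        return Region("chrT", 1000, 1067, seq, role="deletion_5prime_end",
                      border_position=border)

    def test_planted_runx1_heptamer_category_and_distance(self):
        region = self._region_with(sd.RUNX1_HEPTAMER_TEMPLATE, 6)
        hits = ep.compute_region_hits(region)
        records, medians = ep.spatial_classify([hits])
        planted = records[records["runx1_start"] == 1006]
        assert len(planted) == 1
        assert planted["category"].iloc[0] == "RUNX1_heptamer"
        assert planted["distance_bp"].iloc[0] == 6

    def test_planted_rss_module_category(self):
        nona = me.consensus(me.default_nonamer_pwms()[0])
        insert = sd.RUNX1_HEPTAMER_TEMPLATE + "ACGTACGTACGT" + nona
        region = self._region_with(insert, 6)
        hits = ep.compute_region_hits(region)
        records, _ = ep.spatial_classify([hits])
        planted = records[records["runx1_start"] == 1006]
        assert planted["category"].iloc[0] == "RUNX1_RSS"

    def test_partial_heptamer_spacer_rules(self):
        # a strong RUNX1 instance (score 0.99) whose flanks do not create a
        # full heptamer match on either strand, so only the partial rule fires
        runx1_site = "GGTGTGGTGGC"
        nona = me.consensus(me.default_nonamer_pwms()[0])
        for spacer, expected in ((12, "RUNX1_partial_heptamer_nonamer"),
                                 (21, "RUNX1_partial_heptamer_nonamer"),
                                 (15, "RUNX1_only")):
            insert = runx1_site + "GTG" + ("T" * spacer) + nona
            region = self._region_with(insert, 2)
            hits = ep.compute_region_hits(region)
            records, _ = ep.spatial_classify([hits])
            planted = records[records["runx1_start"] == 1002]
            assert len(planted) == 1
            assert planted["category"].iloc[0] == expected, spacer

    def test_region_without_border_skipped(self):
        region = make_region(sd.RUNX1_HEPTAMER_TEMPLATE + "A" * 55)
        hits = ep.compute_region_hits(region)
        records, _ = ep.spatial_classify([hits])
        assert len(records) == 0


class TestChipPeaks:
    def test_empty_peaks_degenerate(self):
        bg = ep.BackgroundStats(100, 10, 50, 5)
        assert ep.chip_peak_rss_enrichment([], bg) == (0, 0, None)

    def test_planted_peaks_counted(self):
        rng = np.random.default_rng(70)
        nona = me.consensus(me.default_nonamer_pwms()[0])
        hept = me.consensus(me.default_heptamer_pwms()[0])
        peaks = []
        for i in range(12):
            seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 120))
            if i < 4:  # RSS module with RUNX1 overlap
                insert = sd.RUNX1_HEPTAMER_TEMPLATE + "ACGTACGTACGT" + nona
            elif i < 8:  # RSS module without RUNX1
                insert = hept + "ACGTACGTACGT" + nona
            else:  # no module at all
                insert = ""
            seq = seq[:30] + insert + seq[30 + len(insert):]
            peaks.append(make_region(seq, start=1000 * i, chrom="chrP"))
        bg = ep.BackgroundStats(1000, 100, 400, 40)
        n_rss, n_rx, result = ep.chip_peak_rss_enrichment(peaks, bg)
        assert n_rss >= 8
        assert n_rx >= 4
        assert result is not None and result.fold > 1.0
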