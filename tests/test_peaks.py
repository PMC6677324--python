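import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmatac.io import GeneModel, GenomicInterval, StrandedCutTrack
from rhythmatac.peaks import (
    LFC_THRESHOLD,
    Peak,
    annotate_peaks,
    call_peaks,
    diff_access,
    feature_enrichment,
    merge_consensus,
    quantify_and_correlate,
    shift_fragments_to_cuts,
)


def _track(plus, minus):
    return StrandedCutTrack(plus=plus, minus=minus)


class TestShiftFragments:
    def test_plus_and_minus_shift_offsets(self):
        frags = pd.DataFrame(
            {
                "scaffold": ["s", "s"],
                "start": [100, 150],
                "end": [180, 200],
                "strand": ["+", "-"],
            }
        )
        track, dropped = shift_fragments_to_cuts(frags, {"s": 300})
        assert dropped == 0
        assert track.plus["s"][104] == 1  # +4 on the plus strand
        assert track.minus["s"][195] == 1  # -5 from the fragment end
        assert track.total_cuts() == 2

    def test_empty_table_and_mass_conservation(self):
        empty = pd.DataFrame(columns=["scaffold", "start", "end", "strand"])
        track, dropped = shift_fragments_to_cuts(empty, {"s": 50})
        assert track.total_cuts() == 0 and dropped == 0

        rng = np.random.default_rng(0)
        n = 500
        frags = pd.DataFrame(
            {
                "scaffold": "s",
                "start": rng.integers(0, 900, n),
                "end": 0,
                "strand": rng.choice(["+", "-"], n),
            }
        )
        frags["end"] = frags["start"] + 80
        track, dropped = shift_fragments_to_cuts(frags, {"s": 1000})
        assert track.total_cuts() + dropped == n

    def test_out_of_bounds_dropped_with_count(self):
        frags = pd.DataFrame(
            {"scaffold": ["s"], "start": [998], "end": [1000], "strand": ["+"]}
        )
        track, dropped = shift_fragments_to_cuts(frags, {"s": 1000})
        assert dropped == 1 and track.total_cuts() == 0


class TestCallPeaks:
    def test_poisson_tail_oracle_window_detected(self):
        rng = np.random.default_rng(1)
        L = 50_000
        lam = 0.25  # per strand -> 100 expected per 200 bp window combined
        plus = rng.poisson(lam, L)
        minus = rng.poisson(lam, L)
        plus[20_000:20_200] += 1  # ~300 observed in that window
        minus[20_000:20_200] += 1
        track = _track({"s": plus}, {"s": minus})
        # oracle: Poisson upper tail for 300 at lambda 100 is astronomically small
        assert stats.poisson.sf(299, 100) < 1e-50
        peaks = call_peaks(track)
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 20_000 < peaks[0].interval.end

    def test_uniform_track_vs_control_no_peaks(self):
        rng = np.random.default_rng(2)
        L = 50_000
        track = _track({"s": rng.poisson(0.5, L)}, {"s": rng.poisson(0.5, L)})
        ctrl = _track({"s": rng.poisson(0.5, L)}, {"s": rng.poisson(0.5, L)})
        assert call_peaks(track, ctrl) == []

    def test_zero_depth_no_peaks(self):
        track = _track({"s": np.zeros(1000, dtype=int)}, {"s": np.zeros(1000, dtype=int)})
        assert call_peaks(track) == []


class TestMergeConsensus:
    def _peak(self, start, end, scaf="s", score=1.0):
        iv = GenomicInterval(scaf, start, end, ".", f"p{start}", score)
        return Peak(interval=iv, summit=start, score=score)

    def test_overlap_coalesces_to_envelope(self):
        merged = merge_consensus([[self._peak(100, 200)], [self._peak(150, 250)]])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 250)

    def test_disjoint_unchanged_and_idempotent(self):
        sets = [[self._peak(0, 10), self._peak(50, 60)]]
        merged = merge_consensus(sets)
        assert [(p.interval.start, p.interval.end) for p in merged] == [(0, 10), (50, 60)]
        again = merge_consensus([merged] * 37)
        assert [(p.interval.start, p.interval.end) for p in again] == [(0, 10), (50, 60)]

    def test_order_invariance(self):
        a = [self._peak(0, 100), self._peak(300, 400)]
        b = [self._peak(50, 150)]
        m1 = merge_consensus([a, b])
        m2 = merge_consensus([b, a])
        assert [(p.interval.start, p.interval.end) for p in m1] == [
            (p.interval.start, p.interval.end) for p in m2
        ]


class TestQuantifyAndCorrelate:
    def _peaks(self, n=50, width=200, gap=400):
        return [
            Peak(
                interval=GenomicInterval("s", i * (width + gap), i * (width + gap) + width, ".", f"p{i}"),
                summit=i * (width + gap),
                score=1.0,
            )
            for i in range(n)
        ]

    def test_duplicated_replicate_r_is_one(self):
        rng = np.random.default_rng(3)
        L = 50 * 600
        track = _track({"s": rng.poisson(1.0, L)}, {"s": rng.poisson(1.0, L)})
        _, corr = quantify_and_correlate(self._peaks(), {"a": track, "b": track})
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_shared_signal_gives_high_r(self):
        rng = np.random.default_rng(4)
        n, L = 200, 200 * 600
        peaks = self._peaks(n)
        signal = rng.lognormal(1.0, 1.0, n)  # strong shared peak-level signal
        lam = np.full(L, 0.05)
        for p, s in zip(peaks, signal):
            lam[p.interval.start : p.interval.end] = s
        tracks = {
            name: _track({"s": rng.poisson(lam)}, {"s": rng.poisson(lam)})
            for name in ("r1", "r2")
        }
        _, corr = quantify_and_correlate(peaks, tracks)
        assert 0.7 <= corr.loc["r1", "r2"] <= 1.0

    def test_anticorrelated_counts_negative_r(self):
        n = 20
        peaks = self._peaks(n)
        up = np.zeros(n * 600, dtype=int)
        down = np.zeros(n * 600, dtype=int)
        for i, p in enumerate(peaks):
            up[p.interval.start] = 10 * (i + 1)
            down[p.interval.start] = 10 * (n - i)
        t1 = _track({"s": up}, {"s": np.zeros_like(up)})
        t2 = _track({"s": down}, {"s": np.zeros_like(down)})
        _, corr = quantify_and_correlate(peaks, {"a": t1, "b": t2})
        assert corr.loc["a", "b"] < 0


class TestDiffAccess:
    def test_depth_rescaling_absorbed(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(200, 300).astype(float)
        cm = pd.DataFrame(
            {"a1": base, "a2": base, "b1": 2 * base, "b2": 2 * base}
        )
        res = diff_access(cm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        np.testing.assert_allclose(res["log2_fc"], 0.0, atol=1e-9)
        assert not res["significant"].any()

    def test_lfc_threshold_matches_printed_cutoff(self):
        assert round(math.log2(1.3), 4) == LFC_THRESHOLD

    def test_truth_recovery_fourfold_changes(self):
        rng = np.random.default_rng(6)
        n, nde = 2000, 100
        base = rng.lognormal(5, 1, n)
        alpha = 0.05

        def nb(mu):
            return rng.poisson(rng.gamma(1 / alpha, mu * alpha))

        fc = np.ones(n)
        idx = rng.choice(n, nde, replace=False)
        fc[idx] = 4.0
        cm = pd.DataFrame(
            {"a1": nb(base), "a2": nb(base), "b1": nb(base * fc), "b2": nb(base * fc)}
        )
        res = diff_access(cm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        called = set(res.index[res["significant"]])
        truth = set(cm.index[idx])
        recall = len(called & truth) / nde
        fdr = len(called - truth) / max(len(called), 1)
        assert recall >= 0.8
        assert fdr <= 0.1

    def test_all_zero_peak_gives_na(self):
        cm = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]},
            index=["z", "ok"],
        )
        res = diff_access(cm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert math.isnan(res.loc["z", "p"])
        assert not res.loc["z", "significant"]


class TestAnnotatePeaks:
    def _gene(self, start, end, strand, gid="g1", scaf="s"):
        iv = GenomicInterval(scaf, start, end, strand, gid)
        third = (end - start) // 3
        exons = [
            GenomicInterval(scaf, start, start + third, strand),
            GenomicInterval(scaf, end - third, end, strand),
        ]
        return GeneModel(gid, iv, exons)

    def _peak_at(self, mid, scaf="s"):
        return Peak(
            interval=GenomicInterval(scaf, mid - 50, mid + 50, ".", f"pk{mid}"),
            summit=mid,
            score=1.0,
        )

    def test_promoter_window_upstream_plus_strand(self):
        gene = self._gene(5000, 8000, "+")
        ann = annotate_peaks([self._peak_at(4500)], [gene])
        assert ann.iloc[0]["category"] == "promoter-TSS"
        assert ann.iloc[0]["gene_id"] == "g1"

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        gene = self._gene(5000, 8000, "-")
        ann = annotate_peaks([self._peak_at(8500)], [gene])  # upstream of TSS=7999
        assert ann.iloc[0]["category"] == "promoter-TSS"

    def test_intron_and_intergenic(self):
        gene = self._gene(5000, 8000, "+")
        mid_intron = 6500  # between the two exons
        ann = annotate_peaks([self._peak_at(mid_intron), self._peak_at(20_000)], [gene])
        assert ann.iloc[0]["category"] == "intron"
        assert ann.iloc[1]["category"] == "intergenic"

    def test_precedence_promoter_beats_exon_vs_exhaustive_check(self):
        # peak midpoint inside an exon of gene X and the promoter of gene Y
        gx = self._gene(1000, 4000, "+", gid="gX")
        gy = self._gene(4500, 7000, "+", gid="gY")
        mid = 3800  # in gX's second exon [3000,4000) and gY's promoter [3500,4601)
        ann = annotate_peaks([self._peak_at(mid)], [gx, gy])
        assert ann.iloc[0]["category"] == "promoter-TSS"
        assert ann.iloc[0]["gene_id"] == "gY"

    def test_annotation_is_a_partition(self, toy_genome):
        _, (seqs, genes, peaks_iv, _) = toy_genome
        peaks = [
            Peak(interval=iv, summit=iv.start, score=1.0) for iv in peaks_iv
        ]
        ann = annotate_peaks(peaks, genes)
        assert len(ann) == len(peaks)
        assert ann["category"].isin(
            ["promoter-TSS", "TTS", "exon", "intron", "intergenic"]
        ).all()


class TestFeatureEnrichment:
    def test_arithmetic_oracle(self):
        res = feature_enrichment(
            {"promoter-TSS": 5, "intergenic": 5},
            {"promoter-TSS": 100, "intergenic": 900},
        )
        prom = next(r for r in res if r.category == "promoter-TSS")
        # (5/10)/(100/1000) = 5.0 -> log2 = 2.3219
        assert prom.log2_enrichment == pytest.approx(2.3219, abs=1e-4)

    def test_uniform_random_peaks_near_zero_enrichment(self):
        rng = np.random.default_rng(7)
        lengths = {"a": 500_000, "b": 300_000, "c": 200_000}
        total = sum(lengths.values())
        draws = rng.choice(
            list(lengths), p=[v / total for v in lengths.values()], size=10_000
        )
        counts = {k: int((draws == k).sum()) for k in lengths}
        res = feature_enrichment(counts, lengths)
        assert all(abs(r.log2_enrichment) <= 0.2 for r in res)

    def test_single_category_whole_genome_zero(self):
        (r,) = feature_enrichment({"intergenic": 7}, {"intergenic": 1234})
        assert r.log2_enrichment == 0.0

    def test_zero_count_category_is_nan(self):
        res = feature_enrichment({"exon": 0, "intron": 5}, {"exon": 10, "intron": 10})
        exon = next(r for r in res if r.category == "exon")
        assert math.isnan(exon.log2_enrichment)
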