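import math

import numpy as np
import pytest
from scipy import stats

from rhythmatac.io import GenomicInterval, StrandedCutTrack
from rhythmatac.footprints import (
    compare_fos_groups,
    extract_profiles,
    fos,
    footprint_fdr,
    rolling_average,
    timepoint_specific,
    wellington_scan,
    FOSRecord,
)
from rhythmatac.synthetic import simulate_cut_tracks


def _uniform_track(L=5000, lam=1.5, seed=0):
    rng = np.random.default_rng(seed)
    return StrandedCutTrack(
        plus={"s": rng.poisson(lam, L)}, minus={"s": rng.poisson(lam, L)}
    )


class TestWellingtonScan:
    def test_binomial_cdf_oracle_on_constructed_dip(self):
        # f+=2 cuts inside a 15 bp dip, F+=40 in the 35 bp upstream flank;
        # independent oracle: explicit term sum of BinomCDF(2; 42, 15/50)
        from math import comb

        p, q, n = 0.3, 0.7, 42
        p_hand = sum(comb(n, k) * p**k * q ** (n - k) for k in range(3))
        p_oracle = stats.binom.cdf(2, n, p)
        assert p_oracle == pytest.approx(p_hand, rel=1e-12)
        assert p_oracle == pytest.approx(5.53e-5, rel=0.01)

        L = 2000
        plus = np.zeros(L, dtype=int)
        minus = np.zeros(L, dtype=int)
        start, l = 1000, 15
        # uniformish flanks, depleted interior on both strands
        for vec in (plus, minus):
            vec[start - 35 : start] = 40 // 35 + (np.arange(35) < 40 % 35)
            vec[start + l : start + l + 35] = 40 // 35 + (np.arange(35) < 40 % 35)
            vec[start : start + l] = 0
            vec[start + 7] = 2  # f = 2, centered so sub-dips cannot exclude it
        track = StrandedCutTrack(plus={"s": plus}, minus={"s": minus})
        peaks = [GenomicInterval("s", 800, 1300)]
        cands = wellington_scan(track, peaks, p_thresh=1.0)
        dip = GenomicInterval("s", start, start + l)
        hit = [c for c in cands if c.overlaps(dip)]
        assert hit, "dip not among candidates"
        # at least as significant as the closed-form oracle for the full dip
        assert max(c.score for c in hit) >= -math.log10(p_oracle) - 0.5

    def test_uniform_track_no_calls_at_threshold(self):
        track = _uniform_track()
        peaks = [GenomicInterval("s", 500, 4500)]
        assert wellington_scan(track, peaks) == []

    def test_zero_track_no_candidates(self):
        track = StrandedCutTrack(
            plus={"s": np.zeros(2000, dtype=int)}, minus={"s": np.zeros(2000, dtype=int)}
        )
        assert wellington_scan(track, [GenomicInterval("s", 100, 1900)]) == []

    def test_peak_too_narrow_skipped(self):
        track = _uniform_track(L=500)
        assert wellington_scan(track, [GenomicInterval("s", 100, 170)]) == []

    def test_monotone_in_interior_depletion(self):
        # deeper interior depletion on both strands -> smaller p (higher score)
        def make(f_inside):
            plus = np.zeros(1000, dtype=int)
            minus = np.zeros(1000, dtype=int)
            s, l = 500, 15
            for vec in (plus, minus):
                vec[s - 35 : s] = 2
                vec[s + l : s + l + 35] = 2
                vec[s : s + l] = 0
                vec[s + 7] = f_inside
            return StrandedCutTrack(plus={"s": plus}, minus={"s": minus})

        peaks = [GenomicInterval("s", 400, 700)]
        dip = GenomicInterval("s", 500, 515)
        scores = []
        for f in (0, 3, 8):
            cands = wellington_scan(make(f), peaks, p_thresh=1.0)
            hit = [c for c in cands if c.overlaps(dip)]
            scores.append(max(c.score for c in hit))
        assert scores[0] >= scores[1] >= scores[2]


class TestFootprintFdr:
    def test_recovery_on_planted_truth(self, toy_genome):
        _, (seqs, _, peaks, truth) = toy_genome
        truth.depth_factors = {("WT", 4.0): 1.0}
        sl = {s: len(q) for s, q in seqs.items()}
        track = simulate_cut_tracks(truth, ("WT", 4.0), sl, seed=21)
        fps, efdr = footprint_fdr(track, peaks, n_shuffles=5, seed=1)
        assert efdr <= 0.01

        def overlaps(a, b):
            return a.scaffold == b.scaffold and a.start < b.end and b.start < a.end

        tp = sum(1 for f in fps if any(overlaps(f, t) for t in truth.footprints))
        recall = sum(
            1 for t in truth.footprints if any(overlaps(f, t) for f in fps)
        ) / len(truth.footprints)
        assert tp / len(fps) >= 0.9
        assert recall >= 0.8

    def test_naked_dna_zero_detections(self, toy_genome):
        _, (seqs, _, peaks, truth) = toy_genome
        sl = {s: len(q) for s, q in seqs.items()}
        naked = simulate_cut_tracks(truth, None, sl, naked_dna=True, seed=2)
        fps, efdr = footprint_fdr(naked, peaks, n_shuffles=3, seed=3)
        assert fps == [] and math.isnan(efdr)

    def test_same_seed_same_fdr(self, toy_genome):
        _, (seqs, _, peaks, truth) = toy_genome
        truth.depth_factors = {("WT", 4.0): 1.0}
        sl = {s: len(q) for s, q in seqs.items()}
        track = simulate_cut_tracks(truth, ("WT", 4.0), sl, seed=22)
        _, e1 = footprint_fdr(track, peaks, n_shuffles=3, seed=9)
        _, e2 = footprint_fdr(track, peaks, n_shuffles=3, seed=9)
        assert e1 == e2


class TestTimepointSpecific:
    def _iv(self, start, end):
        return GenomicInterval("s", start, end)

    def test_overlap_is_shared(self):
        a, b, shared = timepoint_specific([self._iv(100, 120)], [self._iv(110, 130)])
        assert a == [] and b == [] and len(shared) == 2

    def test_disjoint_both_specific(self):
        a, b, shared = timepoint_specific([self._iv(100, 120)], [self._iv(200, 220)])
        assert len(a) == 1 and len(b) == 1 and shared == []

    def test_empty_other_set(self):
        ivs = [self._iv(0, 15), self._iv(50, 70)]
        a, b, shared = timepoint_specific(ivs, [])
        assert a == ivs and b == [] and shared == []

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        A = [self._iv(int(s), int(s) + 15) for s in rng.integers(0, 5000, 40)]
        B = [self._iv(int(s), int(s) + 15) for s in rng.integers(0, 5000, 40)]
        a, b, shared = timepoint_specific(A, B)
        n_shared_a = sum(1 for iv in A if any(iv.overlaps(o) for o in B))
        assert len(a) + n_shared_a == len(A)


class TestProfilesAndRolling:
    def test_profile_window_and_delta(self):
        L = 1000
        plus = np.zeros(L, dtype=int)
        plus[507] = 5  # center of [500, 515) is 507
        track = StrandedCutTrack(plus={"s": plus}, minus={"s": np.zeros(L, dtype=int)})
        fp = GenomicInterval("s", 500, 515, ".", "fp0")
        prof = extract_profiles(track, [fp])
        assert prof.shape == (1, 201)
        assert prof.loc["fp0", 0] == 5
        assert prof.loc["fp0"].sum() == 5

    def test_out_of_bounds_row_dropped(self):
        track = StrandedCutTrack(
            plus={"s": np.zeros(150, dtype=int)}, minus={"s": np.zeros(150, dtype=int)}
        )
        prof = extract_profiles(track, [GenomicInterval("s", 10, 25)])
        assert prof.empty

    def test_rolling_average_definition(self):
        np.testing.assert_allclose(rolling_average([0, 3, 6]), [1.5, 3, 4.5])
        np.testing.assert_allclose(rolling_average(np.full(10, 2.0)), np.full(10, 2.0))
        np.testing.assert_allclose(rolling_average([1, 5, 2], w=1), [1, 5, 2])

    def test_rolling_average_input_validation(self):
        with pytest.raises(ValueError):
            rolling_average([1, 2, 3], w=2)
        with pytest.raises(ValueError):
            rolling_average([1, 2], w=3)


class TestFOS:
    def _track_with(self, C, L_, R, fp=(500, 515), flank=35):
        vec = np.zeros(1000, dtype=int)
        s, e = fp
        vec[s:e] = C
        vec[s - flank : s] = L_
        vec[e : e + flank] = R
        return StrandedCutTrack(plus={"s": vec}, minus={"s": np.zeros(1000, dtype=int)})

    def test_formula_values(self):
        track = self._track_with(9, 10, 10)
        rec = fos(track, GenomicInterval("s", 500, 515, ".", "f"))
        assert rec.fos == pytest.approx(2.0)
        assert rec.inv_fos == pytest.approx(0.5)

        track = self._track_with(0, 5, 5)
        rec = fos(track, GenomicInterval("s", 500, 515, ".", "f"))
        assert rec.fos == pytest.approx(0.4)
        assert rec.inv_fos == pytest.approx(2.5)

    def test_flat_chromatin_limit(self):
        track = self._track_with(1000, 1000, 1000)
        rec = fos(track, GenomicInterval("s", 500, 515, ".", "f"))
        assert rec.fos == pytest.approx(2.0, abs=0.01)
        assert rec.fos > 2.0

    def test_zero_flank_imputed_and_flagged(self):
        track = self._track_with(3, 0, 5)
        rec = fos(track, GenomicInterval("s", 500, 515, ".", "f"))
        assert rec.flank_imputed
        assert rec.L == pytest.approx(1 / 35)

    def test_out_of_bounds_rejected(self):
        track = self._track_with(1, 1, 1)
        with pytest.raises(ValueError):
            fos(track, GenomicInterval("s", 10, 25, ".", "f"))


class TestCompareFosGroups:
    def _records(self, means, n=30, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for (geno, zt), mu in means.items():
            for i in range(n):
                inv = max(rng.normal(mu, 0.1), 0.01)
                recs.append(
                    FOSRecord(
                        footprint_id=f"fp{i}", group=(geno, zt),
                        C=1, L=2, R=2, fos=1 / inv, inv_fos=inv,
                    )
                )
        return recs

    def test_null_rejection_rate(self):
        rng_seeds = range(120)
        rej = 0
        for s in rng_seeds:
            recs = self._records(
                {("WT", 4.0): 0.5, ("WT", 16.0): 0.5, ("KO", 4.0): 0.5}, n=15, seed=s
            )
            rej += compare_fos_groups(recs)["kw_p"] <= 0.05
        assert rej / len(rng_seeds) <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / 120)

    def test_deep_group_uniquely_lettered(self):
        recs = self._records(
            {
                ("WT", 4.0): 1.5,
                ("WT", 16.0): 0.6,
                ("ClkKO", 4.0): 0.6,
                ("ClkKO", 16.0): 0.6,
            },
            seed=1,
        )
        res = compare_fos_groups(recs)
        letters = res["letters"]
        wt04 = letters["WT_ZT04"]
        assert all(
            set(wt04).isdisjoint(set(v)) for k, v in letters.items() if k != "WT_ZT04"
        )

    def test_identical_groups_high_dunn_p(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(1.0, 0.1, 25)
        recs = []
        for geno in ("A", "B"):
            for i, v in enumerate(vals):
                recs.append(
                    FOSRecord(f"fp{i}", (geno, 4.0), 1, 2, 2, 1 / v, v)
                )
        res = compare_fos_groups(recs)
        assert res["dunn"]["p"].iloc[0] >= 0.9
        # identical groups share a letter
        assert set(res["letters"]["A_ZT04"]) & set(res["letters"]["B_ZT04"])
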