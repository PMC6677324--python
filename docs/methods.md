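# Methods

This note records the statistical models implemented in `rhythmatac`, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Rhythm detection

A gene's diurnal series is modeled as a single 24-h harmonic on the RPKM
scale, `E[y(t)] = M·(1 + a_rel·cos(2π(t − φ)/24))`. Two statistics probe
rhythmicity from different angles:

**Cosinor F-test.** Ordinary least squares on
`y = M + a·cos(ωt) + b·sin(ωt)`, `ω = 2π/24`; the p-value is the F-test of
the two rhythm coefficients against the intercept-only model (df = 2 and
n − 3). With the period fixed at 24 h this is the parametric end of the
spectrum: sensitive to sinusoidal shapes, exact under Gaussian noise, only
approximate under the multiplicative noise of RNA-seq (the null simulations
below quantify how close). Amplitude is `√(a²+b²)`; the acrophase
`(24/2π)·atan2(b,a)` is the fitted peak hour in [0, 24).

**Circular umbrella test.** A rank test against the umbrella alternative —
monotone rise to a peak timepoint, monotone fall after it, wrapped on the
24-h circle. For each of the m candidate peak positions the groups are
arranged trough-first and the Mack–Wolfe statistic
`A = Σ_{i<j≤peak} U_ij + Σ_{peak≤i<j} U_ji` (Mann–Whitney pair counts with
midrank ties) is standardized by its no-ties null moments with a
multiplicative tie correction. The search over peak positions is then
corrected in one of two ways:

- `method="bonferroni"`: smallest one-sided normal p × m, capped at 1.
  Closed-form but conservative by roughly 2× because the m statistics are
  strongly inter-correlated.
- `method="calibrated"` (default): the score
  `log min_k p_k + 10⁻³·mean_k log p_k` is referred to a Monte-Carlo null
  (14 999 draws, fixed internal seed) of the same design. Under
  exchangeability the statistic is distribution-free given the group sizes,
  so one null sample is cached per design. The small second term only breaks
  ties on the coarse lattice that a rank statistic occupies at n = 16 — at
  any practical threshold the rejections are min-p rejections — but it makes
  the calibrated null effectively continuous, so null p-values are uniform
  (KS distance ≈ 0.02–0.03 at n = 2000) rather than stair-stepped.

The calibrated mode is the default because the combination step below and
the BH adjustment both assume well-calibrated inputs; the Bonferroni mode is
retained for a dependency-free closed form.

**Combination and gates.** The two p-values are combined by minP for k = 2,
`p = 1 − (1 − min(p₁,p₂))²` — exact under independence, bounded by
`min p ≤ p ≤ 2·min p` — then BH-adjusted across all tested genes. A gene is
called rhythmic when adjusted p ≤ 0.05 and fold change ≥ 1.3. Fold change is
max/min of per-timepoint replicate means by default (replicates estimate the
timepoint mean; raw per-observation extremes are available via
`collapse_replicates=False`, which is noisier and strictly larger).
Expression filtering keeps genes reaching 3 RPKM (replicate mean) at one or
more timepoints.

## Differential rhythmicity

Wild type is sampled 8 × 2 every 3 h, mutants 4 × 2 every 6 h; each genotype
is fit on its own grid (no interpolation) with a robust cosinor: Huber
M-estimation, tuning c = 1.345, via iteratively reweighted least squares.
The test statistic is the Wald form
`W = d'(V_wt + V_mut)⁻¹ d` on the rhythm-coefficient difference
`d = (a,b)_wt − (a,b)_mut`.

Two numerical choices matter at these sample sizes:

- the robust covariance carries an `n/(n − 3)` degrees-of-freedom
  correction — the uncorrected sandwich is noticeably anticonservative at
  n = 8 observations per mutant gene;
- the default reference is `F(2, n_wt + n_mut − 6)` applied to `W/2` rather
  than the asymptotic χ²(2) (available via `reference="chi2"`). In null
  simulations at the study design with 20% multiplicative noise the F form
  holds the 5% level (≈ 4.9% over 800 replicates) where χ²(2) rejects at
  ≈ 6–9%.

The table-level routine BH-adjusts within the rhythmic set, flags genes at
adjusted p ≤ 0.05, and emits cumulative −log10 adjP curves for the rhythmic
set and an arrhythmic background, plus a two-sample KS statistic labeled
descriptive: no formal test of "higher than background" is claimed.

## ATAC peaks

Fragments are reduced to Tn5 cut sites with the standard +4/−5 correction
(plus-strand read start +4; fragment end −5 on the minus strand). Peaks:
200 bp windows at 50 bp steps, combined-strand counts, upper-tail Poisson
p against `λ = max(genome-wide rate, depth-scaled control rate in the
window)·window`, BH across windows at q ≤ 0.01, merge of overlapping or
abutting significant windows, summit at the maximum-count base. This is a
deliberate simplification of model-based callers: no fragment-model building,
no local lambda beyond the control track — adequate for toy genomes where
peaks are well separated, and not intended for real heterochromatin noise.

Differential accessibility uses median-of-ratios size factors, a pooled
method-of-moments NB dispersion (mean of `(s² − μ)/μ²` across peaks and
groups — the mean, not the median, because the per-peak ratio at two
replicates is χ²(1)-skewed and its median underestimates dispersion by
~2–3×), a delta-method Wald test on the log2 fold change with a 0.5
pseudocount, BH, and the joint gate FDR < 0.05 with |log2FC| > 0.3785. No
per-peak dispersion shrinkage: recall ≈ 1.0 and empirical FDR ≈ 0.06–0.08 on
4-fold planted changes in 2000 NB peaks, which is all the stand-in needs.

Annotation assigns each peak by its midpoint with precedence
promoter-TSS > TTS > exon > intron > intergenic, windows strand-aware
(promoter −1 kb..+100 bp of the TSS; TTS −100 bp..+1 kb). Intergenic peaks
attach to the nearest TSS within 10 kb for the peak→gene map, else remain
unassigned. Feature enrichment is `log2[(n_cat/n_total)/(len_cat/len_total)]`;
a zero-count category reports NaN rather than −∞.

## Footprints and FOS

**Detection.** For every position and size l ∈ [11, 25] inside a peak, the
forward test asks whether plus-strand cuts inside the candidate are depleted
against the upstream 35 bp flank — `p⁺ = BinomCDF(f⁺; f⁺+F⁺, l/(l+35))` —
and the reverse test mirrors it with minus-strand cuts against the
downstream flank. The combined p is `max(p⁺, p⁻)`: both strands must show
depletion, which is what distinguishes a bound factor from a coverage dip.
Per position the best size is kept; candidates at p ≤ 1e-10 are selected
greedily by ascending p without overlap. Even-length centers are left-biased
(`start + ⌊l/2⌋`).

**Empirical FDR.** Each of n shuffles circularly rotates the cut counts
within every peak and rescans; FDR = mean shuffle detections / observed.
The two strands rotate by different offsets — rotation with a common offset
would move each footprint intact and re-detect it — and the relative offset
is constrained to exceed the footprint-plus-flank span (~125 bp), because an
unconstrained pair of offsets occasionally re-aligns the same footprint's
two strand dips and plants real signal in the null (measured: inflates the
FDR estimate to ~1.5× the gate). The observed set is emitted only when the
estimate is ≤ 0.01.

**FOS.** `FOS = (C+1)/L + (C+1)/R` with C, L, R the mean combined-strand
cuts/bp over the footprint and its 35 bp flanks; inverse FOS is reported so
deeper footprints score higher. Strand handling sums the two strands per
base and averages per bp (a per-strand profile mode exists for diagnostics).
A zero flank mean is replaced by 1/35 — one pseudo-cut across the window —
and the record flagged; flagged records are excluded from group statistics
by default. Flat chromatin gives FOS → 2 (inverse 0.5) in the large-count
limit, so inverse FOS above ~0.5 indicates genuine protection.

**Group comparison.** Kruskal–Wallis with tie correction on inverse FOS
across genotype × ZT groups; Dunn's pairwise z tests on pooled midranks,
BH-adjusted (the adjustment choice is ours); compact letters by
insert-and-absorb so that groups sharing a letter are not significantly
different at 0.05.

## Motif classes

PWMs are 4 × L probability matrices with a TF-class label, scanned as
log2-odds against a uniform background with a 10⁻³ pseudocount; a hit
requires ≥ 80% of the maximum achievable score, on either strand; N scores
as the worst base. Backgrounds are drawn per target footprint from a
repeat-free pool (lowercase = masked): identical length, |ΔGC| ≤ 0.05,
relaxed in +0.05 steps to at most 0.25 before failing. Enrichment is the
doubly-normalized fold change
`(prop_FP/prop_bg)/(prop_gwFP/prop_gw_bg)`, gate > 1.5, with zero
proportions replaced by 1/(2n) and flagged. Within a footprint at most one
hit per TF class is retained (lowest motif id, for determinism). The bundled
library is 12 consensus-derived PWMs (0.85 dominant-base probability) across
bHLH, forkhead, HTH, MADS, bZIP, NR, GATA, ETS and C2H2-ZF — illustrative,
not a curated database; the enrichment logic is library-agnostic.

## Synthetic data: what it emulates, what it does not

**Expression.** Rhythmic genes are exact cosinors times unit-mean lognormal
noise, `σ = √(ln(1+CV²))`, CV defaulting to 0.2 — the multiplicative noise
scale typical of deeply sequenced bulk RNA-seq. Mutant genotypes multiply
the relative amplitude by an attenuation factor in [0,1] (mesor preserved);
a mesor shift for constitutively low clock-gene expression can be modeled by
adjusting `mesor_range` per genotype configuration. Defaults: 8 timepoints
(ZT1..ZT22) × 2 replicates for wild type, every 6 h for mutants; relative
amplitudes 0.3–0.8; mesors 5–100 RPKM. Not emulated: count-level
(Poisson/NB) sampling at low expression, gene–gene correlation, batch
effects, non-sinusoidal waveforms. Passing tests therefore demonstrate
correct statistical behavior under the stated noise model, not robustness
to waveform misspecification.

**Genome and cut tracks.** Toy scaffolds (2 × 200 kb default) of i.i.d.
bases at 50% GC; 40 non-overlapping peaks of 600–1200 bp; 50 footprints of
11–25 bp placed ≥ 60 bp from peak edges; a consensus motif written into half
of them. Cut counts are per-strand Poisson: background 0.2 cuts/bp
(combined), 6 cuts/bp inside peaks — a deeply sequenced library chosen so a
90%-occupied footprint clears the p ≤ 1e-10 emission threshold with 35 bp
flank evidence — ×1.5 in the 10 bp flanking each footprint (the elevated
integration directly around a bound factor), ×(1 − occupancy·depth_factor)
inside footprints, with `depth_factor` per (genotype, ZT) the dial for
time-of-day occupancy. An optional gamma-Poisson (negative binomial) mode
adds overdispersion for robustness checks. Not emulated: Tn5 sequence bias,
fragment-length structure, mappability, duplicate reads.

**Motif sequence sets.** Each footprint-sized sequence (17–25 bp) carries at
most one base-rate motif (probability 0.9, uniform over the 12 PWMs → 7.5%
per motif in every set) in its left part, and target footprints additionally
carry the planted motif in a dedicated right-end slot (50% of sequences).
Sequences are GC-homogenized — the padding compensates the GC of whatever
motifs are embedded, with binomial tails reject-sampled to ±0.2 — because a
6–10 bp motif is ~30% of such a short sequence, and without compensation
GC-matched background selection couples to motif content and biases every
unplanted motif's fold change by up to ~1.5× in either direction. The
uniform base rate exists so all four proportions are estimable; fold-change
summaries over generator seeds use the geometric mean (the arithmetic mean
of a ratio statistic is upward-biased by ~5–8% at this noise level).

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 1000–2000 genes
per expression simulation, 200–600 Monte-Carlo replicates per calibration
claim, one 2 × 200 kb genome per footprint run, 10 seeds × (400 target +
1600 genome-wide) sequences for motif enrichment — sizes at which every
acceptance quantity's Monte-Carlo error is small against its margin. All
generators and calibrations are deterministic under fixed seeds; the
umbrella null cache uses a fixed internal seed because the calibration
sample is part of the statistic's definition, not of the data.

## Known limitations

- The umbrella calibration assumes exchangeability within the design; heavy
  ties (many identical values) degrade the normal approximation that feeds
  the score.
- The NB Wald test shares one dispersion across peaks; strongly
  peak-dependent dispersion would need shrinkage estimators out of scope
  here.
- The footprint scanner's greedy non-overlap selection returns the locally
  best sub-dip, which may be a few bp narrower than the planted protection;
  recovery is scored by overlap, and boundary-exact calls are not claimed.
- Feature-enrichment windows overlap on dense toy genomes (a promoter
  window can cover intronic bases of a neighbor), so category lengths are
  approximations there; on real annotations the caller should pass
  feature-length totals computed from its own GFF.
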