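"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study design end to end:

- ``simulate_expression``: cosinor-rhythmic plus flat genes sampled on a
  diurnal grid (wild-type: 8 timepoints x 2 replicates every 3 h; clock
  mutants: 4 timepoints x 2 replicates every 6 h) with multiplicative
  lognormal noise; mutant genotypes attenuate rhythm amplitude.
- ``simulate_genome``: toy scaffolds of i.i.d. nucleotides at a chosen GC
  content, non-overlapping gene models, non-overlapping accessible peaks
  containing planted TF footprints, and motif instances written into
  designated footprints.
- ``simulate_cut_tracks``: per-base Poisson Tn5 cut counts on each strand:
  low uniform background outside peaks, elevated inside peaks, a further
  boost in the 10 bp immediately flanking each footprint, and depletion
  inside footprints scaled by occupancy times a (genotype, ZT)-dependent
  depth factor.  A naked-DNA mode emits the uniform background everywhere.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneModel, GenomicInterval, StrandedCutTrack

__all__ = [
    "SimExpressionConfig",
    "SimGenomeConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_genome",
    "simulate_cut_tracks",
]

WT_TIMEPOINTS = tuple(float(h) for h in range(1, 24, 3))  # ZT1..ZT22 every 3 h
MUTANT_TIMEPOINTS = tuple(float(h) for h in range(1, 24, 6))  # every 6 h

# Flank boost around planted footprints: Tn5 integration is elevated in the
# 10 bp directly flanking a bound factor.
FLANK_BOOST_BP = 10
FLANK_BOOST_FACTOR = 1.5


@dataclass
class SimExpressionConfig:
    n_genes: int = 2000
    frac_rhythmic: float = 0.1
    timepoints_h: tuple[float, ...] = WT_TIMEPOINTS
    n_replicates: int = 2
    period_h: float = 24.0
    amplitude_range: tuple[float, float] = (0.3, 0.8)  # relative amplitude
    mesor_range: tuple[float, float] = (5.0, 100.0)  # RPKM
    noise_cv: float = 0.2
    genotype_effects: dict[str, float] = field(default_factory=lambda: {"WT": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(self.timepoints_h)
        if not all(0 <= t < self.period_h for t in tp) or any(
            b <= a for a, b in zip(tp, tp[1:])
        ):
            raise ValueError("timepoints must be strictly increasing within [0, period)")
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError("frac_rhythmic must lie in [0,1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.amplitude_range[1] >= 1.0:
            raise ValueError(
                "relative amplitude must be < 1 (a >= 1 gives negative expectations)"
            )


@dataclass
class SimGenomeConfig:
    n_scaffolds: int = 2
    scaffold_len_bp: int = 200_000
    n_genes: int = 40
    gene_len_bp: tuple[int, int] = (2_000, 6_000)
    n_exons: int = 3
    n_peaks: int = 40
    peak_len_bp: tuple[int, int] = (600, 1_200)
    n_footprints_per_peak: int = 1
    n_footprints: int | None = 50  # total; overrides the per-peak count
    footprint_len_bp: tuple[int, int] = (11, 25)
    planted_motif: str = "CACGTG"
    motif_frac: float = 0.5  # fraction of footprints receiving the motif
    background_gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.footprint_len_bp
        if lo < 11 or hi > 25 or lo > hi:
            raise ValueError("footprint lengths must lie within [11, 25]")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0,1)")


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    ``rhythmic_genes`` maps gene_id -> (relative amplitude, phase_h, mesor);
    ``footprints`` are the planted intervals (named fp0, fp1, ...);
    ``depth_factors`` maps (genotype, zt) -> fractional footprint occupancy
    multiplier; ``motif_footprints`` lists footprint names carrying the
    planted motif, with the motif's genomic start position.
    """

    rhythmic_genes: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    peaks: list[GenomicInterval] = field(default_factory=list)
    footprints: list[GenomicInterval] = field(default_factory=list)
    footprint_occupancy: float = 0.9
    depth_factors: dict[tuple[str, float], float] = field(default_factory=dict)
    motif_footprints: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(cfg: SimExpressionConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Cosinor-rhythmic and flat genes with multiplicative lognormal noise.

    Rhythmic genes follow ``mesor * (1 + a*cos(2*pi*(t - phi)/T)) * eps`` with
    ``eps`` lognormal of unit mean and coefficient of variation ``noise_cv``;
    flat genes have a = 0.  Each genotype in ``genotype_effects`` gets its own
    columns with amplitude multiplied by the attenuation factor (1 = intact
    rhythm, 0 = flat).
    """
    rng = np.random.default_rng(cfg.seed)
    n_rhythmic = int(round(cfg.n_genes * cfg.frac_rhythmic))
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mesor = rng.uniform(*cfg.mesor_range, size=cfg.n_genes)
    amp = np.zeros(cfg.n_genes)
    amp[:n_rhythmic] = rng.uniform(*cfg.amplitude_range, size=n_rhythmic)
    phase = rng.uniform(0.0, cfg.period_h, size=cfg.n_genes)
    phase[n_rhythmic:] = 0.0

    sigma = math.sqrt(math.log1p(cfg.noise_cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal

    columns: dict[str, np.ndarray] = {}
    for genotype, atten in cfg.genotype_effects.items():
        if not 0.0 <= atten <= 1.0:
            raise ValueError(f"attenuation factor for {genotype!r} must lie in [0,1]")
        a_g = amp * atten
        for t in cfg.timepoints_h:
            signal = mesor * (1.0 + a_g * np.cos(2.0 * math.pi * (t - phase) / cfg.period_h))
            for rep in range(1, cfg.n_replicates + 1):
                eps = (
                    np.exp(rng.normal(mu, sigma, size=cfg.n_genes))
                    if cfg.noise_cv > 0
                    else np.ones(cfg.n_genes)
                )
                columns[ExpressionMatrix.sample_name(genotype, t, rep)] = signal * eps

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=gene_ids))
    truth = SimTruth(
        rhythmic_genes={
            gene_ids[i]: (float(amp[i]), float(phase[i]), float(mesor[i]))
            for i in range(n_rhythmic)
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Genome


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    lengths: np.ndarray,
    scaffold_names: list[str],
    scaffold_len: int,
    margin: int,
    max_tries: int = 10_000,
) -> list[tuple[str, int, int]]:
    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffold_names}
    out = []
    for i in range(n):
        length = int(lengths[i])
        for _ in range(max_tries):
            scaf = scaffold_names[int(rng.integers(len(scaffold_names)))]
            start = int(rng.integers(margin, scaffold_len - length - margin))
            end = start + length
            if all(not (start < e + margin and s - margin < end) for s, e in placed[scaf]):
                placed[scaf].append((start, end))
                out.append((scaf, start, end))
                break
        else:
            raise RuntimeError("could not place non-overlapping intervals; genome too small")
    return out


def simulate_genome(
    cfg: SimGenomeConfig,
) -> tuple[dict[str, str], list[GeneModel], list[GenomicInterval], SimTruth]:
    """Toy scaffolds with gene models, accessible peaks and planted footprints.

    Returns ``(sequences, gene_models, peaks, truth)``.  Peaks and genes are
    non-overlapping within their own kind; each peak carries
    ``n_footprints_per_peak`` footprints placed away from the peak edges so a
    35 bp flank fits inside the peak.  A fraction ``motif_frac`` of footprints
    receives the planted motif consensus, centered in the footprint.
    """
    rng = np.random.default_rng(cfg.seed)
    motif = cfg.planted_motif.upper()
    if len(motif) > cfg.footprint_len_bp[0]:
        raise ValueError("planted motif longer than the smallest footprint")

    names = [f"scaf{i + 1}" for i in range(cfg.n_scaffolds)]
    seq_arrays = {s: _random_sequence(rng, cfg.scaffold_len_bp, cfg.background_gc) for s in names}

    # genes with simple exon structure
    gene_lengths = rng.integers(*cfg.gene_len_bp, size=cfg.n_genes)
    gene_pos = _place_nonoverlapping(rng, cfg.n_genes, gene_lengths, names, cfg.scaffold_len_bp, margin=2_000)
    gene_models = []
    for i, (scaf, start, end) in enumerate(gene_pos):
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(scaf, start, end, strand)
        bounds = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * cfg.n_exons - 2, replace=False))
        edges = [start, *bounds.tolist(), end]
        exons = [
            GenomicInterval(scaf, edges[2 * k], edges[2 * k + 1], strand)
            for k in range(cfg.n_exons)
        ]
        gene_models.append(GeneModel(f"gene{i:04d}", iv, exons))

    # peaks, each with footprints far enough from the edge for a 35 bp flank
    peak_lengths = rng.integers(*cfg.peak_len_bp, size=cfg.n_peaks)
    peak_pos = _place_nonoverlapping(rng, cfg.n_peaks, peak_lengths, names, cfg.scaffold_len_bp, margin=300)
    peaks = [
        GenomicInterval(scaf, start, end, ".", f"peak{i}")
        for i, (scaf, start, end) in enumerate(peak_pos)
    ]

    footprints: list[GenomicInterval] = []
    motif_fps: dict[str, int] = {}
    fp_margin = 60  # keep the 35 bp flank plus slack inside the peak
    if cfg.n_footprints is not None:
        base, extra = divmod(cfg.n_footprints, max(cfg.n_peaks, 1))
        fp_quota = [base + (1 if i < extra else 0) for i in range(cfg.n_peaks)]
    else:
        fp_quota = [cfg.n_footprints_per_peak] * cfg.n_peaks
    for peak, quota in zip(peaks, fp_quota):
        for _ in range(quota):
            fp_len = int(rng.integers(cfg.footprint_len_bp[0], cfg.footprint_len_bp[1] + 1))
            lo = peak.start + fp_margin
            hi = peak.end - fp_margin - fp_len
            if hi <= lo:
                continue
            for _ in range(100):
                start = int(rng.integers(lo, hi))
                cand = GenomicInterval(peak.scaffold, start, start + fp_len, ".", f"fp{len(footprints)}")
                if all(
                    not (f.scaffold == cand.scaffold and f.start - 80 < cand.end and cand.start < f.end + 80)
                    for f in footprints
                ):
                    footprints.append(cand)
                    break

    n_motif = int(round(len(footprints) * cfg.motif_frac))
    chosen = rng.choice(len(footprints), size=n_motif, replace=False) if n_motif else []
    for idx in np.asarray(chosen, dtype=int):
        fp = footprints[idx]
        offset = fp.start + (len(fp) - len(motif)) // 2
        seq_arrays[fp.scaffold][offset : offset + len(motif)] = np.frombuffer(
            motif.encode(), dtype="S1"
        )
        motif_fps[fp.name] = offset

    sequences = {s: arr.tobytes().decode() for s, arr in seq_arrays.items()}
    truth = SimTruth(peaks=peaks, footprints=footprints, motif_footprints=motif_fps)
    return sequences, gene_models, peaks, truth


# ---------------------------------------------------------------------------
# Motif-enrichment sequence sets


def simulate_motif_sequence_sets(
    pwms: list,
    planted_id: str,
    n_target: int = 400,
    n_genomewide: int = 1600,
    planted_frac: float = 0.5,
    slot_prob: float = 0.9,
    gc: float = 0.5,
    fp_len_bp: tuple[int, int] = (17, 25),
    pool_factor: int = 4,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Footprint and background-pool sequences for motif-enrichment tests.

    Every sequence draws a length in ``fp_len_bp`` and i.i.d. background
    nucleotides at ``gc``; with probability ``slot_prob`` one motif chosen
    uniformly from ``pwms`` is embedded (its consensus) in the left part of
    the sequence, so each motif occurs at the same base rate in every set.
    In the target footprints, ``planted_frac`` of the sequences additionally
    carry the consensus of ``planted_id`` at the right end — a dedicated slot
    that never collides with the base-rate motif.  Pools (for GC/length-
    matched background selection) follow the base-rate process only and are
    ``pool_factor`` times their set's size.

    Returns keys ``target_fp``, ``target_pool``, ``genomewide_fp``,
    ``genomewide_pool``.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.motif_id: p for p in pwms}
    if planted_id not in by_id:
        raise KeyError(f"planted motif {planted_id!r} not in the PWM set")

    def consensus(pwm) -> str:
        mat = np.asarray(pwm.matrix)
        return "".join("ACGT"[i] for i in mat.argmax(axis=0))

    planted_cons = consensus(by_id[planted_id])
    min_len = max(len(consensus(p)) for p in pwms) + len(planted_cons)
    if fp_len_bp[0] < min_len:
        raise ValueError(
            f"footprint length {fp_len_bp[0]} too short for base motif plus "
            f"planted slot ({min_len} bp)"
        )

    def one_sequence(with_planted: bool) -> str:
        L = int(rng.integers(fp_len_bp[0], fp_len_bp[1] + 1))
        base_cons = (
            consensus(pwms[int(rng.integers(len(pwms)))])
            if rng.random() < slot_prob
            else ""
        )
        # GC-homogenize: padding compensates the GC of whatever motifs this
        # sequence carries, so total GC is ~``gc`` for every sequence in every
        # set.  A short motif is a large fraction of a footprint-sized
        # sequence; without compensation, GC-matched background selection
        # couples to motif content and skews every motif's proportions.
        embedded = base_cons + (planted_cons if with_planted else "")
        embedded_gc = sum(c in "GC" for c in embedded)
        pad_len = L - len(embedded)
        pad_gc = (gc * L - embedded_gc) / pad_len if pad_len > 0 else gc
        pad_gc = float(np.clip(pad_gc, 0.0, 1.0))
        right_reserved = len(planted_cons) if with_planted else 0
        for _ in range(50):  # reject binomial GC tails so matching stays sane
            arr = _random_sequence(rng, L, pad_gc)
            if base_cons:
                hi = L - right_reserved - len(base_cons)
                off = int(rng.integers(0, hi + 1))
                arr[off : off + len(base_cons)] = np.frombuffer(base_cons.encode(), dtype="S1")
            if with_planted:
                arr[L - len(planted_cons) :] = np.frombuffer(planted_cons.encode(), dtype="S1")
            n_gc = int(np.isin(arr, np.frombuffer(b"GC", dtype="S1")).sum())
            if abs(n_gc / L - gc) <= 0.2:
                break
        return arr.tobytes().decode()

    n_planted = int(round(n_target * planted_frac))
    target_fp = [one_sequence(i < n_planted) for i in range(n_target)]
    genomewide_fp = [one_sequence(False) for _ in range(n_genomewide)]
    target_pool = [one_sequence(False) for _ in range(pool_factor * n_target)]
    genomewide_pool = [one_sequence(False) for _ in range(pool_factor * n_genomewide)]
    return {
        "target_fp": target_fp,
        "target_pool": target_pool,
        "genomewide_fp": genomewide_fp,
        "genomewide_pool": genomewide_pool,
    }


# ---------------------------------------------------------------------------
# Cut tracks


def simulate_cut_tracks(
    truth: SimTruth,
    condition: tuple[str, float] | None,
    scaffold_lengths: dict[str, int],
    depth: float = 6.0,
    background_depth: float = 0.2,
    seed: int = 0,
    naked_dna: bool = False,
    overdispersion: float | None = None,
) -> StrandedCutTrack:
    """Per-base stranded Tn5 cut counts for one (genotype, ZT) condition.

    ``depth`` is the mean combined-strand cuts/bp inside accessible peaks;
    ``background_depth`` applies outside peaks.  Inside a planted footprint
    the rate is multiplied by ``1 - occupancy * depth_factor(genotype, zt)``
    and the 10 bp flanking windows are boosted 1.5x.  Counts are Poisson per
    strand (rate split evenly) or negative binomial when ``overdispersion``
    (the NB dispersion alpha, var = mu + alpha*mu^2) is given.  In
    ``naked_dna`` mode the peak/footprint structure is ignored and the uniform
    peak-level rate applies everywhere.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    if naked_dna:
        factor = 0.0
    else:
        if condition is None or condition not in truth.depth_factors:
            raise KeyError(f"unknown condition label {condition!r}")
        factor = truth.depth_factors[condition]

    plus: dict[str, np.ndarray] = {}
    minus: dict[str, np.ndarray] = {}
    for scaf, length in scaffold_lengths.items():
        rate = np.full(length, background_depth / 2.0)  # per strand
        if naked_dna:
            rate[:] = depth / 2.0
        else:
            for peak in truth.peaks:
                if peak.scaffold == scaf:
                    rate[peak.start : peak.end] = depth / 2.0
            for fp in truth.footprints:
                if fp.scaffold != scaf:
                    continue
                lb = max(fp.start - FLANK_BOOST_BP, 0)
                rb = min(fp.end + FLANK_BOOST_BP, length)
                rate[lb : fp.start] *= FLANK_BOOST_FACTOR
                rate[fp.end : rb] *= FLANK_BOOST_FACTOR
                rate[fp.start : fp.end] *= max(0.0, 1.0 - truth.footprint_occupancy * factor)
        if overdispersion is None:
            plus[scaf] = rng.poisson(rate)
            minus[scaf] = rng.poisson(rate)
        else:
            # NB via gamma-Poisson mixture: shape 1/alpha, mean rate
            shape = 1.0 / overdispersion
            plus[scaf] = rng.poisson(rng.gamma(shape, rate * overdispersion))
            minus[scaf] = rng.poisson(rng.gamma(shape, rate * overdispersion))
    return StrandedCutTrack(plus=plus, minus=minus)
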