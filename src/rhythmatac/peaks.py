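"""ATAC-seq peak calling, quantification, differential accessibility and
genomic-feature annotation.

Mapped fragments become single-base Tn5 cut events (+4 bp on plus-strand
reads, -5 bp from the fragment end on minus-strand reads, the standard
correction for the Tn5 insertion offset).  Peaks are called by a Poisson
sliding-window test against the larger of the genome-wide rate and a
depth-scaled naked-DNA control, BH-corrected, and merged.  Differential
accessibility uses median-of-ratios normalization and a negative-binomial
Wald test with a common method-of-moments dispersion.  Peaks are annotated to
promoter-TSS / TTS / exon / intron / intergenic by midpoint containment with
that precedence, and feature enrichment is length-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, GenomicInterval, StrandedCutTrack
from .rhythm import bh_adjust

__all__ = [
    "Peak",
    "FeatureEnrichment",
    "shift_fragments_to_cuts",
    "call_peaks",
    "merge_consensus",
    "quantify_and_correlate",
    "diff_access",
    "annotate_peaks",
    "feature_enrichment",
    "LFC_THRESHOLD",
]

PLUS_SHIFT = 4
MINUS_SHIFT = 5
LFC_THRESHOLD = 0.3785  # log2(1.3) to 4 decimals
CATEGORIES = ("promoter-TSS", "TTS", "exon", "intron", "intergenic")


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int
    score: float  # -log10 q
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak interval")


@dataclass
class FeatureEnrichment:
    category: str
    n_peaks: int
    total_peaks: int
    category_len_bp: int
    total_len_bp: int
    log2_enrichment: float


def shift_fragments_to_cuts(
    fragments: pd.DataFrame, scaffold_lengths: dict[str, int]
) -> tuple[StrandedCutTrack, int]:
    """Convert mapped fragments to shifted single-base cut counts.

    ``fragments`` needs columns scaffold/start/end/strand (0-based half-open).
    A plus-strand read contributes one cut at start+4; a minus-strand read one
    cut at end-5.  Returns the track and the number of fragments dropped
    because the shifted position left the scaffold.
    """
    plus = {s: np.zeros(n, dtype=np.int64) for s, n in scaffold_lengths.items()}
    minus = {s: np.zeros(n, dtype=np.int64) for s, n in scaffold_lengths.items()}
    dropped = 0
    for scaf, sub in fragments.groupby("scaffold"):
        if scaf not in plus:
            raise KeyError(f"fragment on unknown scaffold {scaf!r}")
        n = scaffold_lengths[scaf]
        is_plus = sub["strand"].to_numpy() == "+"
        pos = np.where(
            is_plus,
            sub["start"].to_numpy() + PLUS_SHIFT,
            sub["end"].to_numpy() - MINUS_SHIFT,
        )
        ok = (pos >= 0) & (pos < n)
        dropped += int((~ok).sum())
        np.add.at(plus[scaf], pos[ok & is_plus], 1)
        np.add.at(minus[scaf], pos[ok & ~is_plus], 1)
    return StrandedCutTrack(plus=plus, minus=minus), dropped


def call_peaks(
    track: StrandedCutTrack,
    control_track: StrandedCutTrack | None = None,
    window: int = 200,
    step: int = 50,
    q_thresh: float = 0.01,
) -> list[Peak]:
    """Poisson sliding-window peak caller against a naked-DNA control.

    Combined-strand cuts in each window are tested against an upper-tail
    Poisson with lambda = max(genome-wide mean rate, depth-scaled control rate
    in the window) * window; window p-values are BH-corrected genome-wide and
    significant windows that overlap or abut are merged into peaks.  The
    summit is the highest-count base of the merged peak; peak score is the
    best window -log10 q.
    """
    total = track.total_cuts()
    if total == 0:
        return []
    genome_bp = sum(track.scaffold_lengths.values())
    genome_rate = total / genome_bp
    if control_track is not None:
        ctrl_total = control_track.total_cuts()
        scale = total / ctrl_total if ctrl_total > 0 else 0.0

    windows = []  # (scaffold, start, end, count, lambda)
    for scaf, length in track.scaffold_lengths.items():
        combined = track.combined(scaf)
        cs = np.concatenate(([0], np.cumsum(combined)))
        starts = np.arange(0, max(length - window, 0) + 1, step)
        ends = starts + window
        counts = cs[ends] - cs[starts]
        lam = np.full(len(starts), genome_rate * window)
        if control_track is not None and ctrl_total > 0:
            ctrl = np.concatenate(([0], np.cumsum(control_track.combined(scaf))))
            lam = np.maximum(lam, (ctrl[ends] - ctrl[starts]) * scale)
        for s, e, c, l in zip(starts, ends, counts, lam):
            windows.append((scaf, int(s), int(e), int(c), float(l)))

    pvals = np.array([stats.poisson.sf(c - 1, l) for *_, c, l in windows])
    qvals = bh_adjust(pvals)
    sig = [
        (w[0], w[1], w[2], q)
        for w, q in zip(windows, qvals)
        if q <= q_thresh
    ]
    if not sig:
        return []
    sig.sort()
    peaks: list[Peak] = []
    cur_scaf, cur_start, cur_end, cur_q = sig[0]
    for scaf, s, e, q in sig[1:]:
        if scaf == cur_scaf and s <= cur_end:
            cur_end = max(cur_end, e)
            cur_q = min(cur_q, q)
        else:
            peaks.append(_finalize_peak(track, cur_scaf, cur_start, cur_end, cur_q))
            cur_scaf, cur_start, cur_end, cur_q = scaf, s, e, q
    peaks.append(_finalize_peak(track, cur_scaf, cur_start, cur_end, cur_q))
    return peaks


def _finalize_peak(
    track: StrandedCutTrack, scaf: str, start: int, end: int, q: float
) -> Peak:
    combined = track.combined(scaf)[start:end]
    summit = start + int(np.argmax(combined))
    score = 300.0 if q == 0 else -math.log10(q)
    iv = GenomicInterval(scaf, start, end, ".", f"peak_{scaf}_{start}", score)
    return Peak(interval=iv, summit=summit, score=score)


def merge_consensus(peak_sets: list[list[Peak]]) -> list[Peak]:
    """Coalesce overlapping (>= 1 bp) peaks across sets into their envelope.

    Idempotent and order-invariant; the merged summit/score come from the
    highest-scoring constituent.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    allp = sorted(
        (p for ps in peak_sets for p in ps),
        key=lambda p: (p.interval.scaffold, p.interval.start, p.interval.end),
    )
    if not allp:
        return []
    out: list[Peak] = []
    cur = allp[0]
    cur_start, cur_end = cur.interval.start, cur.interval.end
    best = cur
    for p in allp[1:]:
        if p.interval.scaffold == cur.interval.scaffold and p.interval.start < cur_end:
            cur_end = max(cur_end, p.interval.end)
            if p.score > best.score:
                best = p
        else:
            out.append(_envelope(cur.interval.scaffold, cur_start, cur_end, best))
            cur, cur_start, cur_end, best = p, p.interval.start, p.interval.end, p
    out.append(_envelope(cur.interval.scaffold, cur_start, cur_end, best))
    return out


def _envelope(scaf: str, start: int, end: int, best: Peak) -> Peak:
    iv = GenomicInterval(scaf, start, end, ".", f"peak_{scaf}_{start}", best.score)
    summit = best.summit if start <= best.summit < end else start + (end - start) // 2
    return Peak(interval=iv, summit=summit, score=best.score)


def quantify_and_correlate(
    peaks: list[Peak],
    tracks: dict[str, StrandedCutTrack],
    norm_total: float = 10_000_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak cut totals per sample, normalized to 10 million cuts, and the
    pairwise Pearson correlation of log2(x+1) normalized counts.

    Returns ``(count_matrix, corr)``; the count matrix holds raw (unnormalized)
    totals, correlations are computed on the normalized log scale.
    """
    if not peaks:
        raise ValueError("no peaks to quantify")
    index = [p.interval.name for p in peaks]
    raw = {}
    for name, track in tracks.items():
        total = track.total_cuts()
        if total == 0:
            raise ValueError(f"sample {name!r} has zero cuts")
        col = np.array(
            [
                track.combined(p.interval.scaffold)[p.interval.start : p.interval.end].sum()
                for p in peaks
            ],
            dtype=float,
        )
        raw[name] = col
    counts = pd.DataFrame(raw, index=index)
    totals = {name: tracks[name].total_cuts() for name in tracks}
    norm = counts / pd.Series(totals) * norm_total
    corr = np.log2(norm + 1.0).corr(method="pearson")
    return counts, corr


def diff_access(
    count_matrix: pd.DataFrame,
    group_labels: dict[str, str],
    lfc_thresh: float = LFC_THRESHOLD,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential accessibility on raw per-peak counts.

    Median-of-ratios size factors normalize library depth; the per-peak log2
    fold change compares normalized group means; significance comes from a
    negative-binomial Wald test with a single method-of-moments dispersion
    shared across peaks, BH-corrected.  A peak is significant when
    adj_p < ``fdr`` and |log2FC| > ``lfc_thresh``.  All-zero peaks give NA
    rows.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("diff_access compares exactly two groups")
    cols_a = [c for c in count_matrix.columns if group_labels[c] == groups[0]]
    cols_b = [c for c in count_matrix.columns if group_labels[c] == groups[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 samples per group")
    counts = count_matrix.to_numpy(float)

    # median-of-ratios size factors (geometric-mean reference over nonzero rows)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    finite = np.isfinite(log_counts).all(axis=1)
    log_ref = log_counts[finite].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_counts[finite] - log_ref, axis=0))
    norm = counts / sf

    ia = [count_matrix.columns.get_loc(c) for c in cols_a]
    ib = [count_matrix.columns.get_loc(c) for c in cols_b]
    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)

    # common dispersion, method of moments on normalized counts:
    # var = mu + alpha * mu^2 pooled across groups and peaks
    mus, vars_ = [], []
    for idx in (ia, ib):
        mus.append(norm[:, idx].mean(axis=1))
        vars_.append(norm[:, idx].var(axis=1, ddof=1))
    mu = np.concatenate(mus)
    v = np.concatenate(vars_)
    ok = mu > 0
    # mean, not median: the per-peak (v - mu)/mu^2 ratio at 2 replicates is
    # chi2(1)-skewed, so its median sits far below the true dispersion
    alpha = max(float(np.mean((v[ok] - mu[ok]) / mu[ok] ** 2)), 1e-8)

    pseudo = 0.5  # stabilizes log fold changes of low-count peaks
    lfc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    # Wald: var(log mu_hat) ~ (1/mu + alpha)/n per group (delta method on NB)
    na, nb = len(ia), len(ib)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = (1.0 / (mean_a + pseudo) + alpha) / na + (1.0 / (mean_b + pseudo) + alpha) / nb
        se_log2 = np.sqrt(se2) / math.log(2.0)
        wald = lfc / se_log2
    pvals = 2.0 * stats.norm.sf(np.abs(wald))

    allzero = counts.sum(axis=1) == 0
    pvals[allzero] = np.nan
    lfc[allzero] = np.nan
    adj = np.full_like(pvals, np.nan)
    okp = ~np.isnan(pvals)
    if okp.any():
        adj[okp] = bh_adjust(pvals[okp])
    sig = (adj < fdr) & (np.abs(lfc) > lfc_thresh)
    return pd.DataFrame(
        {
            "log2_fc": lfc,
            "p": pvals,
            "adj_p": adj,
            "significant": np.where(np.isnan(pvals), False, sig),
        },
        index=count_matrix.index,
    )


# ---------------------------------------------------------------------------
# Annotation


def _annotation_windows(gene: GeneModel) -> dict[str, list[GenomicInterval]]:
    """Strand-aware promoter/TTS windows plus exon/intron bodies for one gene."""
    scaf = gene.interval.scaffold
    tss, tts = gene.tss, gene.tts
    if gene.strand == "+":
        prom = (tss - 1000, tss + 100 + 1)
        ttsw = (tts - 100, tts + 1000 + 1)
    else:
        prom = (tss - 100, tss + 1000 + 1)
        ttsw = (tts - 1000, tts + 100 + 1)
    out: dict[str, list[GenomicInterval]] = {"promoter-TSS": [], "TTS": [], "exon": [], "intron": []}
    for key, (lo, hi) in (("promoter-TSS", prom), ("TTS", ttsw)):
        lo = max(lo, 0)
        if hi > lo:
            out[key].append(GenomicInterval(scaf, lo, hi, gene.strand))
    out["exon"] = list(gene.exons)
    out["intron"] = gene.introns()
    return out


def annotate_peaks(
    peaks: list[Peak], gene_models: list[GeneModel], nearest_tss_bp: int = 10_000
) -> pd.DataFrame:
    """Assign each peak one category and (where possible) a gene.

    Membership is decided by containment of the peak midpoint in strand-aware
    windows: promoter-TSS (-1 kb..+100 bp of the TSS), TTS (-100 bp..+1 kb of
    the TTS), any exon, any intron, else intergenic; precedence in that order.
    Intergenic peaks are assigned to the nearest TSS within
    ``nearest_tss_bp``, else left unassigned.
    """
    by_scaf: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_scaf.setdefault(g.interval.scaffold, []).append(g)

    rows = []
    for peak in peaks:
        mid = peak.interval.midpoint
        category, gene_id = "intergenic", ""
        for cat in ("promoter-TSS", "TTS", "exon", "intron"):
            hit = None
            for gene in by_scaf.get(peak.interval.scaffold, []):
                for iv in _annotation_windows(gene)[cat]:
                    if iv.start <= mid < iv.end:
                        hit = gene.gene_id
                        break
                if hit:
                    break
            if hit:
                category, gene_id = cat, hit
                break
        if category == "intergenic":
            best_d = nearest_tss_bp + 1
            for gene in by_scaf.get(peak.interval.scaffold, []):
                d = abs(gene.tss - mid)
                if d < best_d:
                    best_d, gene_id = d, gene.gene_id
            if best_d > nearest_tss_bp:
                gene_id = ""
        rows.append((peak.interval.name, category, gene_id))
    return pd.DataFrame(rows, columns=["peak", "category", "gene_id"]).set_index("peak")


def feature_enrichment(
    category_counts: dict[str, int], category_lengths: dict[str, int]
) -> list[FeatureEnrichment]:
    """Length-normalized log2 enrichment of peaks per genomic feature class:
    log2[(n_cat/n_total) / (len_cat/len_total)].  Categories with zero peaks
    report NaN."""
    n_total = sum(category_counts.values())
    len_total = sum(category_lengths.values())
    if n_total == 0 or len_total == 0:
        raise ValueError("need peaks and nonzero feature lengths")
    out = []
    for cat in category_counts:
        n, ln = category_counts[cat], category_lengths.get(cat, 0)
        if n > 0 and ln > 0:
            enr = math.log2((n / n_total) / (ln / len_total))
        else:
            enr = math.nan
        out.append(
            FeatureEnrichment(
                category=cat,
                n_peaks=n,
                total_peaks=n_total,
                category_len_bp=ln,
                total_len_bp=len_total,
                log2_enrichment=enr,
            )
        )
    return out
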