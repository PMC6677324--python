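"""TF footprint detection and occupancy dynamics from stranded Tn5 cut tracks.

Footprints are short (11-25 bp) intervals inside accessible peaks that are
depleted of Tn5 cuts relative to their 35 bp flanks on *both* strands: the
forward-strand test compares cuts inside the candidate against the upstream
flank, the reverse-strand test against the downstream flank, and the combined
p-value is the worse of the two, so a call requires depletion in both.  An
empirical false-discovery rate is estimated by circularly rotating the cut
counts within each peak.  Footprint depth is summarized by the footprint
occupancy score FOS = (C+1)/L + (C+1)/R over mean cuts/bp in the central
region (C) and the two 35 bp flanks (L, R); the inverse FOS is reported so
that larger values mean deeper footprints.  Group comparisons use
Kruskal-Wallis with Dunn's post-hoc z tests and a compact letter display.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval, StrandedCutTrack

__all__ = [
    "FOSRecord",
    "wellington_scan",
    "footprint_fdr",
    "timepoint_specific",
    "extract_profiles",
    "rolling_average",
    "fos",
    "compare_fos_groups",
]

MIN_FP_LEN = 11
MAX_FP_LEN = 25
FLANK_BP = 35
P_THRESH = 1e-10
FDR_THRESH = 0.01


@dataclass
class FOSRecord:
    footprint_id: str
    group: tuple[str, float]  # (genotype, ZT)
    C: float
    L: float
    R: float
    fos: float
    inv_fos: float
    flank_imputed: bool = False


def _scan_peak(
    plus: np.ndarray,
    minus: np.ndarray,
    peak: GenomicInterval,
    sizes: range,
    flank: int,
) -> list[tuple[int, int, float]]:
    """Candidate (start, length, p) per position inside one peak, best size kept."""
    cp = np.concatenate(([0], np.cumsum(plus)))
    cm = np.concatenate(([0], np.cumsum(minus)))

    best_p = None
    best_len = None
    for l in sizes:
        lo = peak.start + flank
        hi = peak.end - flank - l  # last valid start (inclusive)
        if hi < lo:
            continue
        starts = np.arange(lo, hi + 1)
        f_plus = cp[starts + l] - cp[starts]
        F_plus = cp[starts] - cp[starts - flank]  # upstream flank, plus strand
        f_minus = cm[starts + l] - cm[starts]
        F_minus = cm[starts + l + flank] - cm[starts + l]  # downstream, minus strand
        frac = l / (l + flank)
        p_fwd = stats.binom.cdf(f_plus, f_plus + F_plus, frac)
        p_rev = stats.binom.cdf(f_minus, f_minus + F_minus, frac)
        p = np.maximum(p_fwd, p_rev)  # both strands must show depletion
        if best_p is None:
            width = peak.end - peak.start - 2 * flank - sizes.start + 1
            best_p = np.ones(max(width, 0))
            best_len = np.full(max(width, 0), sizes.start)
        n = len(starts)
        better = p < best_p[:n]
        best_p[:n][better] = p[better]
        best_len[:n][better] = l
    if best_p is None:
        return []
    lo = peak.start + flank
    return [(lo + i, int(best_len[i]), float(best_p[i])) for i in range(len(best_p))]


def wellington_scan(
    track: StrandedCutTrack,
    peaks: list[GenomicInterval],
    sizes: range = range(MIN_FP_LEN, MAX_FP_LEN + 1),
    flank: int = FLANK_BP,
    p_thresh: float = P_THRESH,
) -> list[GenomicInterval]:
    """Strand-imbalance footprint scan inside peaks.

    For every position and footprint size, cuts inside the candidate are
    tested against the adjacent flank with a binomial lower tail on each
    strand (forward test on the upstream flank with plus-strand cuts, reverse
    test on the downstream flank with minus-strand cuts); the combined p is
    the max of the two.  The best size per position is retained, then
    footprints are selected greedily by ascending p without overlap.  Peaks
    too narrow for a candidate plus both flanks are skipped.  Returned
    intervals carry score = -log10(p).
    """
    candidates: list[tuple[float, str, int, int]] = []
    for peak in peaks:
        plus = track.plus[peak.scaffold]
        minus = track.minus[peak.scaffold]
        if peak.start < flank or peak.end + flank > len(plus):
            continue
        for start, length, p in _scan_peak(plus, minus, peak, sizes, flank):
            if p <= p_thresh:
                candidates.append((p, peak.scaffold, start, length))

    candidates.sort()
    chosen: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for p, scaf, start, length in candidates:
        end = start + length
        if any(start < e and s < end for s, e in occupied.get(scaf, [])):
            continue
        occupied.setdefault(scaf, []).append((start, end))
        score = 300.0 if p == 0 else -math.log10(p)
        chosen.append(GenomicInterval(scaf, start, end, ".", f"fp_{scaf}_{start}", score))
    chosen.sort(key=lambda iv: (iv.scaffold, iv.start))
    return chosen


def footprint_fdr(
    track: StrandedCutTrack,
    peaks: list[GenomicInterval],
    n_shuffles: int = 5,
    p_thresh: float = P_THRESH,
    fdr: float = FDR_THRESH,
    seed: int = 0,
    sizes: range = range(MIN_FP_LEN, MAX_FP_LEN + 1),
) -> tuple[list[GenomicInterval], float]:
    """Footprint calls gated by an empirical FDR from within-peak shuffles.

    Each shuffle circularly rotates the cut counts within every peak and
    rescans; empirical FDR = mean shuffle detections / observed detections.
    The two strands rotate by different offsets so that the strand coincidence
    defining a footprint is destroyed while each strand's marginal structure
    is kept; the relative offset is constrained to exceed the footprint-plus-
    flank span, otherwise a rotation can trivially reassemble a real footprint
    and inflate the null.  The observed set is returned only when the FDR is
    <= the threshold; with zero observed detections the FDR is undefined
    (NaN) and the set is empty.
    """
    observed = wellington_scan(track, peaks, sizes=sizes, p_thresh=p_thresh)
    if not observed:
        return [], math.nan
    rng = np.random.default_rng(seed)
    margin = sizes.stop - 1 + 2 * 35 + 20  # footprint + flanks + boost slack
    null_counts = []
    for _ in range(n_shuffles):
        plus = {s: v.copy() for s, v in track.plus.items()}
        minus = {s: v.copy() for s, v in track.minus.items()}
        for peak in peaks:
            sl = slice(peak.start, peak.end)
            width = peak.end - peak.start
            d_plus = int(rng.integers(width))
            if width > 2 * margin:
                rel = int(rng.integers(margin, width - margin))
            else:
                rel = width // 2
            plus[peak.scaffold][sl] = np.roll(plus[peak.scaffold][sl], d_plus)
            minus[peak.scaffold][sl] = np.roll(
                minus[peak.scaffold][sl], (d_plus + rel) % width
            )
        shuffled = StrandedCutTrack(plus=plus, minus=minus)
        null_counts.append(len(wellington_scan(shuffled, peaks, sizes=sizes, p_thresh=p_thresh)))
    empirical_fdr = float(np.mean(null_counts)) / len(observed)
    if empirical_fdr > fdr:
        return [], empirical_fdr
    return observed, empirical_fdr


def timepoint_specific(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval]
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval]]:
    """Partition two footprint sets into (specific_a, specific_b, shared).

    A footprint is shared iff it overlaps (>= 1 bp) any footprint of the
    other set; shared members of both sets are returned together.
    """

    def overlaps_any(iv: GenomicInterval, others: list[GenomicInterval]) -> bool:
        return any(iv.overlaps(o) for o in others)

    specific_a = [iv for iv in set_a if not overlaps_any(iv, set_b)]
    specific_b = [iv for iv in set_b if not overlaps_any(iv, set_a)]
    shared = [iv for iv in set_a if overlaps_any(iv, set_b)] + [
        iv for iv in set_b if overlaps_any(iv, set_a)
    ]
    return specific_a, specific_b, shared


def extract_profiles(
    track: StrandedCutTrack,
    footprints: list[GenomicInterval],
    halfwidth: int = 100,
    per_strand: bool = False,
) -> pd.DataFrame:
    """Combined-strand cut counts around footprint centers.

    Rows are footprints (index = footprint name), columns are offsets
    -halfwidth..+halfwidth relative to the footprint center
    (start + floor(length/2), left-biased for even lengths).  Footprints whose
    window leaves the scaffold are dropped.
    """
    rows = {}
    for iv in footprints:
        center = iv.start + len(iv) // 2
        lo, hi = center - halfwidth, center + halfwidth + 1
        vec_len = len(track.plus[iv.scaffold])
        if lo < 0 or hi > vec_len:
            continue
        if per_strand:
            row = np.concatenate(
                [track.plus[iv.scaffold][lo:hi], track.minus[iv.scaffold][lo:hi]]
            )
        else:
            row = track.combined(iv.scaffold)[lo:hi]
        rows[iv.name or f"{iv.scaffold}:{iv.start}"] = row
    cols = np.arange(-halfwidth, halfwidth + 1)
    if per_strand:
        cols = np.concatenate([cols, cols])
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def rolling_average(vec: np.ndarray, w: int = 3) -> np.ndarray:
    """Centered rolling mean with the window shrinking at the edges.

    Output length equals input length; ``w`` must be odd and no longer than
    the vector.
    """
    v = np.asarray(vec, dtype=float)
    if w % 2 != 1:
        raise ValueError("window must be odd")
    if w > len(v):
        raise ValueError("window longer than vector")
    half = w // 2
    cs = np.concatenate(([0.0], np.cumsum(v)))
    n = len(v)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def fos(
    track: StrandedCutTrack,
    footprint: GenomicInterval,
    group: tuple[str, float] = ("NA", -1.0),
    flank: int = FLANK_BP,
) -> FOSRecord:
    """Footprint occupancy score for one footprint in one condition.

    C, L and R are mean combined-strand cuts/bp over the footprint and its
    left/right ``flank`` bp windows; FOS = (C+1)/L + (C+1)/R, and the inverse
    FOS (1/FOS) grows with footprint depth.  A zero flank mean is replaced by
    1/flank (one pseudo-cut over the window) and the record flagged.
    """
    combined = track.combined(footprint.scaffold)
    if footprint.start - flank < 0 or footprint.end + flank > len(combined):
        raise ValueError("footprint flanks leave the scaffold")
    C = float(combined[footprint.start : footprint.end].mean())
    L = float(combined[footprint.start - flank : footprint.start].mean())
    R = float(combined[footprint.end : footprint.end + flank].mean())
    imputed = False
    if L == 0:
        L, imputed = 1.0 / flank, True
    if R == 0:
        R, imputed = 1.0 / flank, True
    score = (C + 1.0) / L + (C + 1.0) / R
    return FOSRecord(
        footprint_id=footprint.name or f"{footprint.scaffold}:{footprint.start}",
        group=group,
        C=C,
        L=L,
        R=R,
        fos=score,
        inv_fos=1.0 / score,
        flank_imputed=imputed,
    )


# ---------------------------------------------------------------------------
# Group statistics: Kruskal-Wallis + Dunn + compact letter display


def _dunn_pairwise(values: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's z tests on pooled midranks with tie correction, BH-adjusted."""
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    mean_ranks, ns = [], []
    pos = 0
    for v in values:
        mean_ranks.append(ranks[pos : pos + len(v)].mean())
        ns.append(len(v))
        pos += len(v)
    rows = []
    for i, j in itertools.combinations(range(len(values)), 2):
        se = math.sqrt(
            (N * (N + 1) / 12.0 - tie_term) * (1.0 / ns[i] + 1.0 / ns[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    from .rhythm import bh_adjust

    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def _letter_display(
    labels: list[str], different: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different; every
    significant pair ends up with disjoint letter sets.
    """
    letter_sets: list[set[str]] = [set(labels)]
    for a, b in different:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if cand and not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    # absorb redundant sets
    letter_sets = [
        s for s in letter_sets if not any(s < other for other in letter_sets)
    ]
    letter_sets.sort(key=lambda s: min(labels.index(x) for x in s))
    out: dict[str, str] = {lbl: "" for lbl in labels}
    for letter, s in zip(string.ascii_lowercase, letter_sets):
        for lbl in labels:
            if lbl in s:
                out[lbl] += letter
    return out


def compare_fos_groups(
    records: list[FOSRecord],
    alpha: float = 0.05,
    include_imputed: bool = False,
) -> dict:
    """Kruskal-Wallis on inverse FOS across (genotype, ZT) groups with Dunn
    post-hoc tests and a compact letter display.

    Returns a dict with keys ``kw_stat``, ``kw_p``, ``dunn`` (pairwise
    DataFrame with BH-adjusted p), ``letters`` (group -> letters; groups
    sharing a letter are not significantly different at ``alpha``) and
    ``group_medians``.  Records with imputed flank means are excluded unless
    requested; groups with < 2 records are dropped with a warning field.
    """
    usable = [r for r in records if include_imputed or not r.flank_imputed]
    by_group: dict[str, list[float]] = {}
    for r in usable:
        key = f"{r.group[0]}_ZT{int(r.group[1]):02d}"
        by_group.setdefault(key, []).append(r.inv_fos)
    dropped = [g for g, v in by_group.items() if len(v) < 2]
    by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(by_group) < 2:
        raise ValueError("need >=2 groups with >=2 records each")
    labels = sorted(by_group)
    values = [np.asarray(by_group[g]) for g in labels]
    kw_stat, kw_p = stats.kruskal(*values)
    dunn = _dunn_pairwise(values, labels)
    different = {
        (row.group_a, row.group_b)
        for row in dunn.itertuples()
        if row.adj_p <= alpha
    }
    letters = _letter_display(labels, different)
    return {
        "kw_stat": float(kw_stat),
        "kw_p": float(kw_p),
        "dunn": dunn,
        "letters": letters,
        "group_medians": {g: float(np.median(v)) for g, v in zip(labels, values)},
        "dropped_groups": dropped,
    }
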