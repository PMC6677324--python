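"""Motif scanning in footprint sequences and class-level enrichment.

Footprint sequences are scanned on both strands with position weight matrices
(log-odds vs a uniform background; a hit requires >= 80% of the maximum
achievable score).  Enrichment of a motif in time-specific footprints is the
paper-style doubly-normalized fold change

    (prop in target FPs / prop in matched background)
    / (prop in genome-wide FPs / prop in genome-wide background)

with backgrounds drawn from a repeat-free pool matched to the footprints in
length and GC content.  Hits in one footprint are collapsed to at most one
per TF class before class distributions are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "PWM",
    "load_pwms",
    "bundled_pwms",
    "pwm_scan",
    "select_background",
    "motif_fold_change",
    "MotifClassEnrichment",
    "collapse_by_class",
    "class_distribution",
    "gc_content",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
ENRICHMENT_THRESHOLD = 1.5
DEFAULT_SCORE_FRAC = 0.8


@dataclass(frozen=True)
class PWM:
    """A 4 x L probability matrix (rows A, C, G, T) with a TF-class label."""

    motif_id: str
    tf_class: str
    matrix: tuple[tuple[float, ...], ...]
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape[0] != 4 or mat.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix[0])

    def log_odds(self) -> np.ndarray:
        """Log2-odds against a uniform background, pseudocounted."""
        mat = np.asarray(self.matrix, dtype=float) + self.pseudocount
        mat /= mat.sum(axis=0, keepdims=True)
        return np.log2(mat / 0.25)

    def reverse_complement(self) -> np.ndarray:
        return self.log_odds()[::-1, ::-1]


@dataclass
class MotifClassEnrichment:
    motif_id: str
    tf_class: str
    prop_fp: float
    prop_bg: float
    prop_gw_fp: float
    prop_gw_bg: float
    fold_change: float
    enriched: bool
    pseudo_used: bool = False


def load_pwms(path: str | Path) -> list[PWM]:
    """Parse the plain-text PWM format: ``>motif_id class`` header followed by
    four whitespace-separated probability rows (A, C, G, T)."""
    pwms = []
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header, got {lines[i]!r}")
        parts = lines[i][1:].split()
        if len(parts) != 2:
            raise ValueError(f"header must be '>motif_id class': {lines[i]!r}")
        rows = tuple(tuple(float(x) for x in lines[i + 1 + r].split()) for r in range(4))
        pwms.append(PWM(motif_id=parts[0], tf_class=parts[1], matrix=rows))
        i += 5
    return pwms


def bundled_pwms() -> list[PWM]:
    """The small built-in motif set spanning bHLH, forkhead, HTH, MADS and
    other common insect TF classes."""
    ref = resources.files("rhythmatac").joinpath("data/motifs.txt")
    with resources.as_file(ref) as path:
        return load_pwms(path)


def _encode(sequence: str) -> np.ndarray:
    """A/C/G/T -> 0..3; N and any other symbol -> 4 (scores as worst base)."""
    arr = np.full(len(sequence), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(sequence.upper().encode(), dtype="S1") == base.encode()] = idx
    return arr


def pwm_scan(
    sequence: str, pwm: PWM, score_frac: float = DEFAULT_SCORE_FRAC
) -> list[tuple[int, str, float]]:
    """Hits of a PWM in a sequence, both strands.

    Returns ``(offset, strand, score)`` tuples; a hit requires a log-odds
    score >= ``score_frac`` times the maximum achievable score.  Ambiguous
    bases (N) take the worst per-column score, so poly-N stretches never hit.
    """
    L = len(pwm)
    if len(sequence) < L:
        return []
    encoded = _encode(sequence)
    hits = []
    for strand, lo in (("+", pwm.log_odds()), ("-", pwm.reverse_complement())):
        padded = np.vstack([lo, lo.min(axis=0)])  # row 4 = worst base (for N)
        max_score = lo.max(axis=0).sum()
        threshold = score_frac * max_score
        n_offsets = len(sequence) - L + 1
        idx = np.lib.stride_tricks.sliding_window_view(encoded, L)
        scores = padded[idx, np.arange(L)].sum(axis=1)
        for off in np.flatnonzero(scores >= threshold):
            hits.append((int(off), strand, float(scores[off])))
    return sorted(hits)


def gc_content(sequence: str) -> float:
    if not sequence:
        return math.nan
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def _has_repeat(sequence: str) -> bool:
    """Lowercase letters mark repeat-masked sequence."""
    return any(c.islower() for c in sequence)


def select_background(
    pool: list[str],
    targets: list[str],
    seed: int = 0,
    gc_tol: float = 0.05,
    max_gc_tol: float = 0.25,
) -> list[str]:
    """One length- and GC-matched, repeat-free background sequence per target.

    For each target footprint a pool sequence of identical length with
    |GC - GC_target| <= ``gc_tol`` is sampled (seeded, without replacement
    within a target's candidate set being unnecessary since pools are large).
    When no candidate exists the tolerance is relaxed in +0.05 steps up to
    ``max_gc_tol``; beyond that the selection fails.
    """
    if not pool:
        raise ValueError("background pool is empty")
    rng = np.random.default_rng(seed)
    eligible = [s for s in pool if not _has_repeat(s)]
    by_len: dict[int, list[str]] = {}
    for s in eligible:
        by_len.setdefault(len(s), []).append(s)
    out = []
    for target in targets:
        cands = by_len.get(len(target), [])
        gc_t = gc_content(target)
        tol = gc_tol
        chosen = None
        while tol <= max_gc_tol + 1e-9:
            matched = [s for s in cands if abs(gc_content(s) - gc_t) <= tol]
            if matched:
                chosen = matched[int(rng.integers(len(matched)))]
                break
            tol += 0.05
        if chosen is None:
            raise ValueError(
                f"no background sequence of length {len(target)} within GC "
                f"tolerance {max_gc_tol} of target GC {gc_t:.2f}"
            )
        out.append(chosen)
    return out


def _hit_proportion(seqs: list[str], pwm: PWM, score_frac: float) -> tuple[float, bool]:
    """Fraction of sequences with >= 1 hit; zero becomes 1/(2n), flagged."""
    n = len(seqs)
    k = sum(1 for s in seqs if pwm_scan(s, pwm, score_frac))
    if k == 0:
        return 1.0 / (2 * n), True
    return k / n, False


def motif_fold_change(
    target_fp_seqs: list[str],
    target_bg_seqs: list[str],
    genomewide_fp_seqs: list[str],
    genomewide_bg_seqs: list[str],
    pwm: PWM,
    score_frac: float = DEFAULT_SCORE_FRAC,
    threshold: float = ENRICHMENT_THRESHOLD,
) -> MotifClassEnrichment:
    """Doubly-normalized motif enrichment for one PWM.

    fold_change = (prop_fp / prop_bg) / (prop_gw_fp / prop_gw_bg); a motif is
    enriched when fold_change > ``threshold`` (1.5).  Zero proportions are
    replaced by the pseudo-proportion 1/(2n) and the record flagged.
    """
    sets = (target_fp_seqs, target_bg_seqs, genomewide_fp_seqs, genomewide_bg_seqs)
    if any(len(s) == 0 for s in sets):
        raise ValueError("all four sequence sets must be non-empty")
    (p_fp, f1), (p_bg, f2), (p_gw, f3), (p_gwbg, f4) = (
        _hit_proportion(s, pwm, score_frac) for s in sets
    )
    fc = (p_fp / p_bg) / (p_gw / p_gwbg)
    return MotifClassEnrichment(
        motif_id=pwm.motif_id,
        tf_class=pwm.tf_class,
        prop_fp=p_fp,
        prop_bg=p_bg,
        prop_gw_fp=p_gw,
        prop_gw_bg=p_gwbg,
        fold_change=fc,
        enriched=fc > threshold,
        pseudo_used=f1 or f2 or f3 or f4,
    )


def collapse_by_class(
    hits_per_footprint: dict[str, list[PWM]]
) -> dict[str, int]:
    """Per footprint keep at most one hit per TF class (lowest motif_id wins),
    then count retained hits per class over footprints."""
    counts: dict[str, int] = {}
    for fp_id, pwms in hits_per_footprint.items():
        seen: dict[str, str] = {}
        for pwm in pwms:
            if not pwm.tf_class:
                raise ValueError(f"motif {pwm.motif_id} lacks a class label")
            if pwm.tf_class not in seen or pwm.motif_id < seen[pwm.tf_class]:
                seen[pwm.tf_class] = pwm.motif_id
        for cls in seen:
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def class_distribution(
    class_counts_per_set: dict[str, dict[str, int]]
) -> dict[str, dict[str, float]]:
    """Percentage of each motif class within each footprint set.

    Empty sets are omitted.  Per set, percentages sum to 100.
    """
    out = {}
    for set_name, counts in class_counts_per_set.items():
        total = sum(counts.values())
        if total == 0:
            continue
        out[set_name] = {cls: 100.0 * n / total for cls, n in counts.items()}
    return out
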