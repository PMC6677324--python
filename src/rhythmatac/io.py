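"""Readers/writers for the interval, track, annotation and matrix formats shared
by the pipeline, plus the domain containers they populate.

All internal coordinates are 0-based half-open.  Conversions happen only at
format boundaries: BED and bedGraph are natively 0-based half-open and pass
through untouched; GTF is 1-based inclusive and is converted on read/write.
Two intervals overlap iff ``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "StrandedCutTrack",
    "GeneModel",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_cut_track",
    "write_cut_track",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_fasta",
    "write_fasta",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional name/score/strand."""

    scaffold: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.scaffold:
            raise ValueError("scaffold must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


@dataclass
class StrandedCutTrack:
    """Per-scaffold dense integer vectors of Tn5 cut counts, one per strand.

    The plus/minus distinction carries the strand of the *read* whose shifted
    5' end produced the cut; footprint scoring uses the two strands separately,
    everything else sums them.
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.plus) != set(self.minus):
            raise ValueError("plus and minus tracks must cover the same scaffolds")
        for name in self.plus:
            p, m = self.plus[name], self.minus[name]
            if p.shape != m.shape:
                raise ValueError(f"strand vectors differ in length on {name}")
            if (p < 0).any() or (m < 0).any():
                raise ValueError("cut counts must be non-negative")

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(vec) for name, vec in self.plus.items()}

    def combined(self, scaffold: str) -> np.ndarray:
        return self.plus[scaffold] + self.minus[scaffold]

    def total_cuts(self) -> int:
        return int(
            sum(v.sum() for v in self.plus.values())
            + sum(v.sum() for v in self.minus.values())
        )


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TTS and exon structure.

    TSS is ``interval.start`` on the plus strand and ``interval.end - 1`` on
    the minus strand (a single base position, 0-based); TTS is the opposite end.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in "+-":
            raise ValueError(f"gene {self.gene_id} must be stranded (+/-)")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.scaffold, a.end, b.start, self.strand))
        return out


class ExpressionMatrix:
    """Genes x samples matrix of RPKM-scale expression with sample metadata.

    Sample names follow ``{genotype}_ZT{hour:02d}_{replicate}``; metadata is
    parsed from the names on construction and exposed as a DataFrame with
    columns genotype / zt / replicate.
    """

    _NAME_RE = re.compile(r"^(?P<genotype>.+)_ZT(?P<zt>\d+(?:\.\d+)?)_(?P<rep>\d+)$")

    def __init__(self, values: pd.DataFrame):
        if values.columns.duplicated().any():
            raise ValueError("sample labels must be unique")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values
        meta = []
        for col in values.columns:
            m = self._NAME_RE.match(col)
            if m is None:
                raise ValueError(
                    f"sample name {col!r} does not match '<genotype>_ZT<hour>_<rep>'"
                )
            meta.append((m["genotype"], float(m["zt"]), int(m["rep"])))
        self.samples = pd.DataFrame(
            meta, columns=["genotype", "zt", "replicate"], index=values.columns
        )

    @staticmethod
    def sample_name(genotype: str, zt: float, replicate: int) -> str:
        zt_str = f"{zt:05.2f}".rstrip("0").rstrip(".") if zt != int(zt) else f"{int(zt):02d}"
        return f"{genotype}_ZT{zt_str}_{replicate}"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.samples["zt"].unique())

    def subset_genotype(self, genotype: str) -> "ExpressionMatrix":
        cols = self.samples.index[self.samples["genotype"] == genotype]
        if len(cols) == 0:
            raise KeyError(f"no samples for genotype {genotype!r}")
        return ExpressionMatrix(self.values[cols])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)])

    def series(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (hours, values) for one gene, sample order preserved."""
        return self.samples["zt"].to_numpy(float), self.values.loc[gene_id].to_numpy(float)

    def timepoint_means(self) -> pd.DataFrame:
        """Genes x timepoints replicate-mean matrix (single genotype expected)."""
        return self.values.T.groupby(self.samples["zt"].to_numpy()).mean().T


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, sort: bool = False) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if sort:
        intervals.sort(key=lambda iv: (iv.scaffold, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF-lite (features gene/exon, 1-based inclusive, gene_id attribute)

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            scaffold, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            # GTF 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(scaffold, int(start1) - 1, int(end1), strand, gene_id)
            if feature == "gene":
                genes[gene_id] = GeneModel(gene_id, iv)
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
    out = []
    for gene_id, model in genes.items():
        for ex in exons.get(gene_id, []):
            if ex.start < model.interval.start or ex.end > model.interval.end:
                raise ValueError(f"exon {ex} outside gene {gene_id}")
        model.exons = sorted(exons.get(gene_id, []), key=lambda e: e.start)
        out.append(model)
    return out


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in models:
            iv = gm.interval
            attr = f'gene_id "{gm.gene_id}";'
            fh.write(
                f"{iv.scaffold}\trhythmatac\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr}\n"
            )
            for ex in gm.exons:
                fh.write(
                    f"{ex.scaffold}\trhythmatac\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph cut tracks


def _read_bedgraph_vector(
    path: str | Path, scaffold_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    vecs = {name: np.zeros(length, dtype=np.int64) for name, length in scaffold_lengths.items()}
    covered = {name: np.zeros(length, dtype=bool) for name, length in scaffold_lengths.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            name, start, end, value = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if name not in vecs:
                raise ValueError(f"{path}:{lineno}: unknown scaffold {name!r}")
            if not (0 <= start < end <= len(vecs[name])):
                raise ValueError(
                    f"{path}:{lineno}: record [{start},{end}) outside scaffold "
                    f"{name} of length {len(vecs[name])}"
                )
            if covered[name][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph records")
            covered[name][start:end] = True
            vecs[name][start:end] = int(float(value))
    return vecs


def read_cut_track(
    plus_path: str | Path,
    minus_path: str | Path,
    scaffold_lengths: Mapping[str, int],
) -> StrandedCutTrack:
    """Load a stranded cut track from a pair of bedGraph files.

    Positions absent from the bedGraph are zero cuts.
    """
    return StrandedCutTrack(
        plus=_read_bedgraph_vector(plus_path, scaffold_lengths),
        minus=_read_bedgraph_vector(minus_path, scaffold_lengths),
    )


def _write_bedgraph_vector(vecs: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(vecs):
            vec = vecs[name]
            # run-length encode; zero runs are omitted
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{name}\t{s}\t{e}\t{v}\n")


def write_cut_track(track: StrandedCutTrack, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.plus.bedGraph`` and ``<prefix>.minus.bedGraph``."""
    plus_path = Path(f"{prefix}.plus.bedGraph")
    minus_path = Path(f"{prefix}.minus.bedGraph")
    _write_bedgraph_vector(track.plus, plus_path)
    _write_bedgraph_vector(track.minus, minus_path)
    return plus_path, minus_path


# ---------------------------------------------------------------------------
# Expression matrix TSV (first column gene_id, header genotype_ZT<h>_<rep>)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (case preserved for repeat masking)."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
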