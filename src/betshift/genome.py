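"""Genomic coordinate model: intervals, gene annotation, promoter windows.

All coordinates are 0-based half-open (BED convention). "Upstream" and
"downstream" are always in transcription orientation: for a minus-strand
gene the core promoter (the 1 Kb 5' of the TSS) lies at higher genomic
coordinates than the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One transcript: TSS is always the transcription start, so tss > tes
    on the minus strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str = "coding"

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.transcript_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"{self.transcript_id}: - strand requires tes < tss")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models and auxiliary interval sets
    (blacklist, enhancers, H3K27ac domains)."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    blacklist: list[Interval] = field(default_factory=list)
    enhancers: list[Interval] = field(default_factory=list)
    h3k27ac: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.transcript_id} on unknown chromosome {g.chrom}")
        for name in ("blacklist", "enhancers", "h3k27ac"):
            for iv in getattr(self, name):
                if iv.chrom not in self.chrom_sizes:
                    raise ValueError(f"{name} interval on unknown chromosome {iv.chrom}")

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def dedupe_tss(self) -> "GenomeAnnotation":
        """Collapse transcripts identical in (chrom, strand, tss), keeping the
        lexicographically smallest transcript_id."""
        best: dict[tuple, GeneModel] = {}
        for g in sorted(self.genes, key=lambda g: g.transcript_id):
            best.setdefault((g.chrom, g.strand, g.tss), g)
        return GenomeAnnotation(
            chrom_sizes=self.chrom_sizes,
            genes=sorted(best.values(), key=lambda g: (g.chrom, g.tss)),
            blacklist=self.blacklist,
            enhancers=self.enhancers,
            h3k27ac=self.h3k27ac,
        )


@dataclass(frozen=True)
class PromoterWindows:
    """The two flanking 1 Kb windows of a TSS: the core promoter upstream of
    the start site and the Pol II pause site downstream, both in
    transcription orientation. They abut at the TSS."""

    transcript_id: str
    core_promoter: Interval
    pause_site: Interval

    def __post_init__(self):
        if self.core_promoter.overlaps(self.pause_site):
            raise ValueError(f"{self.transcript_id}: windows overlap")


def tss_windows(annotation: GenomeAnnotation, flank: int = 1000) -> list[PromoterWindows]:
    """Build core-promoter (upstream) and pause-site (downstream) windows of
    ``flank`` bp around every TSS, clipped to chromosome bounds.

    Genes on unknown chromosomes are skipped with a warning; a window fully
    clipped away (TSS at the chromosome edge) drops the record.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    out: list[PromoterWindows] = []
    for g in annotation.genes:
        clen = annotation.chrom_sizes.get(g.chrom)
        if clen is None:
            logger.warning("skipping %s: unknown chromosome %s", g.transcript_id, g.chrom)
            continue
        if g.strand == "+":
            core = (g.tss - flank, g.tss)
            pause = (g.tss, g.tss + flank)
        else:
            core = (g.tss, g.tss + flank)
            pause = (g.tss - flank, g.tss)
        core = (max(0, core[0]), min(clen, core[1]))
        pause = (max(0, pause[0]), min(clen, pause[1]))
        if core[0] >= core[1] or pause[0] >= pause[1]:
            logger.warning("skipping %s: window fully outside chromosome", g.transcript_id)
            continue
        out.append(
            PromoterWindows(
                transcript_id=g.transcript_id,
                core_promoter=Interval(g.chrom, *core, g.strand),
                pause_site=Interval(g.chrom, *pause, g.strand),
            )
        )
    return out


def _overlaps_any(iv: Interval, others: Sequence[Interval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def filter_intergenic_enhancers(
    enhancers: Sequence[Interval],
    annotation: GenomeAnnotation,
    flank: int = 1000,
) -> list[Interval]:
    """Keep only enhancers with zero overlap (>= 1 shared base counts) with
    any TSS +/- ``flank`` window. Order is preserved."""
    windows = tss_windows(annotation, flank=flank)
    flat = [w.core_promoter for w in windows] + [w.pause_site for w in windows]
    by_chrom: dict[str, list[Interval]] = {}
    for w in flat:
        by_chrom.setdefault(w.chrom, []).append(w)
    kept = []
    for e in enhancers:
        if not _overlaps_any(e, by_chrom.get(e.chrom, ())):
            kept.append(e)
    return kept


PEAK_CATEGORY_TSS = "TSS±1Kb"
PEAK_CATEGORY_H3K27AC = "H3K27ac-non-TSS"
PEAK_CATEGORY_OTHER = "other"


def categorize_peaks(
    peaks: Sequence[Interval],
    annotation: GenomeAnnotation,
    flank: int = 1000,
) -> list[str]:
    """Assign each peak one category with priority TSS > H3K27ac > other.

    A peak counts as TSS-proximal when it shares >= 1 base with any
    TSS +/- flank window, else H3K27ac-marked when it overlaps an H3K27ac
    domain, else "other".
    """
    windows = tss_windows(annotation, flank=flank)
    tss_by_chrom: dict[str, list[Interval]] = {}
    for w in windows:
        tss_by_chrom.setdefault(w.core_promoter.chrom, []).extend(
            [w.core_promoter, w.pause_site]
        )
    ac_by_chrom: dict[str, list[Interval]] = {}
    for iv in annotation.h3k27ac:
        ac_by_chrom.setdefault(iv.chrom, []).append(iv)
    cats = []
    for p in peaks:
        if _overlaps_any(p, tss_by_chrom.get(p.chrom, ())):
            cats.append(PEAK_CATEGORY_TSS)
        elif _overlaps_any(p, ac_by_chrom.get(p.chrom, ())):
            cats.append(PEAK_CATEGORY_H3K27AC)
        else:
            cats.append(PEAK_CATEGORY_OTHER)
    return cats


# ---------------------------------------------------------------------------
# I/O: BED3/BED6, gene table TSV, chrom.sizes


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 into Intervals (columns beyond 6 ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path, names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """Write BED6 (name/score columns filled with '.'/0 when absent)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


GENE_TABLE_COLUMNS = ["gene_id", "transcript_id", "chrom", "strand", "tss", "tes", "biotype"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id), transcript_id=str(r.transcript_id),
            chrom=str(r.chrom), strand=str(r.strand),
            tss=int(r.tss), tes=int(r.tes), biotype=str(r.biotype),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.transcript_id, g.chrom, g.strand, g.tss, g.tes, g.biotype) for g in genes],
        columns=GENE_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
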