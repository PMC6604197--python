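"""Fragment coverage tracks, 1x (RPGC) normalization, input subtraction,
and strand-oriented TSS metaprofiles.

A CoverageTrack stores, per chromosome, one value per fixed-width bin.
A bin's value is the mean per-base fragment coverage within the bin, so
the genome-wide mean of an RPGC-normalized track is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

NORMALIZATIONS = ("raw", "RPGC", "RPGC-minus-input")


@dataclass
class CoverageTrack:
    bin_size: int
    values: dict  # chrom -> np.ndarray of per-bin values
    normalization: str = "raw"
    effective_genome_size: int | None = None
    n_fragments: int = 0
    extension: int = 0

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def chrom_sizes(self) -> dict:
        # upper bound: length inferred from bin count (exact when chromosome
        # length is a bin multiple, which the constructors guarantee to ceil)
        return {c: len(v) * self.bin_size for c, v in self.values.items()}

    def mean(self) -> float:
        """Genome-wide mean per-base coverage (bins weighted equally; all
        bins have bin_size bases by construction, the last bin of a
        chromosome padded conceptually with zero coverage)."""
        tot = sum(float(v.sum()) for v in self.values.values())
        nbins = sum(len(v) for v in self.values.values())
        return tot / nbins

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )


def extend_and_bin(fragments, chrom_sizes: dict, bin_size: int = 50,
                   extension: int = 300) -> CoverageTrack:
    """Extend each fragment to ``extension`` bases from its 5' end (strand
    aware; unstranded fragments extend from their left end) and accumulate
    per-bin mean per-base coverage.

    ``fragments`` is a FragmentSet or any iterable of Intervals.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if extension <= 0:
        raise ValueError("extension must be positive")
    frags = getattr(fragments, "fragments", fragments)
    nbins = {c: -(-size // bin_size) for c, size in chrom_sizes.items()}
    # accumulate on a per-base difference array, then box-sum into bins
    diffs = {c: np.zeros(size + 1, dtype=np.float64) for c, size in chrom_sizes.items()}
    n = 0
    for f in frags:
        size = chrom_sizes[f.chrom]
        if f.strand == "-":
            end = f.end
            start = max(0, end - extension)
        else:
            start = f.start
            end = min(size, start + extension)
        start = min(start, size)
        end = min(end, size)
        if end <= start:
            continue
        d = diffs[f.chrom]
        d[start] += 1.0
        d[end] -= 1.0
        n += 1
    values = {}
    for c, d in diffs.items():
        per_base = np.cumsum(d[:-1])
        pad = nbins[c] * bin_size - len(per_base)
        if pad:
            per_base = np.concatenate([per_base, np.zeros(pad)])
        values[c] = per_base.reshape(nbins[c], bin_size).mean(axis=1)
    return CoverageTrack(bin_size=bin_size, values=values, normalization="raw",
                         effective_genome_size=sum(chrom_sizes.values()),
                         n_fragments=n, extension=extension)


def rpgc_normalize(track: CoverageTrack, effective_genome_size: int | None = None) -> CoverageTrack:
    """Scale a raw track so mean per-base coverage over the effective genome
    is 1 ("reads per genomic content", the 1x normalization): scale =
    effective_genome_size / (n_fragments * extension)."""
    if track.normalization != "raw":
        raise ValueError("rpgc_normalize expects a raw track")
    egs = effective_genome_size or track.effective_genome_size
    if not egs:
        raise ValueError("effective genome size required")
    denom = track.n_fragments * track.extension
    if denom == 0:
        raise ValueError("cannot RPGC-normalize an empty track")
    scale = egs / denom
    return CoverageTrack(
        bin_size=track.bin_size,
        values={c: v * scale for c, v in track.values.items()},
        normalization="RPGC", effective_genome_size=egs,
        n_fragments=track.n_fragments, extension=track.extension,
    )


def subtract_input(treatment: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Element-wise treatment - input on matching bin grids. Negative values
    are preserved (downstream fragment counting never uses subtracted
    tracks, so no clamping is needed)."""
    if not treatment.same_grid(control):
        raise ValueError("bin grids differ between treatment and input")
    return CoverageTrack(
        bin_size=treatment.bin_size,
        values={c: treatment.values[c] - control.values[c] for c in treatment.values},
        normalization="RPGC-minus-input",
        effective_genome_size=treatment.effective_genome_size,
        n_fragments=treatment.n_fragments, extension=treatment.extension,
    )


@dataclass
class MetaProfile:
    """Mean signal by offset from a set of anchors, strand-oriented so that
    positive offsets are downstream of transcription. Offsets are bin left
    edges relative to the anchor."""

    offsets: np.ndarray
    signal: np.ndarray
    n_anchors: int
    n_dropped: int = 0
    bin_size: int = 50


def metaprofile(track: CoverageTrack, anchors: Sequence[tuple], flank: int = 4000) -> MetaProfile:
    """Average the track around anchors (chrom, position, strand).

    Offsets are anchor-relative bins of the track's bin size; each offset
    bin is sampled at the genomic bin containing its midpoint, so
    minus-strand anchors (whose downstream lies at lower coordinates) are
    mirrored without a half-bin phase bias. Anchors whose window leaves the
    chromosome are dropped and counted.
    """
    b = track.bin_size
    halfn = flank // b
    # midpoints of anchor-relative offset bins [-flank, flank)
    mids = (np.arange(-halfn, halfn) * b + b / 2.0)
    used = 0
    dropped = 0
    acc = np.zeros(2 * halfn, dtype=np.float64)
    for chrom, pos, strand in anchors:
        vals = track.values.get(chrom)
        if vals is None:
            dropped += 1
            continue
        sign = -1.0 if strand == "-" else 1.0
        gpos = pos + sign * mids
        gbin = np.floor(gpos / b).astype(int)
        if gbin.min() < 0 or gbin.max() >= len(vals):
            dropped += 1
            continue
        acc += vals[gbin]
        used += 1
    if used == 0:
        raise ValueError("no usable anchors within chromosome bounds")
    offsets = (np.arange(-halfn, halfn) * b).astype(int)
    return MetaProfile(offsets=offsets, signal=acc / used, n_anchors=used,
                       n_dropped=dropped, bin_size=b)


def profile_modes(profile: MetaProfile, smooth_bins: int = 3):
    """Locate the upstream (< -1 bin) and downstream (> +1 bin) signal modes
    after moving-average smoothing.

    Returns (upstream_mode_offset, downstream_mode_offset, height_ratio)
    where height_ratio = downstream/upstream mode height, or None with a
    unimodal flag when no interior maximum exists on one side.
    """
    if not np.all(np.isfinite(profile.signal)):
        raise ValueError("profile contains non-finite values")
    sig = profile.signal
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        sig = np.convolve(sig, kernel, mode="same")
    b = profile.bin_size
    up_mask = profile.offsets < -b
    down_mask = profile.offsets > b

    def interior_max(mask):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        best = idx[np.argmax(sig[idx])]
        # a real mode is a strict local maximum away from the window edge
        # (monotone or flat flanks carry no interior maximum)
        if best < smooth_bins or best >= len(sig) - smooth_bins:
            return None
        if not (sig[best] > sig[best - 1] or sig[best] > sig[best + 1]):
            return None
        return best

    iu, id_ = interior_max(up_mask), interior_max(down_mask)
    if iu is None or id_ is None:
        return {"unimodal": True, "upstream": None, "downstream": None, "ratio": None}
    ratio = float(sig[id_] / sig[iu]) if sig[iu] != 0 else np.inf
    return {
        "unimodal": False,
        "upstream": int(profile.offsets[iu]),
        "downstream": int(profile.offsets[id_]),
        "ratio": ratio,
    }


# ---------------------------------------------------------------------------
# bedGraph I/O (fixed-step bins)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            b = track.bin_size
            for i, v in enumerate(vals):
                if v != 0:
                    fh.write(f"{chrom}\t{i * b}\t{(i + 1) * b}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: dict, bin_size: int,
                  normalization: str = "raw") -> CoverageTrack:
    """Read a bedGraph whose intervals align to a fixed bin grid."""
    values = {c: np.zeros(-(-s // bin_size)) for c, s in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for r in df.itertuples():
        if r.start % bin_size or (r.end - r.start) % bin_size:
            raise ValueError(f"bedGraph interval {r.chrom}:{r.start}-{r.end} not on the {bin_size} bp grid")
        values[r.chrom][r.start // bin_size:r.end // bin_size] = r.value
    return CoverageTrack(bin_size=bin_size, values=values, normalization=normalization,
                         effective_genome_size=sum(chrom_sizes.values()))


def export_metaprofile(profile: MetaProfile, path: str | Path) -> None:
    pd.DataFrame({"offset": profile.offsets, "signal": profile.signal}).to_csv(
        path, sep="\t", index=False)
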