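"""Broad-domain peak calling and pseudo-replicate consensus.

The caller is a transparent Poisson bin scan: treatment fragment counts per
bin are tested against a local background rate estimated from the input
(the maximum of the genome-wide rate and a 10 kb local window, scaled to
treatment depth), significant bins are merged across gaps up to
``max_gap``, and each peak is scored by its best bin. Confidence comes not
from the caller but from the consensus rule: a peak called on the merged
replicates is kept only if it is also recovered in both random
equal-split pseudo-replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import Interval
from .simulate import FragmentSet


@dataclass(frozen=True)
class Peak:
    interval: Interval
    score: float          # -log10 p of the best bin
    fold: float           # mean fold-over-background across the peak

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end


def split_pseudoreplicates(merged: FragmentSet, seed: int) -> tuple[FragmentSet, FragmentSet]:
    """Randomly partition the merged fragments into two equal halves
    (sizes differ by at most one; the larger half comes first)."""
    n = len(merged.fragments)
    if n < 2:
        raise ValueError("need at least 2 fragments to split")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    perm = rng.permutation(n)
    n1 = -(-n // 2)  # ceil: larger half first
    idx1, idx2 = np.sort(perm[:n1]), np.sort(perm[n1:])
    mk = lambda idx: FragmentSet(
        model=merged.model, track=merged.track, dose=merged.dose,
        replicate=merged.replicate, is_input=merged.is_input,
        fragments=[merged.fragments[i] for i in idx],
    )
    return mk(idx1), mk(idx2)


def _bin_counts(fragments, chrom_sizes: dict, bin_size: int, extension: int) -> dict:
    """Integer per-bin counts of extended fragments overlapping each bin."""
    frags = getattr(fragments, "fragments", fragments)
    counts = {c: np.zeros(-(-s // bin_size), dtype=np.int64) for c, s in chrom_sizes.items()}
    for f in frags:
        size = chrom_sizes[f.chrom]
        if f.strand == "-":
            end = f.end
            start = max(0, end - extension)
        else:
            start = f.start
            end = min(size, start + extension)
        if end <= start:
            continue
        b0 = start // bin_size
        b1 = -(-end // bin_size)
        arr = counts[f.chrom]
        arr[b0:min(b1, len(arr))] += 1
    return counts


def call_broad_peaks(treatment, control, chrom_sizes: dict,
                     p_cutoff: float = 1e-3, bin_size: int = 50,
                     extension: int = 300, max_gap: int = 500,
                     local_window: int = 10_000) -> list[Peak]:
    """Poisson bin-scan broad peak calling.

    Per bin, the treatment count is tested (upper tail) against
    lambda_local = max(genome-wide control rate, local 10 kb control rate),
    with the control scaled to treatment depth. Bins at p <= p_cutoff are
    merged when separated by <= max_gap bp. With an empty control, the
    genome-wide treatment rate is the background (with a warning).
    """
    import logging

    t_counts = _bin_counts(treatment, chrom_sizes, bin_size, extension)
    n_treat = sum(int(v.sum()) for v in t_counts.values())
    if n_treat == 0:
        raise ValueError("treatment sample is empty")
    c_frags = getattr(control, "fragments", control) if control is not None else []
    if control is None or len(c_frags) == 0:
        logging.getLogger(__name__).warning(
            "empty control: falling back to genome-wide treatment background")
        c_counts = t_counts
        scale = 1.0
    else:
        c_counts = _bin_counts(control, chrom_sizes, bin_size, extension)
        n_ctrl = sum(int(v.sum()) for v in c_counts.values())
        scale = n_treat / n_ctrl
    nbins_total = sum(len(v) for v in t_counts.values())
    genome_rate = scale * sum(int(v.sum()) for v in c_counts.values()) / nbins_total

    w = max(1, local_window // bin_size)
    kernel = np.ones(w)
    peaks: list[Peak] = []
    for chrom in t_counts:
        tc = t_counts[chrom]
        cc = c_counts[chrom].astype(np.float64)
        # centered moving-average local control rate over ~local_window
        local = np.convolve(cc, kernel, mode="same") / np.minimum(
            np.convolve(np.ones_like(cc), kernel, mode="same"), w)
        lam = np.maximum(genome_rate, scale * local)
        pvals = stats.poisson.sf(tc - 1, lam)  # P(X >= observed)
        sig = np.flatnonzero(pvals <= p_cutoff)
        if sig.size == 0:
            continue
        gap_bins = max_gap // bin_size
        runs = []
        run_start = prev = sig[0]
        for i in sig[1:]:
            if i - prev <= gap_bins + 1:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        clen = chrom_sizes[chrom]
        for b0, b1 in runs:
            start = b0 * bin_size
            end = min((b1 + 1) * bin_size, clen)
            region = slice(b0, b1 + 1)
            best_p = max(pvals[region].min(), 1e-300)
            fold = float(np.mean(tc[region] / np.maximum(lam[region], 1e-12)))
            peaks.append(Peak(Interval(chrom, start, end), -np.log10(best_p), fold))
    return peaks


def _any_overlap(peak: Peak, others: Sequence[Peak]) -> bool:
    return any(
        o.chrom == peak.chrom and o.start < peak.end and peak.start < o.end
        for o in others
    )


def consensus_peaks(merged_peaks: Sequence[Peak], pr1_peaks: Sequence[Peak],
                    pr2_peaks: Sequence[Peak]) -> list[Peak]:
    """Keep merged-set peaks overlapping (>= 1 bp) at least one peak in EACH
    pseudo-replicate set; coordinates and scores come from the merged set."""
    by_chrom1: dict[str, list] = {}
    for p in pr1_peaks:
        by_chrom1.setdefault(p.chrom, []).append(p)
    by_chrom2: dict[str, list] = {}
    for p in pr2_peaks:
        by_chrom2.setdefault(p.chrom, []).append(p)
    return [
        p for p in merged_peaks
        if _any_overlap(p, by_chrom1.get(p.chrom, ()))
        and _any_overlap(p, by_chrom2.get(p.chrom, ()))
    ]


def remove_blacklisted(peaks: Sequence[Peak], blacklist: Sequence[Interval]) -> list[Peak]:
    """Drop peaks sharing >= 1 bp with any blacklist interval."""
    bl: dict[str, list] = {}
    for iv in blacklist:
        bl.setdefault(iv.chrom, []).append(iv)
    kept = [
        p for p in peaks
        if not any(iv.start < p.end and p.start < iv.end for iv in bl.get(p.chrom, ()))
    ]
    for p in kept:  # post-condition: no residual overlap
        assert not any(iv.start < p.end and p.start < iv.end for iv in bl.get(p.chrom, ()))
    return kept


def consensus_pipeline(rep1: FragmentSet, rep2: FragmentSet, control,
                       chrom_sizes: dict, blacklist: Sequence[Interval] = (),
                       seed: int = 0, **caller_kwargs) -> list[Peak]:
    """Full consensus procedure for one condition: merge the two replicates,
    call peaks on the merged set and on two random equal pseudo-replicate
    splits, keep merged peaks recovered in both splits, then blacklist-filter."""
    merged = FragmentSet(
        model=rep1.model, track=rep1.track, dose=rep1.dose, replicate=0,
        is_input=False, fragments=list(rep1.fragments) + list(rep2.fragments),
    )
    pr1, pr2 = split_pseudoreplicates(merged, seed=seed)
    call = lambda s: call_broad_peaks(s, control, chrom_sizes, **caller_kwargs)
    cons = consensus_peaks(call(merged), call(pr1), call(pr2))
    return remove_blacklisted(cons, blacklist)


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6+ export: name, score = -log10 p, strand '.', fold in column 7."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.score:.4g}\t.\t{p.fold:.4g}\n"
            )
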