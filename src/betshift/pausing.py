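"""RNA Pol II pausing: traveling ratio and treatment-induced TR shifts.

The traveling ratio (pausing index) of a gene is the mean Pol II read
density over the promoter region, -100 bp to +300 bp around the TSS in
transcription orientation (401 bases, mapped to the half-open interval
[TSS-100, TSS+301) on the plus strand), divided by the mean density over
the gene body (+301 bp to the transcript end). A high ratio means
polymerase piles up at the promoter instead of elongating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coverage import CoverageTrack
from .genome import GeneModel


@dataclass
class TRRecord:
    gene_id: str
    condition: str
    promoter_density: float
    body_density: float
    tr: float | None
    valid: bool
    reason: str = ""


def _region_mean(track: CoverageTrack, chrom: str, start: int, end: int) -> float | None:
    """Exact per-base mean of the track's piecewise-constant function over
    [start, end): bins are weighted by their overlap with the region."""
    vals = track.values.get(chrom)
    if vals is None:
        return None
    b = track.bin_size
    clen = len(vals) * b
    if start < 0 or end > clen or end <= start:
        return None
    b0, b1 = start // b, -(-end // b)
    total = 0.0
    for i in range(b0, b1):
        lo = max(start, i * b)
        hi = min(end, (i + 1) * b)
        total += vals[i] * (hi - lo)
    return total / (end - start)


def promoter_body_regions(gene: GeneModel, promoter_up: int = 100,
                          promoter_down: int = 300) -> tuple:
    """Half-open genomic (promoter, body) regions in transcription
    orientation. Promoter covers -promoter_up..+promoter_down inclusive
    (401 bp at defaults); body runs from +301 to the transcript end."""
    if gene.strand == "+":
        promoter = (gene.tss - promoter_up, gene.tss + promoter_down + 1)
        body = (gene.tss + promoter_down + 1, gene.tes)
    else:
        promoter = (gene.tss - promoter_down, gene.tss + promoter_up + 1)
        body = (gene.tes, gene.tss - promoter_down)
    return promoter, body


def traveling_ratio(track: CoverageTrack, gene: GeneModel, condition: str = "",
                    min_body: int = 200) -> TRRecord:
    """Promoter/body density ratio for one gene.

    Invalid (rather than infinite) when the body is shorter than
    ``min_body`` bp, lies outside the chromosome, or has zero density.
    """
    promoter, body = promoter_body_regions(gene)
    if body[1] - body[0] < min_body:
        return TRRecord(gene.gene_id, condition, np.nan, np.nan, None, False, "short_body")
    pd_ = _region_mean(track, gene.chrom, *promoter)
    bd = _region_mean(track, gene.chrom, *body)
    if pd_ is None or bd is None:
        return TRRecord(gene.gene_id, condition, np.nan, np.nan, None, False, "out_of_bounds")
    if bd <= 0:
        return TRRecord(gene.gene_id, condition, pd_, bd, None, False, "zero_body")
    return TRRecord(gene.gene_id, condition, pd_, bd, pd_ / bd, True)


def tr_shift(vehicle: TRRecord, treated: TRRecord, gain_threshold: float = 2.0,
             gain_mode: str = "fold") -> tuple:
    """(fold change, gained flag) between two valid TR records.

    ``gain_mode='fold'`` (default): gained iff TR_treated/TR_vehicle >
    threshold. ``gain_mode='absolute'``: gained iff TR_treated > threshold.
    """
    if not (vehicle.valid and treated.valid):
        raise ValueError("tr_shift requires two valid TR records")
    fold = treated.tr / vehicle.tr
    if gain_mode == "fold":
        gained = fold > gain_threshold
    elif gain_mode == "absolute":
        gained = treated.tr > gain_threshold
    else:
        raise ValueError(f"unknown gain_mode {gain_mode!r}")
    return fold, gained


def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    correction: bool = True) -> float:
    """Two-sided test of equal proportions k1/n1 vs k2/n2.

    Chi-square with Yates continuity correction by default (the corrected
    statistic is floored at 0, so identical proportions give p = 1);
    ``correction=False`` gives the plain two-sample z/chi-square test.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group totals must be positive")
        if not 0 <= k <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table[:, 1].sum() == 0 or table[:, 0].sum() == 0:
        return 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.pvalue)


def gained_fraction_by_group(tr_fold: dict, groups: dict,
                             gain_threshold: float = 2.0) -> dict:
    """Per-group (n_gained, n_total) from gene -> TR fold change and
    gene -> group maps."""
    out: dict[str, list] = {}
    for gene, fold in tr_fold.items():
        g = groups.get(gene)
        if g is None:
            continue
        k, n = out.setdefault(g, [0, 0])
        out[g] = [k + (fold > gain_threshold), n + 1]
    return {g: tuple(v) for g, v in out.items()}
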