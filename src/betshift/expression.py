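"""Expression integration: NB differential expression, binding/expression
overlap, cluster-wise paired comparisons, and pre-ranked gene-set
enrichment.

Differential expression reuses the NB Wald machinery of the binding module
and applies the dual significance threshold (BH-adjusted p < 0.05 and
|log2 fold change| > 1). The pre-ranked GSEA is a from-scratch running-sum
implementation with a gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffbind import nb_wald_test, size_factors


def differential_expression(counts: pd.DataFrame, treated_cols: Sequence[str],
                            vehicle_cols: Sequence[str], fdr: float = 0.05,
                            lfc_threshold: float = 1.0,
                            min_count: float = 10.0) -> pd.DataFrame:
    """NB Wald differential expression with the dual significance rule:
    significant iff adjusted p < fdr AND |LFC| > lfc_threshold."""
    res = nb_wald_test(counts, treated_cols, vehicle_cols, min_count=min_count)
    res["significant"] = (res["padj"] < fdr) & (res["lfc"].abs() > lfc_threshold)
    return res


def db_de_overlap(affected_genes: set, de: pd.DataFrame,
                  direction: str = "down", transcript_to_gene=None) -> tuple:
    """Overlap between differentially bound and differentially expressed
    genes.

    Returns (n_overlap, n_de, percentage of DE genes that are also
    differentially bound). ``direction`` restricts DE genes to
    down- or up-regulated significant calls.
    """
    if transcript_to_gene is not None:
        affected_genes = {transcript_to_gene.get(t, t) for t in affected_genes}
    sig = de["significant"].fillna(False).astype(bool)
    if direction == "down":
        sig &= de["lfc"] < 0
    elif direction == "up":
        sig &= de["lfc"] > 0
    elif direction != "any":
        raise ValueError(f"unknown direction {direction!r}")
    de_genes = set(de.index[sig])
    n_de = len(de_genes)
    n_overlap = len(de_genes & set(affected_genes))
    pct = 100.0 * n_overlap / n_de if n_de else 0.0
    return n_overlap, n_de, pct


def cluster_expression_compare(labels: pd.Series, de_a: pd.DataFrame,
                               de_b: pd.DataFrame, min_pairs: int = 6,
                               alternative: str = "two-sided",
                               transcript_to_gene=None) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparison of per-gene LFCs between two
    models, per cluster.

    Genes in each cluster are matched across the two DE tables; zero
    differences are handled with the Pratt method. Clusters with fewer than
    ``min_pairs`` shared genes, or with all-zero differences, are flagged
    untested.
    """
    if transcript_to_gene is not None:
        labels = labels.rename(index=transcript_to_gene)
        labels = labels[~labels.index.duplicated()]
    rows = []
    for cluster in sorted(labels.unique()):
        genes = labels.index[labels == cluster]
        shared = [g for g in genes if g in de_a.index and g in de_b.index]
        la = de_a.loc[shared, "lfc"].to_numpy(dtype=float)
        lb = de_b.loc[shared, "lfc"].to_numpy(dtype=float)
        ok = np.isfinite(la) & np.isfinite(lb)
        la, lb = la[ok], lb[ok]
        row = {"cluster": cluster, "n_pairs": int(ok.sum()),
               "median_lfc_a": float(np.median(la)) if ok.sum() else np.nan,
               "median_lfc_b": float(np.median(lb)) if ok.sum() else np.nan}
        diffs = la - lb
        if ok.sum() < min_pairs or np.all(diffs == 0):
            row.update(pvalue=np.nan, tested=False)
        else:
            res = stats.wilcoxon(la, lb, zero_method="pratt", alternative=alternative)
            row.update(pvalue=float(res.pvalue), tested=True)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Pre-ranked GSEA


@dataclass
class GSEAResult:
    name: str
    size: int
    es: float
    nes: float
    pvalue: float
    fdr: float

    @property
    def significant(self) -> bool:
        return abs(self.nes) > 1.0 and self.fdr < 0.10


def enrichment_score(metric: np.ndarray, hits: np.ndarray, weight: float = 1.0) -> float:
    """Running-sum enrichment score of a gene set on a ranked list.

    ``metric`` is the ranking metric sorted descending; ``hits`` a boolean
    mask of set membership. Hit steps are |metric|^weight normalized to the
    set total; miss steps are 1/(N - n). ES is the maximum deviation from
    zero (signed, ties to the positive side).
    """
    n_hits = int(hits.sum())
    n = len(metric)
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    w = np.abs(metric) ** weight
    hit_total = w[hits].sum()
    if hit_total == 0:
        # all member metrics are exactly zero: fall back to equal steps
        steps = np.where(hits, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        steps = np.where(hits, w / hit_total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    # float accumulation can overshoot the exact bound by ~1 ulp
    return float(np.clip(running[i], -1.0, 1.0))


def gsea_preranked(ranking: pd.Series, gene_sets: dict, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0, min_size: int = 5,
                   max_size: int = 500) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene -> metric series.

    The null is a gene-label permutation: for each set size the members are
    redrawn uniformly ``n_perm`` times. NES = ES / mean(|ES*|) over
    sign-matched permutation scores; p is the sign-matched permutation
    fraction; the FDR q mirrors the standard pooled-NES procedure.
    Sets with no usable members are skipped with a warning.
    """
    import logging

    ranking = ranking[np.isfinite(ranking)]
    order = np.lexsort((ranking.index.astype(str), -ranking.to_numpy()))
    metric = ranking.to_numpy()[order]
    genes = ranking.index.to_numpy()[order]
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)

    rows = []
    perm_nes_all = []
    for name, members in gene_sets.items():
        idx = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}), dtype=int)
        if not (min_size <= len(idx) <= max_size) or len(idx) == n:
            if len(idx) == 0:
                logging.getLogger(__name__).warning("gene set %s has no ranked members; skipped", name)
            continue
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        es = enrichment_score(metric, hits, weight)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            ph = np.zeros(n, dtype=bool)
            ph[rng.choice(n, size=len(idx), replace=False)] = True
            perm_es[b] = enrichment_score(metric, ph, weight)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(perm_es).mean()
        nes = es / denom if denom > 0 else 0.0
        pval = ((np.abs(same_sign) >= abs(es)).sum() + 1) / (len(same_sign) + 1)
        pos = perm_es >= 0
        pos_mean = perm_es[pos].mean() if pos.any() else 1.0
        neg_mean = np.abs(perm_es[~pos]).mean() if (~pos).any() else 1.0
        perm_nes = np.where(pos, perm_es / max(pos_mean, 1e-12),
                            perm_es / max(neg_mean, 1e-12))
        perm_nes_all.append(perm_nes)
        rows.append({"name": name, "size": len(idx), "es": es, "nes": nes, "pvalue": pval})
    if not rows:
        return pd.DataFrame(columns=["name", "size", "es", "nes", "pvalue", "fdr", "significant"]).set_index("name")

    df = pd.DataFrame(rows).set_index("name")
    pool = np.concatenate(perm_nes_all)
    # pooled-null FDR: fraction of null |NES*| >= |NES| over fraction of
    # observed |NES| >= |NES|, clipped to [0, 1]
    obs = df["nes"].to_numpy()
    fdrs = []
    for nes in obs:
        null_frac = (np.abs(pool) >= abs(nes)).mean()
        obs_frac = max((np.abs(obs) >= abs(nes)).mean(), 1.0 / len(obs))
        fdrs.append(min(1.0, null_frac / obs_frac))
    df["fdr"] = fdrs
    df["significant"] = (df["nes"].abs() > 1.0) & (df["fdr"] < 0.10)
    return df


def read_gmt(path: str | Path) -> dict:
    """Read gene sets from GMT (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(filter(None, parts[2:]))
    return sets


def write_gmt(gene_sets: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
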