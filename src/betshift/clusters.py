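"""Sensitivity clustering of affected TSSs.

Each TSS affected in at least one window x dose contrast gets a 6-column
signature: the log2 fold changes at (50, 500, 5000 nM) x (core promoter,
pause site). K-means with k=4 (default; Ward-linkage hierarchical
clustering available as an alternative) partitions the signatures, and the
clusters are then named by their 5000 nM centroid geometry:

* strongly negative pause-site LFC with near-zero core LFC ->
  "highly-sensitive-pause"
* strongly negative core LFC with near-zero pause LFC ->
  "highly-sensitive-core"
* of the remaining two, the deeper combined displacement ->
  "highly-sensitive-both", the shallower -> "sensitive-both".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .simulate import (
    CLASS_HIGHLY_BOTH,
    CLASS_HIGHLY_CORE,
    CLASS_HIGHLY_PAUSE,
    CLASS_SENSITIVE_BOTH,
)

SIGNATURE_DOSES = (50.0, 500.0, 5000.0)
CLUSTER_LABELS = (
    CLASS_SENSITIVE_BOTH, CLASS_HIGHLY_BOTH, CLASS_HIGHLY_PAUSE, CLASS_HIGHLY_CORE,
)


def build_lfc_matrix(results: dict, fdr: float = 0.05,
                     two_sided: bool = False) -> pd.DataFrame:
    """6-column LFC signature for every TSS affected at any window x dose.

    ``results`` maps dose -> per-(transcript, window) test table. Untested
    LFCs are imputed as 0 and flagged in a parallel ``*_imputed`` column
    block (kept out of the clustering columns).
    """
    affected = set()
    for dose, df in results.items():
        sig = (df["padj"] < fdr)
        if not two_sided:
            sig &= df["lfc"] < 0
        affected.update(df.index.get_level_values("transcript_id")[sig])
    affected = sorted(affected)
    cols, imp_cols = {}, {}
    for dose in SIGNATURE_DOSES:
        df = results[dose]
        for window in ("core", "pause"):
            name = f"lfc_{dose:g}_{window}"
            sub = df.xs(window, level="window")
            lfc = sub["lfc"].reindex(affected)
            tested = sub["tested"].reindex(affected).fillna(False).astype(bool)
            lfc = lfc.where(tested, 0.0).fillna(0.0)
            cols[name] = lfc
            imp_cols[name + "_imputed"] = ~tested
    out = pd.DataFrame({**cols, **imp_cols}, index=pd.Index(affected, name="transcript_id"))
    return out


def signature_columns(matrix: pd.DataFrame) -> list:
    return [c for c in matrix.columns if c.startswith("lfc_") and not c.endswith("_imputed")]


@dataclass
class ClusterAssignment:
    assignments: pd.Series           # transcript_id -> cluster index (0..k-1)
    centroids: pd.DataFrame          # cluster index -> signature centroid
    labels: dict | None = None       # cluster index -> canonical label

    def labeled(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("clusters not yet named")
        return self.assignments.map(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.assignments})
        if self.labels is not None:
            df["label"] = self.labeled()
        return df


def cluster_tss(matrix: pd.DataFrame, k: int = 4, seed: int = 0,
                n_restarts: int = 25, method: str = "kmeans") -> ClusterAssignment:
    """Cluster the LFC signatures into k groups.

    ``method='kmeans'`` (default): best of ``n_restarts`` k-means runs by
    within-cluster sum of squares, seeded. ``method='ward'``: Ward-linkage
    hierarchical clustering cut at k. Signatures are clustered on raw LFCs
    (no row scaling): the distinction between moderately and highly
    sensitive promoters lives in the signed magnitudes.
    """
    X = matrix[signature_columns(matrix)].to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows to cluster, got {len(X)}")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed & 0x7FFFFFFF)
        idx = km.fit_predict(X)
        centroids = km.cluster_centers_
    elif method == "ward":
        Z = linkage(X, method="ward")
        idx = fcluster(Z, t=k, criterion="maxclust") - 1
        centroids = np.vstack([X[idx == i].mean(axis=0) for i in range(k)])
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterAssignment(
        assignments=pd.Series(idx, index=matrix.index, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=signature_columns(matrix)),
    )


def name_clusters(assignment: ClusterAssignment, dose: float = 5000.0) -> ClusterAssignment:
    """Assign canonical sensitivity labels from the strongest-dose centroids.

    With per-cluster mean core LFC c and pause LFC p at ``dose``: among
    clusters with p < 0, the one with the smallest |c| is
    highly-sensitive-pause; symmetrically for highly-sensitive-core; of the
    remaining two, the lower c + p is highly-sensitive-both and the other
    sensitive-both. Deterministic given centroids; ties break by cluster
    index.
    """
    cen = assignment.centroids
    c = cen[f"lfc_{dose:g}_core"].to_numpy()
    p = cen[f"lfc_{dose:g}_pause"].to_numpy()
    k = len(cen)
    if k != 4:
        raise ValueError("canonical naming requires exactly 4 clusters")
    remaining = list(range(k))

    def pick(candidates, key):
        cands = sorted(candidates, key=key)  # stable: ties by cluster index
        return cands[0]

    labels = {}
    pause_cands = [i for i in remaining if p[i] < 0] or remaining
    i_pause = pick(pause_cands, lambda i: (abs(c[i]), i))
    labels[i_pause] = CLASS_HIGHLY_PAUSE
    remaining.remove(i_pause)

    core_cands = [i for i in remaining if c[i] < 0] or remaining
    i_core = pick(core_cands, lambda i: (abs(p[i]), i))
    labels[i_core] = CLASS_HIGHLY_CORE
    remaining.remove(i_core)

    i_hboth = pick(remaining, lambda i: (c[i] + p[i], i))
    labels[i_hboth] = CLASS_HIGHLY_BOTH
    remaining.remove(i_hboth)
    labels[remaining[0]] = CLASS_SENSITIVE_BOTH
    return ClusterAssignment(assignment.assignments, assignment.centroids, labels)


def cluster_overlap(a: ClusterAssignment, b: ClusterAssignment,
                    id_map_a=None, id_map_b=None) -> pd.DataFrame:
    """4x4 table of gene identifiers shared between equally-labeled clusters
    of two assignments (diagonal = equivalent-cluster overlaps).

    ``id_map_*`` optionally map transcript ids to gene ids before
    intersecting.
    """
    la, lb = a.labeled(), b.labeled()
    if id_map_a is not None:
        la = la.rename(index=id_map_a)
    if id_map_b is not None:
        lb = lb.rename(index=id_map_b)
    out = pd.DataFrame(0, index=list(CLUSTER_LABELS), columns=list(CLUSTER_LABELS))
    for ca in CLUSTER_LABELS:
        genes_a = set(la.index[la == ca])
        for cb in CLUSTER_LABELS:
            genes_b = set(lb.index[lb == cb])
            out.loc[ca, cb] = len(genes_a & genes_b)
    return out
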