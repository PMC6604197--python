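"""LFC-signature construction, k-means/Ward clustering and cluster naming."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from betshift.clusters import (
    ClusterAssignment,
    build_lfc_matrix,
    cluster_overlap,
    cluster_tss,
    name_clusters,
    signature_columns,
)

COLS = [f"lfc_{d:g}_{w}" for d in (50, 500, 5000) for w in ("core", "pause")]


def _results(rows):
    """rows: tid -> {(dose, window): (lfc, padj, tested)}"""
    out = {}
    for dose in (50.0, 500.0, 5000.0):
        recs = {}
        for tid, d in rows.items():
            for window in ("core", "pause"):
                lfc, padj, tested = d.get((dose, window), (0.0, 1.0, True))
                recs[(tid, window)] = (lfc, padj, tested)
        idx = pd.MultiIndex.from_tuples(recs.keys(), names=["transcript_id", "window"])
        lfc, padj, tested = zip(*recs.values())
        out[dose] = pd.DataFrame({"lfc": lfc, "padj": padj, "tested": tested}, index=idx)
    return out


class TestBuildLfcMatrix:
    def test_empty_when_nothing_significant(self):
        res = _results({"T1": {(5000.0, "pause"): (-2.0, 0.5, True)}})
        assert len(build_lfc_matrix(res)) == 0

    def test_single_significant_contrast_includes_full_signature(self):
        res = _results({"T1": {
            (5000.0, "pause"): (-2.0, 0.01, True),
            (500.0, "pause"): (-1.0, 0.2, True),
        }})
        m = build_lfc_matrix(res)
        assert list(m.index) == ["T1"]
        assert m.loc["T1", "lfc_5000_pause"] == -2.0
        assert m.loc["T1", "lfc_500_pause"] == -1.0  # populated though not significant

    def test_untested_lfc_imputed_zero_and_flagged(self):
        res = _results({"T1": {
            (5000.0, "pause"): (-2.0, 0.01, True),
            (50.0, "core"): (-5.0, np.nan, False),
        }})
        m = build_lfc_matrix(res)
        assert m.loc["T1", "lfc_50_core"] == 0.0
        assert m.loc["T1", "lfc_50_core_imputed"]

    def test_row_count_equals_affected_any_count(self):
        from betshift.diffbind import affected_tss_table

        res = _results({
            "T1": {(5000.0, "pause"): (-2.0, 0.01, True)},
            "T2": {(500.0, "core"): (-1.5, 0.02, True)},
            "T3": {(50.0, "pause"): (-0.5, 0.9, True)},
        })
        m = build_lfc_matrix(res)
        tab = affected_tss_table(res)
        assert len(m) == tab.loc["any", "total_affected"] == 2


def _blobs(rng, centers, n_per=50, sd=0.1):
    X = np.vstack([rng.normal(c, sd, size=(n_per, 6)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    idx = [f"T{i:04d}" for i in range(len(X))]
    return pd.DataFrame(X, columns=COLS, index=pd.Index(idx, name="transcript_id")), labels


class TestClusterTss:
    def test_separated_blobs_recovered_exactly(self, rng):
        m, truth = _blobs(rng, centers=[0.0, -2.0, -4.0, 2.0])
        asn = cluster_tss(m, seed=0)
        assert adjusted_rand_score(truth, asn.assignments) == 1.0

    def test_duplicated_rows_cluster_identically(self, rng):
        m, _ = _blobs(rng, centers=[0.0, -3.0], n_per=20)
        m = m.iloc[:40]
        doubled = pd.concat([m, m.set_index(m.index + "b")])
        a1 = cluster_tss(m, k=2, seed=5)
        a2 = cluster_tss(doubled, k=2, seed=5)
        first, second = a2.assignments.iloc[:40], a2.assignments.iloc[40:]
        assert (first.to_numpy() == second.to_numpy()).all()
        assert adjusted_rand_score(a1.assignments, first) == 1.0

    def test_seeded_determinism(self, rng):
        m, _ = _blobs(rng, centers=[0.0, -1.0, -2.0, -3.0], sd=0.5)
        a1 = cluster_tss(m, seed=9)
        a2 = cluster_tss(m, seed=9)
        assert (a1.assignments == a2.assignments).all()

    def test_ward_alternative_available(self, rng):
        m, truth = _blobs(rng, centers=[0.0, -2.0, -4.0, 2.0])
        asn = cluster_tss(m, method="ward")
        assert adjusted_rand_score(truth, asn.assignments) == 1.0

    def test_too_few_rows_rejected(self, rng):
        m, _ = _blobs(rng, centers=[0.0], n_per=3)
        with pytest.raises(ValueError):
            cluster_tss(m, k=4)


def _assignment(centroid_cp):
    """Build a ClusterAssignment whose 5000 nM centroids are given
    (core, pause) pairs; other columns zero."""
    k = len(centroid_cp)
    cen = pd.DataFrame(0.0, index=range(k), columns=COLS)
    for i, (c, p) in enumerate(centroid_cp):
        cen.loc[i, "lfc_5000_core"] = c
        cen.loc[i, "lfc_5000_pause"] = p
    assignments = pd.Series(range(k), index=[f"T{i}" for i in range(k)])
    return ClusterAssignment(assignments=assignments, centroids=cen)


class TestNameClusters:
    def test_canonical_geometry(self):
        asn = name_clusters(_assignment([(0.0, -2.0), (-2.0, 0.0), (-2.0, -2.0),
                                         (-0.7, -0.7)]))
        assert asn.labels == {0: "highly-sensitive-pause", 1: "highly-sensitive-core",
                              2: "highly-sensitive-both", 3: "sensitive-both"}

    def test_invariant_to_cluster_reindexing(self):
        base = [(0.0, -2.0), (-2.0, 0.0), (-2.0, -2.0), (-0.7, -0.7)]
        a = name_clusters(_assignment(base))
        perm = [2, 0, 3, 1]
        b = name_clusters(_assignment([base[i] for i in perm]))
        for new_idx, old_idx in enumerate(perm):
            assert b.labels[new_idx] == a.labels[old_idx]

    def test_labels_are_a_bijection(self):
        asn = name_clusters(_assignment([(-1.0, -3.0), (-3.0, -0.5), (-4.0, -4.0),
                                         (-1.2, -1.1)]))
        assert sorted(asn.labels) == [0, 1, 2, 3]
        assert len(set(asn.labels.values())) == 4


class TestClusterOverlap:
    def _labeled(self, mapping):
        tids = list(mapping)
        asn = ClusterAssignment(
            assignments=pd.Series(range(len(tids)), index=tids),
            centroids=pd.DataFrame(),
            labels=dict(enumerate(mapping.values())),
        )
        return asn

    def test_self_overlap_is_diagonal(self):
        a = self._labeled({"g1": "sensitive-both", "g2": "highly-sensitive-pause",
                           "g3": "highly-sensitive-pause"})
        tab = cluster_overlap(a, a)
        assert tab.loc["highly-sensitive-pause", "highly-sensitive-pause"] == 2
        assert tab.loc["sensitive-both", "sensitive-both"] == 1
        assert tab.to_numpy().sum() == 3

    def test_disjoint_universes_all_zero(self):
        a = self._labeled({"g1": "sensitive-both"})
        b = self._labeled({"h1": "sensitive-both"})
        assert cluster_overlap(a, b).to_numpy().sum() == 0

    def test_matches_brute_force_intersections(self, rng):
        labels = ["sensitive-both", "highly-sensitive-both",
                  "highly-sensitive-pause", "highly-sensitive-core"]
        ga = {f"g{i}": labels[rng.integers(4)] for i in range(60)}
        gb = {f"g{i}": labels[rng.integers(4)] for i in range(30, 90)}
        tab = cluster_overlap(self._labeled(ga), self._labeled(gb))
        for la in labels:
            for lb in labels:
                expected = len({g for g, l in ga.items() if l == la}
                               & {g for g, l in gb.items() if l == lb})
                assert tab.loc[la, lb] == expected
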