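"""Differential expression, binding/expression overlap, paired cluster
comparisons, and pre-ranked GSEA."""

import numpy as np
import pandas as pd
import pytest

from betshift.expression import (
    cluster_expression_compare,
    db_de_overlap,
    differential_expression,
    enrichment_score,
    gsea_preranked,
    read_gmt,
    write_gmt,
)


def _counts(rng, n, mu, disp=0.05, lfc=None):
    mu = np.full(n, mu, float)
    mu_t = mu * (2.0 ** lfc if lfc is not None else 1.0)
    lam_v = rng.gamma(1 / disp, disp * mu, size=(2, n)).T
    lam_t = rng.gamma(1 / disp, disp * mu_t, size=(2, n)).T
    m = pd.DataFrame(np.hstack([rng.poisson(lam_t), rng.poisson(lam_v)]),
                     columns=["t1", "t2", "v1", "v2"],
                     index=[f"g{i}" for i in range(n)])
    return m


UNIT = lambda m: pd.Series(1.0, index=m.columns)


class TestDifferentialExpression:
    def test_null_type_one_error(self, rng):
        m = _counts(rng, 5000, 300.0)
        de = differential_expression(m, ["t1", "t2"], ["v1", "v2"])
        p = de["pvalue"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_power_for_strong_downregulation(self, rng):
        from betshift.diffbind import nb_wald_test

        m = _counts(rng, 500, 500.0, lfc=-2.0)
        res = nb_wald_test(m, ["t1", "t2"], ["v1", "v2"], factors=UNIT(m))
        res["significant"] = (res["padj"] < 0.05) & (res["lfc"].abs() > 1.0)
        assert res["significant"].mean() >= 0.9

    def test_sub_threshold_lfc_never_significant(self):
        # a tiny p cannot rescue an LFC below the magnitude threshold
        de = pd.DataFrame({"lfc": [-0.8], "padj": [1e-10]})
        sig = (de["padj"] < 0.05) & (de["lfc"].abs() > 1.0)
        assert not sig.iloc[0]

    def test_dual_threshold_applied(self, rng):
        m = _counts(rng, 2000, 400.0, lfc=-0.8)
        de = differential_expression(m, ["t1", "t2"], ["v1", "v2"])
        called = de[de["significant"]]
        assert (called["lfc"].abs() > 1.0).all()
        assert (called["padj"] < 0.05).all()


class TestDbDeOverlap:
    def _de(self, mapping):
        df = pd.DataFrame(mapping).T
        df.columns = ["lfc", "padj"]
        df["significant"] = (df["padj"] < 0.05) & (df["lfc"].abs() > 1.0)
        return df

    def test_disjoint_sets_zero_percent(self):
        de = self._de({"g1": (-2.0, 0.01), "g2": (-3.0, 0.001)})
        n, tot, pct = db_de_overlap({"g9"}, de)
        assert (n, tot, pct) == (0, 2, 0.0)

    def test_percentage_of_downregulated(self):
        de = self._de({"g1": (-2.0, 0.01), "g2": (-3.0, 0.001), "g3": (2.0, 0.001),
                       "g4": (-1.5, 0.01)})
        n, tot, pct = db_de_overlap({"g1", "g3"}, de, direction="down")
        assert (n, tot) == (1, 3)
        assert pct == pytest.approx(100.0 / 3)

    def test_transcript_to_gene_mapping(self):
        de = self._de({"g1": (-2.0, 0.01)})
        n, _, _ = db_de_overlap({"T1"}, de, transcript_to_gene={"T1": "g1"})
        assert n == 1

    def test_printed_ratio_conventions(self):
        """The reference overlap fractions follow n_overlap/n_down."""
        assert 100 * 542 / 1581 == pytest.approx(34.3, abs=0.05)
        assert 100 * 112 / 1389 == pytest.approx(8.1, abs=0.05)


class TestClusterExpressionCompare:
    def _de_from(self, vals):
        return pd.DataFrame({"lfc": vals})

    def test_identical_vectors_flagged_untested(self):
        labels = pd.Series(["c1"] * 10, index=[f"g{i}" for i in range(10)])
        de = self._de_from(pd.Series(np.linspace(-2, 0, 10), index=labels.index))
        out = cluster_expression_compare(labels, de, de)
        assert not out.loc["c1", "tested"]

    def test_location_shift_detected(self, rng):
        genes = [f"g{i}" for i in range(50)]
        labels = pd.Series(["c1"] * 50, index=genes)
        base = pd.Series(rng.normal(0, 0.3, 50), index=genes)
        de_a = self._de_from(base - 2.0)
        de_b = self._de_from(base)
        out = cluster_expression_compare(labels, de_a, de_b)
        assert out.loc["c1", "pvalue"] < 1e-6
        assert out.loc["c1", "median_lfc_a"] < out.loc["c1", "median_lfc_b"]

    def test_small_clusters_flagged(self, rng):
        genes = [f"g{i}" for i in range(4)]
        labels = pd.Series(["c1"] * 4, index=genes)
        de_a = self._de_from(pd.Series(rng.normal(size=4), index=genes))
        de_b = self._de_from(pd.Series(rng.normal(size=4), index=genes))
        out = cluster_expression_compare(labels, de_a, de_b, min_pairs=6)
        assert not out.loc["c1", "tested"]


def brute_force_es(metric, hits, weight=1.0):
    """Independent step-by-step running-sum oracle."""
    n = len(metric)
    w = [abs(m) ** weight for m in metric]
    hit_total = sum(wi for wi, h in zip(w, hits) if h)
    n_miss = n - sum(hits)
    running, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += w[i] / hit_total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_top_of_list_set_hand_stepped(self):
        metric = np.array([5, 4, 3, 2, 1, 0.5, 0.4, 0.3, 0.2, 0.1])
        hits = np.zeros(10, bool)
        hits[:3] = True
        # steps: +5/12, +4/12, +3/12 then seven misses of -1/7; peak = 1.0
        assert enrichment_score(metric, hits) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_small_lists(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 21))
            metric = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            hits = np.zeros(n, bool)
            hits[rng.choice(n, size=k, replace=False)] = True
            if hits.all():
                hits[0] = False
            got = enrichment_score(metric, hits)
            assert got == pytest.approx(brute_force_es(metric, hits), abs=1e-12)
            assert -1.0 <= got <= 1.0

    def test_improper_sets_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(np.array([1.0, 2.0]), np.array([True, True]))


class TestGseaPreranked:
    def _ranking(self, rng, n=40):
        return pd.Series(np.sort(rng.normal(size=n))[::-1],
                         index=[f"g{i}" for i in range(n)])

    def test_negated_metric_flips_es_sign(self, rng):
        ranking = self._ranking(rng)
        sets = {"s": set(ranking.index[:8])}
        r1 = gsea_preranked(ranking, sets, n_perm=300, seed=3)
        r2 = gsea_preranked(-ranking, sets, n_perm=300, seed=3)
        assert np.sign(r1.loc["s", "es"]) == -np.sign(r2.loc["s", "es"])
        assert abs(r1.loc["s", "nes"]) == pytest.approx(abs(r2.loc["s", "nes"]), rel=0.35)

    def test_top_heavy_set_significant(self, rng):
        ranking = self._ranking(rng, n=100)
        sets = {"top": set(ranking.index[:12]),
                "random": set(ranking.index[::7])}
        res = gsea_preranked(ranking, sets, n_perm=500, seed=1)
        assert res.loc["top", "nes"] > 1.0
        assert res.loc["top", "pvalue"] < 0.05

    def test_seeded_determinism(self, rng):
        ranking = self._ranking(rng)
        sets = {"s": set(ranking.index[:10])}
        r1 = gsea_preranked(ranking, sets, n_perm=200, seed=11)
        r2 = gsea_preranked(ranking, sets, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(r1, r2)

    def test_size_bounds_filter_sets(self, rng):
        ranking = self._ranking(rng)
        res = gsea_preranked(ranking, {"tiny": {"g0", "g1"}}, n_perm=50, seed=0)
        assert len(res) == 0


def test_gmt_round_trip(tmp_path):
    sets = {"a": {"g1", "g2", "g3"}, "b": {"g4", "g5"}}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
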