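"""Coverage tracks: binning, 1x normalization, subtraction, metaprofiles."""

import numpy as np
import pytest

from betshift.coverage import (
    CoverageTrack,
    extend_and_bin,
    metaprofile,
    profile_modes,
    read_bedgraph,
    rpgc_normalize,
    subtract_input,
    write_bedgraph,
)
from betshift.genome import Interval

CHROMS = {"chr1": 10_000}


class TestExtendAndBin:
    def test_single_fragment_fills_its_bins(self):
        t = extend_and_bin([Interval("chr1", 0, 300)], CHROMS, bin_size=50, extension=300)
        assert np.allclose(t.values["chr1"][:6], 1.0)
        assert np.allclose(t.values["chr1"][6:], 0.0)

    def test_linearity_in_duplicated_fragments(self):
        frags = [Interval("chr1", 1000, 1300)]
        t1 = extend_and_bin(frags, CHROMS)
        t2 = extend_and_bin(frags * 2, CHROMS)
        assert np.allclose(t2.values["chr1"], 2 * t1.values["chr1"])

    def test_matches_per_base_oracle(self, rng):
        starts = rng.integers(0, 9000, 100)
        frags = [Interval("chr1", int(s), int(s) + 120) for s in starts]
        t = extend_and_bin(frags, CHROMS, bin_size=50, extension=300)
        per_base = np.zeros(10_000)
        for f in frags:
            per_base[f.start:min(f.start + 300, 10_000)] += 1
        expected = per_base.reshape(-1, 50).mean(axis=1)
        assert np.allclose(t.values["chr1"], expected)

    def test_minus_strand_extends_from_five_prime_end(self):
        t = extend_and_bin([Interval("chr1", 1000, 1100, "-")], CHROMS, extension=300)
        per_base = np.zeros(10_000)
        per_base[800:1100] += 1  # 5' end of a minus fragment is its right edge
        assert np.allclose(t.values["chr1"], per_base.reshape(-1, 50).mean(axis=1))

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            extend_and_bin([], CHROMS, bin_size=0)


class TestRpgc:
    def test_scale_formula(self):
        frags = [Interval("chr1", int(s), int(s) + 300) for s in range(0, 9000, 9)]
        t = extend_and_bin(frags, CHROMS)
        n = rpgc_normalize(t, effective_genome_size=10_000)
        scale = 10_000 / (len(frags) * 300)
        assert np.allclose(n.values["chr1"], t.values["chr1"] * scale)

    def test_mean_coverage_is_one(self, rng):
        starts = rng.integers(0, 9700, 500)
        frags = [Interval("chr1", int(s), int(s) + 300) for s in starts]
        n = rpgc_normalize(extend_and_bin(frags, CHROMS))
        assert n.mean() == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance_under_depth_change(self, rng):
        starts = rng.integers(0, 9700, 200)
        frags = [Interval("chr1", int(s), int(s) + 300) for s in starts]
        n1 = rpgc_normalize(extend_and_bin(frags, CHROMS))
        n3 = rpgc_normalize(extend_and_bin(frags * 3, CHROMS))
        assert np.allclose(n1.values["chr1"], n3.values["chr1"])

    def test_empty_track_rejected(self):
        t = extend_and_bin([], CHROMS)
        with pytest.raises(ValueError):
            rpgc_normalize(t)


class TestSubtract:
    def _tracks(self, rng):
        a = extend_and_bin(
            [Interval("chr1", int(s), int(s) + 300) for s in rng.integers(0, 9700, 300)],
            CHROMS)
        b = extend_and_bin(
            [Interval("chr1", int(s), int(s) + 300) for s in rng.integers(0, 9700, 300)],
            CHROMS)
        return rpgc_normalize(a), rpgc_normalize(b)

    def test_identical_tracks_cancel(self, rng):
        a, _ = self._tracks(rng)
        d = subtract_input(a, a)
        assert np.allclose(d.values["chr1"], 0.0)

    def test_elementwise_difference(self, rng):
        a, b = self._tracks(rng)
        d = subtract_input(a, b)
        assert np.allclose(d.values["chr1"], a.values["chr1"] - b.values["chr1"])
        assert (d.values["chr1"] < 0).any()  # negatives preserved

    def test_mismatched_grids_rejected(self, rng):
        a, _ = self._tracks(rng)
        other = CoverageTrack(bin_size=25, values={"chr1": np.zeros(400)},
                              normalization="RPGC")
        with pytest.raises(ValueError):
            subtract_input(a, other)


class TestMetaprofile:
    def test_uniform_track_gives_flat_profile(self):
        t = CoverageTrack(bin_size=50, values={"chr1": np.full(200, 3.0)})
        p = metaprofile(t, [("chr1", 5000, "+")], flank=1000)
        assert np.allclose(p.signal, 3.0)

    def test_minus_strand_anchor_flips_offsets(self):
        vals = np.zeros(200)
        vals[(5000 - 200) // 50] = 7.0  # signal 200 bp left of the anchor
        t = CoverageTrack(bin_size=50, values={"chr1": vals})
        p = metaprofile(t, [("chr1", 5000, "-")], flank=1000)
        # left of a minus-strand anchor is downstream: positive offset
        peak_offset = p.offsets[np.argmax(p.signal)]
        assert peak_offset == 150  # bin [150, 200) holds distance 200

    def test_anchor_order_invariance(self, rng):
        vals = rng.random(200)
        t = CoverageTrack(bin_size=50, values={"chr1": vals})
        anchors = [("chr1", int(p), s) for p, s in
                   zip(rng.integers(2000, 8000, 10), "+-+-+-+-+-")]
        p1 = metaprofile(t, anchors, flank=1000)
        p2 = metaprofile(t, anchors[::-1], flank=1000)
        assert np.allclose(p1.signal, p2.signal)

    def test_edge_anchors_dropped_and_counted(self):
        t = CoverageTrack(bin_size=50, values={"chr1": np.ones(200)})
        p = metaprofile(t, [("chr1", 100, "+"), ("chr1", 5000, "+")], flank=1000)
        assert p.n_anchors == 1 and p.n_dropped == 1
        with pytest.raises(ValueError):
            metaprofile(t, [("chr1", 100, "+")], flank=1000)


class TestProfileModes:
    def _gaussian_profile(self, centers, heights, bin_size=50, flank=2000):
        offsets = np.arange(-flank, flank, bin_size)
        sig = sum(h * np.exp(-0.5 * ((offsets - c) / 150.0) ** 2)
                  for c, h in zip(centers, heights))
        from betshift.coverage import MetaProfile
        return MetaProfile(offsets=offsets, signal=sig, n_anchors=1, bin_size=bin_size)

    def test_two_gaussians_recovered(self):
        p = self._gaussian_profile([-300, 165], [1.0, 2.0])
        m = profile_modes(p)
        assert not m["unimodal"]
        assert abs(m["upstream"] - (-300)) <= 50
        assert abs(m["downstream"] - 165) <= 100
        assert m["ratio"] == pytest.approx(2.0, rel=0.1)

    def test_symmetric_profile_ratio_one(self):
        p = self._gaussian_profile([-300, 300], [1.5, 1.5])
        m = profile_modes(p)
        assert m["ratio"] == pytest.approx(1.0, rel=1e-6)

    def test_flat_profile_flagged_unimodal(self):
        from betshift.coverage import MetaProfile
        offsets = np.arange(-2000, 2000, 50)
        p = MetaProfile(offsets=offsets, signal=np.linspace(0, 1, len(offsets)),
                        n_anchors=1, bin_size=50)
        assert profile_modes(p)["unimodal"]


def test_bedgraph_round_trip(tmp_path, rng):
    starts = rng.integers(0, 9700, 100)
    t = extend_and_bin([Interval("chr1", int(s), int(s) + 300) for s in starts], CHROMS)
    path = tmp_path / "x.bedgraph"
    write_bedgraph(t, path)
    back = read_bedgraph(path, CHROMS, bin_size=50)
    assert np.allclose(back.values["chr1"], t.values["chr1"])
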