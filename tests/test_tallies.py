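"""Ray traversal, scoring cells and history-by-history statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brachymc import _kernels as K
from brachymc.geometry import GridGeometry
from brachymc.tallies import (CylinderCell, DoseGrid, TrackSegment,
                              analogue_score, cell_tlke,
                              finalize_uncertainty, siddon_traverse,
                              tlke_score)


def marching_chords(p0, p1, geometry, step=1e-5):
    """Fine-step marching oracle: per-voxel lengths of segment p0 -> p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    L = np.linalg.norm(p1 - p0)
    n = max(int(L / step), 1)
    ts = (np.arange(n) + 0.5) / n * L
    u = (p1 - p0) / L
    pts = p0[None, :] + ts[:, None] * u[None, :]
    idx = np.floor((pts - np.asarray(geometry.origin))
                   / np.asarray(geometry.spacing)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(geometry.shape)), axis=1)
    out = {}
    for i in np.flatnonzero(ok):
        key = tuple(idx[i])
        out[key] = out.get(key, 0.0) + L / n
    return out


class TestSiddon:
    def test_axis_aligned_two_voxels(self):
        # 2 mm ray centered on a face between two 1 mm voxels
        g = GridGeometry((4, 1, 1), (0.1, 0.1, 0.1), (0.0, 0.0, 0.0))
        segs = siddon_traverse([0.1, 0.05, 0.05], [0.3, 0.05, 0.05], g)
        assert [(s.voxel, pytest.approx(s.length)) for s in segs] == [
            ((1, 0, 0), pytest.approx(0.1)), ((2, 0, 0), pytest.approx(0.1))]

    def test_oblique_ray_matches_marching_oracle(self):
        # 1 mm voxels, oblique in-plane ray (units: cm)
        g = GridGeometry((2, 2, 1), (0.1, 0.1, 0.1), (0.0, 0.0, 0.0))
        p0, p1 = [0.02, 0.05, 0.05], [0.18, 0.13, 0.05]
        segs = siddon_traverse(p0, p1, g)
        total = np.hypot(0.16, 0.08)
        assert sum(s.length for s in segs) == pytest.approx(total, rel=1e-9)
        oracle = marching_chords(p0, p1, g, step=1e-5)
        assert len(segs) == len(oracle) == 3
        for s in segs:
            assert s.length == pytest.approx(oracle[s.voxel], abs=5e-4)

    def test_ray_outside_grid_is_empty(self):
        g = GridGeometry((2, 2, 2), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        assert siddon_traverse([5, 5, 5], [6, 7, 8], g) == []

    def test_zero_length_ray_is_empty(self):
        g = GridGeometry((2, 2, 2), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        assert siddon_traverse([0.5, 0.5, 0.5], [0.5, 0.5, 0.5], g) == []

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_chord_sum_equals_clipped_length(self, seed):
        """Segment lengths along any interior ray sum to the chord."""
        rng = np.random.default_rng(seed)
        g = GridGeometry((5, 4, 3), (0.4, 0.5, 0.7), (-1.0, -1.0, -1.0))
        p0 = rng.uniform([-0.9, -0.9, -0.9], [0.9, 0.9, 0.9])
        p1 = rng.uniform([-0.9, -0.9, -0.9], [0.9, 0.9, 0.9])
        lo, hi = g.extent
        inside = np.all((p0 >= lo) & (p0 < hi)) and np.all(
            (p1 >= lo) & (p1 < hi))
        if not inside or np.allclose(p0, p1):
            return
        segs = siddon_traverse(p0, p1, g)
        assert sum(s.length for s in segs) == pytest.approx(
            float(np.linalg.norm(p1 - p0)), rel=1e-9)

    def test_kernel_traversal_agrees_with_python(self):
        """The compiled Siddon scorer distributes exactly the same lengths
        as the reference traversal."""
        rng = np.random.default_rng(5)
        g = GridGeometry((6, 5, 4), (0.31, 0.4, 0.55), (-0.9, -1.0, -1.1))
        shape = np.array(g.shape, np.int64)
        spacing = np.array(g.spacing)
        origin = np.array(g.origin)
        nvox = int(np.prod(g.shape))
        muen_log = np.zeros((1, 3))  # log(1): muen == 1 everywhere
        for _ in range(50):
            p0 = rng.uniform(-1.5, 1.5, 3)
            p1 = rng.uniform(-1.5, 1.5, 3)
            L = np.linalg.norm(p1 - p0)
            if L < 1e-9:
                continue
            u = (p1 - p0) / L
            ssum = np.zeros(nvox)
            s2 = np.zeros(nvox)
            buf = np.zeros(nvox)
            tag = np.full(nvox, -1, np.int64)
            K.siddon_score_segment(
                p0[0], p0[1], p0[2], u[0], u[1], u[2], L, 1.0, 1.0,
                shape, spacing, origin,
                np.zeros(nvox, np.int64), 1.0, muen_log, 0.0, 0.0, 1.0, 3,
                ssum, s2, buf, tag, 0)
            K.flush_tagged(ssum, s2, buf, tag)
            ref = np.zeros(g.shape)
            for s in siddon_traverse(p0, p1, g):
                ref[s.voxel] += s.length * 1000.0  # keV -> eV factor
            np.testing.assert_allclose(ssum.reshape(g.shape), ref,
                                       rtol=1e-9, atol=1e-9)


class TestCylinderCell:
    CELL = CylinderCell(inner_radius=0.0, outer_radius=0.5,
                        half_height=0.3, material="air")

    def test_axial_ray_chord_is_full_height(self):
        chord = self.CELL.chord([0.1, 0.0, -5.0], [0, 0, 1], 10.0)
        assert chord == pytest.approx(0.6, rel=1e-12)

    def test_tangent_ray_zero(self):
        assert self.CELL.chord([0.5, -5.0, 0.0], [0, 1, 0], 10.0) == 0.0

    def test_ring_subtracts_inner_cylinder(self):
        ring = CylinderCell(0.2, 0.5, 0.3, material="air")
        chord = ring.chord([-5.0, 0.0, 0.0], [1, 0, 0], 10.0)
        assert chord == pytest.approx(2 * (0.5 - 0.2), rel=1e-12)

    def test_random_rays_match_marching_oracle(self):
        ring = CylinderCell(0.3, 0.8, 0.25, material="air")
        rng = np.random.default_rng(11)
        for _ in range(40):
            p0 = rng.uniform(-1.5, 1.5, 3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            L = 3.0
            n = 300_000
            ts = (np.arange(n) + 0.5) / n * L
            pts = p0[None, :] + ts[:, None] * u[None, :]
            r = np.hypot(pts[:, 0], pts[:, 1])
            inside = ((r >= ring.inner_radius) & (r <= ring.outer_radius)
                      & (np.abs(pts[:, 2]) <= ring.half_height))
            oracle = inside.sum() * L / n
            assert ring.chord(p0, u, L) == pytest.approx(oracle, abs=1e-4)

    def test_cell_tlke_direct_value(self):
        val = cell_tlke(self.CELL, [0.0, 0.0, -5.0], [0, 0, 1], 10.0,
                        energy=100.0, weight=0.5,
                        muen_lookup=lambda m, e: 0.025)
        expected = 0.5 * 0.6 * 100.0 * 0.025 / self.CELL.volume * 1000.0
        assert val == pytest.approx(expected, rel=1e-12)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            CylinderCell(0.5, 0.5, 0.3)


class TestDoseGridStatistics:
    def test_two_history_closed_form(self):
        g = DoseGrid(geometry=GridGeometry((1, 1, 1), (1, 1, 1), (0, 0, 0)))
        g._score((0, 0, 0), 0.0, history=0)
        g._score((0, 0, 0), 2.0, history=1)
        g.n_histories = 2
        mean, rel, note = finalize_uncertainty(g)
        assert mean[0, 0, 0] == pytest.approx(1.0)
        assert rel[0, 0, 0] == pytest.approx(1.0)  # SE 1 on mean 1
        assert note == "k=1"

    def test_identical_histories_zero_uncertainty(self):
        g = DoseGrid(geometry=GridGeometry((1, 1, 1), (1, 1, 1), (0, 0, 0)))
        for h in range(10):
            g._score((0, 0, 0), 3.5, history=h)
        g.n_histories = 10
        _, rel, _ = finalize_uncertainty(g)
        assert rel[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_same_history_contributions_pool_into_one_unit(self):
        """Two half-size scores in one history must equal one full score
        statistically (correlated progeny grouped)."""
        a = DoseGrid(geometry=GridGeometry((1, 1, 1), (1, 1, 1), (0, 0, 0)))
        b = DoseGrid(geometry=GridGeometry((1, 1, 1), (1, 1, 1), (0, 0, 0)))
        for h in range(8):
            a._score((0, 0, 0), 1.0, history=h)
            b._score((0, 0, 0), 0.5, history=h)
            b._score((0, 0, 0), 0.5, history=h)
        a.n_histories = b.n_histories = 8
        ma, ra_, _ = finalize_uncertainty(a)
        mb, rb, _ = finalize_uncertainty(b)
        assert ma[0, 0, 0] == pytest.approx(mb[0, 0, 0])
        assert ra_[0, 0, 0] == pytest.approx(rb[0, 0, 0], abs=1e-12)

    def test_fewer_than_two_histories_undefined(self):
        g = DoseGrid(geometry=GridGeometry((1, 1, 1), (1, 1, 1), (0, 0, 0)))
        g.n_histories = 1
        with pytest.raises(ValueError, match="2 histories"):
            finalize_uncertainty(g)

    def test_coverage_factor_two_doubles(self):
        g = DoseGrid(geometry=GridGeometry((1, 1, 1), (1, 1, 1), (0, 0, 0)))
        g._score((0, 0, 0), 0.0, history=0)
        g._score((0, 0, 0), 2.0, history=1)
        g.n_histories = 2
        _, rel1, _ = finalize_uncertainty(g, coverage_factor=1)
        _, rel2, note = finalize_uncertainty(g, coverage_factor=2)
        assert rel2[0, 0, 0] == pytest.approx(2 * rel1[0, 0, 0])
        assert note == "k=2"


class TestScoringOps:
    GEOM = GridGeometry((2, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

    def test_tlke_single_voxel_direct_substitution(self):
        g = DoseGrid(geometry=self.GEOM)
        segs = [TrackSegment((0, 0, 0), 0.7)]
        tlke_score(g, segs, energy=300.0, weight=1.0,
                   muen_lookup=lambda m, e: 0.031, history=0)
        g.flush()
        g.n_histories = 1
        expected = 0.7 * 300.0 * 0.031 / 1.0 * 1000.0
        assert g.accum_sum[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_length_segment_zero_contribution(self):
        g = DoseGrid(geometry=self.GEOM)
        tlke_score(g, [TrackSegment((0, 0, 0), 0.0)], 300.0, 1.0,
                   lambda m, e: 0.031, history=0)
        g.flush()
        assert g.accum_sum.sum() == 0.0

    def test_analogue_photoelectric_deposits_energy_over_mass(self):
        g = DoseGrid(geometry=self.GEOM,
                     densities=np.full(self.GEOM.shape, 2.0))
        analogue_score(g, [0.5, 0.5, 0.5], energy_transferred=400.0,
                       weight=1.0, history=0)
        g.flush()
        assert g.accum_sum[0, 0, 0] == pytest.approx(400.0 * 1000.0 / 2.0)

    def test_analogue_outside_grid_ignored(self):
        g = DoseGrid(geometry=self.GEOM,
                     densities=np.full(self.GEOM.shape, 1.0))
        analogue_score(g, [9.0, 0.5, 0.5], 100.0, 1.0, history=0)
        g.flush()
        assert g.accum_sum.sum() == 0.0
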