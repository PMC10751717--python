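"""Capsule emission, phase-space files and dwell-plan machinery."""
import numpy as np
import pytest
from scipy import stats

from brachymc.geometry import SourceCapsule, rotation_between
from brachymc.materials import EmissionSpectrum, load_spectrum
from brachymc.sources import (DwellPosition, PhaseSpaceRecord, Plan,
                              PsfFormatError, catheter_orientation,
                              dwell_weights, emit_primary, load_source_config,
                              plan_from_json, plan_source_next, plan_to_json,
                              psf_read, psf_write)

CAP = SourceCapsule(core_radius=0.03, core_half_length=0.175,
                    capsule_radius=0.045, capsule_half_length=0.195)
MONO = EmissionSpectrum(lines=((350.0, 1.0),))


def _lung_like_plan(n_dwells=19, seed=3):
    rng = np.random.default_rng(seed)
    pts = [np.array([0.0, 0.0, 0.5 * k]) for k in range(n_dwells)]
    rots = catheter_orientation(pts)
    times = rng.uniform(2.0, 12.0, n_dwells)
    dwells = [DwellPosition(p, r, float(t), "cath-1")
              for p, r, t in zip(pts, rots, times)]
    return Plan(dwells=dwells, prescription_dose=5.0,
                prescription_point=np.array([1.0, 0.0, 4.5]))


class TestEmission:
    def test_positions_inside_core_and_centered(self, rng):
        pos = np.array([emit_primary(CAP, MONO, rng).position
                        for _ in range(20_000)])
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all(r <= CAP.core_radius + 1e-12)
        assert np.all(np.abs(pos[:, 2]) <= CAP.core_half_length + 1e-12)
        for ax in range(3):
            se = pos[:, ax].std() / np.sqrt(len(pos))
            assert abs(pos[:, ax].mean()) < 3 * se

    def test_direction_cosine_uniform_ks(self, rng):
        w = np.array([emit_primary(CAP, MONO, rng).direction[2]
                      for _ in range(20_000)])
        assert stats.kstest(w, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_weight_is_one(self, rng):
        assert emit_primary(CAP, MONO, rng).weight == 1.0


class TestPsfRoundTrip:
    def _records(self, n=1000, seed=7):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            out.append(PhaseSpaceRecord(
                energy=float(rng.uniform(10, 600)),
                position=tuple(rng.uniform(-0.05, 0.05, 3)),
                direction=tuple(d), weight=float(rng.uniform(0.5, 1.0))))
        return out

    def test_round_trip_preserves_records(self, tmp_path):
        recs = self._records()
        f = tmp_path / "a.psf"
        psf_write(recs, f, capsule_id="generic_hdr", n_primaries=2000,
                  seed=5)
        back, header = psf_read(f)
        assert header["capsule_id"] == "generic_hdr"
        assert header["n_primaries"] == 2000
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert b.energy == pytest.approx(a.energy, rel=1e-7)
            np.testing.assert_allclose(b.position, a.position, rtol=1e-6,
                                       atol=1e-7)
            np.testing.assert_allclose(b.direction, a.direction, atol=1e-6)

    def test_empty_file_valid_header(self, tmp_path):
        f = tmp_path / "empty.psf"
        psf_write([], f, n_primaries=0)
        back, header = psf_read(f)
        assert back == [] and header["n_records"] == 0

    def test_header_count_mismatch_is_format_error(self, tmp_path):
        f = tmp_path / "bad.psf"
        psf_write(self._records(10), f, n_primaries=10)
        raw = bytearray(f.read_bytes())
        truncated = raw[:-32]  # drop one 32-byte record
        f.write_bytes(bytes(truncated))
        with pytest.raises(PsfFormatError, match="records"):
            psf_read(f)

    def test_truncated_record_reports_offset(self, tmp_path):
        f = tmp_path / "trunc.psf"
        psf_write(self._records(10), f, n_primaries=10)
        f.write_bytes(f.read_bytes()[:-7])
        with pytest.raises(PsfFormatError, match="offset"):
            psf_read(f)

    def test_bad_magic_rejected(self, tmp_path):
        f = tmp_path / "junk.psf"
        f.write_bytes(b"NOPE" + b"\x00" * 32)
        with pytest.raises(PsfFormatError, match="magic"):
            psf_read(f)


class TestDwellWeights:
    def _plan(self, times):
        dwells = [DwellPosition(np.array([0.0, 0.0, 0.5 * i]), np.eye(3),
                                t, "c1") for i, t in enumerate(times)]
        return Plan(dwells=dwells, prescription_dose=10.0,
                    prescription_point=np.zeros(3))

    def test_equal_times_equal_weights(self):
        np.testing.assert_allclose(dwell_weights(self._plan([1.0, 1.0])),
                                   [0.5, 0.5])

    def test_three_to_one(self):
        np.testing.assert_allclose(dwell_weights(self._plan([3.0, 1.0])),
                                   [0.75, 0.25])

    def test_zero_time_dwell_gets_zero(self):
        np.testing.assert_allclose(
            dwell_weights(self._plan([2.0, 0.0, 2.0])), [0.5, 0.0, 0.5])

    def test_all_zero_times_rejected(self):
        with pytest.raises(ValueError):
            self._plan([0.0, 0.0])

    def test_sampling_frequencies_chi_square_19_dwell_plan(self, rng):
        """Dwell selection frequencies on a synthetic single-catheter
        19-dwell plan match the dwell-time weights (chi-square, a=0.01)."""
        plan = _lung_like_plan()
        w = dwell_weights(plan)
        rec = PhaseSpaceRecord(350.0, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        counts = np.zeros(len(w))
        n = 20_000
        stream = iter([rec] * n)
        for _ in range(n):
            batch = plan_source_next(plan, stream, split_factor=1, rng=rng)
            # identify the chosen dwell by the transformed position
            d = np.argmin([np.linalg.norm(batch[0].position - dw.position)
                           for dw in plan.dwells])
            counts[d] += 1
        assert stats.chisquare(counts, n * w).pvalue > 0.01


class TestPlanSource:
    def test_split_one_identity_transform(self, rng):
        plan = Plan(
            dwells=[DwellPosition(np.zeros(3), np.eye(3), 4.0, "c1")],
            prescription_dose=10.0, prescription_point=np.zeros(3))
        rec = PhaseSpaceRecord(222.0, (0.01, -0.02, 0.3), (0.0, 0.0, 1.0))
        out = plan_source_next(plan, iter([rec]), 1, rng)
        assert len(out) == 1
        np.testing.assert_allclose(out[0].position, rec.position)
        np.testing.assert_allclose(out[0].direction, rec.direction)
        assert out[0].energy == 222.0 and out[0].weight == 1.0

    def test_split_ten_total_weight_is_one(self, rng):
        plan = _lung_like_plan()
        rec = PhaseSpaceRecord(350.0, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        out = plan_source_next(plan, iter([rec]), 10, rng)
        assert len(out) == 10
        assert sum(p.weight for p in out) == pytest.approx(1.0)

    def test_rotation_maps_capsule_axis_to_catheter_tangent(self, rng):
        rot = rotation_between([0, 0, 1.0], [1.0, 0, 0])  # z -> x
        plan = Plan(
            dwells=[DwellPosition(np.array([5.0, 0.0, 0.0]), rot, 1.0,
                                  "c1")],
            prescription_dose=10.0, prescription_point=np.zeros(3))
        rec = PhaseSpaceRecord(350.0, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        out = plan_source_next(plan, iter([rec]), 1, rng)
        np.testing.assert_allclose(out[0].direction, [1.0, 0.0, 0.0],
                                   atol=1e-12)

    def test_exhausted_stream_signals_end(self, rng):
        plan = _lung_like_plan()
        with pytest.raises(StopIteration):
            plan_source_next(plan, iter([]), 1, rng)


class TestCatheterOrientation:
    def test_straight_line_all_tangents_equal(self):
        pts = [np.array([0.0, 0.0, 0.5 * i]) for i in range(5)]
        for rot in catheter_orientation(pts):
            np.testing.assert_allclose(rot @ [0, 0, 1], [0, 0, 1],
                                       atol=1e-12)

    def test_two_dwell_catheter_along_connecting_segment(self):
        pts = [np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0, 0.0])]
        expect = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        for rot in catheter_orientation(pts):
            np.testing.assert_allclose(rot @ [0, 0, 1], expect, atol=1e-12)

    def test_circular_arc_tangent_perpendicular_to_radius(self):
        """Interior tangents on a planar arc are perpendicular to their
        radius within the chord-discretization bound."""
        radius, n = 5.0, 21
        th = np.linspace(0.0, np.pi / 2, n)
        pts = [np.array([radius * np.cos(t), radius * np.sin(t), 0.0])
               for t in th]
        rots = catheter_orientation(pts)
        dth = th[1] - th[0]
        bound = dth**2  # central-difference error on a circle
        for i in range(1, n - 1):
            tangent = rots[i] @ np.array([0.0, 0.0, 1.0])
            radial = pts[i] / radius
            assert abs(np.dot(tangent, radial)) < bound

    def test_coincident_neighbours_degenerate(self):
        pts = [np.zeros(3), np.zeros(3), np.array([0.0, 0.0, 1.0])]
        with pytest.raises(ValueError, match="tangent"):
            catheter_orientation(pts)

    def test_single_dwell_needs_neighbour(self):
        with pytest.raises(ValueError):
            catheter_orientation([np.zeros(3)])


class TestPlanJson:
    def test_round_trip_mm_boundary(self, tmp_path):
        plan = _lung_like_plan()
        f = tmp_path / "plan.json"
        plan_to_json(plan, f)
        back = plan_from_json(f)
        assert len(back.dwells) == len(plan.dwells)
        assert back.prescription_dose == plan.prescription_dose
        np.testing.assert_allclose(back.prescription_point,
                                   plan.prescription_point, atol=1e-12)
        for a, b in zip(plan.dwells, back.dwells):
            np.testing.assert_allclose(a.position, b.position, atol=1e-12)
            np.testing.assert_allclose(a.orientation, b.orientation,
                                       atol=1e-12)
            assert a.dwell_time == pytest.approx(b.dwell_time)

    def test_wrong_kind_rejected(self, tmp_path):
        f = tmp_path / "x.json"
        f.write_text('{"kind": "something-else"}')
        with pytest.raises(ValueError, match="plan"):
            plan_from_json(f)


class TestSourceConfigs:
    @pytest.mark.parametrize("name", ["generic_hdr", "microselectron_v2"])
    def test_shipped_configs_load(self, name):
        cap = load_source_config(name)
        assert cap.core_radius < cap.capsule_radius
        assert cap.core_material == "iridium"

    def test_unknown_config_rejected(self):
        with pytest.raises(KeyError):
            load_source_config("not_a_source")
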