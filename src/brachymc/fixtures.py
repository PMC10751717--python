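"""Deterministic synthetic fixtures: benchmark scenes, a prostate-like
implant and a palliative endobronchial (lung-like) implant.

The synthetic patients are programmatic stand-ins for the clinical cases
the pipeline targets: an elliptical-cylinder body with an ellipsoidal
target, tubular urethra/rectum and a bladder for the prostate case
(17 catheters, 111 dwells, 15 Gy single fraction); a two-lung + bronchus
thorax with a single 19-dwell catheter prescribed 5 Gy at 1 cm for the
lung case.  Lungs, bronchus and rectum are assigned air (the worst-case
material scheme); bone appears only as a high-intensity image region, not
as a contour, so it exercises intensity-range segmentation.

All geometry is generated from a seed; identical seeds give byte-identical
files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clinical import Structure, StructureSet, structures_to_json
from .geometry import GridGeometry
from .sources import DwellPosition, Plan, catheter_orientation, plan_to_json

__all__ = ["SyntheticCase", "make_prostate_case", "make_lung_case",
           "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("testcase1", "testcase2", "testcase3", "prostate_like",
                 "lung_like")

_POLY_POINTS = 48


def _ellipse(cx, cy, ax, ay, n=_POLY_POINTS):
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.stack([cx + ax * np.cos(th), cy + ay * np.sin(th)], axis=1)


def _ellipsoid_contours(center, semi, zc):
    """Per-slice ellipse contours of an ellipsoid on slice centers zc."""
    out = []
    for z in zc:
        t = (z - center[2]) / semi[2]
        if abs(t) >= 1.0:
            continue
        s = np.sqrt(1.0 - t * t)
        out.append((float(z), _ellipse(center[0], center[1],
                                       semi[0] * s, semi[1] * s)))
    return out


def _tube_contours(cx, cy, radius, z0, z1, zc):
    return [(float(z), _ellipse(cx, cy, radius, radius))
            for z in zc if z0 <= z <= z1]


@dataclass
class SyntheticCase:
    """In-memory bundle: image grid + contours + plan."""

    geometry: GridGeometry
    intensity: np.ndarray  # pseudo-HU: air ~ -1000, water ~ 0, bone ~ 800
    structures: StructureSet
    plan: Plan
    name: str


def make_prostate_case(seed: int = 0, scale: str = "reduced"
                       ) -> SyntheticCase:
    """Prostate-like implant: 17 catheters, 111 dwells, 15 Gy.

    Reduced scale covers the printed 19 x 19 x 20.8 cm volume with 3-4 mm
    voxels (full halves the spacing).
    """
    rng = np.random.default_rng(seed)
    if scale == "full":
        shape, spacing = (128, 128, 104), (0.15, 0.15, 0.2)
    else:
        shape, spacing = (64, 64, 52), (0.3, 0.3, 0.4)
    geom = GridGeometry.centered(shape, spacing)
    zc = geom.voxel_centers(2)
    xs, ys, zs = geom.center_grid()
    body_ax, body_ay = 9.0, 8.5
    intensity = np.where(
        (xs / body_ax) ** 2 + (ys / body_ay) ** 2 <= 1.0, 0.0, -1000.0)
    # high-intensity lateral bone columns (image-only, no contour)
    for bx in (-6.5, 6.5):
        bone = ((xs - bx) ** 2 + ys**2 <= 1.8**2) & (np.abs(zs) <= 8.0)
        intensity[bone] = 800.0
    structures = StructureSet([
        Structure("body", [(float(z), _ellipse(0, 0, body_ax, body_ay))
                           for z in zc], role="body"),
        Structure("prostate",
                  _ellipsoid_contours((0, 0, 0), (2.0, 2.0, 1.75), zc),
                  role="target"),
        Structure("urethra", _tube_contours(0.0, 0.0, 0.3, -1.75, 1.75, zc),
                  role="oar"),
        Structure("rectum", _tube_contours(0.0, -3.2, 1.0, -4.0, 4.0, zc),
                  role="oar"),
        Structure("bladder",
                  _ellipsoid_contours((0, 3.2, 2.0), (2.4, 1.8, 1.9), zc),
                  role="oar"),
    ])
    # 17 needle positions: center + ring of 6 at 1.0 cm + ring of 10 at 1.8
    offsets = [(0.0, 0.0)]
    offsets += [(np.cos(a), np.sin(a))
                for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    offsets += [(1.8 * np.cos(a), 1.8 * np.sin(a))
                for a in np.linspace(0, 2 * np.pi, 10, endpoint=False)
                ]
    dwells = []
    for ci, (ox, oy) in enumerate(offsets):
        n_dwell = 7 if ci < 9 else 6  # 9*7 + 8*6 = 111
        z_lo = -0.25 * (n_dwell - 1)
        pts = [np.array([ox, oy, z_lo + 0.5 * k]) for k in range(n_dwell)]
        rots = catheter_orientation(pts)
        # peripheral and end dwells weighted longer, as a planner would
        radial = np.hypot(ox, oy) / 1.8
        zrel = np.abs(np.linspace(-1, 1, n_dwell))
        times = ((4.0 + 8.0 * radial**2 + 3.0 * zrel**2)
                 * rng.uniform(0.9, 1.1, size=n_dwell))
        for p, r, t in zip(pts, rots, times):
            dwells.append(DwellPosition(position=p, orientation=r,
                                        dwell_time=float(t),
                                        catheter_id=f"cath-{ci + 1:02d}"))
    # prescription at the target surface midway between peripheral needles
    plan = Plan(dwells=dwells, prescription_dose=15.0,
                prescription_point=np.array(
                    [2.0 * np.cos(np.pi / 10), 2.0 * np.sin(np.pi / 10),
                     0.0]),
                name="prostate_like")
    return SyntheticCase(geometry=geom, intensity=intensity,
                         structures=structures, plan=plan,
                         name="prostate_like")


def make_lung_case(seed: int = 0, scale: str = "reduced") -> SyntheticCase:
    """Palliative endobronchial implant: one catheter, 19 dwells, 5 Gy at
    1 cm from the catheter."""
    rng = np.random.default_rng(seed)
    if scale == "full":
        shape, spacing = (140, 140, 80), (0.25, 0.25, 0.255)
    else:
        shape, spacing = (70, 70, 40), (0.5, 0.5, 0.51)
    geom = GridGeometry.centered(shape, spacing)
    zc = geom.voxel_centers(2)
    xs, ys, zs = geom.center_grid()
    body_ax, body_ay = 16.0, 11.0
    intensity = np.where(
        (xs / body_ax) ** 2 + (ys / body_ay) ** 2 <= 1.0, 0.0, -1000.0)
    lung_contours = {"lung_left": [], "lung_right": []}
    for sign, name in ((-1.0, "lung_left"), (1.0, "lung_right")):
        lung = (((xs - sign * 6.0) / 4.5) ** 2 + (ys / 6.5) ** 2
                + (zs / 9.0) ** 2 <= 1.0)
        intensity[lung] = -800.0
        lung_contours[name] = _ellipsoid_contours(
            (sign * 6.0, 0.0, 0.0), (4.5, 6.5, 9.0), zc)
    bronchus = (xs**2 + ys**2 <= 0.8**2) & (zs >= 0.0)
    intensity[bronchus] = -900.0
    structures = StructureSet([
        Structure("body", [(float(z), _ellipse(0, 0, body_ax, body_ay))
                           for z in zc], role="body"),
        Structure("lung_left", lung_contours["lung_left"], role="oar"),
        Structure("lung_right", lung_contours["lung_right"], role="oar"),
        Structure("bronchus", _tube_contours(0.0, 0.0, 0.8, 0.0,
                                             float(zc[-1]), zc),
                  role="oar"),
    ])
    # catheter path: down the bronchus then curving into the left lung
    t = np.linspace(0.0, 1.0, 19)
    path = np.stack([
        -4.5 * t**2,  # curves toward -x
        0.4 * np.sin(np.pi * t),
        8.0 - 9.5 * t,
    ], axis=1)
    rots = catheter_orientation(path)
    times = rng.uniform(3.0, 10.0, size=len(path))
    dwells = [DwellPosition(position=p, orientation=r, dwell_time=float(tt),
                            catheter_id="cath-01")
              for p, r, tt in zip(path, rots, times)]
    mid = path[9]
    plan = Plan(dwells=dwells, prescription_dose=5.0,
                prescription_point=mid + np.array([0.0, 1.0, 0.0]),
                name="lung_like")
    return SyntheticCase(geometry=geom, intensity=intensity,
                         structures=structures, plan=plan, name="lung_like")


def generate_fixture(kind: str, scale: str = "reduced", seed: int = 0,
                     outdir="fixtures") -> dict:
    """Write the fixture files for one scenario; returns the path map.

    Benchmark scenes are written as a scene-descriptor YAML-style text
    file; clinical cases write image (npy), structures (JSON, mm) and plan
    (JSON, mm).  Outputs are deterministic in (kind, scale, seed).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"expected one of {FIXTURE_KINDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if kind.startswith("testcase"):
        case = int(kind[-1])
        doc = {
            "kind": "brachymc-scene",
            "format_version": 1,
            "case": case,
            "scale": scale,
            "voxel_mm": 1.0,
            "source": "generic_hdr",
            "seed": int(seed),
        }
        p = outdir / f"{kind}_{scale}.json"
        p.write_text(json.dumps(doc, indent=1, sort_keys=True))
        paths["scene"] = p
        return paths
    case = (make_prostate_case(seed, scale) if kind == "prostate_like"
            else make_lung_case(seed, scale))
    img = outdir / f"{kind}_{scale}_image.npy"
    np.save(img, case.intensity)
    meta = outdir / f"{kind}_{scale}_grid.json"
    meta.write_text(json.dumps({
        "kind": "brachymc-grid", "format_version": 1,
        "shape": list(case.geometry.shape),
        "spacing_mm": [s * 10.0 for s in case.geometry.spacing],
        "origin_mm": [o * 10.0 for o in case.geometry.origin],
        "seed": int(seed),
    }, indent=1, sort_keys=True))
    structs = outdir / f"{kind}_{scale}_structures.json"
    structures_to_json(case.structures, structs)
    plan = outdir / f"{kind}_{scale}_plan.json"
    plan_to_json(case.plan, plan)
    paths.update({"image": img, "grid": meta, "structures": structs,
                  "plan": plan})
    return paths
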