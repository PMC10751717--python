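"""Shared fixtures; expensive Monte Carlo runs are session-scoped."""
from __future__ import annotations

import numpy as np
import pytest

from brachymc.benchmark import build_test_case
from brachymc.engine import run_capsule_scene
from brachymc.tallies import finalize_uncertainty


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tc1_dual_run():
    """Reduced test-case-1 run with both tallies (shared across tests).

    Returns (scene, tlke mean, tlke rel-unc, analogue mean, analogue
    rel-unc, radius grid, n_histories).
    """
    n = 1_500_000
    scene = build_test_case(1, voxel_mm=1.0, scale="reduced")
    tl, an = scene.make_grids(analogue=True)
    run_capsule_scene(scene, n, seed=424242, tlke_grid=tl, analogue_grid=an)
    mtl, rtl, _ = finalize_uncertainty(tl)
    man, ran_, _ = finalize_uncertainty(an)
    xs, ys, zs = scene.scoring_geometry.center_grid()
    r = np.sqrt(xs**2 + ys**2 + zs**2)
    return scene, mtl, rtl, man, ran_, r, n
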