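"""Sampling physics and the reference transport loop."""
import numpy as np
import pytest
from scipy import stats

from brachymc import _kernels as K
from brachymc.geometry import GridGeometry, SourceCapsule, VoxelPhantom
from brachymc.materials import load_material, load_table
from brachymc.tallies import DoseGrid, TallySet
from brachymc.transport import (MEC2_KEV, Photon, TransportConfig,
                                sample_compton, sample_rayleigh,
                                select_interaction, transport_history,
                                woodcock_step)

WATER = load_table("water")
RHO_W = load_material("water").density


def kn_quadrature_mean_fraction(energy, n=40001):
    """Klein-Nishina mean scattered-energy fraction by quadrature."""
    mu = np.linspace(-1.0, 1.0, n)
    e = energy / MEC2_KEV
    k = 1.0 / (1.0 + e * (1.0 - mu))
    dcs = k**2 * (k + 1.0 / k - (1.0 - mu**2))
    return np.trapezoid(dcs * k, mu) / np.trapezoid(dcs, mu)


def _kernel_state(seed=123):
    s = np.empty(2, dtype=np.uint64)
    K.pcg_seed(s, seed, 54321)
    return s


class TestCompton:
    def test_backscatter_kinematic_minimum(self, rng):
        e, cost = [], []
        for _ in range(2000):
            en, c = sample_compton(300.0, rng)
            e.append(en)
            cost.append(c)
        emin = 300.0 / (1.0 + 2.0 * 300.0 / MEC2_KEV)
        assert emin == pytest.approx(137.98, abs=0.01)
        assert min(e) >= emin - 1e-9
        # the sampled energies obey the kinematic relation exactly
        for en, c in zip(e[:100], cost[:100]):
            assert en == pytest.approx(
                300.0 / (1.0 + 300.0 / MEC2_KEV * (1.0 - c)), rel=1e-12)

    def test_thomson_limit_energy_unchanged(self, rng):
        for _ in range(200):
            en, _ = sample_compton(1.0, rng)
            assert en == pytest.approx(1.0, rel=5e-3)

    def test_mean_scattered_fraction_matches_quadrature(self):
        """1e6 kernel samples at 350 keV vs numerical KN integration."""
        s = _kernel_state()
        n = 1_000_000
        acc = np.empty(n)
        for i in range(n):
            en, _ = K.sample_kn(350.0, s)
            acc[i] = en / 350.0
        expected = kn_quadrature_mean_fraction(350.0)
        se = acc.std() / np.sqrt(n)
        assert abs(acc.mean() - expected) < 3 * se


class TestRayleigh:
    def test_forward_peaked_at_high_energy(self, rng):
        cs = [sample_rayleigh(350.0, "water", rng) for _ in range(300)]
        assert np.mean(cs) > 0.8  # strongly forward at Ir-192 energies

    def test_thomson_shape_in_low_momentum_limit(self, rng):
        """At low photon energy the form factor is nearly flat (F -> Z)
        and the angular distribution approaches the Thomson (1 + cos^2)
        shape: E[cos^2] -> 0.4, E[cos] -> 0."""
        cs = np.array([sample_rayleigh(1.2, "water", rng)
                       for _ in range(4000)])
        assert abs(cs.mean()) < 0.05  # residual screening bias is small
        assert abs((cs**2).mean() - 0.4) < 0.05

    def test_mean_cosine_matches_form_factor_quadrature(self):
        """Kernel sampler at 350 keV in water vs quadrature over the
        shipped (screened Thomas-Fermi) form factor."""
        from brachymc.materials import form_factor_squared
        mat = load_material("water")
        E = 350.0
        xe = E / 12.39842
        cost = np.linspace(-1.0, 1.0, 200_001)
        x = xe * np.sqrt((1.0 - cost) / 2.0)
        pdf = (1.0 + cost**2) * form_factor_squared(mat, x)
        expected = np.trapezoid(cost * pdf, cost) / np.trapezoid(pdf, cost)
        from brachymc.engine import MaterialsPack
        pack = MaterialsPack.build(["water"])
        s = _kernel_state(9)
        n = 200_000
        acc = np.empty(n)
        for i in range(n):
            acc[i] = K.sample_rayleigh_cos(E, 0, pack.ff_x2, pack.ff_cum, s)
        se = acc.std() / np.sqrt(n)
        assert abs(acc.mean() - expected) < 4 * se


class TestSelectInteraction:
    def test_probabilities_proportional_to_partials(self, rng):
        counts = {"photoelectric": 0, "compton": 0, "rayleigh": 0}
        n = 30_000
        for _ in range(n):
            counts[select_interaction(60.0, WATER, rng)] += 1
        pe = WATER.lookup(60.0, "photoelectric")
        co = WATER.lookup(60.0, "compton")
        ra = WATER.lookup(60.0, "rayleigh")
        tot = pe + co + ra
        p = stats.chisquare(
            [counts["photoelectric"], counts["compton"], counts["rayleigh"]],
            [n * pe / tot, n * co / tot, n * ra / tot]).pvalue
        assert p > 0.01

    def test_photoelectric_dominates_at_cutoff_energy(self, rng):
        kinds = {select_interaction(1.0, WATER, rng) for _ in range(500)}
        assert kinds == {"photoelectric"}


class TestWoodcock:
    def make_slab(self):
        geom = GridGeometry((1, 1, 1), (4.0, 50.0, 50.0), (0.0, -25.0, -25.0))
        return VoxelPhantom.homogeneous(geom, "water", RHO_W)

    def test_homogeneous_every_tentative_collision_is_real(self, rng):
        """With margin 1 the acceptance ratio is 1: the first tentative
        collision is accepted, so interaction depths are exponential."""
        ph = self.make_slab()
        tables = {"water": WATER}
        mu = WATER.lookup(350.0, "total") * RHO_W
        depths = []
        for _ in range(4000):
            p = Photon(position=np.array([1e-12, 0.0, 0.0]),
                       direction=np.array([1.0, 0.0, 0.0]), energy=350.0)
            status, point, idx, _ = woodcock_step(p, ph, tables, rng,
                                                  margin=1.0)
            if status == "interact":
                depths.append(point[0])
        # KS against the truncated exponential on [0, 4]
        cdf = lambda x: ((1 - np.exp(-mu * np.asarray(x)))
                         / (1 - np.exp(-mu * 4.0)))
        assert stats.kstest(depths, cdf).pvalue > 0.01

    def test_pencil_beam_slab_attenuation(self, rng):
        """Fraction crossing a 4 cm water slab without interacting follows
        exp(-mu t) within 3 standard errors."""
        ph = self.make_slab()
        tables = {"water": WATER}
        n = 20_000
        exits = 0
        for _ in range(n):
            p = Photon(position=np.array([1e-12, 0.0, 0.0]),
                       direction=np.array([1.0, 0.0, 0.0]), energy=350.0)
            status, *_ = woodcock_step(p, ph, tables, rng)
            exits += status == "exit"
        mu = WATER.lookup(350.0, "total") * RHO_W
        expected = np.exp(-mu * 4.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(exits / n - expected) < 3 * se

    def test_layered_first_interaction_depth_matches_cdf_oracle(self, rng):
        """Two-material slab: first-interaction depths follow the
        piecewise-exponential inverse-CDF law."""
        geom = GridGeometry((2, 1, 1), (2.0, 50.0, 50.0), (0.0, -25.0, -25.0))
        ids = np.array([[[0]], [[1]]], dtype=np.int32)
        rho = np.array([[[RHO_W]], [[1.92]]])
        ph = VoxelPhantom(geometry=geom, material_ids=ids, densities=rho,
                          materials=["water", "bone_cortical"])
        tables = {"water": WATER, "bone_cortical":
                  load_table("bone_cortical")}
        mu1 = WATER.lookup(200.0, "total") * RHO_W
        mu2 = tables["bone_cortical"].lookup(200.0, "total") * 1.92
        depths = []
        for _ in range(6000):
            p = Photon(position=np.array([1e-12, 0.0, 0.0]),
                       direction=np.array([1.0, 0.0, 0.0]), energy=200.0)
            status, point, *_ = woodcock_step(p, ph, tables, rng)
            if status == "interact":
                depths.append(point[0])

        def cdf(x):
            x = np.asarray(x, dtype=float)
            c = np.where(x <= 2.0, 1 - np.exp(-mu1 * x),
                         1 - np.exp(-2 * mu1) * np.exp(-mu2 * (x - 2.0)))
            cmax = 1 - np.exp(-2 * mu1) * np.exp(-mu2 * 2.0)
            return c / cmax

        assert stats.kstest(depths, cdf).pvalue > 0.01


class TestTransportHistory:
    def _scene(self):
        geom = GridGeometry.centered(1, 10.0)
        ph = VoxelPhantom.homogeneous(geom, "water", RHO_W)
        score = GridGeometry.centered(11, 0.5)
        ts = TallySet(
            tlke=DoseGrid(geometry=score),
            analogue=DoseGrid(geometry=score,
                              densities=np.full(score.shape, RHO_W)))
        return ph, ts

    def test_miss_gives_zero_tallies(self, rng):
        ph, ts = self._scene()
        p = Photon(position=np.array([0.0, 0.0, 5.0001]),
                   direction=np.array([0.0, 0.0, 1.0]), energy=350.0)
        res = transport_history(p, ph, None, ts, TransportConfig(), rng)
        assert res.escaped == pytest.approx(350.0)
        assert res.transferred == 0.0
        ts.tlke.flush()
        assert ts.tlke.accum_sum.sum() == 0.0

    def test_energy_conservation_per_history(self, rng):
        ph, ts = self._scene()
        for h in range(300):
            p = Photon(position=np.zeros(3),
                       direction=np.array([0.0, 0.0, 1.0]), energy=350.0)
            res = transport_history(p, ph, None, ts, TransportConfig(),
                                    rng, history=h)
            assert (res.escaped + res.transferred
                    == pytest.approx(res.emitted, rel=1e-9))

    def test_analogue_total_equals_transferred_bookkeeping(self, rng):
        """Grid-total analogue deposit per history equals the transport
        ledger's transferred energy (interactions all land on the grid)."""
        geom = GridGeometry.centered(1, 4.0)
        ph = VoxelPhantom.homogeneous(geom, "water", RHO_W)
        score = GridGeometry.centered(8, 0.5)
        mass = RHO_W * score.voxel_volume
        for h in range(40):
            ts = TallySet(analogue=DoseGrid(
                geometry=score, densities=np.full(score.shape, RHO_W)))
            p = Photon(position=np.zeros(3),
                       direction=np.array([0.0, 0.0, 1.0]), energy=100.0)
            res = transport_history(p, ph, None, ts, TransportConfig(),
                                    rng, history=h)
            ts.analogue.flush()
            total_ev = ts.analogue.accum_sum.sum() * mass
            assert total_ev == pytest.approx(res.transferred * 1000.0,
                                             rel=1e-9)

    def test_nonfinite_state_hard_failure(self, rng):
        ph, ts = self._scene()
        p = Photon(position=np.zeros(3),
                   direction=np.array([0.0, 0.0, 1.0]), energy=350.0)
        p.position = np.array([np.nan, 0.0, 0.0])
        with pytest.raises(RuntimeError, match="non-finite"):
            transport_history(p, ph, None, ts, TransportConfig(), rng)

    def test_capsule_tracking_attenuates_and_conserves(self, rng):
        """Photons born in the capsule core either die inside or emerge;
        the energy ledger still balances."""
        geom = GridGeometry.centered(1, 10.0)
        ph = VoxelPhantom.homogeneous(geom, "water", RHO_W)
        ts = TallySet()
        cap = SourceCapsule(core_radius=0.03, core_half_length=0.175,
                            capsule_radius=0.045, capsule_half_length=0.195)
        survived = 0
        for h in range(150):
            p = Photon(position=np.zeros(3),
                       direction=np.array([1.0, 0.0, 0.0]), energy=350.0)
            res = transport_history(p, ph, cap, ts, TransportConfig(), rng,
                                    history=h)
            assert (res.escaped + res.transferred
                    == pytest.approx(res.emitted, rel=1e-9))
            survived += res.escaped > 0 or res.n_interactions > 0
        assert 0 < survived <= 150


class TestPhotonValidation:
    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            Photon(position=np.zeros(3), direction=np.array([1.0, 1.0, 0.0]),
                   energy=100.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            Photon(position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                   energy=100.0, weight=-0.5)

    def test_cutoff_below_1kev_rejected(self):
        with pytest.raises(ValueError):
            TransportConfig(photon_cutoff=0.5)
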