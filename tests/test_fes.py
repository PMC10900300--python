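"""Collective variables, Boltzmann inversion and basin free energies."""

import numpy as np
import pytest

import deltakern as dk
from deltakern import fixtures as fx
from deltakern.constants import KB_KCAL_MOL_K
from deltakern.fes import (
    AnalysisError,
    GeometryError,
    basin_delta_g_from_free_energy,
    fes_from_cvs,
)
from deltakern.sampler import run_metropolis


def _structure_from_coords(coords, elements=None):
    n = len(coords)
    elements = elements or ("N",) + ("C",) * (n - 1)
    return dk.Structure(elements, np.asarray(coords, float))


@pytest.fixture
def simple_spec():
    return dk.CVSpec(n_index=0, group_indices=(4, 5, 6), plane_indices=(1, 2, 3),
                     orientation_reference=7)


class TestCVd:
    def test_minimum_over_group(self):
        coords = np.zeros((4, 3))
        coords[1] = [3.0, 0, 0]
        coords[2] = [0, 2.5, 0]
        coords[3] = [0, 0, 7.1]
        s = _structure_from_coords(coords)
        spec = dk.CVSpec(0, (1, 2, 3), (1, 2, 3))
        assert dk.cv_d(s, spec) == pytest.approx(2.5)

    def test_single_member_group_is_pair_distance(self, rng):
        coords = rng.normal(scale=3.0, size=(5, 3))
        s = _structure_from_coords(coords)
        spec = dk.CVSpec(0, (4,), (1, 2, 3))
        assert dk.cv_d(s, spec) == pytest.approx(
            np.linalg.norm(coords[4] - coords[0])
        )

    def test_matches_bruteforce_on_random_structure(self, rng):
        coords = rng.normal(scale=6.0, size=(50, 3))
        s = dk.Structure(("N",) + ("C",) * 49, coords)
        group = tuple(range(20, 45))
        spec = dk.CVSpec(0, group, (1, 2, 3))
        brute = min(
            float(np.linalg.norm(coords[g] - coords[0])) for g in group
        )
        assert dk.cv_d(s, spec) == brute

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dk.CVSpec(0, (), (1, 2, 3))


class TestCVTheta:
    def test_unit_normal_distance(self):
        coords = np.array(
            [[0.2, 0.2, 1.0], [0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0],
             [5.0, 5.0, 0.0]]
        )
        s = _structure_from_coords(coords)
        spec = dk.CVSpec(0, (4,), (1, 2, 3))
        assert abs(dk.cv_theta(s, spec)) == pytest.approx(1.0)

    def test_in_plane_nitrogen_gives_zero(self):
        coords = np.array(
            [[0.3, 0.4, 0.0], [0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0],
             [2.0, 2.0, 2.0]]
        )
        s = _structure_from_coords(coords)
        spec = dk.CVSpec(0, (4,), (1, 2, 3))
        assert dk.cv_theta(s, spec) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_reflection_flips_sign(self, rng):
        """With the ordering-based convention theta is a chirality-like
        quantity: reflection flips the sign, keeps the magnitude."""
        coords = rng.normal(scale=2.0, size=(5, 3))
        s = _structure_from_coords(coords)
        spec = dk.CVSpec(0, (4,), (1, 2, 3), orientation_reference=None)
        mirrored = coords.copy()
        mirrored[:, 2] *= -1.0
        sm = _structure_from_coords(mirrored)
        t, tm = dk.cv_theta(s, spec), dk.cv_theta(sm, spec)
        assert tm == pytest.approx(-t, abs=1e-10)
        assert abs(tm) == pytest.approx(abs(t), abs=1e-10)

    def test_rigid_motion_invariance_with_reference(self, rng, rigid_motion):
        coords = rng.normal(scale=2.0, size=(8, 3))
        s = _structure_from_coords(coords, ("N",) + ("C",) * 7)
        spec = dk.CVSpec(0, (4, 5), (1, 2, 3), orientation_reference=6)
        moved = rigid_motion(s, seed=3)
        assert dk.cv_theta(moved, spec) == pytest.approx(
            dk.cv_theta(s, spec), abs=1e-10
        )
        assert dk.cv_d(moved, spec) == pytest.approx(dk.cv_d(s, spec), abs=1e-10)

    def test_collinear_plane_rejected(self):
        coords = np.array(
            [[0.0, 0, 1.0], [0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]]
        )
        s = _structure_from_coords(coords)
        spec = dk.CVSpec(0, (4,), (1, 2, 3))
        with pytest.raises(GeometryError):
            dk.cv_theta(s, spec)


class TestBuildFES:
    def test_uniform_samples_give_flat_surface(self):
        rng = np.random.default_rng(8)
        n = 200_000
        d = rng.uniform(0, 1, n)
        t = rng.uniform(-1, 1, n)
        grid = fes_from_cvs(d, t, bins=(8, 8), temperature=300.0,
                            ranges=((0, 1), (-1, 1)))
        kt = KB_KCAL_MOL_K * 300.0
        per_bin = n / 64
        sd = kt / np.sqrt(per_bin)  # delta-method sd of -kT ln(count)
        assert grid.occupied.all()
        assert grid.free_energy.min() == 0.0
        assert grid.free_energy.max() <= 3 * sd * 3  # max over 64 bins, loose
    def test_gaussian_samples_recover_curvature(self):
        """-kT ln rho of a 2D Gaussian is quadratic with Hessian kT Sigma^-1."""
        rng = np.random.default_rng(4)
        cov = np.array([[0.09, 0.03], [0.03, 0.16]])
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=400_000)
        temperature = 300.0
        kt = KB_KCAL_MOL_K * temperature
        grid = fes_from_cvs(xy[:, 0], xy[:, 1], bins=(40, 40),
                            temperature=temperature)
        dc = 0.5 * (grid.d_edges[:-1] + grid.d_edges[1:])
        tc = 0.5 * (grid.theta_edges[:-1] + grid.theta_edges[1:])
        mask = grid.counts > 0.02 * grid.counts.max()
        ii, jj = np.nonzero(mask)
        x, y = dc[ii], tc[jj]
        f = grid.free_energy[mask]
        A = np.column_stack(
            [x * x, x * y, y * y, x, y, np.ones_like(x)]
        )
        coef, *_ = np.linalg.lstsq(A, f, rcond=None)
        hess = np.array([[2 * coef[0], coef[1]], [coef[1], 2 * coef[2]]])
        expected = kt * np.linalg.inv(cov)
        np.testing.assert_allclose(hess, expected, rtol=0.10)

    def test_sample_order_independent(self, rng):
        d = rng.normal(size=5000)
        t = rng.normal(size=5000)
        g1 = fes_from_cvs(d, t, bins=(12, 12), ranges=((-4, 4), (-4, 4)))
        perm = rng.permutation(5000)
        g2 = fes_from_cvs(d[perm], t[perm], bins=(12, 12), ranges=((-4, 4), (-4, 4)))
        np.testing.assert_array_equal(g1.counts, g2.counts)
        np.testing.assert_array_equal(g1.free_energy, g2.free_energy)

    def test_gauge_and_empty_bin_flags(self, rng):
        d = np.concatenate([rng.normal(-2, 0.1, 500), rng.normal(2, 0.1, 500)])
        t = rng.normal(size=1000)
        grid = fes_from_cvs(d, t, bins=(20, 10))
        assert grid.free_energy[grid.occupied].min() == 0.0
        assert np.isinf(grid.free_energy[~grid.occupied]).all()

    def test_single_bin_warns(self):
        with pytest.warns(UserWarning, match="single bin"):
            fes_from_cvs([1.0, 1.0], [0.5, 0.5], bins=(5, 5))

    def test_doubling_samples_converges(self):
        """Basin free-energy differences stabilise as sampling grows."""
        rng = np.random.default_rng(12)
        pot = fx.DoubleWell1DPotential()
        beta_t = 300.0

        def dg_from_samples(n):
            xs = _dw_samples(rng, pot, n)
            grid = fes_from_cvs(
                xs, np.zeros_like(xs), bins=(24, 1),
                ranges=((-2.5, 2.5), (-1, 1)), temperature=beta_t,
            )
            centers = 0.5 * (grid.d_edges[:-1] + grid.d_edges[1:])
            left = np.broadcast_to((centers < 0)[:, None], grid.counts.shape)
            return dk.basin_delta_g(grid, left, ~left)

        d1 = dg_from_samples(20_000)
        d2 = dg_from_samples(40_000)
        assert abs(d1 - d2) < 0.05

    def test_build_fes_from_structures(self, rng):
        structs = []
        for _ in range(50):
            coords = rng.normal(scale=2.0, size=(5, 3))
            structs.append(_structure_from_coords(coords))
        spec = dk.CVSpec(0, (4,), (1, 2, 3), orientation_reference=None)
        grid = dk.build_fes(structs, spec, bins=(6, 6))
        assert grid.counts.sum() == 50


def _dw_samples(rng, pot, n):
    """Direct 1D rejection-free sampling via inverse-CDF on a fine grid."""
    from deltakern.constants import KB_KCAL_MOL_K

    beta = 1.0 / (KB_KCAL_MOL_K * 300.0)
    x = np.linspace(-3.0, 3.0, 4001)
    w = np.exp(-beta * np.vectorize(pot.v_x)(x))
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    u = rng.uniform(size=n)
    return np.interp(u, cdf, x)


class TestBasinDeltaG:
    def _grid_from_counts(self, counts, temperature=300.0):
        counts = np.asarray(counts)
        kt = KB_KCAL_MOL_K * temperature
        with np.errstate(divide="ignore"):
            f = np.where(counts > 0, -kt * np.log(np.maximum(counts, 1)), np.inf)
        f = f - f[counts > 0].min()
        f[counts <= 0] = np.inf
        return dk.FESGrid(
            np.arange(counts.shape[0] + 1.0), np.arange(counts.shape[1] + 1.0),
            f, counts.astype(int), temperature,
        )

    def test_identical_regions_give_zero(self):
        grid = self._grid_from_counts([[5, 3], [2, 8]])
        mask = np.ones_like(grid.counts, bool)
        assert dk.basin_delta_g(grid, mask, mask) == 0.0

    def test_closed_form_population_ratio(self):
        """At k_B T = 1 (T = 1/k_B), populations in ratio e give Delta G = 1."""
        t_unit = 1.0 / KB_KCAL_MOL_K
        c = np.zeros((2, 2), int)
        c[0, 0] = 27_182_818
        c[1, 1] = 10_000_000
        grid = self._grid_from_counts(c, temperature=t_unit)
        a = np.zeros((2, 2), bool); a[0, 0] = True
        b = np.zeros((2, 2), bool); b[1, 1] = True
        assert dk.basin_delta_g(grid, a, b) == pytest.approx(1.0, abs=1e-6)
        assert dk.basin_delta_g(grid, b, a) == pytest.approx(-1.0, abs=1e-6)

    def test_two_algebraic_routes_agree(self, rng):
        counts = rng.integers(0, 50, size=(10, 10))
        counts[0, 0] = 40
        counts[9, 9] = 25
        grid = self._grid_from_counts(counts)
        a = np.zeros_like(counts, bool); a[:5] = True
        b = ~a
        d1 = dk.basin_delta_g(grid, a, b)
        d2 = basin_delta_g_from_free_energy(grid, a, b)
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_empty_region_rejected(self):
        grid = self._grid_from_counts([[5, 0], [0, 8]])
        a = np.zeros((2, 2), bool); a[0, 1] = True
        b = np.ones((2, 2), bool)
        with pytest.raises(AnalysisError):
            dk.basin_delta_g(grid, a, b)

    def test_double_well_sampler_matches_quadrature(self):
        """Delta G across the barrier from MC sampling agrees with the
        quadrature oracle within Monte-Carlo error."""
        pot = fx.DoubleWell1DPotential()
        cfg = dk.MCConfig(n_steps=400_000, step_sigma=0.35, seed=3,
                          snapshot_stride=100)
        traj = run_metropolis(pot, cfg, dk.Structure(("H",), np.array([[1.0, 0, 0]])))
        xs = np.array([c[0, 0] for c in traj.snapshots[0]])[100:]
        grid = fes_from_cvs(xs, np.zeros_like(xs), bins=(30, 1),
                            ranges=((-2.5, 2.5), (-1, 1)), temperature=300.0)
        centers = 0.5 * (grid.d_edges[:-1] + grid.d_edges[1:])
        left = np.broadcast_to((centers < 0)[:, None], grid.counts.shape)
        dg = dk.basin_delta_g(grid, left, ~left)
        p_left, p_right = fx.double_well_populations(pot, 300.0)
        kt = KB_KCAL_MOL_K * 300.0
        dg_exact = kt * np.log(p_left / p_right)
        ind = (xs < 0).astype(float)
        usable = (len(ind) // 40) * 40
        sem_p = ind[:usable].reshape(40, -1).mean(axis=1).std(ddof=1) / np.sqrt(40)
        p = ind.mean()
        sem_dg = kt * sem_p / (p * (1 - p))  # delta method on ln(p/(1-p))
        assert dg == pytest.approx(dg_exact, abs=3 * sem_dg + 1e-3)

    def test_minimum_mode_antisymmetric(self, rng):
        counts = rng.integers(1, 60, size=(8, 8))
        grid = self._grid_from_counts(counts)
        a = np.zeros_like(counts, bool); a[:4] = True
        b = ~a
        assert dk.basin_delta_g(grid, a, b, mode="minimum") == pytest.approx(
            -dk.basin_delta_g(grid, b, a, mode="minimum")
        )


def test_grid_roundtrip(tmp_path, rng):
    d = rng.normal(size=2000)
    t = rng.normal(size=2000)
    grid = fes_from_cvs(d, t, bins=(9, 7))
    path = tmp_path / "fes.dat"
    grid.write(path)
    back = dk.FESGrid.read(path)
    np.testing.assert_array_equal(back.counts, grid.counts)
    finite = np.isfinite(grid.free_energy)
    np.testing.assert_allclose(
        back.free_energy[finite], grid.free_energy[finite], rtol=1e-9
    )
    assert np.isinf(back.free_energy[~finite]).all()
    assert back.temperature == grid.temperature
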