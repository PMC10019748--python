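"""Reaction–diffusion solver: Thomas oracle equivalence, decay accuracy,
Dirichlet clamping, conservation and qualitative PDE properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepasim.mesh import OutsideDomainError, VoxelMesh
from hepasim.microenv import Microenvironment, SourceSinkTerm, Substrate
from hepasim.tridiag import TridiagonalOperator, ZeroPivotError, thomas_solve


def make_env(n=8, dx=10.0, D=100.0, lam=0.0, init=0.0):
    mesh = VoxelMesh(n, n, n, dx)
    return Microenvironment(mesh, [Substrate("s", D=D, lam=lam, initial_value=init)])


# ------------------------------------------------------------------ tridiag
class TestThomas:
    def test_identity_system(self):
        rhs = np.array([3.0, -1.0, 2.5, 0.0])
        x = thomas_solve(np.zeros(4), np.ones(4), np.zeros(4), rhs)
        np.testing.assert_allclose(x, rhs)

    def test_matches_dense_solver(self):
        # diag 2, off-diag -1, rhs (1,0,0,1) -> (1,1,1,1) by dense oracle
        n = 4
        a = np.full(n, -1.0)
        b = np.full(n, 2.0)
        c = np.full(n, -1.0)
        rhs = np.array([1.0, 0.0, 0.0, 1.0])
        dense = np.diag(b) + np.diag(a[1:], -1) + np.diag(c[:-1], 1)
        expected = np.linalg.solve(dense, rhs)
        np.testing.assert_allclose(thomas_solve(a, b, c, rhs), expected, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=2, max_value=50), st.integers(0, 2**31 - 1))
    def test_random_diagonally_dominant_residual(self, n, seed):
        r = np.random.default_rng(seed)
        sub = r.uniform(-1, 1, n)
        sup = r.uniform(-1, 1, n)
        diag = np.abs(sub) + np.abs(sup) + r.uniform(1.0, 2.0, n)
        rhs = r.uniform(-5, 5, n)
        x = thomas_solve(sub, diag, sup, rhs)
        dense = np.diag(diag) + np.diag(sub[1:], -1) + np.diag(sup[:-1], 1)
        assert np.max(np.abs(dense @ x - rhs)) < 1e-10

    def test_inputs_not_corrupted(self):
        sub, diag, sup = -np.ones(5), np.full(5, 3.0), -np.ones(5)
        rhs = np.arange(5.0)
        copies = [a.copy() for a in (sub, diag, sup, rhs)]
        thomas_solve(sub, diag, sup, rhs)
        for a, c in zip((sub, diag, sup, rhs), copies):
            np.testing.assert_array_equal(a, c)

    def test_zero_pivot_raises_with_index(self):
        with pytest.raises(ZeroPivotError) as err:
            thomas_solve(np.zeros(3), np.array([1.0, 0.0, 1.0]), np.zeros(3), np.ones(3))
        assert err.value.index == 1

    def test_batched_operator_matches_dense(self, rng):
        op = TridiagonalOperator(9, a=0.37)
        rhs = rng.uniform(0, 1, size=(5, 9))
        x = op.solve(rhs)
        dense = op.dense()
        for k in range(5):
            np.testing.assert_allclose(x[k], np.linalg.solve(dense, rhs[k]),
                                       rtol=1e-12, atol=1e-14)


# ---------------------------------------------------------------- diffusion
class TestDiffusion:
    def test_pure_decay_closed_form(self):
        env = make_env(n=4, D=0.0, lam=0.1, init=1.0)
        for _ in range(100):
            env.step_diffusion(0.01)
        expected = np.exp(-0.1 * 1.0)
        assert np.allclose(env.conc[0], env.conc[0].flat[0])  # stays uniform
        assert abs(env.conc[0].flat[0] - expected) / expected < 1e-3

    def test_decay_error_is_first_order_in_dt(self):
        # halving dt halves the pure-decay error
        errs = []
        for dt in (0.02, 0.01):
            env = make_env(n=2, D=0.0, lam=0.5, init=1.0)
            for _ in range(int(round(1.0 / dt))):
                env.step_diffusion(dt)
            errs.append(abs(env.conc[0].flat[0] - np.exp(-0.5)))
        ratio = errs[0] / errs[1]
        assert 1.8 < ratio < 2.2

    def test_lod_sweep_equals_dense_strip_solves(self, rng):
        """One LOD cycle == dense backward-Euler solve per 1-D strip."""
        n, dt = 8, 0.7
        env = make_env(n=n, D=123.0, lam=0.0)
        env.conc[0] = rng.uniform(0.0, 2.0, size=(n, n, n))
        expected = env.conc[0].copy()
        a = 123.0 * dt / env.mesh.dx**2
        dense = TridiagonalOperator(n, a).dense()
        inv = np.linalg.inv(dense)
        for axis in range(3):
            moved = np.moveaxis(expected, axis, -1)
            moved[...] = moved @ inv.T
        env.step_diffusion(dt)
        np.testing.assert_allclose(env.conc[0], expected, rtol=1e-10, atol=1e-12)

    def test_mass_conservation_zero_flux(self, rng):
        env = make_env(n=6, D=500.0, lam=0.0)
        env.conc[0] = rng.uniform(0.0, 3.0, size=(6, 6, 6))
        m0 = env.total_mass("s")
        for _ in range(1000):
            env.step_diffusion(0.05)
        assert abs(env.total_mass("s") - m0) / m0 < 1e-10

    def test_maximum_principle(self, rng):
        env = make_env(n=6, D=200.0, lam=0.0)
        env.conc[0] = rng.uniform(0.5, 2.0, size=(6, 6, 6))
        hi, lo = env.conc[0].max(), env.conc[0].min()
        for _ in range(50):
            env.step_diffusion(0.1)
            assert env.conc[0].max() <= hi + 1e-12
            assert env.conc[0].min() >= lo - 1e-12
            assert env.conc[0].min() >= 0.0

    def test_xy_symmetry_preserved(self, rng):
        # the 1-D sweeps along different axes commute exactly, so a field
        # symmetric under x<->y stays symmetric over full LOD cycles
        n = 8
        env = make_env(n=n, D=150.0, lam=0.01)
        field = rng.uniform(0, 1, size=(n, n, n))
        env.conc[0] = 0.5 * (field + field.transpose(1, 0, 2))  # x<->y symmetric
        for _ in range(10):
            env.step_diffusion(0.5)
        np.testing.assert_allclose(env.conc[0], env.conc[0].transpose(1, 0, 2),
                                   rtol=1e-10, atol=1e-12)

    def test_xy_symmetry_with_dirichlet_converges_with_dt(self):
        # with an interior Dirichlet node, per-sweep re-clamping breaks exact
        # x<->y symmetry at finite dt; the asymmetry must vanish as dt -> 0
        def asymmetry(dt):
            env = make_env(n=6, D=150.0)
            env.add_dirichlet_node((2, 2, 3), 1.0)
            for _ in range(int(round(2.0 / dt))):
                env.step_diffusion(dt)
            return np.max(np.abs(env.conc[0] - env.conc[0].transpose(1, 0, 2)))

        a1, a2 = asymmetry(0.5), asymmetry(0.125)
        assert a2 < a1

    def test_nonfinite_raises_named_error(self):
        env = make_env(n=3)
        env.conc[0, 1, 2, 0] = np.nan
        with pytest.raises(FloatingPointError, match=r"'s' at voxel \(1, 2, 0\)"):
            env.step_diffusion(0.1)


# ---------------------------------------------------------------- dirichlet
class TestDirichlet:
    def test_clamp_value_and_bounds(self):
        env = make_env(n=5, D=300.0)
        env.add_dirichlet_node((2, 2, 2), 1.0)
        assert env.conc[0, 2, 2, 2] == 1.0
        for _ in range(50):
            env.step_diffusion(0.2)
        assert env.conc[0, 2, 2, 2] == 1.0
        assert env.conc[0].max() <= 1.0 + 1e-12
        assert env.conc[0].min() >= 0.0

    def test_add_is_idempotent(self):
        env = make_env()
        env.add_dirichlet_node((1, 1, 1), 2.0)
        env.add_dirichlet_node((1, 1, 1), 2.0)
        assert env.dirichlet_voxels == [(1, 1, 1)]

    def test_corner_clamp_persists(self):
        env = make_env(n=4, D=80.0)
        env.add_dirichlet_node((0, 0, 0), 5.0)
        for _ in range(100):
            env.step_diffusion(0.1)
        assert env.conc[0, 0, 0, 0] == 5.0

    def test_remove_unregistered_warns_not_raises(self, caplog):
        env = make_env()
        with caplog.at_level("WARNING"):
            env.remove_dirichlet_node((0, 0, 0))
        assert "not registered" in caplog.text

    def test_remove_releases_voxel(self):
        env = make_env(n=4, D=0.0, lam=1.0)
        env.add_dirichlet_node((1, 1, 1), 4.0)
        env.remove_dirichlet_node((1, 1, 1))
        env.step_diffusion(1.0)
        assert env.conc[0, 1, 1, 1] < 4.0


# ------------------------------------------------------------- source/sink
class TestSourcesSinks:
    def test_pure_sink_monotone_nonnegative(self):
        env = make_env(n=2, init=1.0)
        term = SourceSinkTerm(0, (0, 0, 0), S=0.0, rho_star=0.0, U=5.0, volume=500.0)
        prev = 1.0
        for _ in range(200):
            env.apply_sources_sinks([term], dt=1.0)
            now = env.conc[0, 0, 0, 0]
            assert 0.0 <= now < prev
            prev = now

    def test_secretion_saturation_fixed_point(self):
        env = make_env(n=2, init=1.0)
        term = SourceSinkTerm(0, (0, 0, 0), S=2.0, rho_star=1.0, U=0.0, volume=500.0)
        for _ in range(100):
            env.apply_sources_sinks([term], dt=0.5)
        assert abs(env.conc[0, 0, 0, 0] - 1.0) < 1e-12

    def test_secretion_uptake_steady_state(self):
        # S = U = 0.1, rho* = 1, rho0 = 0 -> rho -> S rho*/(S+U) = 0.5
        mesh = VoxelMesh(1, 1, 1, 10.0)
        env = Microenvironment(mesh, [Substrate("s", D=0.0, lam=0.0)])
        term = SourceSinkTerm(0, (0, 0, 0), S=0.1, rho_star=1.0, U=0.1,
                              volume=mesh.voxel_volume)
        # relaxation rate c (S+U) = 0.2/min; run ~10 time constants
        for _ in range(5000):
            env.apply_sources_sinks([term], dt=0.01)
        assert abs(env.conc[0, 0, 0, 0] - 0.5) < 0.005

    def test_secretion_never_exceeds_rho_star(self):
        env = make_env(n=2, init=0.0)
        term = SourceSinkTerm(0, (0, 0, 0), S=50.0, rho_star=2.0, U=0.0, volume=1000.0)
        for _ in range(100):
            env.apply_sources_sinks([term], dt=10.0)
        assert env.conc[0, 0, 0, 0] <= 2.0 + 1e-12

    def test_out_of_mesh_voxel_raises(self):
        env = make_env(n=2)
        term = SourceSinkTerm(0, (5, 0, 0), S=1.0, rho_star=1.0, U=0.0, volume=10.0)
        with pytest.raises(IndexError):
            env.apply_sources_sinks([term], dt=0.1)


# -------------------------------------------------------------------- sample
class TestSample:
    def test_voxel_center_reads_that_voxel(self):
        env = make_env(n=3, dx=10.0)
        env.conc[0, 1, 2, 0] = 7.0
        assert env.sample(env.mesh.voxel_center((1, 2, 0)), "s") == 7.0

    def test_same_voxel_same_sample(self):
        env = make_env(n=3, dx=10.0)
        env.conc[0, 0, 0, 0] = 3.0
        assert env.sample((1.0, 2.0, 3.0), "s") == env.sample((9.0, 8.0, 0.5), "s")

    def test_uniform_field_any_position(self, rng):
        env = make_env(n=4, dx=5.0, init=1.7)
        pts = rng.uniform(0, 20, size=(20, 3))
        np.testing.assert_allclose(env.sample_many(pts, "s"), 1.7)

    def test_outside_domain_names_axis(self):
        env = make_env(n=2, dx=10.0)
        with pytest.raises(OutsideDomainError, match="axis 'y'"):
            env.sample((5.0, 25.0, 5.0), "s")


class TestMesh:
    def test_voxel_of_inverse_consistent_on_centers(self):
        mesh = VoxelMesh(3, 4, 5, 7.0, origin=(-10.0, 0.0, 3.0))
        for ijk in [(0, 0, 0), (2, 3, 4), (1, 2, 2)]:
            np.testing.assert_array_equal(mesh.voxel_of(mesh.voxel_center(ijk)), ijk)

    def test_invalid_mesh_rejected(self):
        with pytest.raises(ValueError):
            VoxelMesh(0, 1, 1, 1.0)
        with pytest.raises(ValueError):
            VoxelMesh(1, 1, 1, -2.0)
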