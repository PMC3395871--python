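import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icbem import (
    AssemblyError,
    ChargeSet,
    ConvergenceError,
    ICCSolver,
    NumericalError,
    ProximityError,
    assign_dielectrics,
    solve_icc,
    solve_iter,
    tile_sphere,
)
from icbem.solvers import (
    build_source,
    build_system,
    build_system_accurate,
)

GAUSS_SPHERE = 1.0 * (1.0 / 2.0 - 1.0 / 80.0)  # q (1/eps_out - 1/eps_in) = 0.4875


def _reference_patch_integral(mesh, i, j, order=16):
    """Independent fine quadrature of the kernel integral over tile j.

    Deliberately re-implemented here (plain Gauss-Legendre tensor rule on
    the parametric patch) as an oracle for the assembled matrix entries.
    """
    u0, u1, v0, v1 = mesh.patches[j]
    x, w = np.polynomial.legendre.leggauss(order)
    uu = 0.5 * (u1 - u0) * x + 0.5 * (u0 + u1)
    vv = 0.5 * (v1 - v0) * x + 0.5 * (v0 + v1)
    U, V = np.meshgrid(uu, vv, indexing="ij")
    W = np.outer(w, w) * 0.25 * (u1 - u0) * (v1 - v0)
    pts = mesh.surface.point(U, V)
    jac = mesh.surface.jacobian(U, V)
    diff = mesh.centers[i] - pts
    dist = np.linalg.norm(diff, axis=-1)
    val = np.sum(W * jac * (diff @ mesh.normals[i]) / dist**3)
    f = mesh.delta_eps[i] / (4 * np.pi * mesh.mean_eps[i])
    return f * val


@pytest.fixture(scope="module")
def sphere_mesh():
    return assign_dielectrics(tile_sphere(5.0, 16, 16), eps_ahead=2.0, eps_behind=80.0)


@pytest.fixture(scope="module")
def central_charge():
    return ChargeSet([1.0], [[0.0, 0.0, 0.0]], [80.0])


class TestBuildSystem:
    def test_identity_when_no_contrast(self):
        mesh = assign_dielectrics(tile_sphere(5.0, 8, 8), 80.0, 80.0)
        system = build_system(mesh)
        assert np.array_equal(system.entries, np.eye(len(mesh)))

    def test_offdiagonal_matches_fine_quadrature(self, sphere_mesh, rng):
        system = build_system(sphere_mesh)
        adjacent = sphere_mesh.adjacent_pairs()
        n = len(sphere_mesh)
        checked = 0
        while checked < 25:
            i, j = rng.integers(0, n, size=2)
            if i == j or (min(i, j), max(i, j)) in adjacent:
                continue
            ref = _reference_patch_integral(sphere_mesh, i, j)
            assert system.entries[i, j] == pytest.approx(ref, rel=0.10, abs=1e-12)
            checked += 1

    def test_residual_after_direct_solve(self, sphere_mesh, central_charge):
        system = build_system(sphere_mesh)
        source = build_source(sphere_mesh, central_charge)
        sol = solve_icc(system, source)
        res = system.entries @ sol.h - source.entries
        assert np.max(np.abs(res)) / np.max(np.abs(source.entries)) < 1e-10

    def test_coincident_centers_raise(self, sphere_mesh):
        centers = sphere_mesh.centers.copy()
        centers[1] = centers[0]
        broken = dataclasses.replace(sphere_mesh, centers=centers)
        with pytest.raises(AssemblyError, match="tile"):
            build_system(broken)

    def test_too_few_tiles(self, sphere_mesh):
        tiny = dataclasses.replace(
            sphere_mesh,
            centers=sphere_mesh.centers[:1],
            normals=sphere_mesh.normals[:1],
            areas=sphere_mesh.areas[:1],
            delta_eps=sphere_mesh.delta_eps[:1],
            mean_eps=sphere_mesh.mean_eps[:1],
        )
        with pytest.raises(AssemblyError):
            build_system(tiny)


class TestBuildSource:
    def test_empty_chargeset_gives_zero(self, sphere_mesh):
        b = build_source(sphere_mesh, ChargeSet.empty())
        assert np.array_equal(b.entries, np.zeros(len(sphere_mesh)))

    def test_central_charge_symmetric(self, sphere_mesh, central_charge):
        b = build_source(sphere_mesh, central_charge)
        assert np.allclose(b.entries, b.entries[0], rtol=1e-12)
        assert b.entries[0] > 0  # negative delta_eps and outward field

    def test_linearity(self, sphere_mesh):
        q1 = ChargeSet([1.0], [[0.0, 0.0, 2.0]], [80.0])
        q2 = ChargeSet([-0.5], [[1.0, -1.0, 0.5]], [80.0])
        b1 = build_source(sphere_mesh, q1).entries
        b2 = build_source(sphere_mesh, q2).entries
        b12 = build_source(sphere_mesh, q1 + q2).entries
        scale = np.max(np.abs(b12))
        assert np.allclose(b12, b1 + b2, rtol=1e-12, atol=1e-15 * scale)

    def test_charge_too_close_raises(self, sphere_mesh):
        near = sphere_mesh.centers[0] + 0.05 * sphere_mesh.normals[0]
        with pytest.raises(ProximityError, match="charge"):
            build_source(sphere_mesh, ChargeSet([1.0], [near], [80.0]))

    @settings(max_examples=25, deadline=None)
    @given(
        q=st.floats(-2.0, 2.0, allow_nan=False),
        z=st.floats(-3.0, 3.0, allow_nan=False),
    )
    def test_source_scales_linearly_in_charge(self, sphere_mesh, q, z):
        base = build_source(sphere_mesh, ChargeSet([1.0], [[0.3, 0.0, z]], [80.0]))
        scaled = build_source(sphere_mesh, ChargeSet([q], [[0.3, 0.0, z]], [80.0]))
        assert np.allclose(scaled.entries, q * base.entries, rtol=1e-12, atol=1e-300)


class TestSolveICC:
    def test_no_contrast_gives_zero(self):
        mesh = assign_dielectrics(tile_sphere(5.0, 8, 8), 80.0, 80.0)
        system = build_system(mesh)
        source = build_source(mesh, ChargeSet([1.0], [[0.0, 0.0, 1.0]], [80.0]))
        assert np.array_equal(source.entries, np.zeros(len(mesh)))
        sol = solve_icc(system, source)
        assert np.array_equal(sol.h, np.zeros(len(mesh)))
        assert sol.iterations == 0

    def test_gauss_total_enclosed_charge(self, sphere_mesh, central_charge):
        system = build_system_accurate(sphere_mesh)
        sol = solve_icc(system, build_source(sphere_mesh, central_charge))
        assert sol.total_induced_charge == pytest.approx(GAUSS_SPHERE, rel=0.02)

    def test_factor_reuse(self, sphere_mesh):
        solver = ICCSolver(build_system(sphere_mesh))
        for z in (0.0, 1.0, 2.0, 3.0):
            solver.solve(
                build_source(sphere_mesh, ChargeSet([1.0], [[0.0, 0.0, z]], [80.0]))
            )
        assert solver.n_factorizations == 1

    def test_condition_estimate_finite(self, sphere_mesh, central_charge):
        solver = ICCSolver(build_system(sphere_mesh))
        sol = solver.solve(build_source(sphere_mesh, central_charge), estimate_condition=True)
        assert np.isfinite(sol.condition_estimate)
        assert sol.condition_estimate >= 1.0

    def test_mesh_mismatch_raises(self, sphere_mesh, central_charge):
        other = assign_dielectrics(tile_sphere(5.0, 16, 16), 2.0, 80.0)
        system = build_system(sphere_mesh)
        source = build_source(other, central_charge)
        with pytest.raises(NumericalError):
            ICCSolver(system).solve(source)


class TestSolveIter:
    def test_zero_source_converges_in_one_sweep(self):
        mesh = assign_dielectrics(tile_sphere(5.0, 8, 8), 80.0, 80.0)
        sol = solve_iter(mesh, build_source(mesh, ChargeSet.empty()))
        assert sol.iterations == 1
        assert np.array_equal(sol.h, np.zeros(len(mesh)))

    def test_agrees_with_icc(self, sphere_mesh):
        # benchmark configuration: off-center charge at z = 4 Å
        system = build_system_accurate(sphere_mesh)
        source = build_source(
            sphere_mesh, ChargeSet([1.0], [[0.0, 0.0, 4.0]], [80.0])
        )
        icc = solve_icc(system, source)
        it = solve_iter(sphere_mesh, source, 1e-4, 1000, system=system)
        rel = np.max(np.abs(it.h - icc.h)) / np.max(np.abs(icc.h))
        assert rel <= 10 * 1e-4

    def test_iteration_count_in_reported_band(self, sphere_mesh):
        system = build_system_accurate(sphere_mesh)
        source = build_source(
            sphere_mesh, ChargeSet([1.0], [[0.0, 0.0, 4.0]], [80.0])
        )
        it = solve_iter(sphere_mesh, source, 1e-4, 1000, system=system)
        assert 80 <= it.iterations <= 140

    def test_convergence_error_carries_state(self, sphere_mesh, central_charge):
        source = build_source(sphere_mesh, central_charge)
        with pytest.raises(ConvergenceError) as exc_info:
            solve_iter(sphere_mesh, source, 1e-4, max_iter=3)
        assert exc_info.value.iterations == 3
        assert exc_info.value.final_update > 1e-4

    def test_invalid_parameters(self, sphere_mesh, central_charge):
        source = build_source(sphere_mesh, central_charge)
        with pytest.raises(ValueError):
            solve_iter(sphere_mesh, source, delta_stop=0.0)
        with pytest.raises(ValueError):
            solve_iter(sphere_mesh, source, max_iter=0)


class TestInvariances:
    def test_orientation_flip_leaves_solution_unchanged(self, sphere_mesh, central_charge):
        flipped = sphere_mesh.flipped()
        sol_a = solve_icc(
            build_system(sphere_mesh), build_source(sphere_mesh, central_charge)
        )
        sol_b = solve_icc(build_system(flipped), build_source(flipped, central_charge))
        assert np.allclose(sol_a.h, sol_b.h, rtol=1e-13)
        assert sol_a.total_induced_charge == pytest.approx(
            sol_b.total_induced_charge, rel=1e-13
        )

    def test_superposition_of_solutions(self, sphere_mesh):
        system = build_system(sphere_mesh)
        solver = ICCSolver(system)
        q1 = ChargeSet([1.0], [[0.0, 0.0, 2.0]], [80.0])
        q2 = ChargeSet([0.7], [[1.5, 0.0, -1.0]], [80.0])
        h1 = solver.solve(build_source(sphere_mesh, q1)).h
        h2 = solver.solve(build_source(sphere_mesh, q2)).h
        h12 = solver.solve(build_source(sphere_mesh, q1 + q2)).h
        assert np.allclose(h12, h1 + h2, rtol=1e-12, atol=1e-18)
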