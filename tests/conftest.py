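"""Shared fixtures. Expensive meshes/systems are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from icbem import (
    ChargeSet,
    ICCSolver,
    make_channel_scenario,
    make_sphere_scenario,
)
from icbem.solvers import build_source, build_system_accurate


@pytest.fixture(scope="session")
def sphere16():
    """Coarse sphere benchmark: mesh, charge set, analytic problem."""
    return make_sphere_scenario(16, 16)


@pytest.fixture(scope="session")
def sphere16_system(sphere16):
    mesh, _, _ = sphere16
    return build_system_accurate(mesh)


@pytest.fixture(scope="session")
def sphere16_solution(sphere16, sphere16_system):
    mesh, charges, _ = sphere16
    return ICCSolver(sphere16_system).solve(build_source(mesh, charges))


@pytest.fixture(scope="session")
def channel_small():
    """Reduced-resolution channel mesh (fast) with no charges."""
    mesh, charges = make_channel_scenario(n_tiles_target=240)
    return mesh, charges


@pytest.fixture(scope="session")
def channel_small_solver(channel_small):
    mesh, _ = channel_small
    return ICCSolver(build_system_accurate(mesh))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def axis_ion():
    return ChargeSet([1.0], [[0.0, 0.0, -25.0]], [80.0])
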