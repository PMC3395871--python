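"""Parameterized benchmark scenarios.

Two standard setups are provided:

* a high-permittivity dielectric sphere (eps 80) in a low-permittivity
  medium (eps 2), radius 5 Å, unit charge 4 Å off-center — the accuracy
  benchmark with an analytic oracle;
* a toy ion channel: two water baths (eps 80) joined by a cylindrical pore
  (radius 6.5 Å) through a 30 Å membrane slab (eps 6), optionally decorated
  with rings of dipoles and/or a mobile cation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .field import gauss_check, reaction_potential_at
from .geometry import (
    BoundaryMesh,
    ChargeSet,
    assign_dielectrics,
    tile_channel,
    tile_sphere,
)
from .analytic import SphereProblem
from .solvers import ICCSolver, build_source, build_system

__all__ = [
    "SPHERE_RADIUS",
    "SPHERE_EPS_IN",
    "SPHERE_EPS_OUT",
    "CHANNEL_PORE_RADIUS",
    "CHANNEL_MEMBRANE_WIDTH",
    "CHANNEL_EPS_WATER",
    "CHANNEL_EPS_MEMBRANE",
    "DipoleRingSpec",
    "make_sphere_scenario",
    "make_channel_scenario",
    "trajectory_sweep",
]

# sphere benchmark parameters
SPHERE_RADIUS = 5.0  # Å
SPHERE_EPS_IN = 80.0
SPHERE_EPS_OUT = 2.0
SPHERE_CHARGE_OFFSET = 4.0  # Å, on the +z axis

# toy channel parameters
CHANNEL_PORE_RADIUS = 6.5  # Å
CHANNEL_MEMBRANE_WIDTH = 30.0  # Å
CHANNEL_EPS_WATER = 80.0
CHANNEL_EPS_MEMBRANE = 6.0


@dataclass(frozen=True)
class DipoleRingSpec:
    """Rings of radially oriented dipoles embedded in the membrane.

    Each ring holds ``n_dipoles`` equally spaced dipoles; the negative
    charge sits ``radial_depth_neg`` Å beyond the pore wall (inside the
    membrane), the positive charge ``axial_extra_pos`` Å deeper still.
    ``disabled_indices`` switches off dipoles (both charges) at those ring
    positions, in every ring.
    """

    n_dipoles: int = 20
    z_positions: tuple[float, float] = (-3.0, 3.0)
    radial_depth_neg: float = 2.0
    axial_extra_pos: float = 2.0
    dipole_charge: float = 1.0
    disabled_indices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n_dipoles < 1:
            raise ConfigurationError("n_dipoles must be >= 1")
        bad = [i for i in self.disabled_indices if not (0 <= i < self.n_dipoles)]
        if bad:
            raise ConfigurationError(f"disabled_indices out of range: {bad}")


def make_sphere_scenario(
    n_theta: int = 32, n_phi: int = 32
) -> tuple[BoundaryMesh, ChargeSet, SphereProblem]:
    """Dielectric-sphere benchmark: R = 5 Å, eps 80 in / 2 out, +1 e at z = 4 Å."""
    mesh = tile_sphere(SPHERE_RADIUS, n_theta, n_phi)
    # outward normals point into the low-permittivity exterior
    mesh = assign_dielectrics(mesh, eps_ahead=SPHERE_EPS_OUT, eps_behind=SPHERE_EPS_IN)
    charges = ChargeSet(
        charges=[1.0],
        positions=[[0.0, 0.0, SPHERE_CHARGE_OFFSET]],
        eps_at_charge=[SPHERE_EPS_IN],
    )
    problem = SphereProblem(
        radius=SPHERE_RADIUS,
        eps_in=SPHERE_EPS_IN,
        eps_out=SPHERE_EPS_OUT,
        charge=1.0,
        charge_offset=SPHERE_CHARGE_OFFSET,
    )
    return mesh, charges, problem


def _ring_charges(spec: DipoleRingSpec, pore_radius: float) -> ChargeSet:
    qs, pos, eps = [], [], []
    r_neg = pore_radius + spec.radial_depth_neg
    r_pos = r_neg + spec.axial_extra_pos
    for z0 in spec.z_positions:
        for k in range(spec.n_dipoles):
            if k in spec.disabled_indices:
                continue
            phi = 2.0 * np.pi * k / spec.n_dipoles
            c, s = np.cos(phi), np.sin(phi)
            qs += [-spec.dipole_charge, +spec.dipole_charge]
            pos += [[r_neg * c, r_neg * s, z0], [r_pos * c, r_pos * s, z0]]
            eps += [CHANNEL_EPS_MEMBRANE, CHANNEL_EPS_MEMBRANE]
    if not qs:
        return ChargeSet.empty()
    return ChargeSet(qs, pos, eps)


def make_channel_scenario(
    rings: DipoleRingSpec | None = None,
    ion_position: np.ndarray | None = None,
    n_tiles_target: int = 860,
    *,
    pore_radius: float = CHANNEL_PORE_RADIUS,
    membrane_width: float = CHANNEL_MEMBRANE_WIDTH,
    corner_radius: float = 5.0,
    lateral_extent: float = 40.0,
    eps_water: float = CHANNEL_EPS_WATER,
    eps_membrane: float = CHANNEL_EPS_MEMBRANE,
) -> tuple[BoundaryMesh, ChargeSet]:
    """Toy ion-channel scenario with an optional cation and dipole rings."""
    mesh = tile_channel(
        pore_radius,
        membrane_width,
        corner_radius=corner_radius,
        lateral_extent=lateral_extent,
        n_tiles_target=n_tiles_target,
    )
    # normals point into the membrane phase
    mesh = assign_dielectrics(mesh, eps_ahead=eps_membrane, eps_behind=eps_water)

    charges = ChargeSet.empty()
    if rings is not None:
        ring_set = _ring_charges(rings, pore_radius)
        if len(ring_set):
            in_membrane = mesh.encloses(ring_set.positions)
            if not np.all(in_membrane):
                raise ConfigurationError(
                    "dipole charges must lie inside the membrane dielectric"
                )
            charges = charges + ring_set
    if ion_position is not None:
        ion_position = np.asarray(ion_position, dtype=float).reshape(3)
        if bool(mesh.encloses(ion_position[None, :])[0]):
            raise ConfigurationError(
                f"ion at {ion_position} lies inside the membrane dielectric"
            )
        charges = charges + ChargeSet([1.0], [ion_position], [eps_water])
    return mesh, charges


def trajectory_sweep(
    radial_offset: float,
    z_values: np.ndarray,
    n_tiles_target: int = 860,
    *,
    solver: ICCSolver | None = None,
    channel_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Sweep a +1 e cation along a line parallel to the channel axis.

    The coupling matrix is factored once and reused for every ion position
    (only the source vector changes). Returns one row per z with the
    reaction potential at the ion and the Gauss audit.
    """
    channel_kwargs = channel_kwargs or {}
    if solver is None:
        mesh, _ = make_channel_scenario(
            n_tiles_target=n_tiles_target, **channel_kwargs
        )
        solver = ICCSolver(build_system(mesh))
    mesh = solver.system.mesh

    rows = []
    for z in np.asarray(z_values, dtype=float):
        pos = np.array([radial_offset, 0.0, z])
        if bool(mesh.encloses(pos[None, :])[0]):
            raise ConfigurationError(
                f"trajectory point (offset={radial_offset}, z={z}) lies inside "
                "the membrane dielectric"
            )
        ion = ChargeSet([1.0], [pos], [CHANNEL_EPS_WATER])
        sol = solver.solve(build_source(mesh, ion))
        phi_r = float(
            reaction_potential_at(pos[None, :], sol, mesh).induced_part[0]
        )
        audit = gauss_check(sol, mesh, ion)
        rows.append(
            {
                "radial_offset_angstrom": radial_offset,
                "z_angstrom": float(z),
                "reaction_potential_reduced": phi_r,
                "total_induced_e": audit.total_induced_e,
                "gauss_expected_e": audit.expected_e,
                "gauss_error_percent_of_e": audit.error_percent_of_e,
            }
        )
    return pd.DataFrame(rows)
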