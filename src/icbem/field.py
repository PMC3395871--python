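"""Potential evaluation and the Gauss's-law audit.

Once the induced densities are known, the potential anywhere in space is the
superposition of screened Coulomb terms from the source charges and plain
Coulomb terms from the induced tile charges. The reaction potential is the
induced part alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytic import gauss_expected_charge
from .errors import ConfigurationError, ProximityError
from .geometry import BoundaryMesh, ChargeSet
from .solvers import REDUCED_TO_VOLTS, InducedSolution

__all__ = [
    "PotentialProfile",
    "GaussReport",
    "potential_at",
    "reaction_potential_at",
    "gauss_check",
    "potential_map",
    "PotentialMap",
]

#: Minimum distance (Å) from an evaluation point to any singularity.
MIN_EVAL_DISTANCE = 0.05


@dataclass
class PotentialProfile:
    """Potentials at a set of points, split into source and induced parts."""

    points: np.ndarray  # (P, 3) Å
    source_part: np.ndarray  # (P,) reduced units, e/Å
    induced_part: np.ndarray  # (P,)

    @property
    def total(self) -> np.ndarray:
        return self.source_part + self.induced_part

    @property
    def total_volts(self) -> np.ndarray:
        return self.total * REDUCED_TO_VOLTS

    @property
    def induced_volts(self) -> np.ndarray:
        return self.induced_part * REDUCED_TO_VOLTS


@dataclass
class GaussReport:
    """Consistency of the total induced charge with Gauss's law."""

    total_induced_e: float
    expected_e: float
    error_e: float
    error_percent_of_e: float  # |error| as a percentage of one elementary charge


def _check_proximity(points: np.ndarray, targets: np.ndarray, label: str) -> None:
    if len(targets) == 0:
        return
    d = np.linalg.norm(points[:, None, :] - targets[None, :, :], axis=2)
    if np.any(d < MIN_EVAL_DISTANCE):
        p, t = np.unravel_index(int(np.argmin(d)), d.shape)
        raise ProximityError(
            f"evaluation point {p} is {d[p, t]:.4f} Å from {label} {t} "
            f"(minimum {MIN_EVAL_DISTANCE} Å)"
        )


def _source_potential(points: np.ndarray, charges: ChargeSet) -> np.ndarray:
    if len(charges) == 0:
        return np.zeros(len(points))
    d = np.linalg.norm(points[:, None, :] - charges.positions[None, :, :], axis=2)
    return d**-1 @ (charges.charges / charges.eps_at_charge)


def _induced_potential(
    points: np.ndarray,
    solution: InducedSolution,
    mesh: BoundaryMesh,
    quad_order: int | None = None,
) -> np.ndarray:
    if quad_order is None:
        d = np.linalg.norm(points[:, None, :] - mesh.centers[None, :, :], axis=2)
        return d**-1 @ (solution.h * mesh.areas)
    out = np.zeros(len(points))
    for i in range(len(mesh)):
        qp, qw = mesh.tile_quadrature(i, quad_order, quad_order)
        d = np.linalg.norm(points[:, None, :] - qp[None, :, :], axis=2)
        out += (qw / d).sum(axis=1) * solution.h[i]
    return out


def reaction_potential_at(
    points: np.ndarray,
    solution: InducedSolution,
    mesh: BoundaryMesh,
    *,
    quad_order: int | None = None,
) -> PotentialProfile:
    """Potential due to the induced charges only (the reaction potential).

    By default each tile contributes as a point charge ``h_i a_i`` at its
    collocation point; ``quad_order`` spreads the tile charge over a
    ``quad_order²``-point sub-tile quadrature, which matters only for
    evaluation points within a tile diameter or so of the boundary.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    _check_proximity(pts, mesh.centers, "tile center")
    return PotentialProfile(
        points=pts,
        source_part=np.zeros(len(pts)),
        induced_part=_induced_potential(pts, solution, mesh, quad_order),
    )


def potential_at(
    points: np.ndarray,
    charges: ChargeSet,
    solution: InducedSolution,
    mesh: BoundaryMesh,
    *,
    quad_order: int | None = None,
) -> PotentialProfile:
    """Total potential: screened source Coulomb part plus induced part."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    _check_proximity(pts, mesh.centers, "tile center")
    _check_proximity(pts, charges.positions, "source charge")
    return PotentialProfile(
        points=pts,
        source_part=_source_potential(pts, charges),
        induced_part=_induced_potential(pts, solution, mesh, quad_order),
    )


def gauss_check(
    solution: InducedSolution, mesh: BoundaryMesh, charges: ChargeSet
) -> GaussReport:
    """Compare the total induced charge with the Gauss's-law expectation.

    The expectation is the closed form for the charges enclosed by the
    boundary (zero when every source lies outside), which requires the mesh
    to identify its enclosed region and phase permittivities.
    """
    if mesh.encloses is None or mesh.eps_enclosed is None:
        raise ConfigurationError(
            "mesh does not identify an enclosed region; Gauss audit undefined"
        )
    if len(charges):
        inside = mesh.encloses(charges.positions)
    else:
        inside = np.zeros(0, dtype=bool)
    expected = gauss_expected_charge(
        charges, inside, eps_in=mesh.eps_enclosed, eps_out=mesh.eps_exterior
    )
    total = float(np.sum(solution.h * mesh.areas))
    err = total - expected
    return GaussReport(
        total_induced_e=total,
        expected_e=expected,
        error_e=err,
        error_percent_of_e=100.0 * abs(err),
    )


@dataclass
class PotentialMap:
    """Total potential on a regular grid in a z = const plane."""

    x: np.ndarray  # (G,) grid coordinates, Å
    y: np.ndarray  # (G,)
    plane_z: float
    values: np.ndarray  # (G, G), reduced units; NaN outside the mask
    mask: np.ndarray  # (G, G) bool, True where evaluated

    @property
    def values_volts(self) -> np.ndarray:
        return self.values * REDUCED_TO_VOLTS

    def argmax_xy(self) -> tuple[float, float]:
        """Grid location of the map maximum."""
        flat = np.where(self.mask, self.values, -np.inf)
        i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
        return float(self.x[i]), float(self.y[j])


def potential_map(
    plane_z: float,
    grid_half_width: float,
    grid_n: int,
    charges: ChargeSet,
    solution: InducedSolution,
    mesh: BoundaryMesh,
    *,
    mask_radius: float | None = None,
) -> PotentialMap:
    """Total potential on a square grid in the plane z = ``plane_z``.

    Grid points are restricted to the disk of radius ``mask_radius``
    (default: ``grid_half_width``), i.e. the pore cross-section for channel
    scenarios; values outside the mask are NaN.
    """
    if grid_n < 2:
        raise ConfigurationError("grid_n must be >= 2")
    coords = np.linspace(-grid_half_width, grid_half_width, grid_n)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    if mask_radius is None:
        mask_radius = grid_half_width
    mask = X**2 + Y**2 <= mask_radius**2
    pts = np.column_stack(
        [X[mask], Y[mask], np.full(int(mask.sum()), float(plane_z))]
    )
    values = np.full((grid_n, grid_n), np.nan)
    if len(pts):
        prof = potential_at(pts, charges, solution, mesh)
        values[mask] = prof.total
    return PotentialMap(x=coords, y=coords, plane_z=float(plane_z), values=values, mask=mask)
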