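"""Closed-form reference solutions used as test oracles.

* The Legendre-series reaction potential of a point charge placed off-center
  inside a dielectric sphere embedded in a second dielectric.
* The Gauss's-law closed form for the total charge induced on a closed
  dielectric boundary.

Potentials are in reduced units (e/Å with the 1/(4 pi eps0) prefactor
absorbed), matching the solver convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from .errors import ParameterError
from .geometry import ChargeSet

__all__ = ["SphereProblem", "sphere_reaction_potential", "gauss_expected_charge"]


@dataclass(frozen=True)
class SphereProblem:
    """Point charge inside a dielectric sphere, charge on the +z axis."""

    radius: float  # Å
    eps_in: float
    eps_out: float
    charge: float = 1.0  # e
    charge_offset: float = 0.0  # Å, distance of the charge from the center

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError("radius must be positive")
        if not (0.0 <= self.charge_offset < self.radius):
            raise ParameterError("charge must lie strictly inside the sphere")
        if self.eps_in < 1 or self.eps_out < 1:
            raise ParameterError("relative permittivities must be >= 1")

    @property
    def charge_position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.charge_offset])


def _series_coefficients(problem: SphereProblem, l_max: int) -> np.ndarray:
    """Coefficients c_l of the interior reaction series.

    Interior reaction potential: sum_l c_l (d r / R²)^l P_l(cos θ) / R with
    c_l = q (l+1)(eps_in - eps_out) / (eps_in (l eps_in + (l+1) eps_out)).
    The same c_l give the exterior series (continuous across the boundary).
    """
    ls = np.arange(l_max + 1, dtype=float)
    q, ei, eo = problem.charge, problem.eps_in, problem.eps_out
    return q * (ls + 1.0) * (ei - eo) / (ei * (ls * ei + (ls + 1.0) * eo))


def sphere_reaction_potential(
    problem: SphereProblem,
    points: np.ndarray,
    l_max: int = 100,
    *,
    check_convergence: bool = True,
    convergence_tol: float = 1e-8,
) -> np.ndarray:
    """Reaction (induced-charge-only) potential of the dielectric sphere.

    Evaluates the classical image series in Legendre polynomials, truncated
    at ``l_max``. For points with ``|r| >= 0.95 R`` — where convergence is
    slowest — the series is recomputed at ``2 l_max`` and the two
    truncations are required to agree to ``convergence_tol`` (relative to
    the monopole scale) unless ``check_convergence`` is disabled.
    """
    if l_max < 1:
        raise ParameterError("l_max must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    if np.any(np.linalg.norm(pts - problem.charge_position, axis=1) < 1e-9):
        raise ParameterError("evaluation point coincides with the source charge")
    if np.any(np.abs(r - problem.radius) < 1e-12):
        raise ParameterError("evaluation point lies exactly on the boundary")

    values = _series_sum(problem, pts, r, l_max)
    if check_convergence:
        slow = r >= 0.95 * problem.radius
        if np.any(slow):
            refined = _series_sum(problem, pts[slow], r[slow], 2 * l_max)
            scale = max(
                abs(problem.charge)
                * abs(1.0 / problem.eps_out - 1.0 / problem.eps_in)
                / problem.radius,
                1e-300,
            )
            if np.max(np.abs(refined - values[slow])) / scale > convergence_tol:
                raise ParameterError(
                    f"series not converged at l_max={l_max}; increase l_max"
                )
            values[slow] = refined
    return values


def _series_sum(
    problem: SphereProblem, pts: np.ndarray, r: np.ndarray, l_max: int
) -> np.ndarray:
    R, d = problem.radius, problem.charge_offset
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, pts[:, 2] / np.where(r > 0, r, 1.0), 1.0)
    c = _series_coefficients(problem, l_max)
    ls = np.arange(l_max + 1)
    inside = r < R
    out = np.zeros(len(pts))

    if np.any(inside):
        # ratio (d r / R²)^l stays < 1 strictly inside
        t = np.power.outer(d * r[inside] / R**2, ls)
        pl = eval_legendre(ls[None, :], cos_t[inside, None])
        out[inside] = (t * pl) @ c / R
    outside = ~inside
    if np.any(outside):
        t = np.power.outer(d / r[outside], ls)
        pl = eval_legendre(ls[None, :], cos_t[outside, None])
        out[outside] = ((t * pl) @ c) / r[outside]
    return out


def gauss_expected_charge(
    charges: ChargeSet,
    inside: np.ndarray | bool,
    eps_in: float,
    eps_out: float,
) -> float:
    """Total induced charge implied by Gauss's law for a closed boundary.

    ``inside`` flags the charges enclosed by the boundary (scalar or
    per-charge boolean mask). Under the potential convention in which each
    source contributes ``q_k / (eps(r_k) |r - r_k|)``, the total induced
    charge equals ``sum_enclosed q_k (1/eps_out - 1/eps_in)``; exterior
    charges contribute nothing.
    """
    mask = np.broadcast_to(np.asarray(inside, dtype=bool), charges.charges.shape)
    q_in = float(charges.charges[mask].sum())
    return q_in * (1.0 / eps_out - 1.0 / eps_in)
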