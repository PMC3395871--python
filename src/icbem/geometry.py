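"""Discretized dielectric boundaries: spheres and axisymmetric channel profiles.

A boundary is represented as a set of curved surface tiles. Each tile carries
a collocation point (the area centroid of the patch projected onto the
analytic surface), the outward analytic normal at that point, the exact patch
area, and the local permittivity jump ``delta_eps`` / mean ``mean_eps``.

Tiles are backed by parametric patches on the analytic surface, so that
sub-tile quadrature (for accuracy checks and optional near-field corrections)
can be generated on demand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "Tile",
    "BoundaryMesh",
    "ChargeSet",
    "tile_sphere",
    "tile_channel",
    "assign_dielectrics",
]


@dataclass(frozen=True)
class Tile:
    """One surface element of a discretized dielectric boundary.

    Attributes
    ----------
    center : (3,) ndarray
        Collocation point in Å.
    normal : (3,) ndarray
        Unit outward normal (per mesh orientation convention).
    area : float
        Patch area in Å².
    delta_eps : float
        Permittivity change along the normal, ``eps_ahead - eps_behind``.
    mean_eps : float
        Mean permittivity across the boundary.
    """

    center: np.ndarray
    normal: np.ndarray
    area: float
    delta_eps: float
    mean_eps: float


class _ParamSurface:
    """Analytic surface with a (u, v) parameterization.

    Subclasses provide vectorized ``point``, ``normal`` and ``jacobian``
    (area element ``dA = J du dv``) maps.
    """

    def point(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def normal(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _SphereSurface(_ParamSurface):
    """Sphere of radius R; u = polar angle theta, v = azimuth phi."""

    def __init__(self, radius: float):
        self.radius = float(radius)

    def point(self, u, v):
        st, ct = np.sin(u), np.cos(u)
        return self.radius * np.stack(
            [st * np.cos(v), st * np.sin(v), ct], axis=-1
        )

    def normal(self, u, v):
        st, ct = np.sin(u), np.cos(u)
        return np.stack([st * np.cos(v), st * np.sin(v), ct], axis=-1)

    def jacobian(self, u, v):
        return self.radius**2 * np.sin(u) * np.ones_like(v)


class _GeneratrixSegment:
    """Piece of the 2D profile curve (r(t), z(t)), t = arc length."""

    length: float

    def rz(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def normal_rz(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class _LineSegment(_GeneratrixSegment):
    def __init__(self, p0, p1, normal):
        self.p0 = np.asarray(p0, dtype=float)
        self.p1 = np.asarray(p1, dtype=float)
        self.length = float(np.linalg.norm(self.p1 - self.p0))
        n = np.asarray(normal, dtype=float)
        self._n = n / np.linalg.norm(n)

    def rz(self, t):
        frac = np.asarray(t) / self.length
        r = self.p0[0] + frac * (self.p1[0] - self.p0[0])
        z = self.p0[1] + frac * (self.p1[1] - self.p0[1])
        return r, z

    def normal_rz(self, t):
        t = np.asarray(t)
        return np.full_like(t, self._n[0], dtype=float), np.full_like(
            t, self._n[1], dtype=float
        )


class _ArcSegment(_GeneratrixSegment):
    """Circular arc (rc + c cos psi, zc + c sin psi), psi from psi0 to psi1.

    ``inward`` selects whether the surface normal points toward the arc
    center (+1) or away from it (-1).
    """

    def __init__(self, center, radius, psi0, psi1, inward: bool):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.psi0, self.psi1 = float(psi0), float(psi1)
        self.length = abs(self.psi1 - self.psi0) * self.radius
        self._sign = -1.0 if inward else 1.0

    def psi(self, t):
        return self.psi0 + np.sign(self.psi1 - self.psi0) * np.asarray(t) / self.radius

    def rz(self, t):
        psi = self.psi(t)
        return (
            self.center[0] + self.radius * np.cos(psi),
            self.center[1] + self.radius * np.sin(psi),
        )

    def normal_rz(self, t):
        psi = self.psi(t)
        return self._sign * np.cos(psi), self._sign * np.sin(psi)


class _ChannelSurface(_ParamSurface):
    """Surface of revolution about z; u = generatrix arc length, v = azimuth."""

    def __init__(self, segments: Sequence[_GeneratrixSegment]):
        self.segments = list(segments)
        self.breaks = np.concatenate([[0.0], np.cumsum([s.length for s in segments])])
        self.total_length = self.breaks[-1]

    def _rz_n(self, u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        r = np.empty_like(u)
        z = np.empty_like(u)
        nr = np.empty_like(u)
        nz = np.empty_like(u)
        idx = np.clip(
            np.searchsorted(self.breaks, u, side="right") - 1, 0, len(self.segments) - 1
        )
        for k, seg in enumerate(self.segments):
            m = idx == k
            if not np.any(m):
                continue
            t = np.clip(u[m] - self.breaks[k], 0.0, seg.length)
            r[m], z[m] = seg.rz(t)
            nr[m], nz[m] = seg.normal_rz(t)
        return r, z, nr, nz

    def point(self, u, v):
        u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        r, z, _, _ = self._rz_n(u.ravel())
        r, z = r.reshape(u.shape), z.reshape(u.shape)
        return np.stack([r * np.cos(v), r * np.sin(v), z], axis=-1)

    def normal(self, u, v):
        u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        _, _, nr, nz = self._rz_n(u.ravel())
        nr, nz = nr.reshape(u.shape), nz.reshape(u.shape)
        return np.stack([nr * np.cos(v), nr * np.sin(v), nz], axis=-1)

    def jacobian(self, u, v):
        u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        r, _, _, _ = self._rz_n(u.ravel())
        return r.reshape(u.shape)


@dataclass
class BoundaryMesh:
    """Full tiling of one dielectric boundary.

    Tile data is stored column-wise in numpy arrays; :meth:`tiles` provides
    the per-tile object view. ``patches`` holds the parametric rectangles of
    each tile on the analytic ``surface`` so sub-tile quadrature can be
    generated.
    """

    centers: np.ndarray  # (N, 3) Å
    normals: np.ndarray  # (N, 3) unit
    areas: np.ndarray  # (N,) Å²
    delta_eps: np.ndarray  # (N,)
    mean_eps: np.ndarray  # (N,)
    orientation: str = "into_low_eps"
    closed: bool = True
    surface: _ParamSurface | None = None
    patches: np.ndarray | None = None  # (N, 4): u0, u1, v0, v1
    patch_uv: np.ndarray | None = None  # (N, 2): collocation point in (u, v)
    v_period: float | None = None  # azimuthal period of the parameterization
    normals_point_into_enclosed: bool = False
    eps_enclosed: float | None = None
    eps_exterior: float | None = None
    encloses: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )

    def __len__(self) -> int:
        return self.centers.shape[0]

    @property
    def n_tiles(self) -> int:
        return len(self)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def tiles(self) -> Iterator[Tile]:
        for i in range(len(self)):
            yield Tile(
                center=self.centers[i],
                normal=self.normals[i],
                area=float(self.areas[i]),
                delta_eps=float(self.delta_eps[i]),
                mean_eps=float(self.mean_eps[i]),
            )

    def flipped(self) -> "BoundaryMesh":
        """Mesh with the opposite orientation convention.

        Normals and ``delta_eps`` are negated; all physical results are
        invariant under this transformation.
        """
        orientation = (
            "into_high_eps" if self.orientation == "into_low_eps" else "into_low_eps"
        )
        return dataclasses.replace(
            self,
            normals=-self.normals,
            delta_eps=-self.delta_eps,
            orientation=orientation,
            normals_point_into_enclosed=not self.normals_point_into_enclosed,
        )

    def tile_diameters(self) -> np.ndarray:
        """Characteristic tile size: largest distance between patch corners."""
        if self.surface is None or self.patches is None:
            return np.sqrt(self.areas)
        u0, u1, v0, v1 = self.patches.T
        corners = np.stack(
            [
                self.surface.point(u0, v0),
                self.surface.point(u0, v1),
                self.surface.point(u1, v0),
                self.surface.point(u1, v1),
            ]
        )  # (4, N, 3)
        d = np.zeros(len(self))
        for a in range(4):
            for b in range(a + 1, 4):
                d = np.maximum(d, np.linalg.norm(corners[a] - corners[b], axis=1))
        return d

    def tile_quadrature(
        self, i: int, nu: int = 4, nv: int = 4
    ) -> tuple[np.ndarray, np.ndarray]:
        """Gauss-Legendre sub-tile quadrature for tile ``i``.

        Returns ``(points, weights)`` with ``sum(weights)`` equal to the
        patch area up to quadrature error.
        """
        if self.surface is None or self.patches is None:
            raise ParameterError("mesh carries no parametric patch information")
        u0, u1, v0, v1 = self.patches[i]
        xu, wu = np.polynomial.legendre.leggauss(nu)
        xv, wv = np.polynomial.legendre.leggauss(nv)
        uu = 0.5 * (u1 - u0) * xu + 0.5 * (u0 + u1)
        vv = 0.5 * (v1 - v0) * xv + 0.5 * (v0 + v1)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        W = np.outer(wu, wv) * (0.25 * (u1 - u0) * (v1 - v0))
        pts = self.surface.point(U, V).reshape(-1, 3)
        wts = (W * self.surface.jacobian(U, V)).ravel()
        return pts, wts

    def adjacent_pairs(self) -> set[tuple[int, int]]:
        """Pairs of tiles whose parametric patches share an edge or corner."""
        if self.patches is None:
            return set()
        tol = 1e-9
        out: set[tuple[int, int]] = set()
        p = self.patches
        n = len(self)
        for i in range(n):
            u0, u1, v0, v1 = p[i]
            for j in range(i + 1, n):
                w0, w1, x0, x1 = p[j]
                du = _interval_gap(u0, u1, w0, w1, None)
                dv = _interval_gap(v0, v1, x0, x1, self.v_period)
                if du <= tol and dv <= tol:
                    out.add((i, j))
        return out


def _interval_gap(a0, a1, b0, b1, period):
    """Gap between intervals [a0,a1] and [b0,b1], optionally on a circle."""
    shifts = (0.0,) if period is None else (-period, 0.0, period)
    return min(max(b0 + s - a1, a0 - (b1 + s), 0.0) for s in shifts)


@dataclass
class ChargeSet:
    """Discrete source charges with the local permittivity at each charge."""

    charges: np.ndarray  # (K,) in e
    positions: np.ndarray  # (K, 3) in Å
    eps_at_charge: np.ndarray  # (K,)

    def __post_init__(self):
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.eps_at_charge = np.atleast_1d(np.asarray(self.eps_at_charge, dtype=float))
        if not (
            len(self.charges) == len(self.positions) == len(self.eps_at_charge)
        ):
            raise ParameterError("charge arrays have inconsistent lengths")
        if np.any(self.eps_at_charge < 1.0):
            raise ParameterError("relative permittivity at a charge must be >= 1")

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @classmethod
    def empty(cls) -> "ChargeSet":
        return cls(np.zeros(0), np.zeros((0, 3)), np.ones(0))

    def __add__(self, other: "ChargeSet") -> "ChargeSet":
        return ChargeSet(
            np.concatenate([self.charges, other.charges]),
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.eps_at_charge, other.eps_at_charge]),
        )


# ---------------------------------------------------------------------------
# Sphere tiling
# ---------------------------------------------------------------------------


def tile_sphere(radius: float, n_theta: int, n_phi: int) -> BoundaryMesh:
    """Tile a sphere by uniform subdivision of the spherical angles.

    The sphere of given ``radius`` (Å) is cut into ``n_theta`` polar bands and
    ``n_phi`` azimuthal sectors, giving ``n_theta * n_phi`` curved tiles.
    Patch areas are exact (``R² Δphi (cos θ₁ − cos θ₂)``); the collocation
    point of each tile is the patch area centroid projected onto the sphere,
    with the analytic radial normal.
    """
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if n_theta < 2 or n_phi < 3:
        raise ParameterError(
            f"insufficient subdivision: n_theta={n_theta} (min 2), n_phi={n_phi} (min 3)"
        )
    theta_edges = np.linspace(0.0, np.pi, n_theta + 1)
    phi_edges = np.linspace(0.0, 2 * np.pi, n_phi + 1)
    ct = np.cos(theta_edges)
    dphi = 2 * np.pi / n_phi

    # area centroid of a band is uniform in cos(theta)
    theta_c = np.arccos(0.5 * (ct[:-1] + ct[1:]))
    phi_c = 0.5 * (phi_edges[:-1] + phi_edges[1:])
    band_areas = radius**2 * dphi * (ct[:-1] - ct[1:])

    T, P = np.meshgrid(theta_c, phi_c, indexing="ij")
    surf = _SphereSurface(radius)
    centers = surf.point(T, P).reshape(-1, 3)
    normals = surf.normal(T, P).reshape(-1, 3)
    areas = np.repeat(band_areas, n_phi)

    patches = np.empty((n_theta * n_phi, 4))
    patch_uv = np.empty((n_theta * n_phi, 2))
    k = 0
    for i in range(n_theta):
        for j in range(n_phi):
            patches[k] = (theta_edges[i], theta_edges[i + 1], phi_edges[j], phi_edges[j + 1])
            patch_uv[k] = (theta_c[i], phi_c[j])
            k += 1

    n = n_theta * n_phi
    return BoundaryMesh(
        centers=centers,
        normals=normals,
        areas=areas,
        delta_eps=np.zeros(n),
        mean_eps=np.ones(n),
        orientation="into_low_eps",
        closed=True,
        surface=surf,
        patches=patches,
        patch_uv=patch_uv,
        v_period=2 * np.pi,
        normals_point_into_enclosed=False,
        encloses=lambda pts: np.linalg.norm(np.asarray(pts, float).reshape(-1, 3), axis=1)
        < radius,
    )


# ---------------------------------------------------------------------------
# Channel tiling
# ---------------------------------------------------------------------------


def _channel_generatrix(
    pore_radius: float,
    membrane_width: float,
    corner_radius: float,
    lateral_extent: float,
) -> list[_GeneratrixSegment]:
    a, w2, c, L = pore_radius, membrane_width / 2.0, corner_radius, lateral_extent
    # ordered bottom face -> bottom corner -> pore wall -> top corner -> top face;
    # normals point into the membrane phase.
    return [
        _LineSegment((L, -w2), (a + c, -w2), normal=(0.0, 1.0)),
        _ArcSegment((a + c, -(w2 - c)), c, 1.5 * np.pi, np.pi, inward=True),
        _LineSegment((a, -(w2 - c)), (a, w2 - c), normal=(1.0, 0.0)),
        _ArcSegment((a + c, w2 - c), c, np.pi, 0.5 * np.pi, inward=True),
        _LineSegment((a + c, w2), (L, w2), normal=(0.0, -1.0)),
    ]


def _allocate_bands(
    n_bands: int, pore_radius: float, membrane_width: float, corner_radius: float,
    lateral_extent: float,
) -> tuple[int, int, int]:
    """Split generatrix bands among (face, corner, wall) keeping z-symmetry.

    Faces are weighted by a logarithmic measure so that tiles grow coarser
    away from the pore; corners and the wall by true arc length.
    """
    a, c, L = pore_radius, corner_radius, lateral_extent
    w_face = (a + c) * np.log(L / (a + c))
    w_arc = 0.5 * np.pi * c
    w_wall = membrane_width - 2 * c
    total = 2 * w_face + 2 * w_arc + w_wall
    n_face = max(1, round(n_bands * w_face / total))
    n_arc = max(1, round(n_bands * w_arc / total))
    n_wall = max(1, n_bands - 2 * n_face - 2 * n_arc)
    return n_face, n_arc, n_wall


def tile_channel(
    pore_radius: float,
    membrane_width: float,
    corner_radius: float = 5.0,
    lateral_extent: float = 40.0,
    n_tiles_target: int = 860,
    n_phi: int | None = None,
) -> BoundaryMesh:
    """Tile the water/membrane boundary of an axisymmetric channel.

    The boundary consists of two annular membrane faces at z = ±width/2, a
    cylindrical pore wall of radius ``pore_radius``, and toroidal rounded
    corners of radius ``corner_radius`` joining them; the 2D profile is
    revolved about the z axis. Face bands are geometrically graded so tiles
    coarsen away from the pore. Normals point into the membrane phase.
    """
    if pore_radius <= 0:
        raise ParameterError(f"pore_radius must be positive, got {pore_radius}")
    if membrane_width <= 2 * corner_radius:
        raise ParameterError(
            f"membrane_width ({membrane_width}) must exceed twice the corner "
            f"radius ({corner_radius})"
        )
    if lateral_extent <= pore_radius + corner_radius:
        raise ParameterError(
            f"lateral_extent ({lateral_extent}) must exceed pore_radius + "
            f"corner_radius ({pore_radius + corner_radius})"
        )
    if n_tiles_target < 40:
        raise ParameterError("n_tiles_target too small (min 40)")

    a, w2, c, L = pore_radius, membrane_width / 2.0, corner_radius, lateral_extent

    if n_phi is None:
        # aspect-balanced azimuthal count; reproduces 20 sectors at the
        # 860-tile default
        n_phi = max(8, int(round(np.sqrt(n_tiles_target * 400.0 / 860.0))))
    n_bands = max(5, int(round(n_tiles_target / n_phi)))
    n_face, n_arc, n_wall = _allocate_bands(
        n_bands, a, membrane_width, c, L
    )

    segments = _channel_generatrix(a, membrane_width, c, L)
    surf = _ChannelSurface(segments)

    # band edges in arc length per segment, symmetric under z -> -z
    face_r = np.geomspace(a + c, L, n_face + 1)  # fine near pore
    bot_face_t = (L - face_r)[::-1]  # segment 0 runs r = L -> a+c
    top_face_t = face_r - (a + c)  # segment 4 runs r = a+c -> L
    arc_t = np.linspace(0.0, segments[1].length, n_arc + 1)
    wall_t = np.linspace(0.0, segments[2].length, n_wall + 1)

    band_edges: list[np.ndarray] = []
    for seg_idx, local_t in [
        (0, bot_face_t),
        (1, arc_t),
        (2, wall_t),
        (3, arc_t),
        (4, top_face_t),
    ]:
        band_edges.append(surf.breaks[seg_idx] + local_t)

    phi_edges = np.linspace(0.0, 2 * np.pi, n_phi + 1)
    dphi = 2 * np.pi / n_phi
    phi_c = 0.5 * (phi_edges[:-1] + phi_edges[1:])

    centers, normals, areas, patches, patch_uv = [], [], [], [], []
    for seg_idx, edges in enumerate(band_edges):
        seg = segments[seg_idx]
        for u0, u1 in zip(edges[:-1], edges[1:]):
            t0, t1 = u0 - surf.breaks[seg_idx], u1 - surf.breaks[seg_idx]
            band_area, u_c = _band_area_and_centroid(seg, t0, t1)
            u_c += surf.breaks[seg_idx]
            r, z, nr, nz = surf._rz_n(np.array([u_c]))
            for j in range(n_phi):
                p = phi_c[j]
                centers.append([r[0] * np.cos(p), r[0] * np.sin(p), z[0]])
                normals.append([nr[0] * np.cos(p), nr[0] * np.sin(p), nz[0]])
                areas.append(band_area * dphi / (2 * np.pi))
                patches.append([u0, u1, phi_edges[j], phi_edges[j + 1]])
                patch_uv.append([u_c, p])

    n = len(areas)
    profile_r = _make_profile_r(a, w2, c)

    def encloses(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        inside_slab = np.abs(pts[:, 2]) < w2
        return inside_slab & (rho > profile_r(pts[:, 2])) & (rho < L)

    return BoundaryMesh(
        centers=np.asarray(centers),
        normals=np.asarray(normals),
        areas=np.asarray(areas),
        delta_eps=np.zeros(n),
        mean_eps=np.ones(n),
        orientation="into_low_eps",
        closed=False,
        surface=surf,
        patches=np.asarray(patches),
        patch_uv=np.asarray(patch_uv),
        v_period=2 * np.pi,
        normals_point_into_enclosed=True,
        encloses=encloses,
    )


def _make_profile_r(a: float, w2: float, c: float) -> Callable[[np.ndarray], np.ndarray]:
    """Radius of the water/membrane boundary as a function of z (|z| < w2)."""

    def profile_r(z: np.ndarray) -> np.ndarray:
        z = np.abs(np.asarray(z, dtype=float))
        r = np.full_like(z, a)
        in_corner = z > w2 - c
        dz = np.clip(z[in_corner] - (w2 - c), 0.0, c)
        r[in_corner] = a + c - np.sqrt(np.maximum(c**2 - dz**2, 0.0))
        return r

    return profile_r


def _band_area_and_centroid(
    seg: _GeneratrixSegment, t0: float, t1: float
) -> tuple[float, float]:
    """Exact revolved band area (2π ∫ r dt) and area-centroid parameter."""
    x, w = np.polynomial.legendre.leggauss(16)
    t = 0.5 * (t1 - t0) * x + 0.5 * (t0 + t1)
    wt = 0.5 * (t1 - t0) * w
    r, _ = seg.rz(t)
    m0 = float(np.sum(wt * r))
    m1 = float(np.sum(wt * r * t))
    return 2 * np.pi * m0, m1 / m0


# ---------------------------------------------------------------------------
# Dielectric assignment
# ---------------------------------------------------------------------------


def assign_dielectrics(
    mesh: BoundaryMesh, eps_ahead: float, eps_behind: float
) -> BoundaryMesh:
    """Attach permittivities to a mesh.

    ``eps_ahead`` is the permittivity of the phase the normals point into,
    ``eps_behind`` that of the opposite phase. Every tile then carries
    ``delta_eps = eps_ahead - eps_behind`` and ``mean_eps`` their average.
    """
    if eps_ahead < 1.0 or eps_behind < 1.0:
        raise ParameterError("relative permittivities must be >= 1")
    n = len(mesh)
    if mesh.normals_point_into_enclosed:
        eps_enclosed, eps_exterior = eps_ahead, eps_behind
    else:
        eps_enclosed, eps_exterior = eps_behind, eps_ahead
    return dataclasses.replace(
        mesh,
        delta_eps=np.full(n, float(eps_ahead) - float(eps_behind)),
        mean_eps=np.full(n, 0.5 * (float(eps_ahead) + float(eps_behind))),
        eps_enclosed=eps_enclosed,
        eps_exterior=eps_exterior,
    )
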