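"""Embryo sphere geometry: fitting, unit-sphere mapping, surface meshes, local frames.

The gastrula-stage embryo is modelled as a static sphere. All angular
bookkeeping lives in an embryo-aligned frame: ``theta`` is the elevation
measured from the anterior (animal) pole, in ``[0, pi]``, and ``phi`` the
azimuth measured from the dorsal meridian, in ``(-pi, pi]``, increasing
anticlockwise when viewed from the anterior pole. Radial distances are
normalized by the embryo radius so the surface maps onto a unit sphere
(``r0 = 1``); physical distances stay in micrometres throughout.

The surface is discretized by a deterministic spherical Fibonacci lattice
(2000 nodes by default) triangulated by its convex hull, and each node off
the poles carries a right-handed orthonormal anatomical frame
``(e_AP, e_ML, e_r)``: the tangent along increasing theta
(anterior -> posterior), the tangent along increasing phi (medio-lateral),
and the outward radial direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull

__all__ = [
    "EmbryoGeometry",
    "SphericalCoord",
    "SphericalMesh",
    "LocalFrame",
    "FrameField",
    "fit_sphere",
    "make_mesh",
    "to_embryo_coords",
    "from_embryo_coords",
    "local_frame",
    "local_frames",
    "save_geometry",
    "load_geometry",
    "DEFAULT_POLE_EXCLUSION",
]

#: Golden angle (rad) used by the spherical Fibonacci lattice.
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Default polar cap (rad) within which tangential frames are flagged missing.
DEFAULT_POLE_EXCLUSION = 0.05


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} must be non-zero")
    return v / n


@dataclass(frozen=True)
class EmbryoGeometry:
    """Static embryo sphere plus anatomical reference axes.

    Parameters
    ----------
    center : (3,) array
        Sphere centre, micrometres (laboratory frame).
    radius_R : float
        Physical embryo radius, micrometres.
    anterior_axis : (3,) array
        Direction from centre to the anterior (animal) pole; normalized.
    dorsal_ref : (3,) array
        Direction of the dorsal meridian at the equator; orthogonalized
        against ``anterior_axis`` and normalized.
    r0 : float
        Normalized surface radius; fixed at 1.
    """

    center: np.ndarray
    radius_R: float
    anterior_axis: np.ndarray
    dorsal_ref: np.ndarray
    r0: float = 1.0

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius_R > 0:
            raise ValueError("radius_R must be positive")
        if self.r0 != 1.0:
            raise ValueError("r0 is fixed at 1 (unit-sphere normalization)")
        a = _unit(self.anterior_axis, "anterior_axis")
        d = np.asarray(self.dorsal_ref, dtype=float).reshape(3)
        d = d - (d @ a) * a
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            raise ValueError("dorsal_ref is parallel to anterior_axis")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "radius_R", float(self.radius_R))
        object.__setattr__(self, "anterior_axis", a)
        object.__setattr__(self, "dorsal_ref", d / nd)

    @property
    def basis(self) -> np.ndarray:
        """Orthonormal embryo basis as columns ``[x, y, z]``.

        ``x = dorsal_ref``, ``z = anterior_axis`` and ``y = z x x`` so that
        phi = atan2(y, x) increases anticlockwise seen from the anterior
        pole. Right-handed with determinant +1.
        """
        ex = self.dorsal_ref
        ez = self.anterior_axis
        ey = np.cross(ez, ex)
        return np.stack([ex, ey, ez], axis=1)


@dataclass(frozen=True)
class SphericalCoord:
    """Vectorized embryo-frame spherical coordinates.

    ``r`` is in units of the embryo radius, ``theta`` the elevation from
    the anterior pole in ``[0, pi]``, ``phi`` the azimuth from the dorsal
    meridian in ``(-pi, pi]`` (NaN where undefined, i.e. at the poles).
    """

    r: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    phi_defined: np.ndarray


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through a 3D point cloud.

    Minimizes ``sum((|p - c| - R)^2)`` (geometric distance), seeded by the
    linear algebraic fit and refined by Levenberg-Marquardt.

    Returns ``(center, radius)`` in the units of ``points`` (micrometres).
    Raises ``ValueError`` for fewer than 4 points or a coplanar
    configuration, for which the sphere is unidentifiable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("fit_sphere needs at least 4 three-dimensional points")
    u = pts - pts.mean(axis=0)
    sv = np.linalg.svd(u, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (coplanar) point configuration: sphere is unidentifiable")
    # Algebraic fit: |p|^2 = 2 p.c + (R^2 - |c|^2), linear in (c, k).
    a_mat = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(a_mat, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))

    def resid(p: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    out = least_squares(resid, np.r_[c0, r0], method="lm")
    return out.x[:3].copy(), float(out.x[3])


@dataclass(frozen=True)
class SphericalMesh:
    """Near-uniform node set on the unit sphere with a hull triangulation.

    ``nodes`` are unit vectors in the laboratory frame; ``triangles`` index
    into them with outward-facing orientation.
    """

    nodes: np.ndarray
    triangles: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def physical_nodes(self, geom: EmbryoGeometry) -> np.ndarray:
        """Node centres in physical micrometre coordinates."""
        return geom.center + geom.radius_R * self.nodes


def make_mesh(n_nodes: int = 2000) -> SphericalMesh:
    """Discretize the unit sphere into ``n_nodes`` near-equally-spaced nodes.

    Uses the deterministic spherical Fibonacci lattice (offset form, so no
    node sits exactly on a pole) triangulated by the convex hull of the
    node set. Identical ``n_nodes`` always yields bit-identical output.
    """
    if n_nodes < 12:
        raise ValueError("n_nodes must be at least 12")
    k = np.arange(n_nodes, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_nodes
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    ang = GOLDEN_ANGLE * k
    nodes = np.column_stack([s * np.cos(ang), s * np.sin(ang), z])
    nodes /= np.linalg.norm(nodes, axis=1, keepdims=True)
    hull = ConvexHull(nodes)
    tri = hull.simplices.copy()
    # orient all triangles outward (normal pointing away from the origin)
    nrm = np.cross(nodes[tri[:, 1]] - nodes[tri[:, 0]], nodes[tri[:, 2]] - nodes[tri[:, 0]])
    cen = nodes[tri].mean(axis=1)
    flip = np.einsum("ij,ij->i", nrm, cen) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return SphericalMesh(nodes=nodes, triangles=tri)


def to_embryo_coords(points: np.ndarray, geom: EmbryoGeometry) -> SphericalCoord:
    """Map laboratory-frame positions (micrometres) to embryo spherical coordinates.

    Raises ``ValueError`` if any point coincides with the embryo centre
    (direction undefined). At the poles ``phi`` is NaN and flagged in
    ``phi_defined``.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - geom.center
    q = p @ geom.basis
    rho = np.linalg.norm(q, axis=1)
    if np.any(rho < 1e-9 * geom.radius_R):
        raise ValueError("point at the embryo centre: direction undefined")
    theta = np.arccos(np.clip(q[:, 2] / rho, -1.0, 1.0))
    st = np.hypot(q[:, 0], q[:, 1])
    defined = st > 1e-12 * rho
    with np.errstate(invalid="ignore"):
        phi = np.where(defined, np.arctan2(q[:, 1], q[:, 0]), np.nan)
    return SphericalCoord(r=rho / geom.radius_R, theta=theta, phi=phi, phi_defined=defined)


def from_embryo_coords(
    r: np.ndarray, theta: np.ndarray, phi: np.ndarray, geom: EmbryoGeometry
) -> np.ndarray:
    """Inverse of :func:`to_embryo_coords`; NaN ``phi`` is treated as 0 (poles)."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.where(np.isnan(np.atleast_1d(phi)), 0.0, np.atleast_1d(phi))
    st = np.sin(theta)
    q = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    q *= (r * geom.radius_R)[:, None]
    return geom.center + q @ geom.basis.T


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed anatomical triad at one surface point.

    ``e_AP`` points along increasing theta (anterior -> posterior), ``e_ML``
    along increasing phi, ``e_r`` radially outward; ``valid`` is False inside
    the pole-exclusion caps where the tangential directions are singular.
    """

    e_AP: np.ndarray
    e_ML: np.ndarray
    e_r: np.ndarray
    valid: bool


@dataclass(frozen=True)
class FrameField:
    """Anatomical frames at many surface points (NaN rows where invalid)."""

    e_AP: np.ndarray
    e_ML: np.ndarray
    e_r: np.ndarray
    valid: np.ndarray

    def __getitem__(self, i: int) -> LocalFrame:
        return LocalFrame(self.e_AP[i], self.e_ML[i], self.e_r[i], bool(self.valid[i]))


def local_frames(
    directions: np.ndarray,
    geom: EmbryoGeometry,
    pole_exclusion: float = DEFAULT_POLE_EXCLUSION,
) -> FrameField:
    """Anatomical frames for an array of radial directions (unit or not).

    Frames within ``pole_exclusion`` radians of either pole are flagged
    invalid (NaN) rather than raising: component maps are simply missing
    there.
    """
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    b = geom.basis
    q = u @ b
    ct = np.clip(q[:, 2], -1.0, 1.0)
    st = np.hypot(q[:, 0], q[:, 1])
    valid = st >= np.sin(pole_exclusion)
    with np.errstate(divide="ignore", invalid="ignore"):
        cphi = np.where(valid, q[:, 0] / st, np.nan)
        sphi = np.where(valid, q[:, 1] / st, np.nan)
    e_ap_emb = np.column_stack([ct * cphi, ct * sphi, -st])
    e_ml_emb = np.column_stack([-sphi, cphi, np.zeros(len(u))])
    e_ap = e_ap_emb @ b.T
    e_ml = e_ml_emb @ b.T
    e_r = u.copy()
    e_ap[~valid] = np.nan
    e_ml[~valid] = np.nan
    return FrameField(e_AP=e_ap, e_ML=e_ml, e_r=e_r, valid=valid)


def local_frame(
    node: np.ndarray,
    geom: EmbryoGeometry,
    pole_exclusion: float = DEFAULT_POLE_EXCLUSION,
) -> LocalFrame:
    """Anatomical frame at a single surface direction (see :func:`local_frames`)."""
    return local_frames(np.asarray(node, dtype=float)[None, :], geom, pole_exclusion)[0]


def save_geometry(geom: EmbryoGeometry, path: str) -> None:
    """Write the geometry to a plain-text key-value (YAML) block."""
    payload = {
        "center_um": [float(v) for v in geom.center],
        "radius_um": float(geom.radius_R),
        "anterior_axis": [float(v) for v in geom.anterior_axis],
        "dorsal_ref": [float(v) for v in geom.dorsal_ref],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_geometry(path: str) -> EmbryoGeometry:
    """Read a geometry block written by :func:`save_geometry`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return EmbryoGeometry(
        center=np.asarray(payload["center_um"], dtype=float),
        radius_R=float(payload["radius_um"]),
        anterior_axis=np.asarray(payload["anterior_axis"], dtype=float),
        dorsal_ref=np.asarray(payload["dorsal_ref"], dtype=float),
    )
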