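"""Orthographic hemisphere views of node fields and kymograph rasters.

Color semantics follow the strain-map convention: expansion (positive) is
red, compaction (negative) is blue, on a diverging map with limits
symmetric about zero; missing nodes render neutral gray. Velocity vectors
are classified by direction: toward the anterior pole (green), toward the
posterior pole (red), or predominantly medio-lateral (blue).
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import matplotlib.tri as mtri

from .geometry import EmbryoGeometry, FrameField, SphericalMesh
from .kymo import Kymograph

__all__ = ["VIEWS", "view_axes", "render_map", "render_velocity", "render_kymograph"]

VIEWS = ("dorsal", "ventral", "left", "right", "anterior", "posterior")


def view_axes(geom: EmbryoGeometry, view: str) -> tuple[np.ndarray, np.ndarray]:
    """(view direction, screen-up) unit vectors of a named orthographic view.

    Lateral and dorsal/ventral views are drawn with the anterior pole up;
    polar views with the dorsal meridian up. 'left'/'right' refer to the
    embryo's own left/right sides.
    """
    a, d = geom.anterior_axis, geom.dorsal_ref
    ey = np.cross(a, d)
    table = {
        "dorsal": (d, a),
        "ventral": (-d, a),
        "left": (-ey, a),
        "right": (ey, a),
        "anterior": (a, d),
        "posterior": (-a, d),
    }
    if view not in table:
        raise ValueError(f"unknown view {view!r}; available: {VIEWS}")
    direction, up = table[view]
    return direction, up


def _project(mesh: SphericalMesh, geom: EmbryoGeometry, view: str):
    direction, up = view_axes(geom, view)
    right = np.cross(up, direction)
    x = mesh.nodes @ right
    y = mesh.nodes @ up
    front = mesh.nodes @ direction > 0.0
    return x, y, front


def render_map(
    mesh: SphericalMesh,
    geom: EmbryoGeometry,
    values: np.ndarray,
    view: str,
    path: str | None = None,
    ax: plt.Axes | None = None,
    clim: float | None = None,
    title: str | None = None,
    colorbar: bool = True,
):
    """Orthographic projection of one node field onto a named hemisphere view.

    ``values`` has one entry per mesh node (NaN = missing). Returns the
    Matplotlib axes; saves a PNG when ``path`` is given.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mesh.n_nodes,):
        raise ValueError("values must have one entry per mesh node")
    x, y, front = _project(mesh, geom, view)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    tri = mtri.Triangulation(x, y, mesh.triangles)
    visible = front[mesh.triangles].all(axis=1)
    finite = np.isfinite(values[mesh.triangles]).all(axis=1)
    # neutral-gray disk underneath so back/missing triangles read as missing
    ax.add_patch(plt.Circle((0, 0), 1.0, color="0.85", zorder=0))
    tri.set_mask(~(visible & finite))
    if clim is None:
        vmax = np.nanmax(np.abs(values[front])) if np.isfinite(values[front]).any() else 1.0
        clim = vmax if vmax > 0 else 1.0
    node_vals = np.where(np.isfinite(values), values, 0.0)
    col = ax.tripcolor(tri, node_vals, shading="gouraud", cmap="RdBu_r",
                       vmin=-clim, vmax=clim, zorder=1)
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k", lw=0.8, zorder=2))
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title or view)
    if colorbar:
        plt.colorbar(col, ax=ax, shrink=0.75)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def render_velocity(
    mesh: SphericalMesh,
    geom: EmbryoGeometry,
    v_field: np.ndarray,
    frames: FrameField,
    view: str,
    path: str | None = None,
    scale: float | None = None,
):
    """Domain-velocity quiver colored by direction class.

    Green = toward the anterior pole, red = toward the posterior pole,
    blue = predominantly medio-lateral, following the velocity-map color
    scheme of the analysis.
    """
    x, y, front = _project(mesh, geom, view)
    direction, up = view_axes(geom, view)
    right = np.cross(up, direction)
    ok = front & np.isfinite(v_field).all(axis=1) & frames.valid
    v_ap = np.einsum("ij,ij->i", v_field, np.nan_to_num(frames.e_AP))
    v_ml = np.einsum("ij,ij->i", v_field, np.nan_to_num(frames.e_ML))
    colors = np.where(
        np.abs(v_ap) >= np.abs(v_ml),
        np.where(v_ap < 0, "green", "red"),
        "blue",
    )
    _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k", lw=0.8))
    v_plot = np.nan_to_num(v_field)
    u = v_plot @ right
    w = v_plot @ up
    if scale is None and (not ok.any() or np.hypot(u[ok], w[ok]).max() == 0.0):
        scale = 1.0  # static field: fix the autoscale
    for cls in ("green", "red", "blue"):
        sel = ok & (colors == cls)
        if sel.any():
            ax.quiver(x[sel], y[sel], u[sel], w[sel], color=cls, scale=scale, width=0.003)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"domain velocity ({view})")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def render_kymograph(kym: Kymograph, path: str | None = None, clim: float | None = None):
    """Raster of a kymograph matrix (angle vertical, time horizontal)."""
    _, ax = plt.subplots(figsize=(6, 4))
    if clim is None:
        vmax = np.nanmax(np.abs(kym.values)) if np.isfinite(kym.values).any() else 1.0
        clim = vmax if vmax > 0 else 1.0
    masked = np.ma.masked_invalid(kym.values)
    pc = ax.pcolormesh(kym.times, kym.angles, masked, cmap="RdBu_r", vmin=-clim, vmax=clim)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("angle (deg)")
    ax.set_title(f"{kym.component} ({kym.band})")
    plt.colorbar(pc, ax=ax, label="integrated strain")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
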