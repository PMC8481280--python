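"""Velocity-gradient tensor fields, strain-rate/spin decomposition, strain maps.

This is the core of the tissue-tectonics analysis. Cells are grouped into
overlapping spherical domains of radius 110 um around each mesh node; the
domain velocity is the mean of its member-cell velocities; the 3x3
velocity-gradient tensor ``L`` (``L_ab = dv_a/dx_b``, units 1/min) is
estimated at each node by weighted affine least squares and split into the
strain-rate tensor ``E = (L + L^T)/2`` and the spin tensor
``Omega = (L - L^T)/2``. Diagonal projections of ``E`` onto the local
anatomical frame give the anterior-posterior, medio-lateral and radial
strain-rate components; ``tr(E)`` is the local volume-change rate
(divergence) and ``curl_r = 2 omega . e_r`` the in-surface rotation rate
(positive = anticlockwise viewed from outside the embryo). Component rates
are integrated over a sliding window (30 min by default, 40 min for
perturbation comparisons) to give the strain maps.

All tensor computation happens in physical units (um, min); the unit
sphere is used only for mesh construction and angular bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import (
    DEFAULT_POLE_EXCLUSION,
    EmbryoGeometry,
    FrameField,
    LocalFrame,
    SphericalMesh,
    local_frames,
    to_embryo_coords,
)

__all__ = [
    "TectonicsConfig",
    "GradientField",
    "StrainRateTensor",
    "TensorField",
    "StrainMaps",
    "assign_domains",
    "domain_velocity",
    "velocity_gradients",
    "decompose",
    "decompose_field",
    "compute_tensor_field",
    "integrate_strain",
    "divergence_map",
    "compute_strain_maps",
    "strain_table",
    "write_strain_table",
    "read_strain_table",
    "write_strain_h5",
    "COMPONENT_NAMES",
]

COMPONENT_NAMES = ("e_AP", "e_ML", "e_r", "trace", "curl_r", "curl_mag")


@dataclass(frozen=True)
class TectonicsConfig:
    """Tunable parameters of the strain-map computation.

    ``domain_radius`` (um) is the radius of the overlapping spherical
    domains; ``window`` (min) the strain integration window; domains with
    fewer than ``min_cells_per_domain`` member cells are missing.
    ``gradient_mode`` selects the regression samples: ``cell_regression``
    fits member-cell velocities against their 3D positions (the shell's
    radial thickness identifies radial derivatives), ``node_field`` fits
    neighboring nodes' mean velocities (surface-only samples; radial
    derivatives are then ridge-dominated and ~0). The ridge term
    ``ridge_epsilon`` (relative to the scatter scale) is applied only where
    the weighted scatter matrix is numerically rank-deficient.
    """

    domain_radius: float = 110.0
    window: float = 30.0
    min_cells_per_domain: int = 4
    ridge_epsilon: float = 1e-6
    gradient_mode: str = "cell_regression"
    weight_bandwidth: float | None = None
    clockwise_positive_curl: bool = False
    min_window_coverage: float = 0.8
    rank_tol: float = 1e-10
    pole_exclusion: float = DEFAULT_POLE_EXCLUSION

    def __post_init__(self) -> None:
        if not self.domain_radius > 0:
            raise ValueError("domain_radius must be positive")
        if not self.window > 0:
            raise ValueError("window must be positive")
        if self.gradient_mode not in ("cell_regression", "node_field"):
            raise ValueError("gradient_mode must be 'cell_regression' or 'node_field'")
        if not 0 < self.min_window_coverage <= 1:
            raise ValueError("min_window_coverage must be in (0, 1]")

    @property
    def bandwidth(self) -> float:
        """Gaussian distance-weight bandwidth (um); default domain_radius/2."""
        return self.weight_bandwidth if self.weight_bandwidth is not None else self.domain_radius / 2.0


def assign_domains(
    positions: np.ndarray,
    mesh: SphericalMesh,
    geom: EmbryoGeometry,
    cfg: TectonicsConfig,
) -> list[np.ndarray]:
    """Member-cell indices of every node's spherical domain.

    A cell belongs to node ``i`` iff its Euclidean distance to the node's
    physical position is at most ``cfg.domain_radius``; domains overlap.
    """
    tree = cKDTree(np.atleast_2d(positions))
    hits = tree.query_ball_point(mesh.physical_nodes(geom), cfg.domain_radius)
    return [np.asarray(sorted(h), dtype=np.int64) for h in hits]


def domain_velocity(
    membership: list[np.ndarray],
    velocities: np.ndarray,
    cfg: TectonicsConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arithmetic-mean domain velocities.

    Returns ``(v_mean (N,3) with NaN where missing, n_cells (N,), valid)``;
    a domain is missing where its member count is below
    ``min_cells_per_domain``.
    """
    velocities = np.atleast_2d(velocities)
    n_nodes = len(membership)
    v = np.full((n_nodes, 3), np.nan)
    n_cells = np.array([len(m) for m in membership], dtype=np.int64)
    valid = n_cells >= cfg.min_cells_per_domain
    for i in np.flatnonzero(valid):
        v[i] = velocities[membership[i]].mean(axis=0)
    return v, n_cells, valid


@dataclass(frozen=True)
class GradientField:
    """Per-node velocity-gradient estimates at one time point."""

    L: np.ndarray  # (N, 3, 3), 1/min; NaN where invalid
    valid: np.ndarray  # (N,)
    condition_number: np.ndarray  # (N,)
    n_cells: np.ndarray  # (N,) regression sample count (member cells)
    v_mean: np.ndarray  # (N, 3) domain-mean velocity, NaN where missing
    ridge_applied: np.ndarray  # (N,)


def _affine_fit(
    sample_pos: np.ndarray,
    sample_vel: np.ndarray,
    centers: np.ndarray,
    radius: float,
    bandwidth: float,
    min_samples: int,
    ridge_epsilon: float,
    rank_tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted local affine regression v(x) ~ v0 + L (x - c) at many centers.

    Gaussian distance weights; intercept handled exactly by weighted
    centering. Returns (L, valid, cond, counts, ridge_applied). Ridge is a
    rescue applied only to numerically rank-deficient scatter matrices so
    that full-rank affine fields are recovered to machine precision.
    """
    n_nodes = len(centers)
    tree = cKDTree(sample_pos)
    hits = tree.query_ball_point(centers, radius)
    counts = np.array([len(h) for h in hits], dtype=np.int64)
    node_idx = np.repeat(np.arange(n_nodes), counts)
    samp_idx = np.concatenate([np.asarray(h, dtype=np.int64) for h in hits]) if counts.sum() else np.empty(0, np.int64)

    L = np.full((n_nodes, 3, 3), np.nan)
    cond = np.full(n_nodes, np.inf)
    ridge_applied = np.zeros(n_nodes, dtype=bool)
    ok = counts >= min_samples
    if counts.sum() == 0:
        return L, np.zeros(n_nodes, bool), cond, counts, ridge_applied

    dx0 = sample_pos[samp_idx] - centers[node_idx]
    w = np.exp(-np.einsum("ij,ij->i", dx0, dx0) / (2.0 * bandwidth * bandwidth))
    w_sum = np.bincount(node_idx, weights=w, minlength=n_nodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = np.stack(
            [np.bincount(node_idx, weights=w * sample_pos[samp_idx, k], minlength=n_nodes) for k in range(3)],
            axis=1,
        ) / w_sum[:, None]
        vm = np.stack(
            [np.bincount(node_idx, weights=w * sample_vel[samp_idx, k], minlength=n_nodes) for k in range(3)],
            axis=1,
        ) / w_sum[:, None]
    dxc = sample_pos[samp_idx] - xm[node_idx]
    dvc = sample_vel[samp_idx] - vm[node_idx]
    m_mat = np.zeros((n_nodes, 3, 3))
    b_mat = np.zeros((n_nodes, 3, 3))
    for a in range(3):
        for b in range(3):
            m_mat[:, a, b] = np.bincount(node_idx, weights=w * dxc[:, a] * dxc[:, b], minlength=n_nodes)
            b_mat[:, a, b] = np.bincount(node_idx, weights=w * dxc[:, a] * dvc[:, b], minlength=n_nodes)

    m_safe = np.where(ok[:, None, None], m_mat, np.eye(3))
    evals = np.linalg.eigvalsh(m_safe)  # ascending
    s_min, s_mid, s_max = evals[:, 0], evals[:, 1], evals[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(s_min > 0, s_max / s_min, np.inf)
    full_rank = s_min > s_max * rank_tol
    rank_ge2 = s_mid > s_max * rank_tol
    ridge_applied = ok & ~full_rank
    lam = ridge_epsilon * (np.trace(m_safe, axis1=1, axis2=2) / 3.0)
    m_solve = m_safe + np.where(ridge_applied, lam, 0.0)[:, None, None] * np.eye(3)
    valid = ok & rank_ge2
    if valid.any():
        # M X = B with X = M^{-1} B; model is v_c = L x_c so L = B^T M^{-1} = X^T
        x_sol = np.linalg.solve(m_solve[valid], b_mat[valid])
        L[valid] = np.transpose(x_sol, (0, 2, 1))
    return L, valid, cond, counts, ridge_applied


def velocity_gradients(
    positions: np.ndarray,
    velocities: np.ndarray,
    mesh: SphericalMesh,
    geom: EmbryoGeometry,
    cfg: TectonicsConfig,
) -> GradientField:
    """Estimate the velocity-gradient tensor at every mesh node (one frame).

    ``cell_regression`` regresses the member cells' velocities on their 3D
    positions; ``node_field`` first averages velocities per domain and then
    regresses neighboring nodes' mean velocities (tangential information
    only). Nodes with fewer than ``max(4, min_cells_per_domain)`` member
    cells, or whose scatter is rank < 2 even after the ridge rescue, are
    invalid.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    centers = mesh.physical_nodes(geom)
    membership = assign_domains(positions, mesh, geom, cfg)
    v_mean, n_cells, _ = domain_velocity(membership, velocities, cfg)
    min_samples = max(4, cfg.min_cells_per_domain)

    if cfg.gradient_mode == "cell_regression":
        L, valid, cond, counts, ridge = _affine_fit(
            positions, velocities, centers, cfg.domain_radius, cfg.bandwidth,
            min_samples, cfg.ridge_epsilon, cfg.rank_tol,
        )
        valid &= n_cells >= min_samples
    else:  # node_field
        good = np.isfinite(v_mean).all(axis=1)
        # domain means are attached to the member-cell centroid, not the
        # node centre: the mean of an affine field is the field at the
        # centroid, so this keeps affine flows exactly recoverable
        centroids = np.full((len(centers), 3), np.nan)
        for i in np.flatnonzero(good):
            centroids[i] = positions[membership[i]].mean(axis=0)
        L, valid, cond, counts, ridge = _affine_fit(
            centroids[good], v_mean[good], centers, cfg.domain_radius, cfg.bandwidth,
            4, cfg.ridge_epsilon, cfg.rank_tol,
        )
        valid &= n_cells >= cfg.min_cells_per_domain
    L = np.where(valid[:, None, None], L, np.nan)
    return GradientField(L=L, valid=valid, condition_number=cond, n_cells=n_cells,
                         v_mean=v_mean, ridge_applied=ridge)


@dataclass(frozen=True)
class StrainRateTensor:
    """Decomposition of one velocity-gradient tensor.

    ``E_dot + Omega == L`` exactly; ``trace`` equals the eigenvalue sum of
    ``E_dot``; components are the diagonal projections of ``E_dot`` on the
    local anatomical frame (NaN if the frame is missing, i.e. at poles).
    ``curl_r = 2 omega . e_r`` with omega the spin axial vector, positive =
    anticlockwise viewed from outside; ``curl_mag`` is the Frobenius norm
    of ``Omega``. Eigenpairs of ``E_dot`` are sorted descending.
    """

    L: np.ndarray
    E_dot: np.ndarray
    Omega: np.ndarray
    trace: float
    e_AP: float
    e_ML: float
    e_r: float
    curl_r: float
    curl_mag: float
    eigvals: np.ndarray
    eigvecs: np.ndarray


def decompose(L: np.ndarray, frame: LocalFrame, clockwise_positive_curl: bool = False) -> StrainRateTensor:
    """Strain-rate/spin decomposition of a single tensor (see class docs)."""
    out = decompose_field(
        np.asarray(L, dtype=float)[None],
        FrameField(frame.e_AP[None], frame.e_ML[None], frame.e_r[None], np.array([frame.valid])),
        clockwise_positive_curl,
    )
    eigvals, eigvecs = np.linalg.eigh(out["E_dot"][0])
    order = np.argsort(eigvals)[::-1]
    return StrainRateTensor(
        L=np.asarray(L, dtype=float),
        E_dot=out["E_dot"][0],
        Omega=out["Omega"][0],
        trace=float(out["trace"][0]),
        e_AP=float(out["e_AP"][0]),
        e_ML=float(out["e_ML"][0]),
        e_r=float(out["e_r"][0]),
        curl_r=float(out["curl_r"][0]),
        curl_mag=float(out["curl_mag"][0]),
        eigvals=eigvals[order],
        eigvecs=eigvecs[:, order],
    )


def decompose_field(
    L: np.ndarray,
    frames: FrameField,
    clockwise_positive_curl: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorized decomposition of stacked tensors ``L (..., 3, 3)``.

    Returns a dict with ``E_dot``, ``Omega`` and the scalar components of
    :data:`COMPONENT_NAMES`. Tangential projections are NaN where the local
    frame is missing; ``trace`` and ``curl_mag`` are frame-independent and
    always computed from valid tensors.
    """
    L = np.asarray(L, dtype=float)
    E = 0.5 * (L + np.swapaxes(L, -1, -2))
    Om = 0.5 * (L - np.swapaxes(L, -1, -2))
    trace = np.einsum("...ii->...", E)
    e_ap = np.einsum("...i,...ij,...j->...", frames.e_AP, E, frames.e_AP)
    e_ml = np.einsum("...i,...ij,...j->...", frames.e_ML, E, frames.e_ML)
    e_rr = np.einsum("...i,...ij,...j->...", frames.e_r, E, frames.e_r)
    omega = np.stack([Om[..., 2, 1], Om[..., 0, 2], Om[..., 1, 0]], axis=-1)
    curl_r = 2.0 * np.einsum("...i,...i->...", omega, frames.e_r)
    if clockwise_positive_curl:
        curl_r = -curl_r
    curl_mag = np.sqrt(np.einsum("...ij,...ij->...", Om, Om))
    return {
        "E_dot": E, "Omega": Om, "trace": trace,
        "e_AP": e_ap, "e_ML": e_ml, "e_r": e_rr,
        "curl_r": curl_r, "curl_mag": curl_mag,
    }


@dataclass
class TensorField:
    """Velocity-gradient tensors and their scalar components on (time, node).

    ``components[name]`` has shape ``(T, N)`` with NaN where the tensor or
    the local frame is missing.
    """

    times: np.ndarray
    L: np.ndarray  # (T, N, 3, 3)
    valid: np.ndarray  # (T, N)
    n_cells: np.ndarray  # (T, N)
    condition_number: np.ndarray  # (T, N)
    components: dict[str, np.ndarray]
    mesh: SphericalMesh
    geom: EmbryoGeometry
    frames: FrameField


def compute_tensor_field(
    velocity_table: pd.DataFrame,
    mesh: SphericalMesh,
    geom: EmbryoGeometry,
    cfg: TectonicsConfig,
) -> TensorField:
    """Per-frame velocity-gradient estimation over a velocity table.

    ``velocity_table`` is the output of
    :func:`spheretect.tracks.compute_velocities`.
    """
    times = np.unique(velocity_table["t_min"].to_numpy())
    n_nodes = mesh.n_nodes
    frames_field = local_frames(mesh.nodes, geom, cfg.pole_exclusion)
    L = np.full((len(times), n_nodes, 3, 3), np.nan)
    valid = np.zeros((len(times), n_nodes), dtype=bool)
    n_cells = np.zeros((len(times), n_nodes), dtype=np.int64)
    cond = np.full((len(times), n_nodes), np.inf)
    comps = {name: np.full((len(times), n_nodes), np.nan) for name in COMPONENT_NAMES}
    by_time = velocity_table.groupby("t_min", sort=True)
    for it, (_, sub) in enumerate(by_time):
        pos = sub[["x_um", "y_um", "z_um"]].to_numpy()
        vel = sub[["vx_um_min", "vy_um_min", "vz_um_min"]].to_numpy()
        gf = velocity_gradients(pos, vel, mesh, geom, cfg)
        L[it] = gf.L
        valid[it] = gf.valid
        n_cells[it] = gf.n_cells
        cond[it] = gf.condition_number
        dec = decompose_field(gf.L, frames_field, cfg.clockwise_positive_curl)
        for name in COMPONENT_NAMES:
            comps[name][it] = np.where(gf.valid, dec[name], np.nan)
    return TensorField(times=times, L=L, valid=valid, n_cells=n_cells,
                       condition_number=cond, components=comps,
                       mesh=mesh, geom=geom, frames=frames_field)


@dataclass
class StrainMaps:
    """Window-integrated strain components per node and window-centre time.

    Values are dimensionless (strain accumulated over ``window`` minutes),
    in the instantaneous local frame of each node. ``fields[name]`` has
    shape ``(Tc, N)``; NaN marks missing windows (insufficient coverage or
    missing frame).
    """

    times: np.ndarray
    window: float
    fields: dict[str, np.ndarray]
    n_cells: np.ndarray  # (Tc, N) mean member count over the window
    mesh: SphericalMesh
    geom: EmbryoGeometry


def integrate_strain(
    tf: TensorField,
    window: float | None = None,
    min_coverage: float = 0.8,
) -> StrainMaps:
    """Trapezoidal time-integration of component rates over sliding windows.

    Windows of length ``window`` minutes are centred wherever they fit
    entirely inside the time grid. Missing samples inside a window are
    tolerated up to ``1 - min_coverage``: the mean rate over the covered
    sub-intervals is scaled to the full window, so a constant rate ``s``
    always integrates to ``s * window``. Below the coverage floor the value
    is missing.
    """
    times = tf.times
    if len(times) < 2:
        raise ValueError("need at least two frames to integrate")
    h = float(times[1] - times[0])
    if not np.allclose(np.diff(times), h):
        raise ValueError("tensor field is not on a uniform time grid")
    if window is None:
        window = 30.0
    k = int(round(window / h))
    if abs(k * h - window) > 1e-9 * max(window, 1.0):
        raise ValueError("window must be a multiple of the frame interval")
    if k < 2:
        raise ValueError("window must span at least two frame intervals")
    n_centers = len(times) - k
    if n_centers < 1:
        raise ValueError("window longer than the recording")
    centers = 0.5 * (times[:n_centers] + times[k:])
    fields = {}
    for name, rates in tf.components.items():
        out = np.full((n_centers, rates.shape[1]), np.nan)
        for i in range(n_centers):
            seg = rates[i : i + k + 1]
            pair_ok = np.isfinite(seg[:-1]) & np.isfinite(seg[1:])
            contrib = np.where(pair_ok, 0.5 * h * (np.nan_to_num(seg[:-1]) + np.nan_to_num(seg[1:])), 0.0)
            covered = h * pair_ok.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                val = contrib.sum(axis=0) * (window / covered)
            out[i] = np.where(covered >= min_coverage * window - 1e-9, val, np.nan)
        fields[name] = out
    n_cells = np.stack([tf.n_cells[i : i + k + 1].mean(axis=0) for i in range(n_centers)])
    return StrainMaps(times=centers, window=float(window), fields=fields,
                      n_cells=n_cells, mesh=tf.mesh, geom=tf.geom)


def divergence_map(sm: StrainMaps) -> np.ndarray:
    """The integrated strain-trace field (divergence of the velocity field).

    Identical to ``sm.fields['trace']``; equals the sum of the three
    integrated diagonal components wherever the local frame exists.
    """
    return sm.fields["trace"]


def compute_strain_maps(
    velocity_table: pd.DataFrame,
    mesh: SphericalMesh,
    geom: EmbryoGeometry,
    cfg: TectonicsConfig,
) -> tuple[TensorField, StrainMaps]:
    """End-to-end: velocity table -> tensor field -> integrated strain maps."""
    tf = compute_tensor_field(velocity_table, mesh, geom, cfg)
    sm = integrate_strain(tf, cfg.window, cfg.min_window_coverage)
    return tf, sm


def strain_table(sm: StrainMaps) -> pd.DataFrame:
    """Long-format export: one row per (node, window-centre time).

    Columns ``node_id, theta, phi, t_min, e_AP, e_ML, e_r, trace, curl_r,
    n_cells, valid`` with angles in radians.
    """
    coord = to_embryo_coords(sm.mesh.physical_nodes(sm.geom), sm.geom)
    n_nodes = sm.mesh.n_nodes
    rows = []
    for it, t in enumerate(sm.times):
        df = pd.DataFrame(
            {
                "node_id": np.arange(n_nodes),
                "theta": coord.theta,
                "phi": coord.phi,
                "t_min": t,
                "e_AP": sm.fields["e_AP"][it],
                "e_ML": sm.fields["e_ML"][it],
                "e_r": sm.fields["e_r"][it],
                "trace": sm.fields["trace"][it],
                "curl_r": sm.fields["curl_r"][it],
                "n_cells": np.round(sm.n_cells[it]).astype(int),
            }
        )
        df["valid"] = np.isfinite(sm.fields["e_ML"][it])
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_strain_table(sm: StrainMaps, path: str, delimiter: str = ",") -> None:
    """Write the long-format strain table with a reproducibility header."""
    g = sm.geom
    with open(path, "w") as fh:
        fh.write("# integrated strain components (dimensionless); theta, phi in radians\n")
        fh.write(f"# window_min: {sm.window}\n")
        fh.write(f"# n_nodes: {sm.mesh.n_nodes}\n")
        fh.write(
            "# geometry: center_um=%r radius_um=%r anterior=%r dorsal=%r\n"
            % (list(g.center), g.radius_R, list(g.anterior_axis), list(g.dorsal_ref))
        )
        strain_table(sm).to_csv(fh, sep=delimiter, index=False)


def read_strain_table(path: str, delimiter: str = ",") -> tuple[pd.DataFrame, dict]:
    """Read a strain table written by :func:`write_strain_table`.

    Returns the long-format DataFrame and a metadata dict with
    ``window_min`` and ``n_nodes`` when present in the header.
    """
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# window_min:"):
                meta["window_min"] = float(line.split(":", 1)[1])
            elif line.startswith("# n_nodes:"):
                meta["n_nodes"] = int(line.split(":", 1)[1])
    df = pd.read_csv(path, sep=delimiter, comment="#")
    return df, meta


def write_strain_h5(sm: StrainMaps, path: str) -> None:
    """Binary container for large runs: one HDF5 group per component."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["window_min"] = sm.window
        fh.attrs["radius_um"] = sm.geom.radius_R
        fh.create_dataset("times_min", data=sm.times)
        fh.create_dataset("nodes_unit", data=sm.mesh.nodes)
        fh.create_dataset("n_cells", data=sm.n_cells)
        grp = fh.create_group("components")
        for name, arr in sm.fields.items():
            grp.create_dataset(name, data=arr)
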