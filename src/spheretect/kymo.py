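"""Angle x time kymographs of strain components along annular bands.

Two band families mirror the figures of the analysis: the *equatorial*
band (nodes within ``half_span`` radians of the equatorial plane,
parameterized by the signed azimuth from -180 deg through the dorsal
meridian at 0 deg to +180 deg, anticlockwise seen from the anterior pole)
and the *axial* bands along the dorsal or ventral meridian (parameterized
by the elevation from the anterior pole, 0-180 deg). The default full
span is 0.38 rad. Within a band, node values are averaged (unweighted)
into angle bins of 5 deg per window-centre time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EmbryoGeometry, SphericalMesh, to_embryo_coords
from .tectonics import StrainMaps

__all__ = ["KymographSpec", "BandSelection", "Kymograph", "select_band", "band_from_angles", "build_kymograph", "write_kymograph"]

BANDS = ("equatorial", "axial_dorsal", "axial_ventral")


@dataclass(frozen=True)
class KymographSpec:
    """Band, angular resolution and component of one kymograph."""

    band: str = "equatorial"
    half_span: float = 0.19  # radians; full span 0.38
    angle_bin: float = 5.0  # degrees
    component: str = "e_ML"

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}")
        if not 0 < self.half_span < np.pi / 4:
            raise ValueError("half_span must be in (0, pi/4)")
        if self.band == "equatorial" and abs(round(360 / self.angle_bin) - 360 / self.angle_bin) > 1e-9:
            raise ValueError("360 must be divisible by angle_bin for the equatorial band")


@dataclass(frozen=True)
class BandSelection:
    """Node subset of a band with each node's band angle in degrees."""

    node_idx: np.ndarray
    angles_deg: np.ndarray
    band: str


def band_from_angles(theta: np.ndarray, phi: np.ndarray, spec: KymographSpec) -> BandSelection:
    """Select band members from per-node (theta, phi) in radians."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if spec.band == "equatorial":
        mask = np.abs(theta - np.pi / 2) <= spec.half_span
        angles = np.degrees(phi)
    elif spec.band == "axial_dorsal":
        mask = np.abs(_wrap(phi)) <= spec.half_span
        angles = np.degrees(theta)
    else:  # axial_ventral
        mask = np.abs(_wrap(phi - np.pi)) <= spec.half_span
        angles = np.degrees(theta)
    mask &= np.isfinite(angles)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(
            f"no nodes fall inside the {spec.band} band (half_span={spec.half_span}); "
            "increase half_span or the mesh resolution"
        )
    return BandSelection(node_idx=idx, angles_deg=angles[idx], band=spec.band)


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2 * np.pi)


def select_band(mesh: SphericalMesh, geom: EmbryoGeometry, spec: KymographSpec) -> BandSelection:
    """Band members of a mesh (see :func:`band_from_angles`)."""
    coord = to_embryo_coords(mesh.physical_nodes(geom), geom)
    return band_from_angles(coord.theta, coord.phi, spec)


@dataclass(frozen=True)
class Kymograph:
    """Angle x time matrix of one integrated strain component.

    ``values`` has shape ``(n_bins, n_times)``; bins with no contributing
    domain are NaN (missing, not zero). ``counts`` gives the contributing
    valid-node count per cell.
    """

    angles: np.ndarray  # bin centres, degrees
    times: np.ndarray  # window centres, minutes
    values: np.ndarray
    counts: np.ndarray
    component: str
    band: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.angles, columns=self.times)


def _bin_indices(angles_deg: np.ndarray, spec: KymographSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map band angles to bin indices; returns (indices, bin centres)."""
    width = spec.angle_bin
    if spec.band == "equatorial":
        # circular bins centred on multiples of the bin width; the dorsal 0 deg
        # bin is centred, and +/-180 deg share the wrap-around bin
        n_bins = int(round(360 / width))
        centers = -180.0 + width * np.arange(n_bins)
        idx = np.mod(np.round((angles_deg + 180.0) / width).astype(int), n_bins)
    else:
        n_bins = int(round(180 / width)) + 1
        centers = width * np.arange(n_bins)
        idx = np.clip(np.round(angles_deg / width).astype(int), 0, n_bins - 1)
    return idx, centers


def build_kymograph(sm: StrainMaps | dict, band: BandSelection, spec: KymographSpec,
                    times: np.ndarray | None = None) -> Kymograph:
    """Average one strain component over band nodes into angle x time bins.

    ``sm`` is either a :class:`~spheretect.tectonics.StrainMaps` or a plain
    dict of component arrays ``(T, N)`` (then ``times`` is required). The
    per-bin average is unweighted over valid (finite) band nodes; empty
    bins are missing.
    """
    if isinstance(sm, StrainMaps):
        fields, times = sm.fields, sm.times
    else:
        fields = sm
        if times is None:
            raise ValueError("times required when passing a raw component dict")
    if spec.component not in fields:
        raise ValueError(f"component {spec.component!r} not present; have {sorted(fields)}")
    data = fields[spec.component][:, band.node_idx]  # (T, nband)
    idx, centers = _bin_indices(band.angles_deg, spec)
    n_bins, n_times = len(centers), data.shape[0]
    values = np.full((n_bins, n_times), np.nan)
    counts = np.zeros((n_bins, n_times), dtype=np.int64)
    finite = np.isfinite(data)
    for j in range(n_bins):
        cols = idx == j
        if not cols.any():
            continue
        sub = data[:, cols]
        fin = finite[:, cols]
        n = fin.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nansum(np.where(fin, sub, 0.0), axis=1) / n
        values[j] = np.where(n > 0, mean, np.nan)
        counts[j] = n
    return Kymograph(angles=centers, times=np.asarray(times, dtype=float),
                     values=values, counts=counts,
                     component=spec.component, band=spec.band)


def write_kymograph(kym: Kymograph, path: str, delimiter: str = ",") -> None:
    """Delimited matrix with angle row labels and time column labels."""
    with open(path, "w") as fh:
        fh.write(f"# kymograph: component={kym.component} band={kym.band}; "
                 "rows = angle (deg), columns = window-centre time (min)\n")
        kym.to_frame().to_csv(fh, sep=delimiter, index_label="angle_deg")
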