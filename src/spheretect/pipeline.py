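"""End-to-end orchestration: tracks in, strain tables / kymographs / maps out.

A run is described by a serializable :class:`RunConfig`; every parameter
that affects numerics (domain radius, window, gradient mode, seed, axes)
is logged and a copy of the config is written into the output directory so
runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import render as _render
from .geometry import EmbryoGeometry, fit_sphere, make_mesh, save_geometry
from .kymo import KymographSpec, build_kymograph, select_band, write_kymograph
from .tectonics import (
    StrainMaps,
    TectonicsConfig,
    TensorField,
    compute_strain_maps,
    write_strain_h5,
    write_strain_table,
)
from .tracks import TrackSet, compute_velocities, link_nearest_neighbor, read_detections, read_tracks

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "fit_geometry"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (YAML-serializable)."""

    out_dir: str = "spheretect_out"
    tracks_path: str | None = None
    detections_path: str | None = None
    max_disp: float | None = None
    frame_interval: float = 2.0
    anterior_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dorsal_ref: tuple[float, float, float] = (1.0, 0.0, 0.0)
    center_um: tuple[float, float, float] | None = None
    radius_um: float | None = None
    per_frame_geometry: bool = False
    n_nodes: int = 2000
    tectonics: TectonicsConfig = field(default_factory=TectonicsConfig)
    kymographs: list[KymographSpec] = field(
        default_factory=lambda: [
            KymographSpec(band="equatorial", component=c) for c in ("e_ML", "e_AP", "e_r")
        ]
    )
    render_components: tuple[str, ...] = ("e_ML", "e_AP", "trace", "curl_r")
    views: tuple[str, ...] = ("dorsal", "ventral")
    write_hdf5: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        payload["tectonics"] = dataclasses.asdict(self.tectonics)
        payload["kymographs"] = [dataclasses.asdict(k) for k in self.kymographs]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "tectonics" in payload and payload["tectonics"] is not None:
            payload["tectonics"] = TectonicsConfig(**payload["tectonics"])
        if "kymographs" in payload and payload["kymographs"] is not None:
            payload["kymographs"] = [KymographSpec(**k) for k in payload["kymographs"]]
        for key in ("anterior_axis", "dorsal_ref", "center_um", "render_components", "views"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class PipelineResult:
    """In-memory results plus the paths written by :func:`run_pipeline`."""

    geometry: EmbryoGeometry
    tensor_field: TensorField
    strain_maps: StrainMaps
    kymographs: list
    outputs: dict[str, str]


def fit_geometry(
    ts: TrackSet,
    anterior_axis,
    dorsal_ref,
    center=None,
    radius=None,
    per_frame: bool = False,
) -> EmbryoGeometry:
    """Embryo geometry from tracked positions plus user-supplied axes.

    Unless centre and radius are given, a sphere is fitted to each frame's
    positions and the per-frame fits are averaged into one static geometry
    (``per_frame=True`` returns the same averaged geometry but logs the
    per-frame spread for inspection).
    """
    if center is not None and radius is not None:
        return EmbryoGeometry(center=np.asarray(center, float), radius_R=float(radius),
                              anterior_axis=anterior_axis, dorsal_ref=dorsal_ref)
    centers, radii = [], []
    for t in ts.times:
        _, pos = ts.positions_at(t)
        if len(pos) >= 4:
            c, r = fit_sphere(pos)
            centers.append(c)
            radii.append(r)
    if not centers:
        raise ValueError("not enough positions to fit the embryo sphere")
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    if per_frame:
        log.info("per-frame sphere fits: radius %.2f +/- %.2f um, centre spread %.2f um",
                 radii.mean(), radii.std(), centers.std(axis=0).max())
    return EmbryoGeometry(center=centers.mean(axis=0), radius_R=float(radii.mean()),
                          anterior_axis=anterior_axis, dorsal_ref=dorsal_ref)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full tectonics pipeline and write all outputs to disk."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("spheretect")
    root.addHandler(handler)
    root.setLevel(cfg.log_level)
    outputs: dict[str, str] = {}
    try:
        cfg.to_yaml(str(out / "config.yaml"))
        outputs["config"] = str(out / "config.yaml")
        log.info(
            "run: domain_radius=%.1f um, window=%.1f min, mode=%s, n_nodes=%d, seed=%d",
            cfg.tectonics.domain_radius, cfg.tectonics.window,
            cfg.tectonics.gradient_mode, cfg.n_nodes, cfg.seed,
        )
        if cfg.tracks_path:
            ts = read_tracks(cfg.tracks_path, frame_interval=cfg.frame_interval)
        elif cfg.detections_path:
            frames = read_detections(cfg.detections_path)
            ts = link_nearest_neighbor(frames, max_disp=cfg.max_disp)
        else:
            raise ValueError("config must provide tracks_path or detections_path")
        log.info("loaded %d tracks over %d frames", ts.n_tracks, len(ts.times))

        geom = fit_geometry(ts, cfg.anterior_axis, cfg.dorsal_ref,
                            cfg.center_um, cfg.radius_um, cfg.per_frame_geometry)
        save_geometry(geom, str(out / "geometry.yaml"))
        outputs["geometry"] = str(out / "geometry.yaml")
        log.info("geometry: centre %s, radius %.2f um", np.round(geom.center, 2), geom.radius_R)

        mesh = make_mesh(cfg.n_nodes)
        vel = compute_velocities(ts)
        tf, sm = compute_strain_maps(vel, mesh, geom, cfg.tectonics)
        write_strain_table(sm, str(out / "strain_maps.csv"))
        outputs["strain_table"] = str(out / "strain_maps.csv")
        if cfg.write_hdf5:
            write_strain_h5(sm, str(out / "strain_maps.h5"))
            outputs["strain_h5"] = str(out / "strain_maps.h5")

        kymographs = []
        for spec in cfg.kymographs:
            band = select_band(mesh, geom, spec)
            kym = build_kymograph(sm, band, spec)
            kymographs.append(kym)
            stem = f"kymograph_{spec.band}_{spec.component}"
            write_kymograph(kym, str(out / f"{stem}.csv"))
            _render.render_kymograph(kym, str(out / f"{stem}.png"))
            outputs[stem] = str(out / f"{stem}.csv")

        if len(sm.times):
            mid = len(sm.times) // 2
            for comp in cfg.render_components:
                for view in cfg.views:
                    png = out / f"map_{comp}_{view}.png"
                    _render.render_map(mesh, geom, sm.fields[comp][mid], view, str(png),
                                       title=f"{comp} @ {sm.times[mid]:.0f} min ({view})")
                    outputs[png.stem] = str(png)
            # domain-mean velocities at the middle frame for the vector map
            from .tectonics import assign_domains, domain_velocity

            it_mid = len(tf.times) // 2
            sub = vel[np.isclose(vel["t_min"], tf.times[it_mid])]
            membership = assign_domains(sub[["x_um", "y_um", "z_um"]].to_numpy(), mesh, geom, cfg.tectonics)
            v_mean, _, _ = domain_velocity(membership, sub[["vx_um_min", "vy_um_min", "vz_um_min"]].to_numpy(), cfg.tectonics)
            png = out / "velocity_dorsal.png"
            _render.render_velocity(mesh, geom, v_mean, tf.frames, "dorsal", str(png))
            outputs["velocity_dorsal"] = str(png)
        log.info("pipeline complete: %d output files", len(outputs))
        return PipelineResult(geometry=geom, tensor_field=tf, strain_maps=sm,
                              kymographs=kymographs, outputs=outputs)
    finally:
        root.removeHandler(handler)
        handler.close()
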