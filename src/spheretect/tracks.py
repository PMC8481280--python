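"""Cell-track tables, nearest-neighbor linking, and per-cell velocities.

Tracks are stored as a flat table with columns ``track_id, t_min, x_um,
y_um, z_um`` (time in minutes, positions in micrometres). Detections are
linked frame-to-frame by greedy mutual nearest neighbors; velocities are
central differences at the acquisition interval (2 min by default), with
one-sided differences at track ends and no velocity across gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TrackSet",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "read_detections",
    "write_detections",
    "link_nearest_neighbor",
    "compute_velocities",
    "count_cells_per_frame",
]

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "t_min", "x_um", "y_um", "z_um"]
_COLUMN_ALIASES = {"t": "t_min", "x": "x_um", "y": "y_um", "z": "z_um", "id": "track_id"}


class TrackFormatError(ValueError):
    """Malformed track/detection table (bad rows are named by line number)."""


@dataclass
class TrackSet:
    """An ordered set of cell tracks.

    ``table`` holds one row per (track, time) sample; within each track
    times are strictly increasing and spaced by integer multiples of
    ``frame_interval`` (multiples > 1 are gaps, allowed and recorded in
    ``gap_track_ids``).
    """

    table: pd.DataFrame
    frame_interval: float = 2.0
    gap_track_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.table.columns]
        if missing:
            raise TrackFormatError(f"track table missing columns: {missing}")
        df = (
            self.table[TRACK_COLUMNS]
            .astype({"track_id": np.int64, "t_min": float, "x_um": float, "y_um": float, "z_um": float})
            .sort_values(["track_id", "t_min"], kind="mergesort")
            .reset_index(drop=True)
        )
        if not np.isfinite(df[["t_min", "x_um", "y_um", "z_um"]].to_numpy()).all():
            raise TrackFormatError("non-finite time or position in track table")
        dt = df.groupby("track_id")["t_min"].diff()
        bad_mono = df.loc[dt <= 0, "track_id"].unique()
        if len(bad_mono):
            raise TrackFormatError(f"non-monotonic times within track(s): {sorted(bad_mono)}")
        steps = dt.dropna() / self.frame_interval
        off_grid = np.abs(steps - np.round(steps)) > 1e-6
        if off_grid.any():
            bad = df.loc[steps.index[off_grid], "track_id"].unique()
            raise TrackFormatError(
                f"track sample spacing is not a multiple of frame_interval for track(s): {sorted(bad)}"
            )
        gaps = np.round(steps) > 1
        gap_ids = frozenset(int(i) for i in df.loc[steps.index[gaps], "track_id"].unique())
        dup = df.duplicated(subset=["t_min", "x_um", "y_um", "z_um"], keep=False)
        if dup.any() and df.loc[dup].duplicated(subset=["t_min", "x_um", "y_um", "z_um"]).any():
            raise TrackFormatError("two tracks share an identical (time, position) entry")
        object.__setattr__(self, "table", df)
        object.__setattr__(self, "gap_track_ids", gap_ids)

    @property
    def track_ids(self) -> np.ndarray:
        return self.table["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.table["t_min"].to_numpy())

    def positions_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Track ids and (n, 3) positions of all cells present at time ``t``."""
        sub = self.table[np.isclose(self.table["t_min"], t)]
        return sub["track_id"].to_numpy(), sub[["x_um", "y_um", "z_um"]].to_numpy()

    def iter_tracks(self):
        """Yield ``(track_id, times, positions)`` per track, time-ordered."""
        for tid, sub in self.table.groupby("track_id", sort=True):
            yield int(tid), sub["t_min"].to_numpy(), sub[["x_um", "y_um", "z_um"]].to_numpy()


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _parse_table(path: str, columns: list[str], dialect: str | None) -> pd.DataFrame:
    """Strict line-by-line reader reporting malformed rows by line number."""
    rows: list[tuple] = []
    bad: list[int] = []
    header: list[str] | None = None
    delim = dialect
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                delim = delim or _detect_delimiter(line)
                names = [_COLUMN_ALIASES.get(f.strip(), f.strip()) for f in line.split(delim)]
                missing = [c for c in columns if c not in names]
                if missing:
                    raise TrackFormatError(f"{path}: header missing columns {missing} (line {lineno})")
                header = names
                idx = [names.index(c) for c in columns]
                continue
            parts = line.split(delim)
            if len(parts) != len(header):
                bad.append(lineno)
                continue
            try:
                rows.append(tuple(float(parts[i]) for i in idx))
            except ValueError:
                bad.append(lineno)
    if header is None:
        raise TrackFormatError(f"{path}: no header row found")
    if bad:
        raise TrackFormatError(f"{path}: malformed row(s) at line(s) {bad}")
    return pd.DataFrame(rows, columns=columns)


def read_tracks(path: str, dialect: str | None = None, frame_interval: float = 2.0) -> TrackSet:
    """Read a delimited track table (columns ``track_id, t, x, y, z`` or the
    ``_min``/``_um`` suffixed forms; ``#`` lines are comments)."""
    df = _parse_table(path, TRACK_COLUMNS, dialect)
    return TrackSet(table=df, frame_interval=frame_interval)


def write_tracks(ts: TrackSet, path: str, delimiter: str = ",") -> None:
    """Write a track table; round-trips losslessly through :func:`read_tracks`."""
    with open(path, "w") as fh:
        fh.write("# units: t_min = minutes post start; x_um, y_um, z_um = micrometres\n")
        ts.table.to_csv(fh, sep=delimiter, index=False)


def read_detections(path: str, dialect: str | None = None) -> list[tuple[float, np.ndarray]]:
    """Read per-frame detections (columns ``t, x, y, z``) as a time-sorted
    list of ``(time, (n, 3) positions)`` pairs."""
    df = _parse_table(path, ["t_min", "x_um", "y_um", "z_um"], dialect)
    frames = []
    for t, sub in df.groupby("t_min", sort=True):
        frames.append((float(t), sub[["x_um", "y_um", "z_um"]].to_numpy()))
    return frames


def write_detections(frames: list[tuple[float, np.ndarray]], path: str, delimiter: str = ",") -> None:
    rows = [(t, *p) for t, pos in frames for p in np.atleast_2d(pos)]
    df = pd.DataFrame(rows, columns=["t_min", "x_um", "y_um", "z_um"])
    with open(path, "w") as fh:
        fh.write("# units: t_min = minutes post start; x_um, y_um, z_um = micrometres\n")
        df.to_csv(fh, sep=delimiter, index=False)


def _mutual_links(a: np.ndarray, b: np.ndarray, max_disp: float) -> list[tuple[int, int, float]]:
    """Greedy mutual-nearest-neighbor pairs (ia, ib, dist) within max_disp."""
    if len(a) == 0 or len(b) == 0:
        return []
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    _, nn_ab = tree_b.query(a)
    d_ba, nn_ba = tree_a.query(b)
    out = []
    for ib in range(len(b)):
        ia = int(nn_ba[ib])
        if int(nn_ab[ia]) == ib and d_ba[ib] <= max_disp:
            out.append((ia, ib, float(d_ba[ib])))
    return out


def link_nearest_neighbor(
    frames: list[tuple[float, np.ndarray]],
    max_disp: float | None = None,
    frame_interval: float | None = None,
) -> TrackSet:
    """Link per-frame detections into tracks by mutual nearest neighbors.

    Consecutive frames are matched greedily: a pair links only if each
    detection is the other's nearest neighbor and their distance does not
    exceed ``max_disp``. Unmatched detections start new tracks; tracks with
    no match terminate (a detection that reappears gets a new id).

    ``max_disp=None`` estimates the cutoff as 3x the median frame-to-frame
    displacement from a first, unthresholded linking pass. The procedure is
    deterministic; equidistant candidates are resolved by the k-d tree's
    fixed tie order (lowest index, hence smallest track id for same-frame
    starts).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to link")
    frames = sorted(frames, key=lambda fp: fp[0])
    if max_disp is None:
        disps = []
        for (_, a), (_, b) in zip(frames[:-1], frames[1:]):
            disps.extend(d for _, _, d in _mutual_links(a, b, np.inf))
        med = float(np.median(disps)) if disps else 0.0
        max_disp = 3.0 * med if med > 0 else np.inf
        log.info("link_nearest_neighbor: estimated max_disp = %.3g um", max_disp)

    t0, p0 = frames[0]
    ids = np.arange(len(p0), dtype=np.int64)
    next_id = len(p0)
    rows = [(int(i), t0, *xyz) for i, xyz in zip(ids, p0)]
    for (ta, a), (tb, b) in zip(frames[:-1], frames[1:]):
        if len(b) == 0:
            log.warning("empty frame at t=%.3g min: all tracks terminate", tb)
        new_ids = np.full(len(b), -1, dtype=np.int64)
        for ia, ib, _ in _mutual_links(a, b, max_disp):
            new_ids[ib] = ids[ia]
        for ib in np.flatnonzero(new_ids < 0):
            new_ids[ib] = next_id
            next_id += 1
        rows.extend((int(i), tb, *xyz) for i, xyz in zip(new_ids, b))
        ids = new_ids

    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if frame_interval is None:
        ts = np.array(sorted({t for t, _ in frames}))
        frame_interval = float(np.min(np.diff(ts))) if len(ts) > 1 else 2.0
    return TrackSet(table=df, frame_interval=frame_interval)


def compute_velocities(ts: TrackSet, max_speed: float | None = None) -> pd.DataFrame:
    """Per-cell velocities (um/min) at every sample where a difference exists.

    Central differences in the track interior, one-sided at track ends;
    samples isolated by gaps larger than one frame get no velocity and are
    dropped (counts logged). Rows exceeding ``max_speed`` are flagged in the
    ``speed_flag`` column, never dropped.

    Returns a DataFrame ``track_id, t_min, x_um.., vx_um_min.., speed_flag``.
    """
    df = ts.table.copy()
    h = ts.frame_interval
    g = df.groupby("track_id", sort=False)
    tp, tn = g["t_min"].shift(1), g["t_min"].shift(-1)
    has_prev = np.isclose(df["t_min"] - tp, h)
    has_next = np.isclose(tn - df["t_min"], h)
    for c, vc in (("x_um", "vx_um_min"), ("y_um", "vy_um_min"), ("z_um", "vz_um_min")):
        xp, xn = g[c].shift(1), g[c].shift(-1)
        central = (xn - xp) / (tn - tp)
        fwd = (xn - df[c]) / (tn - df["t_min"])
        bwd = (df[c] - xp) / (df["t_min"] - tp)
        df[vc] = np.where(
            has_prev & has_next, central, np.where(has_next, fwd, np.where(has_prev, bwd, np.nan))
        )
    n_before = len(df)
    df = df.dropna(subset=["vx_um_min", "vy_um_min", "vz_um_min"]).reset_index(drop=True)
    skipped = n_before - len(df)
    if skipped:
        log.info("compute_velocities: %d samples without velocity (gaps/single points)", skipped)
    speed = np.linalg.norm(df[["vx_um_min", "vy_um_min", "vz_um_min"]].to_numpy(), axis=1)
    df["speed_flag"] = speed > max_speed if max_speed is not None else False
    if max_speed is not None and df["speed_flag"].any():
        log.warning("compute_velocities: %d samples exceed max_speed", int(df["speed_flag"].sum()))
    return df


def count_cells_per_frame(ts: TrackSet) -> pd.DataFrame:
    """Number of distinct tracks present at each frame time."""
    out = ts.table.groupby("t_min")["track_id"].nunique().reset_index()
    return out.rename(columns={"track_id": "n_cells"})
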