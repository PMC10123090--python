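"""Track containers and I/O for single-particle tracking data.

Tracks are per-molecule localization time series. Coordinates are physical
micrometres, frame indices are 0-based integers, and time is derived as
``frame * frame_interval``. Readers exist for a plain CSV dialect
(``track_id,frame,x_um,y_um[,t_s]``) and for the TrackMate model-XML dialect
(spots + track edges); spot detection and track linking themselves are out
of scope — tracks are consumed, never built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Track",
    "TrackSet",
    "TrackFormatError",
    "TrackValidationError",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_trackmate_xml",
    "filter_tracks",
]


class TrackFormatError(ValueError):
    """Input file does not conform to the expected dialect."""


class TrackValidationError(ValueError):
    """Track content violates an invariant (e.g. non-monotone frames)."""


@dataclass(frozen=True)
class Track:
    """A single trajectory: strictly increasing frames with x/y in µm.

    ``state_label`` carries the ground-truth diffusive state for simulated
    tracks (``None`` for experimental data). Frame gaps are legal and are
    preserved; downstream displacement computations pair only frames that
    are exactly ``lag`` apart, so gap closures never masquerade as
    single-frame jumps.
    """

    track_id: int
    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    state_label: int | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (len(frames) == len(x) == len(y)):
            raise TrackValidationError(
                f"track {self.track_id}: frames/x/y length mismatch"
            )
        if len(frames) < 2:
            raise TrackValidationError(
                f"track {self.track_id}: needs >= 2 localizations, got {len(frames)}"
            )
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: frame indices not strictly increasing"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrackValidationError(f"track {self.track_id}: non-finite coordinate")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.frames)

    def times(self, frame_interval: float) -> np.ndarray:
        """Times in seconds for each localization."""
        return self.frames * frame_interval


@dataclass
class TrackSet:
    """A collection of tracks sharing one frame interval.

    ``provenance`` accumulates free-text records of the source file and
    every filter applied, so any downstream number can be traced back.
    """

    tracks: list[Track]
    frame_interval: float  # seconds
    condition_label: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be > 0")
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise TrackValidationError("duplicate track ids in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def n_localizations(self) -> int:
        return sum(len(t) for t in self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": t.track_id,
                        "frame": t.frames,
                        "x_um": t.x,
                        "y_um": t.y,
                        "t_s": t.frames * self.frame_interval,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um", "t_s"])
        return pd.concat(rows, ignore_index=True)


REQUIRED_CSV_COLUMNS = ("track_id", "frame", "x_um", "y_um")


def read_tracks_csv(
    path, frame_interval: float = 0.024, condition_label: str = ""
) -> TrackSet:
    """Read the track CSV dialect ``track_id,frame,x_um,y_um[,t_s]``.

    Parameters
    ----------
    path : str or file-like
        CSV file with the required header.
    frame_interval : float
        Frame-to-frame interval in seconds (default 24 ms, the camera cycle
        time of the time-lapse protocol this dialect was designed around).
    """
    df = pd.read_csv(path)
    for col in REQUIRED_CSV_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"missing required column {col!r}")
    bad = df[list(REQUIRED_CSV_COLUMNS[1:])].isna().any(axis=1) | df["track_id"].isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise TrackFormatError(f"malformed rows at lines {lines}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        if grp["frame"].duplicated().any():
            raise TrackValidationError(f"track {tid}: duplicate frame index")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x_um"].to_numpy(dtype=np.float64),
                y=grp["y_um"].to_numpy(dtype=np.float64),
            )
        )
    name = getattr(path, "name", str(path))
    return TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        condition_label=condition_label,
        provenance=[f"read_tracks_csv:{name}"],
    )


def write_tracks_csv(ts: TrackSet, path) -> None:
    """Write a TrackSet in the CSV dialect (coordinates to 6 decimals)."""
    df = ts.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6f")


_MICRON_UNITS = {"micron", "microns", "um", "µm", "micrometer", "micrometre"}


def read_trackmate_xml(
    path, frame_interval: float | None = None, condition_label: str = ""
) -> TrackSet:
    """Read a TrackMate model XML export (spots + track edges).

    Only the ``Model`` section is consumed: ``Spot`` elements with
    ``POSITION_X``/``POSITION_Y`` (µm) and ``FRAME``, grouped into tracks by
    the ``Edge`` elements of ``AllTracks``. Detection and linking settings
    found in the file are recorded as provenance strings, never applied.

    Raises
    ------
    TrackFormatError
        If the spatial units are missing or not micrometres — there is no
        silent unit guessing.
    """
    tree = etree.parse(str(path) if not hasattr(path, "read") else path)
    root = tree.getroot()
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise TrackFormatError("no <Model> element found")
    units = (model.get("spatialunits") or "").strip().lower()
    if units not in _MICRON_UNITS:
        raise TrackFormatError(
            f"spatial units {units!r} are not micrometres; refusing to guess"
        )
    if frame_interval is None:
        ti = model.get("timeinterval")
        frame_interval = float(ti) if ti else 0.024

    spots: dict[int, tuple[int, float, float]] = {}
    for spot in model.iter("Spot"):
        sid = int(spot.get("ID"))
        spots[sid] = (
            int(float(spot.get("FRAME"))),
            float(spot.get("POSITION_X")),
            float(spot.get("POSITION_Y")),
        )

    provenance = [f"read_trackmate_xml:{getattr(path, 'name', str(path))}"]
    settings = root.find("Settings")
    if settings is not None:
        for holder in settings.iter("LinkerSettings", "DetectorSettings"):
            for k, v in sorted(holder.attrib.items()):
                provenance.append(f"trackmate_setting:{holder.tag}.{k}={v}")

    tracks = []
    all_tracks = model.find("AllTracks")
    if all_tracks is None:
        raise TrackFormatError("no <AllTracks> element found")
    for trk in all_tracks.iter("Track"):
        tid = int(trk.get("TRACK_ID"))
        member_ids: set[int] = set()
        for edge in trk.iter("Edge"):
            member_ids.add(int(edge.get("SPOT_SOURCE_ID")))
            member_ids.add(int(edge.get("SPOT_TARGET_ID")))
        if not member_ids:
            continue
        data = sorted(spots[sid] for sid in member_ids)
        frames = np.array([d[0] for d in data], dtype=np.int64)
        tracks.append(
            Track(
                track_id=tid,
                frames=frames,
                x=np.array([d[1] for d in data]),
                y=np.array([d[2] for d in data]),
            )
        )
    return TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        condition_label=condition_label,
        provenance=provenance,
    )


def filter_tracks(
    ts: TrackSet, min_length: int = 5, bleach_cutoff_frame: int = 500
) -> TrackSet:
    """Apply the standard SPT quality filter.

    Localizations with ``frame < bleach_cutoff_frame`` are dropped first
    (removal of the dye bleaching phase at the start of a movie, applied at
    the localization level), then any track left with fewer than
    ``min_length`` localizations is removed. The defaults — 5 localizations,
    500-frame cutoff — are the acquisition-protocol values the CSV dialect
    was built around; simulated data starting at frame 0 should pass
    ``bleach_cutoff_frame=0``.

    Idempotent: applying the same filter twice equals applying it once.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    kept = []
    for t in ts.tracks:
        mask = t.frames >= bleach_cutoff_frame
        if int(mask.sum()) < min_length:
            continue
        kept.append(
            replace(t, frames=t.frames[mask], x=t.x[mask], y=t.y[mask])
            if not mask.all()
            else t
        )
    return TrackSet(
        tracks=kept,
        frame_interval=ts.frame_interval,
        condition_label=ts.condition_label,
        provenance=ts.provenance
        + [f"filter_tracks:min_length={min_length},bleach_cutoff_frame={bleach_cutoff_frame}"],
    )
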