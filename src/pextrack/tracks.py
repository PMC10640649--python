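"""Track containers and I/O for 2-D single-particle tracks.

A :class:`Track` is one particle's time-ordered sequence of planar
positions (in micrometres) with integer frame indices and a frame
interval ``dt`` (seconds).  Tracks are grouped into a :class:`TrackSet`
by experimental condition and by the cell they were recorded in, which
is the unit of aggregation for all downstream per-cell statistics.

Two input formats are supported: a plain CSV table
(``track_id,frame,x,y[,cell_id,condition]``) and TrackMate model XML
(spots + track edges, positions in micrometres).  Spot detection,
linking and gap closing happen upstream in the tracking software; this
module only consumes their output.  Frame gaps (from gap-closed links)
are preserved as non-consecutive frame indices so that downstream speed
computation can use the true elapsed time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Track",
    "TrackSet",
    "TrackFormatError",
    "TrackDataError",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_trackmate_xml",
    "write_trackmate_xml",
    "filter_min_steps",
]

#: spellings of the micrometre unit accepted in TrackMate metadata
_MICRON_UNITS = {"µm", "um", "micron", "microns", "micrometer", "micrometre", "µm"}


class TrackFormatError(ValueError):
    """The input file does not conform to the expected format."""


class TrackDataError(ValueError):
    """The input file parses but contains inconsistent data."""


@dataclass(frozen=True)
class Track:
    """One particle's 2-D trajectory.

    Parameters
    ----------
    track_id : str
        Unique identifier within a :class:`TrackSet`.
    frames : ndarray of int
        Strictly increasing frame indices, 0-based.  Non-consecutive
        values mark gap-closed links.
    positions : ndarray, shape (n, 2)
        x/y coordinates in micrometres, one row per frame.
    dt : float
        Frame interval in seconds (> 0).
    cell_id : str
        Identifier of the cell the track was recorded in.
    condition : str
        Experimental-condition label.
    """

    track_id: str
    frames: np.ndarray
    positions: np.ndarray
    dt: float
    cell_id: str = "cell0"
    condition: str = "default"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(frames) != len(positions):
            raise ValueError("frames and positions must have equal length")
        if len(frames) < 2:
            raise ValueError("a track needs at least 2 positions")
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)

    @property
    def n_steps(self) -> int:
        """Number of displacement steps (positions minus one)."""
        return len(self.frames) - 1

    @property
    def duration(self) -> float:
        """Elapsed time in seconds from first to last frame."""
        return (self.frames[-1] - self.frames[0]) * self.dt

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """A collection of tracks with per-condition / per-cell grouping.

    Track ids must be unique; each track belongs to exactly one cell.
    """

    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise TrackDataError("duplicate track_id in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, track_id: str) -> Track:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)

    @property
    def grouping(self) -> Mapping[str, Mapping[str, list[str]]]:
        """Nested mapping ``condition -> cell_id -> [track_id, ...]``."""
        out: dict[str, dict[str, list[str]]] = {}
        for t in self.tracks:
            out.setdefault(t.condition, {}).setdefault(t.cell_id, []).append(t.track_id)
        return out

    def conditions(self) -> list[str]:
        return sorted({t.condition for t in self.tracks})

    def by_cell(self, condition: str | None = None) -> dict[str, list[Track]]:
        """Tracks grouped by cell, optionally restricted to one condition."""
        out: dict[str, list[Track]] = {}
        for t in self.tracks:
            if condition is not None and t.condition != condition:
                continue
            out.setdefault(t.cell_id, []).append(t)
        return out

    def subset(self, track_ids: Iterable[str]) -> "TrackSet":
        wanted = set(track_ids)
        return TrackSet([t for t in self.tracks if t.track_id in wanted])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("track_id", "frame", "x", "y")


def read_tracks_csv(path: str | Path, dt: float, condition: str | None = None) -> TrackSet:
    """Read tracks from a ``track_id,frame,x,y[,cell_id,condition]`` CSV.

    Rows may appear in any order; they are sorted by frame within each
    track.  A missing ``cell_id`` column defaults to the file stem, a
    missing ``condition`` column to ``condition`` (or ``"default"``).

    Raises
    ------
    TrackFormatError
        If a required column is missing.
    TrackDataError
        If the same (track_id, frame) pair occurs twice.
    """
    path = Path(path)
    if not dt > 0:
        raise ValueError("dt must be positive")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {missing}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise TrackDataError("duplicate (track_id, frame) rows")
    if "cell_id" not in df.columns:
        df["cell_id"] = path.stem
    if "condition" not in df.columns:
        df["condition"] = condition if condition is not None else "default"

    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=g["frame"].to_numpy(dtype=np.int64),
                positions=g[["x", "y"]].to_numpy(dtype=np.float64),
                dt=dt,
                cell_id=str(g["cell_id"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
            )
        )
    return TrackSet(tracks)


def write_tracks_csv(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to CSV with full precision (bit-exact round trip)."""
    rows = []
    for t in ts:
        for f, (x, y) in zip(t.frames, t.positions):
            rows.append((t.track_id, int(f), x, y, t.cell_id, t.condition))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "cell_id", "condition"])
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# TrackMate XML
# ---------------------------------------------------------------------------


def read_trackmate_xml(path: str | Path, dt: float | None = None) -> TrackSet:
    """Read tracks from a TrackMate model XML file.

    Only spots, track edges and the frame-interval metadata are
    consumed.  Positions must be calibrated in micrometres (the
    ``spatialunits`` attribute of ``<Model>``); any other unit raises.

    Parameters
    ----------
    path : path-like
        TrackMate XML file.
    dt : float, optional
        Frame interval override in seconds.  If omitted, the value is
        read from ``Settings/ImageData@timeinterval``.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message detail
        raise TrackFormatError(f"unparseable XML: {exc}") from exc
    root = tree.getroot()
    model = root if root.tag == "Model" else root.find("Model")
    if model is None:
        raise TrackFormatError("no <Model> element found")
    units = model.get("spatialunits", "µm")
    if units.strip().lower() not in {u.lower() for u in _MICRON_UNITS}:
        raise TrackFormatError(
            f"spatial unit {units!r} is not micrometres; convert upstream or pass calibrated data"
        )
    if dt is None:
        img = root.find("Settings/ImageData")
        if img is not None and img.get("timeinterval") is not None:
            dt = float(img.get("timeinterval"))
        else:
            raise TrackFormatError("no frame interval in XML; pass dt explicitly")

    spots: dict[str, tuple[int, float, float]] = {}
    for spot in model.iterfind("AllSpots/SpotsInFrame/Spot"):
        sid = spot.get("ID")
        frame = int(float(spot.get("FRAME", spot.getparent().get("frame"))))
        spots[sid] = (frame, float(spot.get("POSITION_X")), float(spot.get("POSITION_Y")))

    tracks = []
    for trk in model.iterfind("AllTracks/Track"):
        tid = trk.get("TRACK_ID", trk.get("name"))
        spot_ids: set[str] = set()
        for edge in trk.iterfind("Edge"):
            spot_ids.add(edge.get("SPOT_SOURCE_ID"))
            spot_ids.add(edge.get("SPOT_TARGET_ID"))
        if not spot_ids:
            continue
        entries = sorted(spots[s] for s in spot_ids)
        frames = np.array([e[0] for e in entries], dtype=np.int64)
        positions = np.array([[e[1], e[2]] for e in entries], dtype=np.float64)
        tracks.append(
            Track(track_id=str(tid), frames=frames, positions=positions, dt=dt, cell_id=path.stem)
        )
    return TrackSet(tracks)


def write_trackmate_xml(ts: TrackSet, path: str | Path, dt: float | None = None) -> None:
    """Write a minimal TrackMate-style model XML (spots + edges).

    Intended for interoperability tests and small exports; real
    TrackMate files carry many more attributes which are not needed to
    round-trip the geometry.
    """
    if dt is None:
        dts = {t.dt for t in ts}
        if len(dts) != 1:
            raise ValueError("tracks have differing dt; pass dt explicitly")
        dt = dts.pop()
    root = etree.Element("TrackMate")
    model = etree.SubElement(root, "Model", spatialunits="µm", timeunits="s")
    allspots = etree.SubElement(model, "AllSpots")
    alltracks = etree.SubElement(model, "AllTracks")
    spot_id = 0
    frame_elems: dict[int, etree._Element] = {}
    for t in ts:
        ids = []
        for f, (x, y) in zip(t.frames, t.positions):
            f = int(f)
            if f not in frame_elems:
                frame_elems[f] = etree.SubElement(allspots, "SpotsInFrame", frame=str(f))
            etree.SubElement(
                frame_elems[f],
                "Spot",
                ID=str(spot_id),
                FRAME=str(f),
                POSITION_X=repr(float(x)),
                POSITION_Y=repr(float(y)),
            )
            ids.append(spot_id)
            spot_id += 1
        trk = etree.SubElement(alltracks, "Track", TRACK_ID=str(t.track_id))
        for a, b in zip(ids[:-1], ids[1:]):
            etree.SubElement(trk, "Edge", SPOT_SOURCE_ID=str(a), SPOT_TARGET_ID=str(b))
    settings = etree.SubElement(root, "Settings")
    etree.SubElement(settings, "ImageData", timeinterval=repr(float(dt)))
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_min_steps(ts: TrackSet, min_steps: int = 50) -> TrackSet:
    """Keep tracks with at least ``min_steps`` displacement steps.

    The default of 50 steps (5 s at 10 frames/s) excludes short tracks
    whose statistics are dominated by localization noise.  The input is
    not modified; filtering is idempotent.
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    return TrackSet([t for t in ts if t.n_steps >= min_steps])
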