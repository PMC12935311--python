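"""Reading trajectory / event logs and cutting training paths into segments.

Positions are recorded once per second as continuous (x, y, z)
coordinates; event logs mark the session start, each object found
during training, and each placement during test.  A *segment* is the
slice of a training path from one found object (or the session start)
to the next found object — the unit of all downstream curve analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .terrain import Block, TerrainMap

logger = logging.getLogger(__name__)

PATH_COLUMNS = ["participant_id", "session_id", "t", "x", "y", "z"]
EVENT_COLUMNS = ["participant_id", "session_id", "t", "kind", "object_id", "x", "y", "z"]

EVENT_KINDS = {"session_start", "object_found", "object_placed", "trial_start", "session_end"}


@dataclass
class TrackedPath:
    """One participant-session trajectory sampled at nominally 1 Hz."""

    participant_id: str
    session_id: str
    samples: pd.DataFrame  # columns t, x, y, z; sorted by t

    def __post_init__(self) -> None:
        t = self.samples["t"].to_numpy()
        if len(t) < 2:
            raise ValueError(
                f"path {self.participant_id}/{self.session_id}: need >= 2 samples"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError(
                f"path {self.participant_id}/{self.session_id}: "
                "sample times must be strictly increasing"
            )


@dataclass
class EventLog:
    """Ordered key events of one participant-session."""

    participant_id: str
    session_id: str
    events: pd.DataFrame  # columns t, kind, object_id, x, y, z

    def __post_init__(self) -> None:
        t = self.events["t"].to_numpy()
        if len(t) and not np.all(np.diff(t) >= 0):
            raise ValueError(
                f"event log {self.participant_id}/{self.session_id}: "
                "event times must be non-decreasing"
            )
        found = self.events[self.events["kind"] == "object_found"]
        if found["object_id"].duplicated().any():
            dupes = found.loc[found["object_id"].duplicated(), "object_id"].tolist()
            raise ValueError(
                f"event log {self.participant_id}/{self.session_id}: "
                f"objects found more than once: {dupes}"
            )


@dataclass
class Segment:
    """Object-to-object slice of a training path.

    ``start_label`` is ``"session_start"`` or the previous object id;
    ``end_label`` is the object found at the segment's end.  ``samples``
    holds the trajectory rows in the half-open interval
    (t_start, t_end] plus the sample at t_start itself, so consecutive
    segments share exactly their boundary sample position.
    """

    participant_id: str
    session_id: str
    start_label: str
    end_label: str
    samples: pd.DataFrame
    duration: float
    end_position: tuple[float, float, float] | None = None
    index: int = 0
    is_first: bool = False
    is_last: bool = False
    environment: str | None = None
    meta: dict = field(default_factory=dict)


def read_path_log(path: str | Path) -> list[TrackedPath]:
    """Parse a trajectory CSV into one :class:`TrackedPath` per session.

    The file must have columns participant_id, session_id, t, x, y, z.
    Rows are sorted by time within each session; a duplicated
    (participant, session, t) triple is rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in PATH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"path log {path}: missing columns {missing}")
    dupes = df.duplicated(subset=["participant_id", "session_id", "t"])
    if dupes.any():
        bad = df.loc[dupes, ["participant_id", "session_id", "t"]].head(5)
        raise ValueError(f"path log {path}: duplicated timestamps:\n{bad}")
    paths = []
    for (pid, sid), group in df.groupby(["participant_id", "session_id"], sort=True):
        samples = group.sort_values("t")[["t", "x", "y", "z"]].reset_index(drop=True)
        paths.append(TrackedPath(str(pid), str(sid), samples))
    return paths


def read_event_log(path: str | Path) -> list[EventLog]:
    """Parse an event CSV into one :class:`EventLog` per session."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log {path}: missing columns {missing}")
    unknown = set(df["kind"]) - EVENT_KINDS
    if unknown:
        raise ValueError(f"event log {path}: unknown event kinds {sorted(unknown)}")
    logs = []
    for (pid, sid), group in df.groupby(["participant_id", "session_id"], sort=True):
        events = group.sort_values("t", kind="stable")[
            ["t", "kind", "object_id", "x", "y", "z"]
        ].reset_index(drop=True)
        logs.append(EventLog(str(pid), str(sid), events))
    return logs


def snap_to_block(terrain: TerrainMap, x: float, y: float) -> Block:
    """Map a continuous position to the block whose cell contains it.

    The cell boundary belongs to its own cell (floor convention); the
    block's z is read from the terrain height field, not from the
    recorded z, so a mid-jump sample still snaps to the ground.
    """
    cx, cy = math.floor(x), math.floor(y)
    if not terrain.in_bounds(cx, cy):
        raise IndexError(
            f"position ({x}, {y}) snaps to cell ({cx}, {cy}) outside "
            f"{terrain.width}x{terrain.depth} map"
        )
    return terrain.block_at(cx, cy)


def segment_training_path(path: TrackedPath, log: EventLog,
                          environment: str | None = None) -> list[Segment]:
    """Split a training path at its object-found events.

    One segment per consecutive event pair: session start to the first
    found object, then each object to the next.  A participant who
    finds m objects yields m segments.  Trajectory recorded after the
    last found object is discarded — a cost-difference curve needs a
    destination object.
    """
    if (path.participant_id, path.session_id) != (log.participant_id, log.session_id):
        raise ValueError(
            f"path {path.participant_id}/{path.session_id} does not match "
            f"log {log.participant_id}/{log.session_id}"
        )
    starts = log.events[log.events["kind"] == "session_start"]
    if starts.empty:
        raise ValueError(
            f"event log {log.participant_id}/{log.session_id} has no session_start"
        )
    found = log.events[log.events["kind"] == "object_found"]
    boundary_times = [float(starts["t"].iloc[0])]
    labels = ["session_start"]
    positions: list[tuple[float, float, float] | None] = [None]
    for _, ev in found.iterrows():
        boundary_times.append(float(ev["t"]))
        labels.append(str(ev["object_id"]))
        positions.append((float(ev["x"]), float(ev["y"]), float(ev["z"])))

    t = path.samples["t"].to_numpy()
    segments = []
    n_objects = len(boundary_times) - 1
    for k in range(n_objects):
        t0, t1 = boundary_times[k], boundary_times[k + 1]
        # half-open (t0, t1]; the boundary sample at t0 opens this segment
        mask = (t >= t0) & (t <= t1)
        sl = path.samples[mask].reset_index(drop=True)
        if k > 0 and len(sl) > 1:
            # drop nothing: sample at t0 is shared by construction
            pass
        if sl.empty:
            logger.warning(
                "segment %s/%s %s->%s has no trajectory samples; skipped",
                path.participant_id, path.session_id, labels[k], labels[k + 1],
            )
            continue
        end_pos = positions[k + 1]
        if end_pos is not None:
            last = sl.iloc[-1]
            gap = math.hypot(last["x"] - end_pos[0], last["y"] - end_pos[1])
            if gap > 2.0:
                logger.warning(
                    "segment %s/%s ends %.1f cells from the %s event position",
                    path.participant_id, path.session_id, gap, labels[k + 1],
                )
        segments.append(Segment(
            participant_id=path.participant_id,
            session_id=path.session_id,
            start_label=labels[k],
            end_label=labels[k + 1],
            samples=sl,
            duration=t1 - t0,
            end_position=end_pos,
            index=k,
            is_first=(k == 0),
            is_last=(k == n_objects - 1),
            environment=environment,
        ))
    return segments
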