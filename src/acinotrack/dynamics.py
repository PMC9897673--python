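"""Frame-to-frame object linking and mean invasion speed.

Objects are linked across consecutive frames by greedy nearest-centroid
matching (closest pairs first, one-to-one, capped by a maximum link
distance).  There is no gap closing: a missed frame terminates the track.
Mean invasion speed is path-based — the mean of consecutive-frame centroid
displacement magnitudes divided by the frame interval — because
tunnel-forming acini move back and forth and a net-displacement definition
would score them near zero.  Tracks shorter than 12 consecutive frames are
excluded from speed statistics (with a reason code) rather than erroring.

The object centroid stands in for the nucleus position: synthetic movies
have no subcellular detail, and at acinus scale the two coincide for the
purpose of measuring translocation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composites import CompositeObject

MIN_TRACK_LEN = 12  # consecutive frames required for a speed measurement


@dataclass
class Track:
    """Consecutive-frame trajectory of one object (centroids in µm)."""

    track_id: int
    frames: np.ndarray  # (N,) strictly consecutive ints
    centroids: np.ndarray  # (N, 2) µm
    well: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)


def _greedy_match(
    prev: np.ndarray, curr: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """One-to-one matches (closest pairs first) within ``max_dist``."""
    if len(prev) == 0 or len(curr) == 0:
        return []
    d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    pairs = np.argwhere(d <= max_dist)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_p: set[int] = set()
    used_c: set[int] = set()
    matches = []
    for i, j in pairs[order]:
        if i in used_p or j in used_c:
            continue
        used_p.add(int(i))
        used_c.add(int(j))
        matches.append((int(i), int(j)))
    return matches


def link_tracks(
    centroids: pd.DataFrame,
    max_link_dist: float = 50.0,
    well: str = "",
    condition: str = "",
) -> list[Track]:
    """Link per-frame centroids into tracks.

    ``centroids`` needs columns ``frame, x_um, y_um`` (e.g. from
    :func:`acinotrack.imaging_io.outline_centroids`).  Unmatched objects
    start or terminate tracks; single-point tracks are dropped.
    """
    if len(centroids) == 0:
        return []
    by_frame = {
        int(f): g[["x_um", "y_um"]].to_numpy(dtype=float)
        for f, g in centroids.groupby("frame", sort=True)
    }
    frames = sorted(by_frame)
    # open tracks: list of (frames list, points list); index by position in prev frame
    open_tracks: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    done: list[tuple[list[int], list[np.ndarray]]] = []
    prev_pts = by_frame[frames[0]]
    open_tracks = {
        i: ([frames[0]], [prev_pts[i]]) for i in range(len(prev_pts))
    }
    for fprev, fcurr in zip(frames[:-1], frames[1:]):
        curr_pts = by_frame[fcurr]
        if fcurr != fprev + 1:  # gap in acquisition: close everything
            matches = []
        else:
            matches = _greedy_match(prev_pts, curr_pts, max_link_dist)
        matched_prev = {i for i, _ in matches}
        matched_curr = {j for _, j in matches}
        nxt: dict[int, tuple[list[int], list[np.ndarray]]] = {}
        for i, j in matches:
            fr, pts = open_tracks[i]
            fr.append(fcurr)
            pts.append(curr_pts[j])
            nxt[j] = (fr, pts)
        for i, track in open_tracks.items():
            if i not in matched_prev:
                done.append(track)
        for j in range(len(curr_pts)):
            if j not in matched_curr:
                nxt[j] = ([fcurr], [curr_pts[j]])
        open_tracks = nxt
        prev_pts = curr_pts
    done.extend(open_tracks.values())

    tracks = []
    tid = 0
    for fr, pts in done:
        if len(fr) < 2:
            continue
        tracks.append(
            Track(
                track_id=tid,
                frames=np.asarray(fr),
                centroids=np.asarray(pts),
                well=well,
                condition=condition,
            )
        )
        tid += 1
    return tracks


def mean_invasion_speed(
    track: Track, dt: float, min_track_len: int = MIN_TRACK_LEN
) -> float | None:
    """Path-based mean speed in µm/h, or ``None`` for short tracks.

    Speed = mean consecutive-frame centroid displacement magnitude / dt,
    over tracks spanning at least ``min_track_len`` consecutive frames.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(track) < min_track_len:
        return None
    steps = np.linalg.norm(np.diff(track.centroids, axis=0), axis=1)
    return float(steps.mean() / dt)


def _majority_class(
    track: Track,
    composites_by_window: list[list[CompositeObject]],
    class_calls: dict[str, str],
    pixel_size: float,
) -> str | None:
    """Majority phenotype call over the windows a track traverses.

    A track is assigned, per window, to the composite whose union mask
    contains its mean position in that window; ties across windows
    exclude the track (return None).
    """
    votes: dict[str, int] = {}
    for window in composites_by_window:
        if not window:
            continue
        start, end = window[0].frame_range
        sel = (track.frames >= start) & (track.frames < end)
        if not sel.any():
            continue
        mean_um = track.centroids[sel].mean(axis=0)
        col = int(round(mean_um[0] / pixel_size))
        row = int(round(mean_um[1] / pixel_size))
        for comp in window:
            h, w = comp.union_mask.shape
            if 0 <= row < h and 0 <= col < w and comp.union_mask[row, col]:
                call = class_calls.get(comp.composite_id)
                if call is not None:
                    votes[call] = votes.get(call, 0) + 1
                break
    if not votes:
        return None
    top = max(votes.values())
    winners = [c for c, v in votes.items() if v == top]
    return winners[0] if len(winners) == 1 else None


def speed_by_class(
    tracks: list[Track],
    composites_by_window: list[list[CompositeObject]],
    class_calls: dict[str, str],
    dt: float,
    pixel_size: float,
    min_track_len: int = MIN_TRACK_LEN,
) -> pd.DataFrame:
    """Per-track speed table with phenotype class and exclusion reasons.

    Columns: condition, well, track_id, class, n_frames, speed_um_h, reason
    (empty for included tracks; ``short_track`` / ``ambiguous_class`` /
    ``no_composite`` otherwise).  Aggregate with :func:`speed_summary`.
    """
    rows = []
    for tr in tracks:
        speed = mean_invasion_speed(tr, dt, min_track_len)
        if speed is None:
            rows.append((tr.condition, tr.well, tr.track_id, None, len(tr), np.nan,
                         "short_track"))
            continue
        cls = _majority_class(tr, composites_by_window, class_calls, pixel_size)
        if cls is None:
            reason = "ambiguous_class" if any(composites_by_window) else "no_composite"
            rows.append((tr.condition, tr.well, tr.track_id, None, len(tr), np.nan,
                         reason))
            continue
        rows.append((tr.condition, tr.well, tr.track_id, cls, len(tr), speed, ""))
    return pd.DataFrame(
        rows,
        columns=["condition", "well", "track_id", "class", "n_frames",
                 "speed_um_h", "reason"],
    )


def speed_summary(speed_table: pd.DataFrame) -> pd.DataFrame:
    """n / mean / sd of track speeds per (condition, class)."""
    ok = speed_table[speed_table["reason"] == ""]
    return (
        ok.groupby(["condition", "class"])["speed_um_h"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
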