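"""Frame-to-frame trajectory linking by optimal assignment.

Detections in consecutive frames are linked by solving, for every frame pair,
a rectangular linear assignment problem whose cost is the squared Euclidean
distance, with a hard gate: each spot also has a "no-link" alternative priced
at ``max_link_distance**2``, so no accepted link can ever exceed the gate and
the solver trades off link quality against starting new tracks exactly as the
classical frame-to-frame LAP formulation prescribes. There is no gap closing:
a particle missing for one frame terminates its track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def _pair_assignment(
    a_xy: np.ndarray, b_xy: np.ndarray, max_link_distance: float
) -> list[tuple[int, int]]:
    """Optimal gated links between two frames as (index_in_a, index_in_b).

    Solves the augmented square problem: real-real links cost squared
    distance (infeasible beyond the gate), and every spot can instead take a
    dummy partner at cost ``gate**2``.
    """
    n, m = len(a_xy), len(b_xy)
    if n == 0 or m == 0:
        return []
    gate2 = max_link_distance**2
    d2 = ((a_xy[:, None, :] - b_xy[None, :, :]) ** 2).sum(axis=2)
    top_left = np.where(d2 <= gate2, d2, np.inf)
    top_right = np.full((n, n), np.inf)
    np.fill_diagonal(top_right, gate2)
    bottom_left = np.full((m, m), np.inf)
    np.fill_diagonal(bottom_left, gate2)
    bottom_right = np.zeros((m, n))
    cost = np.block([[top_left, top_right], [bottom_left, bottom_right]])
    rows, cols = linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols) if r < n and c < m]


def link_spots(spots: pd.DataFrame, max_link_distance: float = 0.4) -> pd.DataFrame:
    """Link a spot table into trajectories.

    Parameters
    ----------
    spots
        Table with at least ``frame, x_um, y_um`` (as produced by
        :func:`nanospt.detect.detect_spots`).
    max_link_distance
        Hard gate in µm; links longer than this are never made.

    Returns
    -------
    The input rows with a ``track_id`` column; every spot belongs to exactly
    one track and every track occupies strictly consecutive frames. The
    result is independent of the input row order (spots are canonicalized by
    position within each frame before assignment).
    """
    if max_link_distance <= 0:
        raise ValueError("max_link_distance must be positive")
    if spots.empty:
        out = spots.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out[["track_id"] + [c for c in out.columns if c != "track_id"]]

    spots = spots.sort_values(["frame", "x_um", "y_um"], kind="mergesort").reset_index(
        drop=True
    )
    by_frame = {int(f): g.index.to_numpy() for f, g in spots.groupby("frame")}
    xy = spots[["x_um", "y_um"]].to_numpy()

    track_of = np.full(len(spots), -1, dtype=int)
    next_track = 0
    frames = sorted(by_frame)
    # spots in the earliest frame all start tracks
    for idx in by_frame[frames[0]]:
        track_of[idx] = next_track
        next_track += 1
    for f in frames[1:]:
        curr = by_frame[f]
        prev = by_frame.get(f - 1, np.array([], dtype=int))
        linked_curr: set[int] = set()
        if len(prev) and len(curr):
            for ia, ib in _pair_assignment(xy[prev], xy[curr], max_link_distance):
                track_of[curr[ib]] = track_of[prev[ia]]
                linked_curr.add(int(curr[ib]))
        for idx in curr:
            if int(idx) not in linked_curr:
                track_of[idx] = next_track
                next_track += 1

    out = spots.copy()
    out["track_id"] = track_of
    cols = ["track_id"] + [c for c in out.columns if c != "track_id"]
    return out[cols].sort_values(["track_id", "frame"]).reset_index(drop=True)


def filter_tracks(tracks: pd.DataFrame, min_points: int = 10) -> pd.DataFrame:
    """Keep only tracks with at least ``min_points`` successive detections.

    The default of 10 points corresponds, at 20 frames per second, to
    particles followed for 500 ms — short, noisy fragments below that are
    discarded before any mobility analysis.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    counts = tracks.groupby("track_id")["frame"].size()
    keep = counts.index[counts >= min_points]
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


def track_summary(tracks: pd.DataFrame, frame_interval: float) -> pd.DataFrame:
    """Per-track point count and duration (``n_points * frame_interval``).

    The duration convention counts frames, not intervals: ten points at 20
    fps is reported as 500 ms.
    """
    counts = tracks.groupby("track_id")["frame"].size().rename("n_points")
    out = counts.to_frame()
    out["duration_s"] = out["n_points"] * frame_interval
    return out.reset_index()
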