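"""Frame-to-frame cell linking by mutual nearest neighbors.

A step from frame t to t+1 is accepted only when the two detections are each
other's nearest neighbors across the frame pair (an unambiguous match);
exact distance ties are treated as ambiguous and produce no link. Steps in
crowded regions — where a detection's nearest *same-frame* neighbor is
within a threshold distance (default 40 μm) in both the prior and the
latter frame — are excluded, since they are the ones prone to identity
swaps. Accepted links are chained into trajectories; a rejected link ends a
trajectory and starts a new one. Finally, trajectories whose cell never
moves more than 2 px from its initial location are removed as nonmovers.

All distances are in μm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_CROWD_DIST_UM = 40.0  # 16 px at 2.5 μm/px
DEFAULT_NONMOVER_PX = 2.0


def _nearest(pts_from: np.ndarray, pts_to: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index of each point's nearest neighbor in the other set, with exact
    distance ties marked ambiguous (index −1)."""
    tree = cKDTree(pts_to)
    k = min(2, len(pts_to))
    d, j = tree.query(pts_from, k=k)
    if k == 1:
        return np.atleast_1d(j), np.atleast_1d(d)
    ambiguous = d[:, 0] == d[:, 1]
    idx = j[:, 0].copy()
    idx[ambiguous] = -1
    return idx, d[:, 0]


def match_frames(pts_t: np.ndarray, pts_t1: np.ndarray) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbor links between two consecutive frames.

    Returns index pairs ``(i, j)``: point i of frame t linked to point j of
    frame t+1, accepted iff j is i's nearest neighbor forward AND i is j's
    nearest neighbor backward, with no exact distance tie on either side.
    """
    pts_t = np.asarray(pts_t, dtype=float)
    pts_t1 = np.asarray(pts_t1, dtype=float)
    if len(pts_t) == 0 or len(pts_t1) == 0:
        return []
    fwd, _ = _nearest(pts_t, pts_t1)
    bwd, _ = _nearest(pts_t1, pts_t)
    links = []
    for i, j in enumerate(fwd):
        if j >= 0 and bwd[j] == i:
            links.append((i, int(j)))
    return links


def same_frame_nn_distance(pts: np.ndarray) -> np.ndarray:
    """Distance from each detection to its nearest neighbor in the same
    frame (inf for a lone detection)."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 2:
        return np.full(len(pts), np.inf)
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def crowding_filter(
    links: list[tuple[int, int]],
    pts_t: np.ndarray,
    pts_t1: np.ndarray,
    d_thresh_um: float = DEFAULT_CROWD_DIST_UM,
) -> list[tuple[int, int]]:
    """Drop links whose cell is crowded in *both* frames.

    A link (i, j) is removed iff detection i's nearest same-frame neighbor
    in frame t is within ``d_thresh_um`` AND detection j's nearest
    same-frame neighbor in frame t+1 is too. Crowding in only one of the two
    frames keeps the step.
    """
    if not links:
        return []
    nn_t = same_frame_nn_distance(pts_t)
    nn_t1 = same_frame_nn_distance(pts_t1)
    return [
        (i, j)
        for i, j in links
        if not (nn_t[i] <= d_thresh_um and nn_t1[j] <= d_thresh_um)
    ]


def track(
    detections: pd.DataFrame,
    frame_interval_s: float = 30.0,
    crowd_dist_um: float = DEFAULT_CROWD_DIST_UM,
    max_link_dist_um: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Link a well/channel detection table into trajectories.

    ``detections`` needs columns ``frame, x_um, y_um`` (one well and one
    channel at a time; populations are tracked independently). An optional
    ``t_s`` column supplies per-frame acquisition times; otherwise
    ``frame × frame_interval_s`` is used. ``max_link_dist_um`` optionally
    caps the link displacement (off by default: mutual nearest neighbors is
    the only linking rule).

    Returns ``(tracks, steps)``: the input with a ``track_id`` column added,
    and a step table (columns ``track_id, frame0, frame1, x0_um, y0_um,
    x1_um, y1_um, dt_s``) holding one row per accepted link.
    """
    det = detections.reset_index(drop=True).copy()
    if det.empty:
        det["track_id"] = pd.Series(dtype=int)
        return det, pd.DataFrame(
            columns=["track_id", "frame0", "frame1", "x0_um", "y0_um", "x1_um", "y1_um", "dt_s"]
        )
    frames = np.sort(det["frame"].unique())
    by_frame = {f: det.index[det["frame"] == f].to_numpy() for f in frames}
    pts = {f: det.loc[by_frame[f], ["x_um", "y_um"]].to_numpy() for f in frames}
    times = det["t_s"] if "t_s" in det.columns else det["frame"] * float(frame_interval_s)

    successor: dict[int, int] = {}
    has_parent: set[int] = set()
    for f0, f1 in zip(frames, frames[1:]):
        if f1 != f0 + 1:
            continue  # a missing frame terminates all trajectories
        links = match_frames(pts[f0], pts[f1])
        links = crowding_filter(links, pts[f0], pts[f1], crowd_dist_um)
        if max_link_dist_um is not None:
            links = [
                (i, j)
                for i, j in links
                if np.hypot(*(pts[f1][j] - pts[f0][i])) <= max_link_dist_um
            ]
        for i, j in links:
            a = int(by_frame[f0][i])
            b = int(by_frame[f1][j])
            if a in successor or b in has_parent:
                raise ValueError("duplicate object participation in links")
            successor[a] = b
            has_parent.add(b)

    track_id = np.full(len(det), -1, dtype=int)
    next_id = 0
    for idx in det.sort_values("frame").index:
        if idx in has_parent:
            continue
        # start of a chain
        track_id[idx] = next_id
        cur = idx
        while cur in successor:
            cur = successor[cur]
            track_id[cur] = next_id
        next_id += 1
    det["track_id"] = track_id

    steps_rows = []
    for a, b in successor.items():
        steps_rows.append(
            {
                "track_id": track_id[a],
                "frame0": int(det.at[a, "frame"]),
                "frame1": int(det.at[b, "frame"]),
                "x0_um": det.at[a, "x_um"],
                "y0_um": det.at[a, "y_um"],
                "x1_um": det.at[b, "x_um"],
                "y1_um": det.at[b, "y_um"],
                "dt_s": float(times[b] - times[a]),
            }
        )
    steps = pd.DataFrame(
        steps_rows,
        columns=["track_id", "frame0", "frame1", "x0_um", "y0_um", "x1_um", "y1_um", "dt_s"],
    ).sort_values(["track_id", "frame0"], ignore_index=True)
    return det, steps


def filter_nonmoving(
    tracks: pd.DataFrame,
    pixel_size: float = 2.5,
    max_disp_px: float = DEFAULT_NONMOVER_PX,
) -> pd.DataFrame:
    """Remove trajectories that never move more than ``max_disp_px`` pixels
    from their initial location (strict: a maximum excursion of exactly the
    threshold is still removed)."""
    thresh_um = max_disp_px * pixel_size
    keep_ids = []
    for tid, d in tracks.sort_values("frame").groupby("track_id"):
        xy = d[["x_um", "y_um"]].to_numpy()
        if np.max(np.hypot(*(xy - xy[0]).T)) > thresh_um:
            keep_ids.append(tid)
    return tracks[tracks["track_id"].isin(keep_ids)].copy()
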