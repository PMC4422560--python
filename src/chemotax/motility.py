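"""Per-step and per-well statistics of directed cell migration.

Each tracked cell step (one frame-to-frame displacement) yields a movement
vector ``v``. Direction is quantified against the *optimal direction* unit
vector ``u`` pointing from the step's origin toward the gradient center:

- movement angle ``theta`` = angle between ``v`` and ``u``, in degrees;
  0 means straight toward the center, 180 straight away,
- angular bias = 90 − mean(theta): 0 for random direction, 90 for maximal
  directionality toward the center, negative for movement away,
- directed displacement = ``v · u`` (signed, μm); divided by the frame
  interval it gives the directed speed.

Angles are only computed for steps longer than a minimum displacement
(default 10 μm), because for nearly stationary cells the angle would reflect
centroid localization noise rather than movement. In-gradient statistics are
restricted to steps originating within a radial annulus around the gradient
center (defaults 250–1625 μm) where cell behavior is homogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_R_MIN_UM = 250.0
DEFAULT_R_MAX_UM = 1625.0
DEFAULT_MIN_ANGLE_DIST_UM = 10.0

#: epoch labels for steps relative to the uncaging frame
PRE, POST, SPANNING = "pre", "post", "spanning"


@dataclass(frozen=True)
class WellMotilitySummary:
    """Per-well, per-population motility summary.

    Speeds are in μm/min; ``angular_bias`` in degrees within [−90, 90].
    Fields are NaN when no qualifying steps exist (never silently 0).
    """

    basal_speed: float
    stimulated_speed: float
    directed_speed: float
    angular_bias: float
    n_basal: int
    n_stimulated: int
    n_angle: int
    well: str | None = None
    population: str | None = None

    def as_dict(self) -> dict:
        return {
            "well": self.well,
            "population": self.population,
            "basal_speed": self.basal_speed,
            "stimulated_speed": self.stimulated_speed,
            "directed_speed": self.directed_speed,
            "angular_bias": self.angular_bias,
            "n_basal": self.n_basal,
            "n_stimulated": self.n_stimulated,
            "n_angle": self.n_angle,
        }


def steps_from_positions(
    positions: np.ndarray,
    frame_interval_s: float,
    frame_times_s: np.ndarray | None = None,
) -> pd.DataFrame:
    """Expand a dense position array into a long table of steps.

    Parameters
    ----------
    positions : (n_cells, n_frames, 2) array of (x, y) in μm.
    frame_interval_s : nominal frame interval, used when ``frame_times_s``
        is not given.
    frame_times_s : optional per-frame acquisition times in seconds.

    Returns a DataFrame with one row per cell per frame pair, columns
    ``cell_id, frame0, frame1, x0_um, y0_um, x1_um, y1_um, dt_s``.
    """
    positions = np.asarray(positions, dtype=float)
    n_cells, n_frames, _ = positions.shape
    if frame_times_s is None:
        frame_times_s = np.arange(n_frames) * float(frame_interval_s)
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    f0 = np.arange(n_frames - 1)
    cell = np.repeat(np.arange(n_cells), n_frames - 1)
    frame0 = np.tile(f0, n_cells)
    p0 = positions[:, :-1, :].reshape(-1, 2)
    p1 = positions[:, 1:, :].reshape(-1, 2)
    return pd.DataFrame(
        {
            "cell_id": cell,
            "frame0": frame0,
            "frame1": frame0 + 1,
            "x0_um": p0[:, 0],
            "y0_um": p0[:, 1],
            "x1_um": p1[:, 0],
            "y1_um": p1[:, 1],
            "dt_s": np.diff(frame_times_s)[frame0],
        }
    )


def step_metrics(
    steps: pd.DataFrame,
    gradient_center_um: tuple[float, float],
    uncage_frame: int = 17,
) -> pd.DataFrame:
    """Compute movement metrics for each step.

    ``uncage_frame`` is the 0-based index of the first post-stimulus frame
    (default 17, i.e. frames 0–16 precede gradient generation). A step is
    *pre* if both its frames precede the uncaging frame, *post* if both its
    frames are at or after it; the single step spanning the uncaging event
    is labeled *spanning* and excluded from epoch statistics.

    Adds columns ``distance_um, theta_deg, directed_um, origin_r_um, epoch,
    at_center``. ``theta_deg`` is NaN for zero-length steps and for steps
    originating exactly at the gradient center (where the optimal direction
    is undefined; such steps are flagged via ``at_center``).
    """
    out = steps.copy()
    cx, cy = gradient_center_um
    vx = out["x1_um"].to_numpy() - out["x0_um"].to_numpy()
    vy = out["y1_um"].to_numpy() - out["y0_um"].to_numpy()
    ux = cx - out["x0_um"].to_numpy()
    uy = cy - out["y0_um"].to_numpy()
    r = np.hypot(ux, uy)
    dist = np.hypot(vx, vy)
    at_center = r == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        directed = (vx * ux + vy * uy) / r
        cos_theta = np.clip(directed / dist, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))
    theta[at_center | (dist == 0.0)] = np.nan
    directed[at_center] = np.nan

    frame0 = out["frame0"].to_numpy()
    frame1 = out["frame1"].to_numpy()
    epoch = np.full(len(out), SPANNING, dtype=object)
    epoch[frame1 < uncage_frame] = PRE
    epoch[frame0 >= uncage_frame] = POST

    out["distance_um"] = dist
    out["theta_deg"] = theta
    out["directed_um"] = directed
    out["origin_r_um"] = r
    out["epoch"] = epoch
    out["at_center"] = at_center
    return out


def _mean_or_nan(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else math.nan


def well_summary(
    steps: pd.DataFrame,
    r_min_um: float = DEFAULT_R_MIN_UM,
    r_max_um: float = DEFAULT_R_MAX_UM,
    min_angle_dist_um: float = DEFAULT_MIN_ANGLE_DIST_UM,
    well: str | None = None,
    population: str | None = None,
) -> WellMotilitySummary:
    """Aggregate step metrics into a per-well motility summary.

    Basal speed is the mean of ``distance/Δt`` over all pre-stimulus steps
    (pre-stimulus behavior is spatially homogeneous, so no radial bound is
    applied). Stimulated speed, directed speed and angular bias are computed
    over post-stimulus steps originating within ``[r_min_um, r_max_um]`` of
    the gradient center; angles additionally require a displacement of at
    least ``min_angle_dist_um``.
    """
    required = {"distance_um", "theta_deg", "directed_um", "origin_r_um", "epoch"}
    missing = required - set(steps.columns)
    if missing:
        raise ValueError(f"steps missing metric columns {sorted(missing)}; run step_metrics first")

    dist = steps["distance_um"].to_numpy()
    dt = steps["dt_s"].to_numpy()
    epoch = steps["epoch"].to_numpy()
    r = steps["origin_r_um"].to_numpy()

    pre = epoch == PRE
    post = (epoch == POST) & (r >= r_min_um) & (r <= r_max_um)
    angle_ok = post & (dist >= min_angle_dist_um) & np.isfinite(steps["theta_deg"].to_numpy())
    directed_ok = post & ~steps["at_center"].to_numpy()

    basal = _mean_or_nan(60.0 * dist[pre] / dt[pre])
    stim = _mean_or_nan(60.0 * dist[post] / dt[post])
    directed = _mean_or_nan(
        60.0 * steps["directed_um"].to_numpy()[directed_ok] / dt[directed_ok]
    )
    mean_theta = _mean_or_nan(steps["theta_deg"].to_numpy()[angle_ok])
    bias = 90.0 - mean_theta if math.isfinite(mean_theta) else math.nan

    return WellMotilitySummary(
        basal_speed=basal,
        stimulated_speed=stim,
        directed_speed=directed,
        angular_bias=bias,
        n_basal=int(pre.sum()),
        n_stimulated=int(post.sum()),
        n_angle=int(angle_ok.sum()),
        well=well,
        population=population,
    )


def time_course(
    steps: pd.DataFrame,
    n_angle_bins: int = 12,
    min_angle_dist_um: float = DEFAULT_MIN_ANGLE_DIST_UM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame mean speed / directed speed and a movement-angle histogram.

    Steps are assigned to their later frame, so a stimulus-induced speed
    change appears exactly at the uncaging frame. Returns ``(curves, hist)``:
    ``curves`` has columns ``frame, mean_speed, mean_directed_speed, n``;
    ``hist`` is indexed by frame with one column per angle bin over
    [0°, 180°], each row normalized to sum to 1 when it has ≥ 1 qualifying
    step (angle threshold applied).
    """
    if "distance_um" not in steps.columns:
        raise ValueError("run step_metrics first")
    g = steps.groupby("frame1")
    curves = pd.DataFrame(
        {
            "mean_speed": g.apply(
                lambda d: _mean_or_nan(60.0 * d["distance_um"].to_numpy() / d["dt_s"].to_numpy()),
                include_groups=False,
            ),
            "mean_directed_speed": g.apply(
                lambda d: _mean_or_nan(
                    60.0
                    * d["directed_um"].to_numpy()[np.isfinite(d["directed_um"].to_numpy())]
                    / d["dt_s"].to_numpy()[np.isfinite(d["directed_um"].to_numpy())]
                ),
                include_groups=False,
            ),
            "n": g.size(),
        }
    )
    curves.index.name = "frame"
    curves = curves.reset_index()

    edges = np.linspace(0.0, 180.0, n_angle_bins + 1)
    ok = steps[
        (steps["distance_um"] >= min_angle_dist_um) & np.isfinite(steps["theta_deg"])
    ]
    rows = {}
    for frame, d in ok.groupby("frame1"):
        counts, _ = np.histogram(d["theta_deg"].to_numpy(), bins=edges)
        total = counts.sum()
        rows[frame] = counts / total if total else counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = pd.DataFrame.from_dict(rows, orient="index", columns=centers)
    hist.index.name = "frame"
    return curves, hist
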