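"""Ground-truthed synthetic data: trajectories, rendered movies, whole plates.

The cell motion model is a biased persistent random walk. At each frame a
cell draws a target heading from a von Mises distribution — uniform before
the stimulus, concentrated (``bias_kappa``) around the direction toward the
gradient center after it — and blends it with its previous heading according
to a persistence weight. Step lengths are gamma distributed with mean
``speed × Δt``. A configurable fraction of cells never moves (emulating dead
or undifferentiated cells), pinned at their initial position. All rendered
and reported positions carry centroid localization noise.

Plates are simulated with two cell populations per well (an experimental
population plus an in-well control) that share a multiplicative well-to-well
speed factor, the structure exploited by the in-well-control normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from chemotax import motility

#: von Mises concentrations at or above this cap are treated as a point mass
#: on the optimal direction (every step exactly toward the center).
KAPPA_CAP = 1e6


@dataclass(frozen=True)
class CellSimParams:
    """Parameters of the per-well cell motion model.

    Speeds are in μm/min. ``persistence`` in [0, 1) sets the step-to-step
    direction correlation; ``bias_kappa`` ≥ 0 is the von Mises concentration
    of post-stimulus headings around the direction toward the gradient
    center (0 = unbiased). ``position_noise_px`` is centroid localization
    noise in pixels; ``step_shape`` the gamma shape of step lengths.
    """

    n_cells: int = 150
    basal_speed: float = 6.0
    stimulated_speed: float = 12.0
    persistence: float = 0.5
    bias_kappa: float = 1.5
    nonmover_fraction: float = 0.05
    position_noise_px: float = 0.3
    step_shape: float = 2.0

    def validate(self) -> None:
        vals = [
            self.basal_speed,
            self.stimulated_speed,
            self.persistence,
            self.bias_kappa,
            self.nonmover_fraction,
            self.position_noise_px,
            self.step_shape,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite simulation parameter")
        if self.basal_speed < 0 or self.stimulated_speed < 0:
            raise ValueError("speeds must be >= 0")
        if self.bias_kappa < 0:
            raise ValueError("bias_kappa must be >= 0")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must be in [0, 1)")
        if not 0.0 <= self.nonmover_fraction <= 1.0:
            raise ValueError("nonmover_fraction must be in [0, 1]")
        if self.step_shape <= 0:
            raise ValueError("step_shape must be > 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging geometry and timing.

    Defaults correspond to a 1,024 × 1,280-pixel field at 2.5 μm/px imaged
    every 30 s for 50 frames, 17 before and 33 after gradient generation.
    """

    image_shape: tuple[int, int] = (1024, 1280)  # (rows, cols)
    pixel_size: float = 2.5  # μm/px
    frame_interval: float = 30.0  # s
    n_pre_frames: int = 17
    n_post_frames: int = 33
    gradient_center_px: tuple[float, float] | None = None  # (x, y); None = image center

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_post_frames

    @property
    def uncage_frame(self) -> int:
        """0-based index of the first post-stimulus frame."""
        return self.n_pre_frames

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in μm."""
        rows, cols = self.image_shape
        return cols * self.pixel_size, rows * self.pixel_size

    @property
    def gradient_center_um(self) -> tuple[float, float]:
        if self.gradient_center_px is not None:
            x, y = self.gradient_center_px
        else:
            rows, cols = self.image_shape
            x, y = (cols - 1) / 2.0, (rows - 1) / 2.0
        return x * self.pixel_size, y * self.pixel_size


@dataclass(frozen=True)
class OpticsParams:
    """Rendering settings: nuclei as isotropic Gaussian spots on a smooth
    non-uniform background with shot (Poisson) noise."""

    spot_sigma_px: float = 1.5
    spot_amplitude: float = 400.0
    background_level: float = 100.0
    background_tilt: float = 0.2  # fractional corner-to-corner ramp
    poisson_noise: bool = True


@dataclass
class GroundTruth:
    """True positions of every simulated cell in every frame.

    ``positions`` has shape (n_cells, n_frames, 2) holding (x, y) in μm
    (these include localization noise; ``true_positions`` does not).
    """

    positions: np.ndarray
    true_positions: np.ndarray
    nonmover: np.ndarray
    params: CellSimParams
    acq: AcquisitionParams
    population: str = "experimental"
    well: str = "A1"

    def steps(self) -> pd.DataFrame:
        """Step table with movement metrics, from the noisy positions."""
        steps = motility.steps_from_positions(self.positions, self.acq.frame_interval)
        return motility.step_metrics(
            steps, self.acq.gradient_center_um, self.acq.uncage_frame
        )

    def to_dataframe(self) -> pd.DataFrame:
        n_cells, n_frames, _ = self.positions.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n_cells), n_frames),
                "frame": np.tile(np.arange(n_frames), n_cells),
                "x_um": self.positions[:, :, 0].ravel(),
                "y_um": self.positions[:, :, 1].ravel(),
                "population": self.population,
                "well": self.well,
            }
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v / n
    u[n[..., 0] == 0] = 0.0
    return u


def simulate_trajectories(
    params: CellSimParams,
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int = 0,
    population: str = "experimental",
    well: str = "A1",
) -> GroundTruth:
    """Simulate biased-persistent-random-walk trajectories for one well.

    Pre-stimulus frames use ``basal_speed`` and unbiased headings; frames at
    or after the uncaging frame use ``stimulated_speed`` and headings drawn
    von Mises-concentrated around the unit vector from the current position
    toward the gradient center. ``bias_kappa`` at or above the implementation
    cap makes every post-stimulus step point exactly at the center. Cells are
    reflected at the field boundary.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_cells
    width, height = acq.field_um
    center = np.asarray(acq.gradient_center_um)
    dt_min = acq.frame_interval / 60.0  # frame interval in minutes

    pos = np.empty((n, acq.n_frames, 2))
    pos[:, 0, 0] = rng.uniform(0, width, n)
    pos[:, 0, 1] = rng.uniform(0, height, n)
    nonmover = rng.random(n) < params.nonmover_fraction
    if params.basal_speed == 0 and params.stimulated_speed == 0:
        nonmover[:] = True

    theta0 = rng.uniform(0, 2 * np.pi, n)
    heading = np.column_stack([np.cos(theta0), np.sin(theta0)])

    for f in range(1, acq.n_frames):
        post = f >= acq.uncage_frame
        speed = params.stimulated_speed if post else params.basal_speed
        mean_len = speed * dt_min
        lengths = (
            rng.gamma(params.step_shape, mean_len / params.step_shape, n)
            if mean_len > 0
            else np.zeros(n)
        )
        if post and params.bias_kappa > 0:
            to_center = _unit(center - pos[:, f - 1])
            mu = np.arctan2(to_center[:, 1], to_center[:, 0])
            if params.bias_kappa >= KAPPA_CAP:
                heading = to_center
                blend = False
            else:
                ang = rng.vonmises(mu, params.bias_kappa)
                target = np.column_stack([np.cos(ang), np.sin(ang)])
                blend = True
        else:
            ang = rng.uniform(0, 2 * np.pi, n)
            target = np.column_stack([np.cos(ang), np.sin(ang)])
            blend = True
        if blend:
            mixed = params.persistence * heading + (1 - params.persistence) * target
            norms = np.linalg.norm(mixed, axis=1)
            degenerate = norms < 1e-12
            mixed[degenerate] = target[degenerate]
            heading = _unit(mixed)

        new = pos[:, f - 1] + lengths[:, None] * heading
        # reflect at the field boundary
        new[:, 0] = np.abs(new[:, 0])
        new[:, 1] = np.abs(new[:, 1])
        new[:, 0] = width - np.abs(width - new[:, 0])
        new[:, 1] = height - np.abs(height - new[:, 1])
        new[nonmover] = pos[nonmover, 0]
        pos[:, f] = new

    noisy = pos + rng.normal(
        0.0, params.position_noise_px * acq.pixel_size, pos.shape
    )
    return GroundTruth(
        positions=noisy,
        true_positions=pos,
        nonmover=nonmover,
        params=params,
        acq=acq,
        population=population,
        well=well,
    )


def render_movie(
    truth: GroundTruth,
    optics: OpticsParams = OpticsParams(),
    seed: int = 0,
    max_object_area_px: float = 75.0,
) -> np.ndarray:
    """Render a ground truth into an image stack of shape (n_frames, rows, cols).

    Each nucleus is an isotropic Gaussian spot added onto a smooth tilted
    background; shot noise is Poisson on the expected intensity. A warning is
    raised when the spot footprint (radius 2σ) exceeds the upper area filter,
    since such objects would be discarded downstream.
    """
    acq = truth.acq
    rows, cols = acq.image_shape
    sigma = optics.spot_sigma_px
    if np.pi * (2.0 * sigma) ** 2 > max_object_area_px:
        warnings.warn(
            "spot radius so large that expected object area exceeds the "
            f"upper area filter ({max_object_area_px} px)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    yy = np.arange(rows)[:, None] / max(rows - 1, 1)
    xx = np.arange(cols)[None, :] / max(cols - 1, 1)
    background = optics.background_level * (
        1.0 + optics.background_tilt * (0.5 * xx + 0.5 * yy - 0.5)
    )

    half = int(np.ceil(4 * sigma))
    stack = np.empty((acq.n_frames, rows, cols), dtype=np.float64)
    for f in range(acq.n_frames):
        frame = background.copy()
        pts_px = truth.positions[:, f, :] / acq.pixel_size  # (x, y)
        for x, y in pts_px:
            cx, cy = int(round(x)), int(round(y))
            x0, x1 = max(cx - half, 0), min(cx + half + 1, cols)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, rows)
            if x0 >= x1 or y0 >= y1:
                continue
            gx = np.arange(x0, x1) - x
            gy = np.arange(y0, y1) - y
            spot = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma**2))
            frame[y0:y1, x0:x1] += optics.spot_amplitude * spot
        if optics.poisson_noise:
            frame = rng.poisson(frame).astype(np.float64)
        stack[f] = frame
    return stack


def write_movie_tiff(stack: np.ndarray, path) -> None:
    """Write an image stack as a multi-page TIFF (uint16)."""
    import tifffile

    tifffile.imwrite(path, np.clip(stack, 0, 65535).astype(np.uint16))


@dataclass
class PlateSimSpec:
    """Layout and ground-truth effects for a synthetic plate.

    ``conditions`` assigns one condition label per well (wells sharing a
    label are replicates). ``effects`` maps condition → relative effect per
    parameter (keys among ``basal_speed``, ``stimulated_speed``,
    ``bias_kappa``); an effect of −0.5 multiplies the experimental
    population's parameter by 0.5. The in-well control population uses
    ``base_params`` in every well. Both populations in a well share one
    multiplicative lognormal well-to-well speed factor with log-sd
    ``well_effect_sd``.
    """

    conditions: list[str]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    well_effect_sd: float = 0.1
    base_params: CellSimParams = CellSimParams()
    acq: AcquisitionParams = AcquisitionParams()

    def __post_init__(self) -> None:
        if len(self.conditions) > 96:
            raise ValueError("at most 96 wells per plate")


def _apply_effects(params: CellSimParams, eff: dict[str, float]) -> CellSimParams:
    allowed = {"basal_speed", "stimulated_speed", "bias_kappa"}
    unknown = set(eff) - allowed
    if unknown:
        raise ValueError(f"unknown effect parameters {sorted(unknown)}")
    changes = {k: getattr(params, k) * (1.0 + v) for k, v in eff.items()}
    return replace(params, **changes)


def _scale_speeds(params: CellSimParams, factor: float) -> CellSimParams:
    return replace(
        params,
        basal_speed=params.basal_speed * factor,
        stimulated_speed=params.stimulated_speed * factor,
    )


def make_plate(spec: PlateSimSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a plate and return per-well motility summaries.

    Each well holds an experimental and an in-well control population,
    labeled by channel as in a two-color assay. Returns one row per well per
    population with the motility summary plus ground-truth columns
    (``well_factor`` and the true effects applied).

    Per-well randomness is derived from ``seed`` via ``SeedSequence.spawn``,
    so wells are independent and the whole plate is reproducible.
    """
    root = np.random.SeedSequence(seed)
    well_seqs = root.spawn(len(spec.conditions))
    rows = []
    seen: dict[str, int] = {}
    for i, (condition, seq) in enumerate(zip(spec.conditions, well_seqs)):
        well = f"W{i + 1:02d}"
        replicate = seen.get(condition, 0)
        seen[condition] = replicate + 1
        s_factor, s_exp, s_ctrl = seq.spawn(3)
        factor = float(
            np.exp(
                np.random.default_rng(s_factor).normal(0.0, spec.well_effect_sd)
            )
        )
        eff = spec.effects.get(condition, {})
        pops = {
            "experimental": _scale_speeds(_apply_effects(spec.base_params, eff), factor),
            "control": _scale_speeds(spec.base_params, factor),
        }
        for (population, params), sub in zip(pops.items(), (s_exp, s_ctrl)):
            truth = simulate_trajectories(
                params,
                spec.acq,
                seed=sub,
                population=population,
                well=well,
            )
            summary = motility.well_summary(
                truth.steps(), well=well, population=population
            )
            row = summary.as_dict()
            row.update(
                condition=condition,
                replicate=replicate,
                well_factor=factor,
                true_effect_basal=eff.get("basal_speed", 0.0),
                true_effect_stimulated=eff.get("stimulated_speed", 0.0),
                true_effect_bias=eff.get("bias_kappa", 0.0),
            )
            rows.append(row)
    return pd.DataFrame(rows)
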