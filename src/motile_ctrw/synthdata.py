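"""Synthetic run-and-tumble trajectories and microscopy-like renders.

The generator produces 2-D trajectories that alternate waiting periods
(position fixed) with straight runs traversed at constant speed, with
heavy-tailed jump-length and waiting-time marginals (jump mode near
5–6 µm with a hard 100 µm maximum; waits reaching hundreds of seconds)
and optional lag-1 correlation between successive jumps or waits via a
calibrated Gaussian copula.  A slow uniform drift can be superimposed,
emulating the residual creep seen in sealed observation chambers.
Trajectories can then be rendered as dark disks on a bright noisy
background so the entire detection → linking → segmentation pipeline is
exercisable without any recorded video.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .distributions import CorrelatedSampler, DistributionSpec
from .tracking import FrameStack
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "MotilityParams",
    "ImagingParams",
    "generate_trajectories",
    "render_frames",
    "default_jump_spec",
    "default_wait_spec",
]

STEP_COLUMNS = [
    "cell_id",
    "step_index",
    "dx_um",
    "dy_um",
    "eps_um",
    "tau_s",
    "tau_wait_s",
    "tau_run_s",
]


def default_jump_spec() -> DistributionSpec:
    """Lognormal jump lengths, mode 5.5 µm, hard maximum 100 µm."""
    return DistributionSpec("lognormal", {"mode": 5.5, "sigma": 0.8}, upper=100.0)


def default_wait_spec() -> DistributionSpec:
    """Heavy-tailed waits: truncated Pareto, support reaching 250 s."""
    return DistributionSpec(
        "truncpareto", {"b": 1.2, "lower": 0.25, "upper": 250.0}
    )


@dataclass
class MotilityParams:
    """Ground-truth motility model for one synthetic species.

    ``run_speed`` converts a jump length into a run duration (runs are
    traversed at constant speed, so multi-frame runs exist and per-frame
    displacements are well defined).  ``jump_corr``/``wait_corr`` are
    target lag-1 Pearson correlations of successive jump lengths /
    waiting times; 0 means independent steps.  ``frame_aligned``
    quantises event durations to the ``sample_dt`` grid and
    ``min_turn_deg`` redraws run directions closer than that angle to the
    previous run — together they make every generated step recoverable by
    the downstream angle/wait segmentation rules.
    """

    jump_pdf: DistributionSpec = field(default_factory=default_jump_spec)
    wait_pdf: DistributionSpec = field(default_factory=default_wait_spec)
    body_length: float = 3.0
    run_speed: float = 12.0
    drift_speed: float = 0.0
    drift_direction: float = 0.0
    jump_corr: float = 0.0
    wait_corr: float = 0.0
    n_cells: int = 100
    t_max: float = 125.0
    seed: int = 0
    sample_dt: float = 0.25
    frame_aligned: bool = False
    min_turn_deg: float = 0.0
    start_box: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.run_speed <= 0 or self.body_length <= 0 or self.sample_dt <= 0:
            raise ValueError("run_speed, body_length and sample_dt must be > 0")
        for c in (self.jump_corr, self.wait_corr):
            if not -1.0 <= c <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")


def _wrap_angle(a: np.ndarray | float):
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def generate_trajectories(
    params: MotilityParams,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Generate ground-truth trajectories and their true step table.

    Each cell alternates a waiting period (position fixed) with a
    straight run of length eps at ``run_speed`` in a uniformly random
    direction.  One step record spans a wait plus the following run
    (``tau = tau_wait + tau_run``), so the taus of a trajectory sum to
    its covered duration.  Cells end at the last completed step not
    exceeding ``t_max`` (always at least one step).  Positions are
    sampled on a regular ``sample_dt`` grid; drift, when present, is
    added to the sampled positions, not to the step table.

    Returns the trajectory list (µm / s) and a DataFrame with columns
    ``cell_id, step_index, dx_um, dy_um, eps_um, tau_s, tau_wait_s,
    tau_run_s``.
    """
    rng = np.random.default_rng(params.seed)
    jump_sampler = CorrelatedSampler(params.jump_pdf.build(), params.jump_corr)
    wait_sampler = CorrelatedSampler(params.wait_pdf.build(), params.wait_corr)
    mean_step = (
        wait_sampler.dist.mean() + jump_sampler.dist.mean() / params.run_speed
    )
    batch = max(8, int(1.5 * params.t_max / max(mean_step, 1e-9)) + 4)
    dt = params.sample_dt
    min_turn = np.deg2rad(params.min_turn_deg)
    drift_vx = params.drift_speed * np.cos(params.drift_direction)
    drift_vy = params.drift_speed * np.sin(params.drift_direction)

    trajectories: list[Trajectory] = []
    rows: list[tuple] = []
    for cell_id in range(params.n_cells):
        jumps, zj = jump_sampler.sample_chain(batch, rng)
        waits, zw = wait_sampler.sample_chain(batch, rng)
        if params.start_box is not None:
            (x0a, x0b), (y0a, y0b) = params.start_box
            x0 = rng.uniform(x0a, x0b)
            y0 = rng.uniform(y0a, y0b)
        else:
            x0 = y0 = 0.0
        bt = [0.0]
        bx = [x0]
        by = [y0]
        t = 0.0
        x, y = x0, y0
        theta_prev: float | None = None
        k = 0
        n_steps = 0
        while True:
            if k >= len(jumps):
                more_j, zj = jump_sampler.sample_chain(batch, rng, z0=zj)
                more_w, zw = wait_sampler.sample_chain(batch, rng, z0=zw)
                jumps = np.concatenate([jumps, more_j])
                waits = np.concatenate([waits, more_w])
            eps = float(jumps[k])
            wait = float(waits[k])
            if params.frame_aligned:
                wait = round(wait / dt) * dt
                n_run = max(1, round(eps / (params.run_speed * dt)))
                eps = n_run * params.run_speed * dt
                tau_run = n_run * dt
            else:
                tau_run = eps / params.run_speed
            theta = rng.uniform(0.0, 2.0 * np.pi)
            if min_turn > 0.0 and theta_prev is not None:
                while abs(_wrap_angle(theta - theta_prev)) < min_turn:
                    theta = rng.uniform(0.0, 2.0 * np.pi)
            step_end = t + wait + tau_run
            if n_steps > 0 and step_end > params.t_max:
                break
            dx = eps * np.cos(theta)
            dy = eps * np.sin(theta)
            if wait > 0.0:
                bt.append(t + wait)
                bx.append(x)
                by.append(y)
            x += dx
            y += dy
            t = step_end
            bt.append(t)
            bx.append(x)
            by.append(y)
            rows.append(
                (cell_id, n_steps, dx, dy, eps, wait + tau_run, wait, tau_run)
            )
            theta_prev = theta
            n_steps += 1
            k += 1
            if t > params.t_max:
                break
        ts = np.arange(0.0, t + 1e-9, dt)
        xs = np.interp(ts, bt, bx) + drift_vx * ts
        ys = np.interp(ts, bt, by) + drift_vy * ts
        trajectories.append(Trajectory(cell_id, ts, xs, ys, units="um"))
    steps = pd.DataFrame(rows, columns=STEP_COLUMNS)
    return trajectories, steps


@dataclass
class ImagingParams:
    """Virtual microscope/camera settings for rendering.

    Defaults mimic a 1024×1024 sensor with 13 µm pixel pitch recording
    1000 frames; cells are rendered darker than the background (bright
    light), with Gaussian sensor noise.
    """

    magnification: float = 20.0
    frequency: float = 4.0
    sensor_pixel: float = 13.0
    frame_size: int = 1024
    n_frames: int = 1000
    cell_radius_px: float = 2.0
    background_level: float = 200.0
    cell_level: float = 60.0
    noise_sd: float = 4.0
    dtype: str = "uint8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.magnification <= 0:
            raise ValueError("frequency and magnification must be > 0")
        if self.frame_size <= 0 or self.n_frames <= 0:
            raise ValueError("frame_size and n_frames must be > 0")
        if abs(self.cell_level - self.background_level) <= 3.0 * self.noise_sd:
            raise ValueError(
                "cell/background contrast must exceed 3x the noise level"
            )
        if self.cell_radius_px < 1.0:
            raise ValueError("cell_radius_px must be >= 1 (cells span >= 2 px)")


def render_frames(
    trajectories: list[Trajectory], imaging: ImagingParams
) -> FrameStack:
    """Render µm/s trajectories into a noisy microscopy-like FrameStack.

    Positions are converted to pixels with the inverse unit-conversion
    (px = µm × magnification / sensor_pixel; frame = t × frequency) and
    each in-frame cell is drawn as a filled disk of ``cell_level``
    intensity on a ``background_level`` canvas; i.i.d. Gaussian noise is
    added per frame.  Cells outside the frame are simply absent; disks
    straddling the edge are clipped (counted and logged).
    """
    for traj in trajectories:
        if traj.units != "um":
            raise ValueError("render_frames expects trajectories in µm/s units")
    rng = np.random.default_rng(imaging.seed)
    scale = imaging.magnification / imaging.sensor_pixel  # px per µm
    h = w = imaging.frame_size
    r = imaging.cell_radius_px
    info = np.iinfo(np.dtype(imaging.dtype))
    frames = np.empty((imaging.n_frames, h, w), dtype=imaging.dtype)
    n_clipped = 0
    for k in range(imaging.n_frames):
        t = k / imaging.frequency
        canvas = np.full((h, w), imaging.background_level, dtype=np.float32)
        for traj in trajectories:
            xu, yu = traj.position_at(t)
            if np.isnan(xu):
                continue
            col = float(xu) * scale
            row = float(yu) * scale
            if row < -r or row > h - 1 + r or col < -r or col > w - 1 + r:
                continue  # fully outside the viewing window
            rr, cc = draw_disk((row, col), r + 0.5, shape=(h, w))
            if rr.size == 0:
                continue
            if row < r or row > h - 1 - r or col < r or col > w - 1 - r:
                n_clipped += 1
            canvas[rr, cc] = imaging.cell_level
        if imaging.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, imaging.noise_sd, size=(h, w)).astype(
                np.float32
            )
        frames[k] = np.clip(canvas, info.min, info.max).astype(imaging.dtype)
    if n_clipped:
        logger.warning("%d cell renders clipped at the frame edge", n_clipped)
    return FrameStack(
        frames,
        frequency=imaging.frequency,
        magnification=imaging.magnification,
        sensor_pixel=imaging.sensor_pixel,
    )
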