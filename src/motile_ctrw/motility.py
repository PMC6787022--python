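"""Step segmentation and motility statistics.

A trajectory in physical units is decomposed into an alternating
sequence of *waiting states* (frame-to-frame displacement below the
species' body length) and *runs* (continuous motion in an approximately
constant direction).  A new jump is registered when the cell leaves a
waiting state or when the direction of motion deviates from the current
run's mean direction by more than an angular threshold (±5° by
default).  Each step record spans the accumulated wait plus the
following run, so the step times of a trajectory sum to its covered
duration; this is the increment sequence a continuous-time random walk
resamples.

The module also builds the pooled master step table, empirical
probability densities, ensemble displacement moments (mean travel
distance and mean-centred variance versus time, truncated where fewer
than 50 trajectories remain), the ensemble drift speed, and lag-1
correlations of successive steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import STEP_COLUMNS
from .trajectory import Trajectory

__all__ = [
    "convert_units",
    "segment_steps",
    "build_master",
    "EmpiricalPDF",
    "empirical_pdf",
    "log_bin_edges",
    "MomentSeries",
    "ensemble_moments",
    "drift_speed",
    "StepCorrelation",
    "step_correlation",
]


def convert_units(
    traj: Trajectory,
    frequency: float,
    magnification: float,
    sensor_pixel: float = 13.0,
) -> Trajectory:
    """Convert a pixel/frame trajectory to µm and seconds.

    Time (s) = frames × (1 / frequency); distance (µm) = pixels ×
    (sensor_pixel / magnification).  E.g. 1000 frames at 8 Hz span
    125 s, and one pixel at 20X spans 13/20 = 0.65 µm.
    """
    if frequency <= 0 or magnification <= 0:
        raise ValueError("frequency and magnification must be > 0")
    if traj.units != "px":
        raise ValueError("trajectory is not in pixel/frame units")
    px = sensor_pixel / magnification
    return Trajectory(
        traj.cell_id, traj.t / frequency, traj.x * px, traj.y * px, units="um"
    )


def segment_steps(
    traj: Trajectory,
    body_length: float,
    angle_threshold_deg: float = 5.0,
) -> pd.DataFrame:
    """Segment a µm/s trajectory into jump/wait step records.

    Frame-to-frame displacements below ``body_length`` accumulate into
    the waiting time; a run opens with the first displacement at or
    above body length and extends while each displacement direction
    stays within ``angle_threshold_deg`` of the run's net (mean)
    direction.  A run closes — emitting a record with eps = the run's
    net displacement, its duration, and the preceding wait — on a
    waiting frame or a sharper turn.  Trailing accumulated wait with no
    following run is emitted as a terminal pure-wait record (eps = 0).

    Returns a DataFrame with the master-table columns.
    """
    if traj.units != "um":
        raise ValueError("segment_steps expects a trajectory in µm/s units")
    if body_length <= 0:
        raise ValueError("body_length must be > 0")
    rows: list[tuple] = []
    n = len(traj)
    if n < 2:
        return pd.DataFrame(rows, columns=STEP_COLUMNS)
    dt = np.diff(traj.t)
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    disp = np.hypot(dx, dy)
    thresh = np.deg2rad(angle_threshold_deg)

    pending_wait = 0.0
    in_run = False
    run_dx = run_dy = run_time = run_wait = 0.0

    def emit_run() -> None:
        eps = float(np.hypot(run_dx, run_dy))
        rows.append(
            (
                traj.cell_id,
                len(rows),
                run_dx,
                run_dy,
                eps,
                run_wait + run_time,
                run_wait,
                run_time,
            )
        )

    for i in range(n - 1):
        if disp[i] < body_length:
            if in_run:
                emit_run()
                in_run = False
            pending_wait += dt[i]
            continue
        if in_run:
            dev = np.arctan2(dy[i], dx[i]) - np.arctan2(run_dy, run_dx)
            dev = abs((dev + np.pi) % (2.0 * np.pi) - np.pi)
            if dev > thresh:
                emit_run()
                in_run = False
        if not in_run:
            run_dx, run_dy, run_time = dx[i], dy[i], dt[i]
            run_wait, pending_wait = pending_wait, 0.0
            in_run = True
        else:
            run_dx += dx[i]
            run_dy += dy[i]
            run_time += dt[i]
    if in_run:
        emit_run()
    elif pending_wait > 0.0:
        rows.append(
            (traj.cell_id, len(rows), 0.0, 0.0, 0.0, pending_wait, pending_wait, 0.0)
        )
    return pd.DataFrame(rows, columns=STEP_COLUMNS)


def build_master(step_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-trajectory step tables into one master table.

    The master table (one row per jump, with x-increment, y-increment,
    jump length and waiting time) is the sole input to CTRW sampling.
    """
    tables = [t for t in step_tables if t is not None and len(t)]
    if not tables:
        warnings.warn("building an empty master table", stacklevel=2)
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(tables, ignore_index=True)


@dataclass
class EmpiricalPDF:
    """Histogram density: non-negative, integrating to 1 over its bins."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def log_bin_edges(
    lo: float, hi: float, bins_per_decade: int = 30
) -> np.ndarray:
    """Logarithmically spaced bin edges (default 30 per decade)."""
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    n = max(2, int(np.ceil(np.log10(hi / lo) * bins_per_decade)) + 1)
    return np.logspace(np.log10(lo), np.log10(hi), n)


def empirical_pdf(values, bin_edges) -> EmpiricalPDF:
    """Normalized histogram density of jump lengths or waiting times."""
    values = np.asarray(values, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if values.size == 0:
        raise ValueError("cannot build a PDF from no samples")
    if np.any(values < 0):
        raise ValueError("values must be non-negative")
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be 1-D and strictly increasing")
    density, _ = np.histogram(values, bins=bin_edges, density=True)
    return EmpiricalPDF(bin_edges, density, int(values.size))


@dataclass
class MomentSeries:
    """Ensemble mean displacement and mean-centred variance versus time.

    ``variance`` is radial: the mean squared distance of cells from the
    ensemble-mean position (sum of the two per-axis variances).  The
    series is truncated at the last time with at least the required
    number of live trajectories.
    """

    times: np.ndarray
    mean_disp: np.ndarray
    variance: np.ndarray
    n_alive: np.ndarray

    def __len__(self) -> int:
        return self.times.size


def ensemble_moments(
    trajs: list[Trajectory],
    min_unique: int = 50,
    dt: float | None = None,
) -> MomentSeries:
    """Displacement moments over an ensemble of µm/s trajectories.

    All trajectories are shifted to start at the origin at time zero and
    evaluated on a common regular grid (default: the finest native frame
    interval present); each contributes only over its recorded span.  At
    every grid time, ``mean_disp`` is the mean of |r(t)| and ``variance``
    the mean squared distance from the ensemble-mean position.  Times
    with fewer than ``min_unique`` live trajectories are dropped, and
    the series ends at the last time satisfying that cutoff.
    """
    trajs = [t for t in trajs if len(t) >= 2]
    if not trajs:
        warnings.warn("no usable trajectories for moments", stacklevel=2)
        empty = np.empty(0)
        return MomentSeries(empty, empty.copy(), empty.copy(), np.empty(0, int))
    if dt is None:
        dt = min(float(np.median(np.diff(t.t))) for t in trajs)
    t_end = max(t.duration for t in trajs)
    grid = np.arange(0.0, t_end + dt * 0.5, dt)
    xs = np.full((len(trajs), grid.size), np.nan)
    ys = np.full_like(xs, np.nan)
    for i, traj in enumerate(trajs):
        rel = traj.shifted_to_origin()
        live = grid <= rel.duration + 1e-9
        xs[i, live] = np.interp(grid[live], rel.t, rel.x)
        ys[i, live] = np.interp(grid[live], rel.t, rel.y)
    n_alive = np.sum(~np.isnan(xs), axis=0)
    ok = n_alive >= min_unique
    if not ok.any():
        warnings.warn(
            f"no time with >= {min_unique} unique trajectories", stacklevel=2
        )
        empty = np.empty(0)
        return MomentSeries(empty, empty.copy(), empty.copy(), np.empty(0, int))
    last = int(np.nonzero(ok)[0][-1]) + 1
    grid, xs, ys, n_alive = grid[:last], xs[:, :last], ys[:, :last], n_alive[:last]
    keep = n_alive >= min_unique
    grid, xs, ys, n_alive = grid[keep], xs[:, keep], ys[:, keep], n_alive[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_disp = np.nanmean(np.hypot(xs, ys), axis=0)
        mx = np.nanmean(xs, axis=0)
        my = np.nanmean(ys, axis=0)
        variance = np.nanmean((xs - mx) ** 2 + (ys - my) ** 2, axis=0)
    return MomentSeries(grid, mean_disp, variance, n_alive.astype(int))


def drift_speed(moments: MomentSeries) -> float:
    """Ensemble drift speed: OLS slope of mean displacement versus time."""
    if len(moments) < 3:
        raise ValueError("need at least 3 moment time points")
    if np.ptp(moments.times) <= 0:
        raise ValueError("degenerate time axis")
    slope, _ = np.polyfit(moments.times, moments.mean_disp, 1)
    return float(slope)


@dataclass
class StepCorrelation:
    """Lag-1 Pearson correlations of successive jump lengths and waits.

    ``sparse`` flags fewer than 10 pairs, where the estimate is not
    meaningful.
    """

    eps_corr: float
    tau_corr: float
    n_pairs_eps: int
    n_pairs_tau: int

    @property
    def sparse(self) -> bool:
        return min(self.n_pairs_eps, self.n_pairs_tau) < 10


def _lag1_pairs(master: pd.DataFrame, column: str, drop_zero_eps: bool):
    a_all: list[np.ndarray] = []
    b_all: list[np.ndarray] = []
    for _, grp in master.groupby("cell_id", sort=False):
        grp = grp.sort_values("step_index")
        if drop_zero_eps:
            grp = grp[grp["eps_um"] > 0]
        vals = grp[column].to_numpy(dtype=float)
        idx = grp["step_index"].to_numpy()
        if vals.size < 2:
            continue
        consecutive = np.diff(idx) == 1
        a_all.append(vals[:-1][consecutive])
        b_all.append(vals[1:][consecutive])
    if not a_all:
        return np.empty(0), np.empty(0)
    return np.concatenate(a_all), np.concatenate(b_all)


def step_correlation(master: pd.DataFrame) -> StepCorrelation:
    """Correlations between step n and step n+1 within each trajectory.

    Pairs are formed only between consecutive steps of the same cell;
    terminal pure-wait records (eps = 0) are excluded from the
    jump-length pairs since they are not jumps.
    """

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    ea, eb = _lag1_pairs(master, "eps_um", drop_zero_eps=True)
    ta, tb = _lag1_pairs(master, "tau_s", drop_zero_eps=False)
    return StepCorrelation(corr(ea, eb), corr(ta, tb), ea.size, ta.size)
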