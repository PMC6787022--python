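"""Monte-Carlo continuous-time random walk driven by the master step table.

The walk recursion is r[n+1] = r[n] + eps[n], t[n+1] = t[n] + tau[n],
with increments resampled from the empirical master table rather than a
fitted parametric law.  In the *coupled* variant a whole row
(dx, dy, tau) is drawn at once, so waiting times stay conditioned on
their observed jump lengths (the empirical joint distribution); in the
*uncoupled* variant the displacement and the waiting time come from two
independently drawn rows, making every waiting time equally likely
regardless of jump magnitude.  The full event history of every particle
is retained so first-passage times at radial control planes can be
interpolated within steps: a particle sits still through its waiting
component, then traverses the jump chord at constant speed over the run
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import BreakthroughCurve
from .trajectory import Trajectory

__all__ = [
    "CTRWConfig",
    "WalkEnsemble",
    "simulate_ctrw",
    "first_passage",
    "histories_from_trajectories",
]


@dataclass
class CTRWConfig:
    """Monte-Carlo settings for a CTRW ensemble.

    ``resample_direction`` replaces each drawn (dx, dy) by an isotropic
    direction of the same length (off by default: using the increments
    as recorded preserves any anisotropy in the data).
    """

    coupled: bool = True
    n_particles: int = 1000
    t_max: float = 250.0
    seed: int = 0
    resample_direction: bool = False

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")


@dataclass
class WalkEnsemble:
    """Event histories of a walker ensemble, padded to a common length.

    ``times``/``x``/``y`` have shape (n_particles, max_steps + 1): entry
    k is the state after k steps, starting from the origin at t = 0.
    ``tau_wait``/``tau_run`` (n_particles, max_steps) split each step's
    duration into its motionless and moving parts.  Only the first
    ``n_steps[i]`` steps of particle i are meaningful; every particle
    has at least one step and its last step crosses ``t_max``.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tau_wait: np.ndarray
    tau_run: np.ndarray
    n_steps: np.ndarray
    t_max: float

    @property
    def n_particles(self) -> int:
        return self.times.shape[0]


def _master_arrays(master: pd.DataFrame):
    dx = master["dx_um"].to_numpy(dtype=float)
    dy = master["dy_um"].to_numpy(dtype=float)
    tau = master["tau_s"].to_numpy(dtype=float)
    if "tau_run_s" in master.columns and "tau_wait_s" in master.columns:
        tw = master["tau_wait_s"].to_numpy(dtype=float)
        tr = master["tau_run_s"].to_numpy(dtype=float)
    else:  # minimal master: traverse the chord over the whole tau
        tw = np.zeros_like(tau)
        tr = tau.copy()
    return dx, dy, tau, tw, tr


def simulate_ctrw(master: pd.DataFrame, cfg: CTRWConfig) -> WalkEnsemble:
    """Simulate an ensemble of CTRW particles from a master step table.

    Every particle starts at the origin at time zero and keeps stepping
    until its clock exceeds ``cfg.t_max`` (each particle completes at
    least one step).  Rows are drawn uniformly with replacement —
    jointly (coupled) or with the waiting time drawn from an independent
    row (uncoupled).
    """
    if master is None or len(master) == 0:
        raise ValueError("master table is empty")
    dx, dy, tau, tw, tr = _master_arrays(master)
    if np.any(tau <= 0):
        raise ValueError("master waiting times must be positive")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_particles
    mean_tau = float(np.mean(tau))
    block = max(4, int(1.2 * cfg.t_max / mean_tau) + 2)

    idx_xy = rng.integers(0, len(tau), size=(n, block))
    idx_tau = idx_xy if cfg.coupled else rng.integers(0, len(tau), size=(n, block))
    while np.min(np.sum(tau[idx_tau], axis=1)) <= cfg.t_max:
        extra_xy = rng.integers(0, len(tau), size=(n, block))
        extra_tau = (
            extra_xy if cfg.coupled else rng.integers(0, len(tau), size=(n, block))
        )
        idx_xy = np.concatenate([idx_xy, extra_xy], axis=1)
        idx_tau = np.concatenate([idx_tau, extra_tau], axis=1)

    taus = tau[idx_tau]
    cum = np.cumsum(taus, axis=1)
    # steps while t <= t_max, plus the one that crosses; never fewer than 1
    n_steps = np.clip(np.sum(cum <= cfg.t_max, axis=1) + 1, 1, taus.shape[1])
    k_max = int(n_steps.max())

    dxs = dx[idx_xy[:, :k_max]]
    dys = dy[idx_xy[:, :k_max]]
    if cfg.resample_direction:
        eps = np.hypot(dxs, dys)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=dxs.shape)
        dxs = eps * np.cos(theta)
        dys = eps * np.sin(theta)
    zeros = np.zeros((n, 1))
    x = np.concatenate([zeros, np.cumsum(dxs, axis=1)], axis=1)
    y = np.concatenate([zeros, np.cumsum(dys, axis=1)], axis=1)
    times = np.concatenate([zeros, cum[:, :k_max]], axis=1)
    return WalkEnsemble(
        times=times,
        x=x,
        y=y,
        tau_wait=tw[idx_tau[:, :k_max]],
        tau_run=tr[idx_tau[:, :k_max]],
        n_steps=n_steps.astype(int),
        t_max=float(cfg.t_max),
    )


def histories_from_trajectories(
    trajs: list[Trajectory], t_max: float | None = None
) -> WalkEnsemble:
    """Encode recorded µm/s trajectories as walk histories.

    Each trajectory is shifted to the origin and its sample-to-sample
    segments become steps with zero waiting component (the recorded
    positions already embed any dwell), so first-passage interpolation
    treats the path as piecewise linear in time — exactly the "real
    path" convention.  ``t_max`` defaults to the longest duration.
    """
    trajs = [t for t in trajs if len(t) >= 2]
    if not trajs:
        raise ValueError("no trajectories with at least two samples")
    if t_max is None:
        t_max = max(t.duration for t in trajs)
    k_max = max(len(t) - 1 for t in trajs)
    n = len(trajs)
    times = np.zeros((n, k_max + 1))
    x = np.zeros((n, k_max + 1))
    y = np.zeros((n, k_max + 1))
    tr = np.zeros((n, k_max))
    n_steps = np.empty(n, dtype=int)
    for i, traj in enumerate(trajs):
        rel = traj.shifted_to_origin()
        m = len(rel) - 1
        times[i, : m + 1] = rel.t
        x[i, : m + 1] = rel.x
        y[i, : m + 1] = rel.y
        tr[i, :m] = np.diff(rel.t)
        n_steps[i] = m
    return WalkEnsemble(
        times=times,
        x=x,
        y=y,
        tau_wait=np.zeros_like(tr),
        tau_run=tr,
        n_steps=n_steps,
        t_max=float(t_max),
    )


def first_passage(
    ensemble: WalkEnsemble,
    radii,
    n_bins: int = 100,
    t_max: float | None = None,
) -> list[BreakthroughCurve]:
    """First-passage breakthrough curves at radial control planes.

    For each particle and radius L the first time |r(t)| >= L is found
    with |r| interpolated along each jump chord (the radius along a
    straight chord is maximal at its endpoints, so the first event state
    with |r| >= L brackets the true crossing).  The particle rests
    through each step's waiting component before traversing the chord
    over its run component.  Particles not reaching L within ``t_max``
    are censored.
    """
    if ensemble.n_particles == 0:
        raise ValueError("empty ensemble")
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if t_max is None:
        t_max = ensemble.t_max
    r2 = ensemble.x**2 + ensemble.y**2
    n, kp1 = r2.shape
    cols = np.arange(kp1)
    valid = cols[None, :] <= ensemble.n_steps[:, None]
    rows_all = np.arange(n)
    curves = []
    for L in radii:
        cand = (r2 >= L * L) & valid
        cand[:, 0] = False  # all particles start at the origin, inside L
        has = cand.any(axis=1)
        k_star = np.argmax(cand, axis=1)
        rows = rows_all[has]
        k = k_star[has]
        j = k - 1
        xp = ensemble.x[rows, j]
        yp = ensemble.y[rows, j]
        ddx = ensemble.x[rows, k] - xp
        ddy = ensemble.y[rows, k] - yp
        a = ddx**2 + ddy**2
        b = 2.0 * (xp * ddx + yp * ddy)
        c = xp**2 + yp**2 - L * L
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (-b + np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))) / (2.0 * a)
        s = np.where(a > 0, np.clip(s, 0.0, 1.0), 0.0)
        arrival = (
            ensemble.times[rows, j]
            + ensemble.tau_wait[rows, j]
            + s * ensemble.tau_run[rows, j]
        )
        arrival = arrival[arrival <= t_max]
        curves.append(
            BreakthroughCurve.from_arrival_times(
                arrival, ensemble.n_particles, L, t_max, n_bins
            )
        )
    return curves
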