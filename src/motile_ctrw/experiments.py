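"""End-to-end validation experiments on synthetic ground truth.

Each function wires several pipeline stages together under conditions
with a known answer: rendering and re-tracking a scene of separated
cells, segmenting a frame-aligned ensemble back into its generating
step table, and closing the loop from trajectories through the master
table to a coupled-CTRW breakthrough compared against an independent
"real path" ensemble.  They are used by the test suite and the
reproduction script; sizes are arguments so both can scale them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .breakthrough import real_breakthrough
from .ctrw import CTRWConfig, first_passage, simulate_ctrw
from .distributions import DistributionSpec
from .motility import _lag1_pairs, build_master, segment_steps, step_correlation
from .synthdata import ImagingParams, MotilityParams, generate_trajectories, render_frames
from .tracking import detect_cells, link_detections

__all__ = [
    "recoverable_motility_params",
    "separated_scene",
    "tracking_recovery",
    "distribution_recovery",
    "self_consistency",
]


def recoverable_motility_params(**overrides) -> MotilityParams:
    """Generator settings whose steps segmentation can recover exactly.

    Event durations are aligned to the 0.25 s sampling grid, run
    directions are redrawn when within 6° of the previous run (just
    outside the ±5° turn rule), and the 16 µm/s run speed keeps every
    per-frame run displacement above the 3 µm body length.
    """
    base = dict(
        n_cells=200,
        t_max=125.0,
        seed=0,
        frame_aligned=True,
        min_turn_deg=6.0,
        sample_dt=0.25,
        body_length=3.0,
        run_speed=16.0,
    )
    base.update(overrides)
    return MotilityParams(**base)


def separated_scene(
    n_cells: int = 20,
    t_max: float = 60.0,
    seed: int = 0,
    frame_size: int = 1024,
    magnification: float = 20.0,
) -> list:
    """Well-separated cells on a grid, with jumps small enough that no
    two cells approach each other and none leaves the window."""
    px = 13.0 / magnification
    n_side = int(np.ceil(np.sqrt(n_cells)))
    margin = 0.15 * frame_size
    pitch = (frame_size - 2 * margin) / max(n_side - 1, 1)
    jump = DistributionSpec("lognormal", {"mode": 3.0, "sigma": 0.5}, upper=15.0)
    wait = DistributionSpec("exponential", {"scale": 2.0})
    trajs = []
    for i in range(n_cells):
        col = (margin + pitch * (i % n_side)) * px
        row = (margin + pitch * (i // n_side)) * px
        params = MotilityParams(
            jump_pdf=jump,
            wait_pdf=wait,
            n_cells=1,
            t_max=t_max,
            run_speed=8.0,
            body_length=2.0,
            seed=seed * 1000 + i,
            start_box=((col, col), (row, row)),
        )
        traj = generate_trajectories(params)[0][0]
        traj.cell_id = i
        trajs.append(traj)
    return trajs


def tracking_recovery(
    seed: int = 0,
    n_cells: int = 20,
    n_frames: int = 200,
    frame_size: int = 1024,
    noise_sd: float = 0.0,
    search_radius: float = 8.0,
) -> dict:
    """Render a separated scene, re-track it, and score the recovery.

    Returns the ground-truth and recovered trajectory counts and the
    per-sample position RMSE (px) after matching each recovered track to
    the nearest-starting true cell.
    """
    frequency, magnification = 4.0, 20.0
    trajs = separated_scene(
        n_cells,
        t_max=n_frames / frequency + 10.0,
        seed=seed,
        frame_size=frame_size,
        magnification=magnification,
    )
    imaging = ImagingParams(
        magnification=magnification,
        frequency=frequency,
        frame_size=frame_size,
        n_frames=n_frames,
        cell_radius_px=2.0,
        noise_sd=noise_sd,
        background_level=200.0,
        cell_level=60.0,
        seed=seed,
    )
    stack = render_frames(trajs, imaging)
    detections = detect_cells(stack, k_sigma=5.0, min_blob_pixels=2)
    tracks = link_detections(detections, search_radius=search_radius)
    scale = magnification / 13.0
    sq_err: list[float] = []
    for trk in tracks:
        best = min(
            trajs,
            key=lambda tr: (tr.x[0] * scale - trk.x[0]) ** 2
            + (tr.y[0] * scale - trk.y[0]) ** 2,
        )
        xu, yu = best.position_at(trk.t / frequency)
        sq_err.extend(
            (trk.x - xu * scale) ** 2 + (trk.y - yu * scale) ** 2
        )
    return {
        "n_true": len(trajs),
        "n_recovered": len(tracks),
        "rmse_px": float(np.sqrt(np.mean(sq_err))) if sq_err else float("nan"),
        "n_samples": len(sq_err),
    }


def distribution_recovery(
    seed: int = 0,
    n_cells: int = 300,
    jump_corr: float = 0.5,
    wait_corr: float = -0.3,
) -> dict:
    """Segment a correlated frame-aligned ensemble against its ground truth.

    Returns two-sample KS statistics/p-values between segmented and true
    jump/wait marginals (values rounded to 1e-6 to merge floating-point
    ties at quantisation atoms) and the recovered lag-1 correlations.
    The injected wait correlation lives on the waiting-state component
    (the run duration rides on the jump length), so it is recovered from
    ``tau_wait``; and a negative wait correlation needs a mild marginal,
    so waits are exponential here.
    """
    params = recoverable_motility_params(
        n_cells=n_cells,
        seed=seed,
        jump_corr=jump_corr,
        wait_corr=wait_corr,
        wait_pdf=DistributionSpec("exponential", {"scale": 2.0}),
    )
    trajs, truth = generate_trajectories(params)
    master = build_master([segment_steps(t, params.body_length) for t in trajs])
    jumps = master[master["eps_um"] > 0]
    ks_eps = stats.ks_2samp(
        np.round(jumps["eps_um"], 6), np.round(truth["eps_um"], 6)
    )
    ks_tau = stats.ks_2samp(
        np.round(jumps["tau_s"], 6), np.round(truth["tau_s"], 6)
    )
    corr = step_correlation(master)
    wa, wb = _lag1_pairs(master, "tau_wait_s", drop_zero_eps=False)
    wait_corr_rec = float(np.corrcoef(wa, wb)[0, 1])
    return {
        "n_steps": int(len(master)),
        "ks_eps_stat": float(ks_eps.statistic),
        "ks_eps_p": float(ks_eps.pvalue),
        "ks_tau_stat": float(ks_tau.statistic),
        "ks_tau_p": float(ks_tau.pvalue),
        "eps_corr": float(corr.eps_corr),
        "tau_corr": wait_corr_rec,
        "injected_eps_corr": jump_corr,
        "injected_tau_corr": wait_corr,
    }


def self_consistency(
    seed: int = 0,
    jump_corr: float = 0.0,
    radii=(10.0, 60.0),
    n_cells: int = 300,
    n_particles: int = 2000,
) -> dict:
    """Close the loop: segmented master -> coupled CTRW vs real paths.

    Ensemble A is generated, segmented and pooled into a master table
    that drives a coupled CTRW; its breakthroughs are compared against
    the real-path breakthroughs of an independently seeded ensemble B
    from the same parameters.  With independent steps the two agree in
    distribution; with positive jump correlation the CTRW (which
    resamples steps independently) degrades with distance.
    """
    radii = [float(r) for r in radii]
    params_a = recoverable_motility_params(
        n_cells=n_cells, seed=seed, jump_corr=jump_corr
    )
    params_b = recoverable_motility_params(
        n_cells=n_cells, seed=seed + 7919, jump_corr=jump_corr
    )
    trajs_a, _ = generate_trajectories(params_a)
    trajs_b, _ = generate_trajectories(params_b)
    master = build_master(
        [segment_steps(t, params_a.body_length) for t in trajs_a]
    )
    ensemble = simulate_ctrw(
        master,
        CTRWConfig(
            coupled=True,
            n_particles=n_particles,
            t_max=params_a.t_max,
            seed=seed + 15485863,
        ),
    )
    ctrw_curves = first_passage(ensemble, radii)
    real_curves = real_breakthrough(trajs_b, radii, t_max=params_a.t_max)
    ks = stats.ks_2samp(
        ctrw_curves[0].arrival_times, real_curves[0].arrival_times
    )
    return {
        "radii": radii,
        "ks_p_smallest_L": float(ks.pvalue),
        "ks_stat_smallest_L": float(ks.statistic),
        "ctrw_mean": [c.mean_arrival for c in ctrw_curves],
        "real_mean": [c.mean_arrival for c in real_curves],
        "mean_abs_diff": [
            abs(c.mean_arrival - r.mean_arrival)
            for c, r in zip(ctrw_curves, real_curves)
        ],
        "ctrw_recovery": [c.recovery for c in ctrw_curves],
        "real_recovery": [c.recovery for c in real_curves],
    }
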