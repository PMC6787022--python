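"""Real-path breakthroughs and model-vs-observation comparison.

The "real path" breakthrough is the ground truth every model is judged
against: recorded trajectories are translated to a common origin and
tracked until their radial distance first reaches each control radius.
The comparison report assembles recovery, mean and standard deviation of
arrival time per control plane for the real path, the ADE model, and
the coupled/uncoupled CTRW models, and overlays their first-arrival
densities per radius (curves recovering less than 2% of the ensemble
are excluded from plots — too few arrivals for a clear profile).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ctrw import first_passage, histories_from_trajectories
from .curves import RECOVERY_RELIABLE_MIN, BreakthroughCurve
from .trajectory import Trajectory

__all__ = [
    "real_breakthrough",
    "moments_of_curve",
    "compare_report",
    "plot_comparison",
]


def real_breakthrough(
    trajs: list[Trajectory],
    radii,
    n_bins: int = 100,
    t_max: float | None = None,
) -> list[BreakthroughCurve]:
    """First-passage breakthroughs of recorded trajectories.

    Each (filtered, µm/s) trajectory is shifted to start at the origin;
    its first radial crossing of each L is located with linear
    interpolation between samples.  Curves are limited in time to the
    longest recorded duration unless ``t_max`` says otherwise; cells
    whose record ends before reaching L are censored.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    ensemble = histories_from_trajectories(trajs, t_max=t_max)
    return first_passage(ensemble, radii, n_bins=n_bins)


def moments_of_curve(curve: BreakthroughCurve) -> tuple[float, float]:
    """Mean and population standard deviation of arrival times.

    Sampled curves use the arrival times of arrivers; analytic (density
    only) curves use density-weighted moments.  Raises when the curve
    has no arrivals at all.
    """
    if curve.arrival_times is not None:
        if curve.n_arrived == 0:
            raise ValueError(f"no arrivals at L={curve.L}; moments undefined")
        return (
            float(np.mean(curve.arrival_times)),
            float(np.std(curve.arrival_times)),
        )
    if not np.isfinite(curve.mean_arrival):
        raise ValueError(f"zero-mass density at L={curve.L}; moments undefined")
    return curve.mean_arrival, curve.std_arrival


_SOURCES = ("real", "ade", "ctrw_coupled", "ctrw_uncoupled")


def compare_report(
    real: list[BreakthroughCurve],
    ade: list[BreakthroughCurve],
    ctrw_coupled: list[BreakthroughCurve],
    ctrw_uncoupled: list[BreakthroughCurve],
    radii,
) -> pd.DataFrame:
    """Per-radius table of recovery / mean / std for every source.

    All four curve lists must cover the same control radii.  Rows whose
    recovery falls below 2% are flagged ``excluded`` (mirroring control
    planes dropped from breakthrough figures for lack of arrivals).
    """
    radii = [float(r) for r in np.atleast_1d(radii)]
    rows = []
    for source, curves in zip(_SOURCES, (real, ade, ctrw_coupled, ctrw_uncoupled)):
        got = [round(c.L, 9) for c in curves]
        if got != [round(r, 9) for r in radii]:
            raise ValueError(
                f"{source} curves cover radii {got}, expected {radii}"
            )
        for c in curves:
            try:
                mean, std = moments_of_curve(c)
            except ValueError:
                mean = std = float("nan")
            rows.append(
                {
                    "L_um": c.L,
                    "source": source,
                    "recovery": c.recovery,
                    "mean_arrival_s": mean,
                    "std_arrival_s": std,
                    "n_arrived": c.n_arrived,
                    "excluded": c.recovery < RECOVERY_RELIABLE_MIN,
                }
            )
    return pd.DataFrame(rows)


def plot_comparison(
    curve_sets: dict[str, list[BreakthroughCurve]],
    out_dir,
    prefix: str = "breakthrough",
) -> list[str]:
    """Overlay first-arrival densities per control radius as PNG files.

    Curves with recovery below 2% are skipped; a radius with no
    plottable curve produces no file.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    radii = sorted({c.L for curves in curve_sets.values() for c in curves})
    written = []
    for L in radii:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        plotted = False
        for name, curves in curve_sets.items():
            for c in curves:
                if c.L == L and not c.unreliable:
                    ax.plot(c.times, c.density, label=name)
                    plotted = True
        if not plotted:
            plt.close(fig)
            continue
        ax.set_xlabel("time (s)")
        ax.set_ylabel("first-arrival density (1/s)")
        ax.set_title(f"Breakthrough at L = {L:g} µm")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{prefix}_L{L:g}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
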