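"""Breakthrough (first-arrival-time) curve container.

A breakthrough curve at a control radius L collects, over an ensemble of
walkers released at the origin, the first times their radial distance
reaches L.  The density is normalized by the *total* ensemble size C0,
so its area equals the recovery — the fraction of the ensemble that ever
arrives within the observation window (the curve's zeroth moment).
Arrival-time moments are computed over arrivers only; curves with
recovery below 2% are flagged unreliable (too few arrivals to display a
clear profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BreakthroughCurve", "RECOVERY_RELIABLE_MIN"]

#: below this recovery a curve does not display a clear profile
RECOVERY_RELIABLE_MIN = 0.02


@dataclass
class BreakthroughCurve:
    """First-arrival-time density and cumulative recovery at radius ``L``.

    ``times`` are bin centers (sampled arrivals) or evaluation times
    (analytic curves); ``density`` integrates to ``recovery``.  For
    sampled curves the raw ``arrival_times`` of arrivers are retained so
    distributional tests can avoid binning.
    """

    L: float
    times: np.ndarray
    density: np.ndarray
    cumulative: np.ndarray
    recovery: float
    mean_arrival: float
    std_arrival: float
    n_arrived: int
    n_total: int
    arrival_times: np.ndarray | None = field(default=None, repr=False)

    @property
    def unreliable(self) -> bool:
        return self.recovery < RECOVERY_RELIABLE_MIN

    @classmethod
    def from_arrival_times(
        cls,
        arrivals: np.ndarray,
        n_total: int,
        L: float,
        t_max: float,
        n_bins: int = 100,
    ) -> "BreakthroughCurve":
        """Curve from sampled first-arrival times of ``n_total`` walkers.

        ``arrivals`` holds only the arrivers (censored walkers excluded);
        mean/std use the population (divide-by-n) convention.
        """
        arrivals = np.asarray(arrivals, dtype=float)
        if n_total <= 0:
            raise ValueError("n_total must be positive")
        edges = np.linspace(0.0, t_max, n_bins + 1)
        counts, _ = np.histogram(arrivals, bins=edges)
        widths = np.diff(edges)
        density = counts / (n_total * widths)
        cumulative = np.cumsum(counts) / n_total
        n_arr = int(arrivals.size)
        mean = float(np.mean(arrivals)) if n_arr else float("nan")
        std = float(np.std(arrivals)) if n_arr else float("nan")
        return cls(
            L=float(L),
            times=0.5 * (edges[:-1] + edges[1:]),
            density=density,
            cumulative=cumulative,
            recovery=n_arr / n_total,
            mean_arrival=mean,
            std_arrival=std,
            n_arrived=n_arr,
            n_total=int(n_total),
            arrival_times=arrivals,
        )

    @classmethod
    def from_density(
        cls, L: float, times: np.ndarray, density: np.ndarray
    ) -> "BreakthroughCurve":
        """Curve from an analytic first-arrival density on a time grid.

        Recovery is the integral of the density; arrival moments are
        density-weighted over the grid.
        """
        times = np.asarray(times, dtype=float)
        density = np.asarray(density, dtype=float)
        area = float(np.trapezoid(density, times))
        cumulative = np.concatenate(
            [[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(times))]
        )
        if area > 0:
            mean = float(np.trapezoid(times * density, times) / area)
            var = float(np.trapezoid((times - mean) ** 2 * density, times) / area)
            std = float(np.sqrt(max(var, 0.0)))
        else:
            mean = std = float("nan")
        return cls(
            L=float(L),
            times=times,
            density=density,
            cumulative=cumulative,
            recovery=area,
            mean_arrival=mean,
            std_arrival=std,
            n_arrived=0,
            n_total=0,
            arrival_times=None,
        )
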