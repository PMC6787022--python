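"""Single-cell trajectory container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time-ordered positions of one cell.

    ``units`` is ``"px"`` (``t`` holds frame indices, ``x``/``y`` pixel
    columns/rows, origin top-left) or ``"um"`` (``t`` in seconds,
    positions in µm).  Frame indices / times are strictly increasing.
    """

    cell_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    units: str = "um"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have matching shapes")
        if self.t.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time/frame axis must be strictly increasing")
        if self.units not in ("px", "um"):
            raise ValueError("units must be 'px' or 'um'")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Covered duration in the trajectory's own time units."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def shifted_to_origin(self) -> "Trajectory":
        """Translate so the first sample sits at (0, 0) at time 0."""
        return Trajectory(
            self.cell_id,
            self.t - self.t[0],
            self.x - self.x[0],
            self.y - self.y[0],
            self.units,
        )

    def position_at(self, t):
        """Linearly interpolated position at time(s) ``t`` within the span.

        Values outside the recorded span are returned as NaN (the cell is
        not observed there).
        """
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.t, self.x)
        y = np.interp(t, self.t, self.y)
        outside = (t < self.t[0]) | (t > self.t[-1])
        x = np.where(outside, np.nan, x)
        y = np.where(outside, np.nan, y)
        return x, y
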