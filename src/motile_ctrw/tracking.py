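"""Cell detection and trajectory linking from intensity frame stacks.

Bright-field microscopy shows swimming bacteria as small dark blobs on a
bright, temporally stable background.  Detection therefore builds a
per-pixel temporal background model (median with a robust MAD-based
scale), flags pixels whose intensity deviates by more than ``k_sigma``
robust standard deviations, groups them by 8-connectivity, and takes the
centroid of each blob.  Linking is greedy nearest-neighbour within a
search radius, frame to frame, with a separate radius outside which a
detection is declared a new cell and a missed-frame allowance before a
track is closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "Detection",
    "detect_cells",
    "link_detections",
    "filter_trajectories",
]

#: 1.4826 scales a median absolute deviation to a Gaussian sigma.
MAD_TO_SIGMA = 1.4826


@dataclass
class FrameStack:
    """A recorded video: (frame, row, col) intensities plus acquisition metadata.

    ``sensor_pixel`` is the physical camera pixel pitch in µm; one image
    pixel spans ``sensor_pixel / magnification`` µm in the sample plane.
    """

    intensity: np.ndarray
    frequency: float
    magnification: float
    sensor_pixel: float = 13.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3 or 0 in self.intensity.shape:
            raise ValueError("intensity must be a non-empty 3-D (frame,row,col) array")
        if self.frequency <= 0 or self.magnification <= 0 or self.sensor_pixel <= 0:
            raise ValueError("frequency, magnification and sensor_pixel must be > 0")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def pixel_size_um(self) -> float:
        """Physical size of one image pixel in the sample plane (µm)."""
        return self.sensor_pixel / self.magnification

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frequency


@dataclass(frozen=True)
class Detection:
    """One blob in one frame; centroid in fractional pixels (x = col, y = row)."""

    frame_index: int
    centroid_x: float
    centroid_y: float
    n_pixels: int


def _background_model(stack: np.ndarray, k_sigma: float, row_chunk: int = 64):
    """Per-pixel temporal median and MAD scale, computed in row chunks.

    Pixels occupied by a cell for most of the video would otherwise carry
    the cell's own intensity as their background; such outlier pixels
    (median far from the frame-wide background level) are repaired to the
    global background level so that even a permanently stationary cell
    remains detectable.
    """
    n, h, w = stack.shape
    med = np.empty((h, w), dtype=np.float32)
    scale = np.empty((h, w), dtype=np.float32)
    for r0 in range(0, h, row_chunk):
        block = stack[:, r0 : r0 + row_chunk, :].astype(np.float32)
        m = np.median(block, axis=0)
        med[r0 : r0 + row_chunk] = m
        scale[r0 : r0 + row_chunk] = MAD_TO_SIGMA * np.median(
            np.abs(block - m[None]), axis=0
        )
    b0 = float(np.median(med))
    sigma0 = float(np.median(scale))
    bad = np.abs(med - b0) > k_sigma * np.maximum(scale, sigma0)
    if bad.any():
        med[bad] = b0
        scale[bad] = sigma0
    return med, scale


# 8-connectivity structure for blob labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


def detect_cells(
    stack: FrameStack,
    k_sigma: float = 5.0,
    min_blob_pixels: int = 2,
) -> list[list[Detection]]:
    """Detect cell blobs in every frame of a stack.

    A pixel is foreground in a frame when its intensity deviates from the
    temporal-median background by more than ``k_sigma`` times the robust
    per-pixel scale (strictly; an all-constant stack yields no
    detections).  Foreground pixels are grouped by 8-connectivity,
    components smaller than ``min_blob_pixels`` are discarded as noise,
    and each surviving blob is summarised by the arithmetic-mean centroid
    of its member pixels.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be > 0")
    frames = stack.intensity
    med, scale = _background_model(frames, k_sigma)
    thresh = k_sigma * scale
    out: list[list[Detection]] = []
    for k in range(frames.shape[0]):
        resid = np.abs(frames[k].astype(np.float32) - med)
        mask = resid > thresh
        dets: list[Detection] = []
        if mask.any():
            labels, n_lab = ndimage.label(mask, structure=_STRUCT8)
            if n_lab:
                idx = np.arange(1, n_lab + 1)
                sizes = ndimage.sum_labels(mask, labels, idx)
                keep = idx[sizes >= min_blob_pixels]
                if keep.size:
                    centroids = ndimage.center_of_mass(mask, labels, keep)
                    for lab, (cy, cx) in zip(keep, centroids):
                        dets.append(
                            Detection(k, float(cx), float(cy), int(sizes[lab - 1]))
                        )
        out.append(dets)
    return out


@dataclass
class _Track:
    track_id: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    missed: int = 0

    @property
    def end(self) -> tuple[float, float]:
        return self.xs[-1], self.ys[-1]

    def append(self, det: Detection) -> None:
        self.frames.append(det.frame_index)
        self.xs.append(det.centroid_x)
        self.ys.append(det.centroid_y)
        self.missed = 0


def link_detections(
    detections: list[list[Detection]],
    search_radius: float,
    new_path_radius: float | None = None,
    max_missed: int = 2,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories (pixel/frame units).

    Frame to frame, (track, detection) candidate pairs within
    ``search_radius`` of the track end are assigned greedily in order of
    increasing distance (ties broken by lower detection index, then lower
    track index), so no detection joins two tracks.  A leftover detection
    farther than ``new_path_radius`` from every open track end starts a
    new track; leftovers near an open track are treated as spurious and
    dropped.  Tracks unmatched for more than ``max_missed`` consecutive
    frames are closed.
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    if new_path_radius is None:
        new_path_radius = search_radius
    open_tracks: list[_Track] = []
    done: list[_Track] = []
    next_id = 0
    for frame_dets in detections:
        ends = np.array([t.end for t in open_tracks], dtype=float).reshape(-1, 2)
        pts = np.array(
            [(d.centroid_x, d.centroid_y) for d in frame_dets], dtype=float
        ).reshape(-1, 2)
        assigned_det = np.zeros(len(frame_dets), dtype=bool)
        assigned_trk = np.zeros(len(open_tracks), dtype=bool)
        if len(open_tracks) and len(frame_dets):
            dist = np.hypot(
                ends[:, 0][:, None] - pts[:, 0][None],
                ends[:, 1][:, None] - pts[:, 1][None],
            )
            ti, di = np.nonzero(dist <= search_radius)
            order = np.lexsort((ti, di, dist[ti, di]))
            for j in order:
                t, d = ti[j], di[j]
                if assigned_trk[t] or assigned_det[d]:
                    continue
                open_tracks[t].append(frame_dets[d])
                assigned_trk[t] = True
                assigned_det[d] = True
        # unmatched tracks age; close the stale ones
        still_open: list[_Track] = []
        for t, trk in enumerate(open_tracks):
            if assigned_trk[t]:
                still_open.append(trk)
            else:
                trk.missed += 1
                (still_open if trk.missed <= max_missed else done).append(trk)
        # leftover detections far from every pre-update track end are new cells
        for d, det in enumerate(frame_dets):
            if assigned_det[d]:
                continue
            if ends.size:
                dmin = float(
                    np.min(np.hypot(ends[:, 0] - pts[d, 0], ends[:, 1] - pts[d, 1]))
                )
            else:
                dmin = np.inf
            if dmin > new_path_radius:
                trk = _Track(next_id)
                next_id += 1
                trk.append(det)
                still_open.append(trk)
        open_tracks = still_open
    done.extend(open_tracks)
    done.sort(key=lambda t: t.track_id)
    return [
        Trajectory(t.track_id, np.array(t.frames, float), t.xs, t.ys, units="px")
        for t in done
        if t.frames
    ]


def filter_trajectories(
    trajs: list[Trajectory],
    min_frames: int = 10,
    require_jump: bool = True,
    body_length_um: float = 3.0,
    magnification: float | None = None,
    sensor_pixel: float = 13.0,
) -> list[Trajectory]:
    """Keep trajectories with meaningful duration and at least one jump.

    A trajectory survives when it has at least ``min_frames`` samples
    and, if ``require_jump``, at least one displacement between
    successive samples exceeding the species' body length (completely
    idle cells carry no motility information).  For pixel-unit
    trajectories the body length is converted to pixels via
    ``magnification`` and ``sensor_pixel``.
    """
    kept = []
    for traj in trajs:
        if len(traj) < min_frames:
            continue
        if require_jump:
            if traj.units == "px":
                if magnification is None:
                    raise ValueError(
                        "magnification required to test the jump condition in px"
                    )
                body = body_length_um * magnification / sensor_pixel
            else:
                body = body_length_um
            disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
            if not np.any(disp > body):
                continue
        kept.append(traj)
    return kept
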