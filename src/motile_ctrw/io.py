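"""File formats: multi-page TIFF stacks, trajectory/master CSVs, YAML configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import tifffile
import yaml

from .curves import BreakthroughCurve
from .distributions import DistributionSpec
from .motility import MomentSeries
from .synthdata import STEP_COLUMNS, ImagingParams, MotilityParams
from .tracking import FrameStack
from .trajectory import Trajectory

__all__ = [
    "write_stack",
    "read_stack",
    "write_trajectories",
    "read_trajectories",
    "write_master",
    "read_master",
    "write_moments",
    "write_breakthrough",
    "load_motility_config",
    "load_imaging_config",
]


def write_stack(stack: FrameStack, path) -> None:
    tifffile.imwrite(path, stack.intensity, photometric="minisblack")


def read_stack(
    path, frequency: float, magnification: float, sensor_pixel: float = 13.0
) -> FrameStack:
    """Read a multi-page TIFF; acquisition metadata is supplied by the caller."""
    return FrameStack(
        tifffile.imread(path),
        frequency=frequency,
        magnification=magnification,
        sensor_pixel=sensor_pixel,
    )


def write_trajectories(trajs: list[Trajectory], path) -> None:
    """Trajectories as CSV: (cell_id, t_s, x_um, y_um) or (cell_id, frame, x_px, y_px)."""
    frames = []
    for traj in trajs:
        cols = (
            ("t_s", "x_um", "y_um") if traj.units == "um" else ("frame", "x_px", "y_px")
        )
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": traj.cell_id,
                    cols[0]: traj.t,
                    cols[1]: traj.x,
                    cols[2]: traj.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    units = "um" if "t_s" in df.columns else "px"
    tcol, xcol, ycol = (
        ("t_s", "x_um", "y_um") if units == "um" else ("frame", "x_px", "y_px")
    )
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values(tcol)
        out.append(
            Trajectory(
                cell_id,
                grp[tcol].to_numpy(float),
                grp[xcol].to_numpy(float),
                grp[ycol].to_numpy(float),
                units=units,
            )
        )
    return out


def write_master(master: pd.DataFrame, path) -> None:
    master.to_csv(path, index=False, columns=STEP_COLUMNS)


def read_master(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_moments(moments: MomentSeries, path) -> None:
    pd.DataFrame(
        {
            "t_s": moments.times,
            "mean_disp_um": moments.mean_disp,
            "variance_um2": moments.variance,
            "n_alive": moments.n_alive,
        }
    ).to_csv(path, index=False)


def write_breakthrough(curve: BreakthroughCurve, path) -> None:
    pd.DataFrame(
        {
            "t_s": curve.times,
            "density_per_s": curve.density,
            "cumulative_recovery": curve.cumulative,
        }
    ).to_csv(path, index=False)


def _dist_spec(node: dict) -> DistributionSpec:
    node = dict(node)
    return DistributionSpec(
        family=node.pop("family"),
        upper=node.pop("upper", None),
        params=node.pop("params", node),
    )


def load_motility_config(path) -> MotilityParams:
    """Build MotilityParams from a YAML file (must carry an explicit seed)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    if "jump_pdf" in cfg:
        cfg["jump_pdf"] = _dist_spec(cfg["jump_pdf"])
    if "wait_pdf" in cfg:
        cfg["wait_pdf"] = _dist_spec(cfg["wait_pdf"])
    if "start_box" in cfg and cfg["start_box"] is not None:
        (a, b), (c, d) = cfg["start_box"]
        cfg["start_box"] = ((float(a), float(b)), (float(c), float(d)))
    return MotilityParams(**cfg)


def load_imaging_config(path) -> ImagingParams:
    return ImagingParams(**yaml.safe_load(Path(path).read_text()))
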