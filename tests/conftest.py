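import numpy as np
import pytest

from motile_ctrw import (
    DistributionSpec,
    MotilityParams,
    Trajectory,
    generate_trajectories,
)


@pytest.fixture(scope="session")
def brownian_trajs():
    """Isotropic Gaussian walks with per-axis D0 = 2 µm²/s, dt = 0.5 s.

    2000 walkers keep the relative standard error of the variance slope
    near 3%, giving the 5%-level slope checks adequate power.
    """
    rng = np.random.default_rng(42)
    D0, dt, n, nt = 2.0, 0.5, 2000, 200
    out = []
    for i in range(n):
        steps = rng.normal(0.0, np.sqrt(2.0 * D0 * dt), size=(nt, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        out.append(Trajectory(i, np.arange(nt + 1) * dt, pos[:, 0], pos[:, 1], "um"))
    return out, D0


def recoverable_params(**overrides) -> MotilityParams:
    """Generator settings whose steps the segmentation rules can recover."""
    from motile_ctrw.experiments import recoverable_motility_params

    overrides.setdefault("seed", 7)
    return recoverable_motility_params(**overrides)


@pytest.fixture(scope="session")
def segmentable_ensemble():
    """Frame-aligned ensemble with its ground-truth step table."""
    params = recoverable_params()
    trajs, truth = generate_trajectories(params)
    return params, trajs, truth


@pytest.fixture()
def exp_wait_spec():
    return DistributionSpec("exponential", {"scale": 2.0})
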