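# motile-ctrw

Tools for analysing the motility of swimming/twitching bacteria recorded in
quasi-2-D micromodel chambers, and for predicting their ensemble transport.
The pipeline covers every stage between a raw intensity video and a
model-vs-observation breakthrough comparison:

1. **Tracking** — detect dark cell blobs against a per-pixel temporal-median
   background, link them frame-to-frame by greedy nearest-neighbour search
   within a radius, and filter out short (< 10 frames) or completely idle
   trajectories.
2. **Motility statistics** — convert to physical units
   (`t = frames / frequency`, `x = pixels × sensor_pixel / magnification`),
   segment each trajectory into *jumps* (runs of approximately constant
   direction, closed by a waiting state or a turn > ±5°) and *waiting times*
   (frame displacements below the body length), pool all steps into a master
   table, and compute empirical jump/wait PDFs, ensemble displacement
   moments, drift speed and lag-1 step correlations.
3. **Transport models** — ensemble breakthrough (first-passage) curves at
   concentric control radii *L* from:
   - a **coupled CTRW**: the walk `r[n+1] = r[n] + ε[n]`,
     `t[n+1] = t[n] + τ[n]`, with whole rows `(ε, τ)` bootstrapped from the
     master table so waiting times stay conditioned on jump lengths;
   - an **uncoupled CTRW**: jump and waiting time drawn from independent
     rows;
   - an **ADE** with time-varying diffusivity: `D(t) = ½ dσ²/dt` from the
     observed variance growth and
     `C/C0 = ½ erfc((L − V·t) / (2√(D·t)))`;
   all compared against the **real-path** breakthroughs of the recorded
   trajectories themselves.
4. **Synthetic data** — a ground-truth run-and-tumble generator (heavy-tailed
   jump and wait distributions, optional calibrated lag-1 correlations and
   slow drift) plus a microscopy-style renderer, so every stage above is
   testable end-to-end with known answers.

The interesting transport physics sits in the tails: jump lengths peak at
5–6 µm but reach ~100 µm, waiting times span milliseconds to hundreds of
seconds, and successive steps of a cell need not be independent. The package
exists to quantify how far the classical ADE and the (memoryless) CTRW can
be pushed before those features break them.

## Worked example

```python
import numpy as np
from motile_ctrw import (
    MotilityParams, generate_trajectories, segment_steps, build_master,
    step_correlation, ensemble_moments, drift_speed, diffusion_coefficient,
    ADEParams, ade_breakthrough, CTRWConfig, simulate_ctrw, first_passage,
    real_breakthrough, compare_report,
)

params = MotilityParams(n_cells=200, t_max=125.0, seed=1)   # 125 s of motion
trajs, truth = generate_trajectories(params)
master = build_master([segment_steps(t, params.body_length) for t in trajs])
print(f"{len(trajs)} trajectories -> {len(master)} steps")
corr = step_correlation(master)
print(f"lag-1 corr: jump {corr.eps_corr:+.3f}, wait {corr.tau_corr:+.3f}")

moments = ensemble_moments(trajs, min_unique=50)
V = max(drift_speed(moments), 0.0)
D = diffusion_coefficient(moments, smooth_window=9)

radii = [10.0, 20.0, 30.0, 40.0]
ens_c = simulate_ctrw(master, CTRWConfig(coupled=True,  n_particles=5000, t_max=125.0, seed=2))
ens_u = simulate_ctrw(master, CTRWConfig(coupled=False, n_particles=5000, t_max=125.0, seed=3))
ade = ade_breakthrough(ADEParams(V=V, D=D, L_list=radii), np.linspace(0.25, 125.0, 500))
table = compare_report(real_breakthrough(trajs, radii, t_max=125.0), ade,
                       first_passage(ens_c, radii), first_passage(ens_u, radii), radii)
print(table.round(2).to_string(index=False))
```

Output:

```
200 trajectories -> 10614 steps
lag-1 corr: jump +0.099, wait +0.061
 L_um         source  recovery  mean_arrival_s  std_arrival_s  n_arrived  excluded
 10.0           real      1.00            3.11           6.63        200     False
 20.0           real      1.00            5.98           7.24        199     False
 30.0           real      1.00           10.46          11.33        199     False
 40.0           real      1.00           16.48          16.40        199     False
 10.0            ade      0.61           68.91          45.25          0     False
 ...
 10.0   ctrw_coupled      1.00            8.99           8.84       5000     False
 20.0   ctrw_coupled      1.00           22.05          17.77       4998     False
 ...
```

Reading the table: `recovery` is the fraction of the ensemble reaching the
control radius within the observation window (the curve's zeroth moment);
`mean/std_arrival_s` are moments of the first-arrival times among arrivers.
Even on synthetic data the resampling models are visibly optimistic about
late arrivals — their mean arrival times run several times above the
real-path values, while the real curves are narrower — because a walk that
redraws every step independently keeps giving each particle fresh chances to
draw a very long wait, whereas a recorded trajectory that drew one simply
never arrives and is censored. The small spurious lag-1 correlations are
segmentation artifacts of finite frame rate; both effects mirror what the
models do on real recordings.

A command-line interface mirrors the library
(`motile-ctrw synth | track | stats | simulate | ade | compare`); run any
subcommand with `--help`.

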