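# motorcpd

Bayesian change point analysis for intracellular transport trajectories.

Cargo hauled along microtubules by molecular motors (kinesin-1, activated
dynein complexes such as DDB, or antagonistic pairs) switches between
biophysical states — processive runs at different speeds, pauses, reversals.
Quantifying those states from single-particle tracking data requires finding
the *velocity change points* of each trajectory without a human marking
segments by hand. `motorcpd` implements a two-stage Bayesian protocol for
this, aimed at researchers analyzing in-vitro tracking experiments:

1. **Stage 1 — how many changes?** The longitudinal cargo position is
   modeled as Brownian motion with piecewise-constant drift: frame-to-frame
   increments are independent `Normal(v_j Δ, Δ/η)` within segment *j*. Change
   configurations are a switch point process with a minimum segment duration
   (default 5 frames) and a renewal prior; segment velocities carry compact
   `Uniform(−v_max, v_max)` priors and are integrated out analytically, so a
   Metropolis–Hastings sampler explores only the configuration, the switch
   rate λ, and the precision η. The estimate `k_MAP` is the posterior mode of
   the number of changes.
2. **Stage 2 — where, and how fast?** Given *k*, a component-wise sampler
   (random-walk velocities and change times, conjugate Gibbs precision) draws
   the joint posterior of `(τ, v, η)`, with split-R̂/ESS convergence checks.
   Point estimates are the joint posterior MAP.

Around the core method the package provides the biophysical simulator used
for validation (Poisson motor stepping, an exactly-sampled Ornstein–Uhlenbeck
tethered cargo, camera subsampling with localization noise), pre-processing
of raw 2-D tracks (orthogonal-regression microtubule fitting, projection,
missing-frame imputation), two frequentist baselines (minimum-RSS dynamic
programming with BIC, and LRT binary segmentation), and dataset-level
summaries (duration-weighted speed distributions, Initial/Paused/Reversed
state classification, transition probabilities, run metrics).

## Worked example

Simulate a cargo that runs at 0.6 µm/s, pauses near 0.05 µm/s between 4 s
and 7 s, then resumes, and recover the structure from the noisy observations:

```python
import numpy as np
from motorcpd import (
    IncrementSeries, PhysicalParams, SteppingSchedule, simulate_path,
    run_stage1, k_map, run_stage2, map_point_estimates, check_convergence,
)

schedule = SteppingSchedule(change_times=(4.0, 7.0),
                            rates=(0.60 / 0.008, 0.05 / 0.008, 0.60 / 0.008))
path = simulate_path(schedule, PhysicalParams(), np.random.default_rng(10))
xi = IncrementSeries(np.diff(path.obs_positions), dt=0.05)

stage1 = run_stage1(xi, n_iter=200_000, n_chains=2, thin=100, rng=0)
k_hat, pmf = k_map(stage1)
print(f"k_MAP = {k_hat}; posterior P(K=k): "
      + ", ".join(f"{k}: {p:.2f}" for k, p in sorted(pmf.items())))

stage2 = run_stage2(xi, k=k_hat, n_iter=40_000, n_chains=4, thin=50, rng=1,
                    eta_map1=stage1.eta_map,
                    init_changes=stage1.map_sample()[0])
tau, v, eta = map_point_estimates(stage2)
ok, _ = check_convergence(stage2)
print(f"change times (s): {np.round(tau, 2)}")
print(f"velocities (um/s): {np.round(v, 3)}")
print(f"precision eta: {eta:.0f}; converged: {ok}")
```

Output:

```
k_MAP = 2; posterior P(K=k): 2: 0.77, 3: 0.20, 4: 0.03, 5: 0.00
change times (s): [4. 7.]
velocities (um/s): [0.589 0.014 0.575]
precision eta: 213; converged: True
```

The sampler puts 77% posterior mass on the true two changes, locates them at
4.0 s and 7.0 s (the truth, to within the 0.05 s frame), and estimates the
three segment velocities within ~0.04 µm/s of the simulated 0.60/0.05/0.60.
η is the model's common precision nuisance (its inverse is the lumped
diffusion-scale noise of the increments).

A command-line interface wraps the same functions:

```bash
motorcpd simulate --case 1 --n-paths 200 --seed 1 --out data/case1
motorcpd preprocess --in track.csv --max-gap 20 --out long.csv
motorcpd stage1 --in data/case1/path_0000.csv --out s1.json
motorcpd stage2 --in data/case1/path_0000.csv --k 2 --out s2.json
motorcpd baseline --method rss --in data/case1/path_0000.csv --out rss.json
motorcpd benchmark --cases 1,4 --methods rss,lrt --n-paths 200 --seed 1 --out report.json
```

## Layout

- `motorcpd.simulate` — motor/cargo/camera forward model and the four
  validation scenarios
- `motorcpd.preprocess` — 2-D track → longitudinal increments
- `motorcpd.model` — likelihoods and the velocity-marginalized likelihood
- `motorcpd.stage1` / `motorcpd._stage1_kernel` — posterior on the number of
  changes (reference and numba implementations)
- `motorcpd.stage2` — conditional inference of change times and velocities
- `motorcpd.postprocess` — speeds, states, transitions, run metrics
- `motorcpd.baselines` — RSS+BIC dynamic program, LRT binary segmentation
- `motorcpd.evaluate` — scenario benchmark harness
- `docs/methods.md` — models, priors, defaults, numerical choices
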