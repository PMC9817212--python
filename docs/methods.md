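# Methods

`motorcpd` detects velocity change points in one-dimensional projections of
single-particle tracking data from molecular-motor experiments, estimates the
velocities and change times of the resulting segments, and summarizes motor
behavior at the dataset level. This note records the models, the defaults and
why they hold, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Biophysical forward model (simulator)

A motor-protein complex (kinesin-1, dynein--dynactin--BicD2, or a pair)
carries a tagged cargo along a microtubule. The simulator composes three
layers:

1. **Motor stepping.** The motor position `Z(t)` is a scaled Poisson process:
   steps of size `delta` (default 0.008 um, the kinesin-1 step) arrive at a
   piecewise-constant rate `rho_j`, so segment speed is `v_j = rho_j * delta`.
   Rate changes at times `tau` represent switches in the motor configuration.
   Steps are realized as per-interval Poisson counts on the union of a uniform
   mesh (`sim_dt`, default 1e-4 s), the change times, and the camera frames,
   which is an exact realization at the grid points because every interval has
   a single rate.
2. **Cargo relaxation.** The cargo is tethered to the motor by a spring and
   diffuses: an Ornstein--Uhlenbeck process centered on `Z(t)` with relaxation
   rate `kappa/gamma` (default 1000 /s) and free diffusivity `D` (default
   0.01 um^2/s). The update uses the exact Gaussian transition
   (mean `e^{-th ds} X + (1 - e^{-th ds}) Z`, variance
   `(D/th)(1 - e^{-2 th ds})`), so `sim_dt` introduces no discretization error
   in the OU dynamics; it only bounds how long the motor position is held
   constant between updates. At the defaults that hold is 0.1 ms against a
   1 ms cargo relaxation time and a 50 ms frame, i.e. negligible.
3. **Camera.** Observations are the cargo position subsampled at the frame
   interval `Delta` (default 0.05 s, 20 fps) plus i.i.d. Gaussian localization
   noise (sigma = 0.003 um), for `T_final` = 10 s (201 frames).

**Validation scenarios.** Four scenario families cross two factors: change
times uniformly *spaced* (Cases 1, 2) versus an ordered Uniform(0, T) sample
(Cases 3, 4), and slow/fast speed distributions with negligible overlap
(folded Normal(0.1, 0.05^2) / (0.6, 0.1^2); Cases 1, 3) versus substantial
overlap ((0.1, 0.1^2) / (0.6, 0.2^2); Cases 2, 4). The number of changes per
path is Poisson(3); segment speeds alternate between the fast and slow laws.
Whether the first segment is fast or slow is not determined by the scenario
definitions; the default starts fast (a processive start is typical of these
experiments) and is exposed as `first_segment_fast` — by the symmetry of the
alternation it does not affect aggregate accuracy. All speeds are positive:
the scenarios model changes in motor interaction, not reversals.

The generator is the canonical input source for validation (the experimental
quantum-dot data is not public). What it does emulate: Poisson stepping,
OU-tethered cargo, uniform frames, localization noise, realistic change
structure. What it does not: multiple mechanistically interacting motors
(velocity switching abstracts them), microtubule curvature, 2-D effects,
missing frames, or tracker artifacts such as transient spikes. Passing the
validation therefore shows the inference recovers changes under the stated
physics, not that it is robust to every artifact of real tracking data.

## Statistical model

Inference never sees the motor path. The longitudinal position is modeled as
Brownian motion with piecewise-constant drift: increments
`xi_n = X_{n+1} - X_n` on the frame grid are independent
`Normal(v_j Delta, Delta / eta)`, where `v_j` is the segment velocity and the
common precision `eta` is a nuisance lumping stepping noise, tether
fluctuation, and localization error. Change times are mapped to increment
indices by `M_j = floor(tau_j / Delta)`; segment `j` covers increments
`M_{j-1}+1 .. M_j` (1-based, half-open on the left). The model is
deliberately misspecified in two known ways — increments have a small MA(1)
correlation from shared localization noise, and stepping noise makes fast
segments noisier than slow ones — both inherited from the design and absorbed
by the single `eta`.

## Stage 1: number of change points

The change configuration is a switch point process `r` (binary over interior
indices) with a minimum segment duration `d_r` (default 5 observations, i.e.
0.25 s: roughly ten motor steps at a 0.01 s/step pace). Its prior is a
truncated renewal form `(1 - e^{-lam Delta})^{K_r} (e^{-lam Delta})^{A_r}` on
the feasible set, where `A_r` counts positions at which an extra change could
legally be inserted; at `d_r = 1` this reduces to the Bernoulli process. The
switch rate has a Gamma(15, 50) prior (mean 0.3 /s — three changes per 10 s);
velocities get independent Uniform(-2, 2) um/s priors (a compact prior is
essential: an unbounded conjugate Normal prior lets overfitted many-change
configurations buy likelihood, and is exposed only as a known-bad option in
spirit, not used anywhere); `eta` gets an empirical
Gamma(0.15 eta_umvu, 0.1) prior centered 1.5x above the no-change estimate
`eta_umvu = Delta / Var(xi)`.

The velocities are integrated out analytically against their uniform priors,
so the sampler explores only `(r, lam, eta)`. Each segment contributes a
Gaussian-CDF difference term; the implementation is certified against direct
1-D/2-D/3-D quadrature of likelihood x priors to 1e-6 relative, which is the
binding definition of the marginal (the closed form is easy to mistype).

Metropolis--Hastings moves:

* `r`: with probability 0.25 an **independence proposal** — a feasible
  configuration drawn as `K ~ Poisson(lam T)` truncated to feasible counts,
  then uniform among the `C(N - (K+1) d_r + K, K)` feasible placements via a
  stars-and-bars bijection; its density is exactly computable, which is all
  an independence kernel needs. With probability 0.25 a **birth/death** pair
  (uniform feasible insertion / uniform deletion, paired Hastings ratio);
  otherwise a **shift** of one change uniform in its feasible window
  (symmetric). Moves without a feasible target propose the identity.
* `lam`: Gamma(2.5, 10) independence proposal.
* `eta`: Normal random walk with sd `eta_umvu / 4`; negative proposals
  rejected.

Kernel correctness is established end-to-end by running the chain with the
likelihood switched off and comparing empirical configuration frequencies
against exhaustively enumerated prior masses (chi-square, N = 10) — this
check binds both the pure-Python reference chain and the numba production
kernel. The chain is initialized at the minimum-RSS segmentation with
`k_0 ~ Poisson(3)` (the prior-mean number of changes over the path; the
alternative reading of the initialization parameter as shape x rate x T gives
a nonsensical mean of 7500) and `lam, eta` drawn from their priors.

The estimate `k_MAP` is the mode of the pooled posterior of `K_r` over
chains, ties broken toward fewer changes. Production defaults follow the
published protocol (200k iterations per chain, first half burn-in, thin 100);
the validation suite uses 2 chains of 200k, which the prior-recovery and
accuracy checks show is ample at N = 200.

## Stage 2: change times and velocities given k

Conditional on `k`, a component-wise sampler draws `(tau, v, eta)`:
velocities by Normal random walks (sd 0.5 um/s, rejected outside the uniform
prior support), `eta` by an exact conjugate Gibbs draw
Gamma(0.1 eta_MAP1 + N/2, 0.1 + RSS/(2 Delta)) with the residual sum over
all k+1 segments, and each `tau_j` by a uniform random walk on continuous
time with half-width `ceil((1+k)^{-2} N) Delta`, mapped through `floor` for
likelihood evaluation and rejected if any segment would drop below `d = 5`
observations (the printed middle ordering constraint is unsatisfiable as
displayed; the implemented bound `(M_{j+1} - d + 1) Delta` is the one
consistent with the first and last constraints). `eta_MAP1` is the precision
component of the stage-1 joint-MAP sample, falling back to `eta_umvu` when
stage 1 is skipped. Update order is fixed (v's, eta, tau's) for
reproducibility. Starts are jittered per chain so the split R-hat diagnostic
is meaningful; convergence requires R-hat < 1.1 and effective sample size
> 5 x chains for every parameter (computed with ArviZ).

Point estimates are the components of the highest-log-posterior retained
draw (joint MAP), not marginal means — multimodal change-time posteriors make
means misleading.

## Downstream summaries

Speed distributions pool per-segment posterior draws weighted by segment
occupancy (as many draws as observations in the segment, absolute values —
microtubule polarity is unknown). Segments are classified as
Initial/Paused/Reversed from the MAP velocity and the segment distance with
thresholds 0.1 um/s and 0.4 um (both configurable; 0.2/0.5 is a reasonable
robustness choice): a slow segment that still covers 0.4 um is treated as
active, the reference direction is the first active segment's sign, and paths
with no active segment are excluded from transition analysis. One-step
transition matrices are row-normalized counts; rows with no observed exits
are reported as undefined rather than zero.

## Baselines

* **RSS + BIC**: exact dynamic-programming minimum-RSS segmentation
  (intercept-only segments, minimum length 5) for each k, then
  `BIC(k) = N log(RSS_k/N) + (2k+1) log N` (the parameter count offset among
  published variants shifts BIC by a constant in k and cannot change the
  argmin). The DP is verified against exhaustive enumeration at small N.
* **LRT binary segmentation**: recursive splitting on the Gaussian
  mean-change generalized likelihood-ratio statistic. The alpha = 0.05
  critical value is obtained by null Monte-Carlo calibration at the path
  length with a fixed internal seed (deterministic, scale-invariant, and
  size-correct by construction — verified empirically); the same per-path
  threshold is reused down the recursion.

## The "meaningful changes" subset

A simulated path is in the subset when every gap **between consecutive change
points** spans at least 5 observations and every consecutive velocity jump is
at least 0.1 um/s. The first and last segments are exempt from the duration
condition: with the condition applied to all k+1 segments the expected number
of violating Case-3 paths is ~57/200 (analytically,
`E[1 - (1 - (k+1)c)^k]` over `k ~ Poisson(3)` with `c = 0.025`), while the
interior-gap rule gives ~35.5/200 — only the latter is compatible with the
validation study's reported counts, and it is the rule the package uses.

## Numerical choices and limitations

* All likelihood work is in log space; CDF differences use the complementary
  log-CDF on the reflected pair when both arguments are positive, avoiding
  cancellation out to arguments where `erfc` underflows (far beyond any
  configuration a chain can reach from a finite state).
* The production stage-1 kernel is numba-jitted (the pure-Python chain is
  retained as the reference implementation and fallback); both pass the
  enumeration oracle, and the jitted marginal likelihood is asserted equal to
  the numpy reference at 1e-9.
* Problem sizes in the validation suite: 200-path datasets for the baseline
  accuracy checks; 40--80 path subsets with 2 x 200k-iteration chains for the
  Bayesian accuracy checks; 50 paths for credible-interval coverage. These
  sizes keep Monte-Carlo error well below the tolerances being asserted.
* Accuracy comparisons against the published simulation study are stochastic
  on both sides: the study reports one 200-path realization per case. Our
  replications agree within roughly two binomial standard errors everywhere;
  the RSS baseline runs ~0.05 above the published Case-1 value across seeds
  and the LRT ~0.05 below the published Case-4 value, consistent with
  dataset-level variability plus minor unknowable details of the original R
  implementations (their LRT critical-value approximation is not printed; an
  anti-conservative approximation would raise their accuracy under the
  under-estimation regime these scenarios produce).
* Known limitations: single microtubule and 1-D projection only; no handling
  of tracker spike artifacts; the common-precision assumption is wrong in
  detail for strongly heteroscedastic paths (it widens velocity intervals on
  slow segments — observed as mild over-coverage in the credible-interval
  check); model averaging over k is out of scope by design (the two-stage
  split is the method).
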