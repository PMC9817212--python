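"""Biophysical motor--cargo simulator.

A motor-protein complex steps along a microtubule as a Poisson process whose
rate is piecewise constant in time (each rate regime is a "segment"); the
cargo is tethered to the motor by a harmonic spring and diffuses, i.e. it
follows an Ornstein--Uhlenbeck process centered at the motor position.  A
camera observes the cargo at a fixed frame interval with additive Gaussian
localization noise.

The four validation scenarios combine two crossed factors: whether change
times are uniformly *spaced* or drawn as an ordered uniform sample, and
whether the slow/fast folded-normal speed distributions overlap negligibly
or substantially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "PhysicalParams",
    "SteppingSchedule",
    "SimulatedPath",
    "ScenarioSpec",
    "scenario_spec",
    "simulate_motor",
    "simulate_cargo",
    "observe",
    "simulate_path",
    "generate_scenario",
]

#: merge tolerance for the union time grid, seconds
_GRID_TOL = 1e-12


@dataclass(frozen=True)
class PhysicalParams:
    """Physical and camera constants.

    step_size
        Motor step size delta, um (kinesin-1: 0.008).
    kappa_over_gamma
        Tether stiffness / drag, 1/s; the cargo relaxation rate.
    diffusivity
        Free cargo diffusivity D, um^2/s.
    obs_noise_sd
        Localization noise sigma, um.
    sim_dt
        Simulation mesh spacing, s.
    frame_dt
        Camera frame interval Delta, s.
    duration
        Total tracked time T_final, s.
    """

    step_size: float = 0.008
    kappa_over_gamma: float = 1000.0
    diffusivity: float = 0.01
    obs_noise_sd: float = 0.003
    sim_dt: float = 1e-4
    frame_dt: float = 0.05
    duration: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "step_size",
            "kappa_over_gamma",
            "diffusivity",
            "obs_noise_sd",
            "sim_dt",
            "frame_dt",
            "duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa_over_gamma <= 0:
            raise ValueError("kappa_over_gamma must be positive (degenerate OU)")
        if not (self.sim_dt <= self.frame_dt <= self.duration):
            raise ValueError("require sim_dt <= frame_dt <= duration")

    @property
    def n_frames(self) -> int:
        """Number of increments N; there are N+1 observation times."""
        return int(math.floor(self.duration / self.frame_dt + _GRID_TOL))


@dataclass(frozen=True)
class SteppingSchedule:
    """Piecewise-constant stepping rates with change times.

    ``rates`` has one more entry than ``change_times``; segment speeds are
    ``rates * step_size``.
    """

    change_times: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        tau = np.asarray(self.change_times, dtype=float)
        rho = np.asarray(self.rates, dtype=float)
        if rho.size != tau.size + 1:
            raise ValueError("need len(rates) == len(change_times) + 1")
        if tau.size and np.any(np.diff(tau) <= 0):
            raise ValueError("change_times must be strictly increasing")
        if np.any(rho < 0):
            raise ValueError("stepping rates must be non-negative")

    @property
    def k(self) -> int:
        return len(self.change_times)

    def velocities(self, step_size: float) -> np.ndarray:
        return np.asarray(self.rates) * step_size


@dataclass(frozen=True)
class SimulatedPath:
    """One simulated motor/cargo/camera realization with its ground truth."""

    times: np.ndarray  # union grid {s_n}
    motor: np.ndarray  # Z(s_n)
    cargo: np.ndarray  # X(s_n)
    obs_times: np.ndarray  # frame grid t_n = n*Delta
    obs_positions: np.ndarray  # X_hat_n
    schedule: SteppingSchedule
    params: PhysicalParams

    @property
    def true_k(self) -> int:
        return self.schedule.k

    @property
    def true_velocities(self) -> np.ndarray:
        return self.schedule.velocities(self.params.step_size)


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative settings of one validation scenario (Cases 1-4)."""

    case_id: int
    spacing: str  # "spaced" | "distributed"
    v_slow: tuple[float, float]  # folded-normal (mean, sd), um/s
    v_fast: tuple[float, float]
    change_rate: float = 3.0  # Poisson mean for the number of changes
    n_paths: int = 200
    first_segment_fast: bool = True
    params: PhysicalParams = field(default_factory=PhysicalParams)

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3, 4):
            raise ValueError("case_id must be in {1,2,3,4}")
        if self.spacing not in ("spaced", "distributed"):
            raise ValueError("spacing must be 'spaced' or 'distributed'")


_CASE_TABLE = {
    1: ("spaced", (0.1, 0.05), (0.6, 0.1)),
    2: ("spaced", (0.1, 0.1), (0.6, 0.2)),
    3: ("distributed", (0.1, 0.05), (0.6, 0.1)),
    4: ("distributed", (0.1, 0.1), (0.6, 0.2)),
}


def scenario_spec(case_id: int, n_paths: int = 200, **overrides) -> ScenarioSpec:
    """The canonical spec for one of the four cases."""
    spacing, v_slow, v_fast = _CASE_TABLE[case_id]
    return ScenarioSpec(
        case_id=case_id,
        spacing=spacing,
        v_slow=v_slow,
        v_fast=v_fast,
        n_paths=n_paths,
        **overrides,
    )


def union_grid(params: PhysicalParams, change_times=()) -> np.ndarray:
    """Sorted merge of the uniform sim_dt mesh, the change times, and the
    frame times, de-duplicated with tolerance so rate jumps align with grid
    endpoints."""
    n_sim = int(round(params.duration / params.sim_dt))
    mesh = np.arange(n_sim + 1, dtype=float) * params.sim_dt
    frames = np.arange(params.n_frames + 1, dtype=float) * params.frame_dt
    extra = np.asarray([t for t in change_times if 0.0 < t < params.duration])
    grid = np.concatenate([mesh, frames, extra])
    grid.sort()
    keep = np.empty(grid.size, dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(grid) > _GRID_TOL
    return grid[keep]


def simulate_motor(
    schedule: SteppingSchedule,
    params: PhysicalParams,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a motor path on the union grid.

    Per-interval Poisson counts at the segment rate are an exact realization
    of the scaled Poisson process at the grid points (the change times are
    grid points, so each interval has a single rate).  Returns ``(times,
    positions)`` with positions in um, starting at 0.
    """
    if grid is None:
        grid = union_grid(params, schedule.change_times)
    dt = np.diff(grid)
    # rate in force on interval [s_{n-1}, s_n): segment containing the left end
    seg = np.searchsorted(schedule.change_times, grid[:-1], side="right")
    rates = np.asarray(schedule.rates, dtype=float)[seg]
    counts = rng.poisson(rates * dt)
    z = np.empty(grid.size)
    z[0] = 0.0
    np.cumsum(counts * params.step_size, out=z[1:])
    return grid, z


@njit(cache=False)
def _ou_recursion(x0, z, decay, noise):  # pragma: no cover - jitted
    x = np.empty(z.size)
    x[0] = x0
    for n in range(1, z.size):
        a = decay[n - 1]
        x[n] = a * x[n - 1] + (1.0 - a) * z[n - 1] + noise[n - 1]
    return x


def simulate_cargo(
    times: np.ndarray,
    motor: np.ndarray,
    params: PhysicalParams,
    rng: np.random.Generator,
    x0: float = 0.0,
) -> np.ndarray:
    """Sample the tethered cargo on the motor's grid via the exact OU
    transition: mean ``exp(-th*ds)*X + (1-exp(-th*ds))*Z`` and variance
    ``(D/th)*(1-exp(-2*th*ds))`` per step, th = kappa/gamma."""
    th = params.kappa_over_gamma
    if th <= 0:
        raise ValueError("kappa_over_gamma must be positive")
    ds = np.diff(times)
    decay = np.exp(-th * ds)
    var = (params.diffusivity / th) * (1.0 - decay**2)
    noise = rng.standard_normal(ds.size) * np.sqrt(var)
    return _ou_recursion(float(x0), np.asarray(motor, dtype=float), decay, noise)


def observe(
    times: np.ndarray,
    cargo: np.ndarray,
    params: PhysicalParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the cargo at the frame grid and add N(0, sigma^2) noise."""
    frames = np.arange(params.n_frames + 1, dtype=float) * params.frame_dt
    idx = np.searchsorted(times, frames - _GRID_TOL)
    idx = np.clip(idx, 0, times.size - 1)
    # snap to the nearest union-grid time
    left = np.clip(idx - 1, 0, times.size - 1)
    snap_left = np.abs(times[left] - frames) < np.abs(times[idx] - frames)
    idx = np.where(snap_left, left, idx)
    noise = params.obs_noise_sd * rng.standard_normal(frames.size)
    return frames, cargo[idx] + noise


def simulate_path(
    schedule: SteppingSchedule,
    params: PhysicalParams,
    rng: np.random.Generator,
    x0: float = 0.0,
) -> SimulatedPath:
    """Full motor -> cargo -> camera chain for one path."""
    grid = union_grid(params, schedule.change_times)
    _, motor = simulate_motor(schedule, params, rng, grid=grid)
    cargo = simulate_cargo(grid, motor, params, rng, x0=x0)
    obs_t, obs_x = observe(grid, cargo, params, rng)
    return SimulatedPath(
        times=grid,
        motor=motor,
        cargo=cargo,
        obs_times=obs_t,
        obs_positions=obs_x,
        schedule=schedule,
        params=params,
    )


def draw_schedule(spec: ScenarioSpec, rng: np.random.Generator) -> SteppingSchedule:
    """Draw one ground-truth stepping schedule for a scenario path.

    k ~ Poisson(change_rate); change times uniformly spaced (Cases 1/2) or an
    ordered Uniform(0, T) sample (Cases 3/4); segment speeds alternate between
    the fast and slow folded-normal distributions.
    """
    p = spec.params
    k = int(rng.poisson(spec.change_rate))
    if spec.spacing == "spaced":
        tau = p.duration * np.arange(1, k + 1) / (k + 1)
    else:
        tau = np.sort(rng.uniform(0.0, p.duration, size=k))
    v = np.empty(k + 1)
    for j in range(k + 1):
        fast = (j % 2 == 0) == spec.first_segment_fast
        mean, sd = spec.v_fast if fast else spec.v_slow
        v[j] = abs(rng.normal(mean, sd))  # folded normal
    rates = v / p.step_size
    return SteppingSchedule(change_times=tuple(tau), rates=tuple(rates))


def generate_scenario(
    spec: ScenarioSpec, rng: np.random.Generator | int
) -> list[SimulatedPath]:
    """Simulate ``spec.n_paths`` paths; per-path substreams of a master seed
    make the dataset reproducible under any evaluation order."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_paths)
    paths = []
    for s in seeds:
        sub = np.random.default_rng(int(s))
        schedule = draw_schedule(spec, sub)
        paths.append(simulate_path(schedule, spec.params, sub))
    return paths


def true_segment_frames(path: SimulatedPath) -> np.ndarray:
    """Number of observation frames in each true segment, via M_j = floor(
    tau_j / Delta) with M_0 = 0 and M_{k+1} = N."""
    p = path.params
    m = [0]
    for t in path.schedule.change_times:
        m.append(int(math.floor(t / p.frame_dt)))
    m.append(p.n_frames)
    return np.diff(np.asarray(m))
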