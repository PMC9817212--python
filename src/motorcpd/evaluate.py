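"""Validation harness: detector accuracy on simulated scenario datasets.

Runs change point detectors over the four simulated scenarios, scores the
fraction of paths whose estimated number of change points equals the truth
(with a Normal-approximation binomial confidence interval), the residual
distribution of k_hat - k_true, and the restriction to the "meaningful"
subset of paths whose changes a detector could plausibly see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baselines, stage1
from .model import IncrementSeries
from .simulate import ScenarioSpec, SimulatedPath, generate_scenario, true_segment_frames

__all__ = [
    "AccuracyReport",
    "accuracy",
    "meaningful_subset",
    "residual_distribution",
    "detect_rss",
    "detect_lrt",
    "detect_ncci",
    "run_benchmark",
]


@dataclass
class AccuracyReport:
    method: str
    case_id: int
    n_paths: int
    accuracy: float
    ci: tuple[float, float]
    residuals: dict[int, float]
    subset: bool = False
    budget: dict = field(default_factory=dict)


def accuracy(estimates, truths) -> tuple[float, tuple[float, float]]:
    """Fraction of exact recoveries of k with a 95% Normal-approximation
    binomial CI: p_hat +/- 1.96 sqrt(p_hat (1 - p_hat) / n)."""
    est = np.asarray(estimates)
    tru = np.asarray(truths)
    if est.size == 0 or est.size != tru.size:
        raise ValueError("need equal-length nonempty paired lists")
    p = float(np.mean(est == tru))
    half = 1.96 * np.sqrt(p * (1.0 - p) / est.size)
    return p, (max(p - half, 0.0), min(p + half, 1.0))


def meaningful_subset(
    paths: list[SimulatedPath],
    min_frames: int = 5,
    min_jump: float = 0.1,
) -> np.ndarray:
    """Mask of paths whose true changes are biophysically meaningful: every
    gap between consecutive change points spans at least ``min_frames``
    observations and every consecutive velocity jump is at least ``min_jump``
    um/s.  Paths with no change points pass vacuously."""
    mask = np.ones(len(paths), dtype=bool)
    for i, p in enumerate(paths):
        frames = true_segment_frames(p)
        if frames.size > 2 and np.any(frames[1:-1] < min_frames):
            mask[i] = False
            continue
        v = p.true_velocities
        if v.size > 1 and np.any(np.abs(np.diff(v)) < min_jump):
            mask[i] = False
    return mask


def short_segment_mask(paths: list[SimulatedPath], min_frames: int = 5) -> np.ndarray:
    """Mask of paths containing a between-change gap shorter than
    ``min_frames`` observations."""
    out = np.zeros(len(paths), dtype=bool)
    for i, p in enumerate(paths):
        frames = true_segment_frames(p)
        out[i] = frames.size > 2 and bool(np.any(frames[1:-1] < min_frames))
    return out


def residual_distribution(estimates, truths) -> dict[int, float]:
    """Relative frequencies of the residual k_hat - k_true."""
    res = np.asarray(estimates) - np.asarray(truths)
    vals, counts = np.unique(res, return_counts=True)
    return {int(v): float(c) / res.size for v, c in zip(vals, counts)}


def path_increments(path: SimulatedPath) -> IncrementSeries:
    return IncrementSeries(
        values=np.diff(path.obs_positions), dt=path.params.frame_dt
    )


def detect_rss(path: SimulatedPath, min_seg: int = 5, **_) -> int:
    return baselines.rss_breakpoints(
        path_increments(path).values, min_seg=min_seg
    ).k_hat


def detect_lrt(path: SimulatedPath, alpha: float = 0.05, min_seg: int = 5, **_) -> int:
    return baselines.lrt_binary_segmentation(
        path_increments(path).values, alpha=alpha, min_seg=min_seg
    ).k_hat


def detect_ncci(
    path: SimulatedPath,
    rng: np.random.Generator | int | None = None,
    n_iter: int = 20_000,
    n_chains: int = 2,
    thin: int = 20,
    hyper: stage1.Stage1Hyper | None = None,
    **_,
) -> int:
    res = stage1.run_stage1(
        path_increments(path),
        hyper=hyper,
        n_iter=n_iter,
        n_chains=n_chains,
        thin=thin,
        rng=rng,
    )
    return stage1.k_map(res)[0]


_DETECTORS = {"rss": detect_rss, "lrt": detect_lrt, "ncci": detect_ncci}


def run_benchmark(
    specs: list[ScenarioSpec],
    methods: list[str],
    rng: np.random.Generator | int | None = None,
    budget: dict | None = None,
    subset_only: bool = False,
) -> list[AccuracyReport]:
    """Simulate each scenario, run each detector, and score accuracy.

    ``budget`` holds reduced-scale knobs forwarded to the Bayesian detector
    (n_iter, n_chains, thin) and is recorded in the report.  Per-path
    detector failures are logged and excluded, not fatal.
    """
    rng = np.random.default_rng(rng)
    budget = budget or {}
    reports = []
    for spec in specs:
        paths = generate_scenario(spec, rng)
        truths = np.asarray([p.true_k for p in paths])
        keep = (
            meaningful_subset(paths) if subset_only else np.ones(len(paths), bool)
        )
        for method in methods:
            det = _DETECTORS[method]
            est, tru = [], []
            for p, t, inc in zip(paths, truths, keep):
                if not inc:
                    continue
                try:
                    est.append(det(p, rng=rng, **budget))
                    tru.append(t)
                except Exception:  # noqa: BLE001 - scored as a failure
                    continue
            acc, ci = accuracy(est, tru)
            reports.append(
                AccuracyReport(
                    method=method,
                    case_id=spec.case_id,
                    n_paths=len(est),
                    accuracy=acc,
                    ci=ci,
                    residuals=residual_distribution(est, tru),
                    subset=subset_only,
                    budget=dict(budget),
                )
            )
    return reports
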