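"""Dataset-level summaries of fitted trajectories.

Turns per-path posterior output into the quantities of biological interest:
duration-weighted speed distributions, run length / run time tables, and a
three-state behavioral classification (Initial / Paused / Reversed) with
empirical one-step transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stage2 import Stage2Result, map_point_estimates

__all__ = [
    "SegmentAnnotation",
    "RunSummary",
    "weighted_speed_distribution",
    "classify_segments",
    "transition_matrix",
    "run_metrics",
    "annotate_path",
]

STATES = ("Initial", "Paused", "Reversed")


@dataclass(frozen=True)
class SegmentAnnotation:
    index: int
    duration: float  # s
    velocity: float  # MAP velocity, um/s
    distance: float  # |displacement| over the segment, um
    state: str | None = None


@dataclass(frozen=True)
class RunSummary:
    run_length: float  # um
    run_time: float  # s
    k_hat: int


def _map_bounds(result: Stage2Result) -> np.ndarray:
    tau_hat, _, _ = map_point_estimates(result)
    m = np.floor(tau_hat / result.xi.dt).astype(int)
    return np.concatenate([[0], m, [result.xi.n]])


def weighted_speed_distribution(
    results: list[Stage2Result],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Pooled posterior speed sample, weighted by segment duration.

    For each segment of each path, draw as many velocity samples from its
    merged posterior as there are observations in the segment (at the MAP
    change times), pool across paths, and return absolute values.
    """
    rng = np.random.default_rng(rng)
    pooled = []
    for res in results:
        bounds = _map_bounds(res)
        counts = np.diff(bounds)
        v = res.merged("v")  # (draws, k+1)
        for j, c in enumerate(counts):
            draws = v[rng.integers(0, v.shape[0], size=int(c)), j]
            pooled.append(np.abs(draws))
    return np.concatenate(pooled) if pooled else np.empty(0)


def annotate_path(result: Stage2Result, positions: np.ndarray) -> list[SegmentAnnotation]:
    """Segment durations, MAP velocities and segment distances for one path.

    ``positions`` is the longitudinal position series (length N+1) the
    increment series was built from; segment distance is the absolute
    displacement between MAP change indices.
    """
    bounds = _map_bounds(result)
    tau_hat, v_hat, _ = map_point_estimates(result)
    dt = result.xi.dt
    out = []
    for j in range(len(v_hat)):
        a, b = bounds[j], bounds[j + 1]
        out.append(
            SegmentAnnotation(
                index=j,
                duration=float((b - a) * dt),
                velocity=float(v_hat[j]),
                distance=float(abs(positions[b] - positions[a])),
            )
        )
    return out


def classify_segments(
    segments: list[SegmentAnnotation],
    speed_threshold: float = 0.1,
    distance_threshold: float = 0.4,
) -> list[SegmentAnnotation] | None:
    """Assign Initial / Paused / Reversed states to a path's segments.

    A segment is "active" if |v| >= speed_threshold, or if it is slow but
    covers at least distance_threshold um (slow-but-processive).  The
    reference direction v0 is the velocity of the first active segment; paths
    with no active segment cannot be oriented and return None.
    """

    def active(s: SegmentAnnotation) -> bool:
        return abs(s.velocity) >= speed_threshold or s.distance >= distance_threshold

    ref = next((s for s in segments if active(s)), None)
    if ref is None:
        return None
    sign0 = np.sign(ref.velocity)
    out = []
    for s in segments:
        if not active(s):
            state = "Paused"
        elif np.sign(s.velocity) == sign0:
            state = "Initial"
        else:
            state = "Reversed"
        out.append(
            SegmentAnnotation(s.index, s.duration, s.velocity, s.distance, state)
        )
    return out


def transition_matrix(state_sequences: list[list[str]]):
    """Empirical 1-step transition counts and row-normalized probabilities
    over the three states, plus per-path and per-second transition rates.

    Rows with no observed exits are NaN (undefined), not zero.
    """
    idx = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((3, 3), dtype=int)
    n_trans = 0
    for seq in state_sequences:
        for a, b in zip(seq[:-1], seq[1:]):
            counts[idx[a], idx[b]] += 1
            n_trans += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / counts.sum(axis=1, keepdims=True)
    return {
        "counts": counts,
        "probs": probs,
        "n_transitions": n_trans,
        "per_path": n_trans / len(state_sequences) if state_sequences else np.nan,
    }


def run_metrics(
    positions_list: list[np.ndarray],
    dt: float,
    k_hats: list[int] | None = None,
):
    """Run length (|end - start| of the longitudinal position), run time
    (tracked duration) per path, and dataset medians."""
    rows = []
    for i, x in enumerate(positions_list):
        rows.append(
            RunSummary(
                run_length=float(abs(x[-1] - x[0])),
                run_time=float((len(x) - 1) * dt),
                k_hat=int(k_hats[i]) if k_hats is not None else -1,
            )
        )
    lengths = np.array([r.run_length for r in rows])
    times = np.array([r.run_time for r in rows])
    return {
        "paths": rows,
        "median_run_length": float(np.median(lengths)),
        "median_run_time": float(np.median(times)),
    }
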