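"""Pre-processing of raw 2-D tracking data.

Single-particle tracks are recorded as (x, y) camera coordinates while the
model is one-dimensional, so each track is projected onto its microtubule:
the microtubule is approximated by the orthogonal (total) least-squares line
through the track, the points are projected onto that line, and the projected
positions are rotated onto the axis of initial motion to give the
longitudinal position X_par (anchored at 0 at the first point).  Missing
frames are filled by noisy linear interpolation; gaps longer than ``max_gap``
truncate the track.  The increment series of the gap-free longitudinal track
is what all inference consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IncrementSeries

__all__ = [
    "RawTrack2D",
    "LongitudinalTrack",
    "LineFit",
    "fit_microtubule",
    "project_to_longitudinal",
    "impute_missing",
    "to_increments",
    "read_track_csv",
]


@dataclass(frozen=True)
class RawTrack2D:
    """Times on a uniform grid (up to missing frames), camera coordinates in
    um, and a missing mask (True where the frame was not observed)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if np.count_nonzero(~self.missing) < 3:
            raise ValueError("need at least 3 observed points")


@dataclass(frozen=True)
class LongitudinalTrack:
    times: np.ndarray
    x_par: np.ndarray  # longitudinal position, um; NaN where missing
    missing: np.ndarray
    imputed: np.ndarray
    dt: float


@dataclass(frozen=True)
class LineFit:
    """Orthogonal-regression line y = intercept + slope * x (or a vertical
    line x = x_mean) with an RMS perpendicular-residual linearity score."""

    slope: float
    intercept: float
    vertical: bool
    x_mean: float
    rms_residual: float

    def is_linear(self, threshold: float) -> bool:
        """Path-linearity filter: approximately linear iff the RMS
        perpendicular residual is below ``threshold``."""
        return self.rms_residual <= threshold


def fit_microtubule(track: RawTrack2D) -> LineFit:
    """Fit the microtubule by orthogonal least squares.

    The slope is the minimizing root of the total-least-squares quadratic

        slope = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy)

    with s_xx, s_yy, s_xy the sample (co)variances, and the intercept is
    y_mean - slope * x_mean.  When s_xy -> 0 with s_yy > s_xx the limit is a
    vertical line, handled explicitly.
    """
    obs = ~track.missing
    x = track.x[obs]
    y = track.y[obs]
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("degenerate track: all points identical")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    xb, yb = float(np.mean(x)), float(np.mean(y))
    scale = max(sxx, syy)
    if abs(sxy) < 1e-12 * max(scale, 1e-30):
        if syy > sxx:  # vertical line x = x_mean
            rms = float(np.sqrt(np.mean((x - xb) ** 2)))
            return LineFit(math.inf, math.nan, True, xb, rms)
        slope = 0.0
    else:
        slope = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    intercept = yb - slope * xb
    resid = (y - intercept - slope * x) / math.sqrt(1.0 + slope**2)
    return LineFit(slope, intercept, False, xb, float(np.sqrt(np.mean(resid**2))))


def _project_points(track: RawTrack2D, line: LineFit):
    if line.vertical:
        xh = np.full_like(track.x, line.x_mean)
        yh = track.y.copy()
    else:
        b0, b1 = line.intercept, line.slope
        xh = track.x + b1 / (b1**2 + 1.0) * (track.y - b0 - b1 * track.x)
        yh = b0 + b1 * xh
    return xh, yh


def project_to_longitudinal(
    track: RawTrack2D, line: LineFit | None = None
) -> LongitudinalTrack:
    """Project onto the fitted line and rotate so motion is along the x-axis.

    X_par_n = cos(beta) (xh_n - xh_1) - sin(beta) (yh_n - yh_1), where -beta
    is the angle of the vector from the first projected point to the next
    distinct one, so the initial motion direction is positive.
    """
    if line is None:
        line = fit_microtubule(track)
    xh, yh = _project_points(track, line)
    obs_idx = np.flatnonzero(~track.missing)
    i0 = obs_idx[0]
    dx = xh[obs_idx] - xh[i0]
    dy = yh[obs_idx] - yh[i0]
    # first observed pair with nonzero separation defines the direction
    sep = np.hypot(dx, dy)
    nz = np.flatnonzero(sep > 0)
    if nz.size == 0:
        alpha = 0.0
    else:
        j = nz[0]
        alpha = math.atan2(dy[j], dx[j])
    ca, sa = math.cos(alpha), math.sin(alpha)
    x_par = np.full(track.x.shape, np.nan)
    x_par[~track.missing] = ca * dx + sa * dy
    return LongitudinalTrack(
        times=track.times,
        x_par=x_par,
        missing=track.missing.copy(),
        imputed=np.zeros_like(track.missing),
        dt=track.dt,
    )


def impute_missing(
    track: LongitudinalTrack,
    max_gap: int = 20,
    rng: np.random.Generator | int | None = None,
    noise_scale: float | None = None,
) -> LongitudinalTrack:
    """Fill interior gaps of up to ``max_gap`` frames by linear interpolation
    plus Normal(0, eps^2) noise with eps^2 = var(X_par)/10 over observed
    points.

    A gap longer than ``max_gap``, or one touching either end of the track,
    truncates the track at the gap (never extrapolates).
    """
    rng = np.random.default_rng(rng)
    x = track.x_par.copy()
    missing = track.missing.copy()
    obs = np.flatnonzero(~missing)
    if obs.size == 0:
        raise ValueError("track has no observed points")
    # drop leading/trailing gaps
    lo, hi = obs[0], obs[-1]
    x = x[lo : hi + 1]
    missing = missing[lo : hi + 1]
    times = track.times[lo : hi + 1]
    # truncate at the first over-long gap
    gap_start = None
    run = 0
    cut = x.size
    for i, miss in enumerate(missing):
        if miss:
            if run == 0:
                gap_start = i
            run += 1
            if run > max_gap:
                cut = gap_start
                break
        else:
            run = 0
    x = x[:cut]
    missing = missing[:cut]
    times = times[:cut]
    if noise_scale is None:
        var = float(np.var(x[~missing], ddof=1)) if np.count_nonzero(~missing) > 1 else 0.0
        noise_scale = math.sqrt(var / 10.0)
    imputed = np.zeros(x.size, dtype=bool)
    i = 0
    while i < x.size:
        if missing[i]:
            j = i
            while j < x.size and missing[j]:
                j += 1
            r = j - i  # gap length; endpoints x[i-1], x[j] observed
            frac = np.arange(1, r + 1) / (r + 1.0)
            interp = x[i - 1] + frac * (x[j] - x[i - 1])
            x[i:j] = interp + noise_scale * rng.standard_normal(r)
            imputed[i:j] = True
            i = j
        else:
            i += 1
    return LongitudinalTrack(
        times=times,
        x_par=x,
        missing=np.zeros(x.size, dtype=bool),
        imputed=imputed,
        dt=track.dt,
    )


def to_increments(track: LongitudinalTrack | np.ndarray, dt: float | None = None) -> IncrementSeries:
    """Increment series xi_n = X_{n+1} - X_n of a gap-free uniform track."""
    if isinstance(track, LongitudinalTrack):
        if np.any(track.missing):
            raise ValueError("impute or truncate gaps before incrementing")
        values = np.diff(track.x_par)
        dt = track.dt
    else:
        if dt is None:
            raise ValueError("dt required for a bare position array")
        values = np.diff(np.asarray(track, dtype=float))
    return IncrementSeries(values=values, dt=dt)


def read_track_csv(path, dt: float | None = None) -> RawTrack2D:
    """Read a tracking CSV with columns frame, t, x, y; absent frames between
    the first and last recorded ones are marked missing."""
    df = pd.read_csv(path)
    frames = df["frame"].to_numpy(dtype=int)
    if dt is None:
        tt = df["t"].to_numpy(dtype=float)
        dframe = np.diff(frames)
        dt = float(np.median(np.diff(tt) / dframe))
    full = np.arange(frames[0], frames[-1] + 1)
    n = full.size
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    pos = frames - frames[0]
    x[pos] = df["x"].to_numpy(dtype=float)
    y[pos] = df["y"].to_numpy(dtype=float)
    missing = np.ones(n, dtype=bool)
    missing[pos] = False
    times = full * dt
    return RawTrack2D(times=times, x=x, y=y, missing=missing, dt=dt)
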