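"""Doppler phase-shift estimators on complex M-scans/B-scans.

Two estimator families operate on windows of m densely sampled complex
A-lines at a fixed depth:

* the conventional (Kasai-style) estimator: the phase of the summed
  lag-one autocorrelation of the first N adjacent pairs,
  ``theta = arg(sum_k s_{k+1} conj(s_k))`` — an amplitude-weighted
  average of pairwise phase differences;

* complex regression: an exhaustive search for the per-interval phase
  ``theta`` in (-pi, pi] that, after derotating the k-th point by
  ``k*theta``, minimizes the dispersion (standard deviation) of the
  realigned complex points. The total shift over the window is
  ``delta_phi = (m-1)*theta`` and may exceed 2*pi without wrapping,
  because the search is carried out in polar coordinates where phase
  accumulation merely circles the origin.

Because derotation preserves moduli, the dispersion identity

    dispersion(theta)^2 = mean|s_k|^2 - |mean(s_k * exp(-i k theta))|^2

holds exactly, so minimizing the dispersion is equivalent to maximizing
the magnitude of the coherent sum — the fast path used here. A
brute-force dispersion search is kept (``method="bruteforce"``) as an
independent check; both paths search the identical grid and apply the
identical tie-break (smallest |theta| first, then negative theta).
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import DopplerConfig, EstimatorKind, EstimatorSpec, phase_to_velocity

__all__ = [
    "MScan",
    "PhaseEstimate",
    "VelocityMap",
    "UndefinedPhaseError",
    "kasai_phase",
    "conventional_doppler",
    "realign",
    "complex_dispersion",
    "theta_grid",
    "complex_regression_phase",
    "doppler_image",
    "complex_average",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = 1e-3  # rad; the 1-mrad search grid


class UndefinedPhaseError(ValueError):
    """Raised when a window carries no phase information (all-zero signal)."""


@dataclass
class MScan:
    """A complex-valued scan: A-line index (time) by depth.

    For M-mode the beam is fixed and the first axis is pure time; for
    B-mode ``lateral_positions`` records the per-A-line lateral beam
    coordinate (m).
    """

    samples: np.ndarray
    aline_interval_s: float
    lateral_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (A-line x depth) array")
        if self.samples.shape[0] < 2:
            raise ValueError("an M-scan needs at least 2 A-lines")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (math.isfinite(self.aline_interval_s) and self.aline_interval_s > 0):
            raise ValueError("aline_interval_s must be strictly positive")
        if self.lateral_positions is not None:
            self.lateral_positions = np.asarray(self.lateral_positions, dtype=float)
            if self.lateral_positions.shape != (self.samples.shape[0],):
                raise ValueError("lateral_positions must have one entry per A-line")

    @property
    def n_alines(self) -> int:
        return self.samples.shape[0]

    @property
    def n_depth(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class PhaseEstimate:
    """Result of a phase-shift estimation on one window.

    ``theta_rad`` is the per-interval phase (the quantity converted to
    velocity with the adjacent-A-line interval); ``delta_phi_rad`` is the
    total accumulated phase over the window, ``(m-1)*theta`` for the
    regression estimator. The conventional estimator measures a single
    interval, so there ``delta_phi_rad == theta_rad``. ``dispersion`` is
    the minimized standard deviation of the realigned points (NaN for the
    conventional estimator, which has no dispersion objective).
    """

    theta_rad: float
    delta_phi_rad: float
    dispersion: float
    n_points: int

    def __post_init__(self) -> None:
        if not abs(self.theta_rad) <= math.pi + 1e-12:
            raise ValueError(f"|theta_rad| must be <= pi, got {self.theta_rad!r}")
        if not (math.isnan(self.dispersion) or self.dispersion >= 0):
            raise ValueError("dispersion must be non-negative")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def _as_window(window) -> np.ndarray:
    arr = np.asarray(window, dtype=np.complex128)
    if arr.ndim != 1:
        raise ValueError("window must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("window must contain finite values")
    return arr


def kasai_phase(window: Sequence[complex]) -> float:
    """Phase of the summed lag-one autocorrelation of a window.

    ``theta = arg(sum_k s_{k+1} * conj(s_k))`` over all adjacent pairs of
    the window; an amplitude-weighted average of the pairwise phase
    differences, in (-pi, pi].
    """
    arr = _as_window(window)
    if arr.size < 2:
        raise ValueError("kasai_phase needs at least 2 points")
    acc = np.sum(arr[1:] * np.conj(arr[:-1]))
    if acc == 0:
        raise UndefinedPhaseError(
            "summed lag-one autocorrelation is zero; phase undefined")
    return float(np.angle(acc))


def conventional_doppler(mscan: MScan, depth: int, window_start: int,
                         n_averages: int) -> PhaseEstimate:
    """Conventional Doppler estimate from the first N adjacent pairs.

    Applies :func:`kasai_phase` to A-lines ``window_start .. window_start
    + n_averages`` at the given depth, i.e. the first ``n_averages``
    adjacent pairs of the processing window. The result is a
    single-interval phase: ``delta_phi_rad == theta_rad``.
    """
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    if window_start < 0 or window_start + n_averages + 1 > mscan.n_alines:
        raise IndexError(
            f"window [{window_start}, {window_start + n_averages + 1}) exceeds "
            f"scan length {mscan.n_alines}")
    segment = mscan.samples[window_start:window_start + n_averages + 1, depth]
    theta = kasai_phase(segment)
    return PhaseEstimate(theta_rad=theta, delta_phi_rad=theta,
                         dispersion=float("nan"), n_points=n_averages + 1)


def realign(window: Sequence[complex], theta: float) -> np.ndarray:
    """Derotate the k-th point by k*theta: ``s_k * exp(-i k theta)``.

    Aligns all points of a uniformly rotating window with the first
    A-line; moduli are unchanged.
    """
    arr = _as_window(window)
    k = np.arange(arr.size)
    return arr * np.exp(-1j * k * theta)


def complex_dispersion(points: Sequence[complex]) -> float:
    """Standard deviation of complex points about their complex mean.

    Population convention: ``sqrt(mean(|z_k - mean(z)|^2))``.
    """
    arr = _as_window(points)
    if arr.size < 2:
        raise ValueError("complex_dispersion needs at least 2 points")
    return float(np.sqrt(np.mean(np.abs(arr - arr.mean()) ** 2)))


@functools.lru_cache(maxsize=8)
def theta_grid(grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """The search grid over (-pi, pi]: multiples of the step, plus pi.

    Symmetric about zero (0 is always a grid point), half-open at -pi to
    avoid the duplicate of the +pi candidate.
    """
    if not (0 < grid_step < math.pi):
        raise ValueError(f"grid_step must lie in (0, pi), got {grid_step!r}")
    n = int(math.floor(math.pi / grid_step))
    grid = np.arange(-n, n + 1, dtype=float) * grid_step
    if grid[-1] < math.pi:
        grid = np.append(grid, math.pi)
    return grid


@functools.lru_cache(maxsize=8)
def _tiebreak_order(grid_step: float, n_grid: int) -> np.ndarray:
    """Grid indices sorted by (|theta|, theta): preferred candidates first."""
    grid = theta_grid(grid_step)
    assert grid.size == n_grid
    return np.lexsort((grid, np.abs(grid)))


@functools.lru_cache(maxsize=8)
def _steering_matrix(m: int, grid_step: float) -> np.ndarray:
    """exp(-i k theta) over the tie-break-ordered grid, shape (G, m)."""
    grid = theta_grid(grid_step)
    order = _tiebreak_order(grid_step, grid.size)
    k = np.arange(m)
    return np.exp(-1j * np.outer(grid[order], k))


def _coherent_search(windows: np.ndarray, grid_step: float):
    """Vectorized regression search on column windows.

    ``windows``: (m, W) complex. Returns (theta, dispersion) arrays of
    length W. Maximizes |mean(s_k exp(-i k theta))| over the grid, which
    by the modulus-preservation identity minimizes the dispersion of the
    realigned points. The grid is traversed in (|theta|, theta) order so
    ``argmax`` implements the tie-break.
    """
    m, n_win = windows.shape
    grid = theta_grid(grid_step)
    order = _tiebreak_order(grid_step, grid.size)
    steering = _steering_matrix(m, grid_step)
    coherent = steering @ windows / m          # (G, W) complex means
    power = np.abs(coherent) ** 2
    best = np.argmax(power, axis=0)
    theta = grid[order][best]
    mean_sq = np.mean(np.abs(windows) ** 2, axis=0)
    disp_sq = np.clip(mean_sq - power[best, np.arange(n_win)], 0.0, None)
    return theta, np.sqrt(disp_sq)


def complex_regression_phase(window: Sequence[complex],
                             grid_step: float = DEFAULT_GRID_STEP,
                             method: str = "fast") -> PhaseEstimate:
    """Complex-regression phase estimate of a window of m A-lines.

    Searches theta over the (-pi, pi] grid (:func:`theta_grid`) for the
    value minimizing :func:`complex_dispersion` of
    ``realign(window, theta)``. Ties are broken toward the smallest
    |theta|, then toward negative theta (preferring the slower velocity
    under ambiguity). ``delta_phi_rad = (m-1) * theta_rad``.

    ``method="fast"`` maximizes the coherent-sum magnitude (identical
    argmin, O(m) per candidate); ``method="bruteforce"`` evaluates the
    dispersion objective literally and is kept as an independent check.
    """
    arr = _as_window(window)
    if arr.size < 2:
        raise ValueError("complex regression needs at least 2 points")
    if not np.any(arr):
        raise UndefinedPhaseError("all-zero window; phase undefined")
    if method == "fast":
        theta, disp = _coherent_search(arr[:, None], grid_step)
        theta_best, disp_best = float(theta[0]), float(disp[0])
    elif method == "bruteforce":
        grid = theta_grid(grid_step)
        order = _tiebreak_order(grid_step, grid.size)
        best_idx, best_disp = 0, np.inf
        for idx in order:
            d = complex_dispersion(realign(arr, grid[idx]))
            if d < best_disp:
                best_idx, best_disp = idx, d
        theta_best, disp_best = float(grid[best_idx]), float(best_disp)
    else:
        raise ValueError(f"unknown method {method!r}")
    m = arr.size
    return PhaseEstimate(theta_rad=theta_best,
                         delta_phi_rad=(m - 1) * theta_best,
                         dispersion=disp_best, n_points=m)


@dataclass
class VelocityMap:
    """Per-window, per-depth axial velocity with window provenance."""

    axial_velocity: np.ndarray        # (n_windows, n_depth), m/s, signed
    window_start_index: np.ndarray    # (n_windows,)
    window_length: int
    estimator: EstimatorSpec
    theta_rad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.axial_velocity = np.asarray(self.axial_velocity, dtype=float)
        self.window_start_index = np.asarray(self.window_start_index, dtype=int)
        if self.axial_velocity.ndim != 2:
            raise ValueError("axial_velocity must be 2-D (window x depth)")
        if self.window_start_index.shape[0] != self.axial_velocity.shape[0]:
            raise ValueError("one start index per window required")
        if np.any(np.diff(self.window_start_index) <= 0):
            raise ValueError("window_start_index must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return self.axial_velocity.shape[0]

    def to_dataframe(self):
        """Long-format table: window_index, depth_index, axial_velocity_mps."""
        import pandas as pd

        n_win, n_depth = self.axial_velocity.shape
        win, depth = np.meshgrid(np.arange(n_win), np.arange(n_depth), indexing="ij")
        return pd.DataFrame({
            "window_index": win.ravel(),
            "depth_index": depth.ravel(),
            "axial_velocity_mps": self.axial_velocity.ravel(),
        })


def doppler_image(mscan: MScan, estimator: EstimatorSpec,
                  window_length: int = 64, stride: Optional[int] = None,
                  config: DopplerConfig = DopplerConfig(),
                  grid_step: float = DEFAULT_GRID_STEP) -> VelocityMap:
    """Apply an estimator window-by-window and depth-by-depth.

    A-lines are partitioned into windows of ``window_length`` starting
    every ``stride`` A-lines (non-overlapping by default); any trailing
    remainder is dropped. Per window and depth the estimator's
    per-interval phase is converted to axial velocity.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if window_length > mscan.n_alines:
        raise ValueError(
            f"window_length {window_length} exceeds scan length {mscan.n_alines}")
    stride = window_length if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = np.arange(0, mscan.n_alines - window_length + 1, stride)
    dropped = mscan.n_alines - (starts[-1] + window_length)
    if dropped:
        logger.info("doppler_image: dropping %d trailing A-lines", dropped)
    logger.info("doppler_image: %d windows of %d A-lines (stride %d), %s",
                len(starts), window_length, stride, estimator.label)

    theta = np.empty((len(starts), mscan.n_depth), dtype=float)
    if estimator.kind is EstimatorKind.COMPLEX_REGRESSION:
        m = window_length
        for z in range(mscan.n_depth):
            cols = np.stack([mscan.samples[s:s + m, z] for s in starts], axis=1)
            zero = ~np.any(cols, axis=0)
            if np.any(zero):
                logger.warning("doppler_image: %d all-zero windows at depth %d "
                               "flagged NaN", int(zero.sum()), z)
                cols = cols.copy()
                cols[0, zero] = 1.0  # placeholder; overwritten with NaN below
            th, _ = _coherent_search(cols, grid_step)
            th[zero] = np.nan
            theta[:, z] = th
    else:
        n_avg = estimator.n_points
        if n_avg + 1 > window_length:
            raise ValueError(
                f"conventional estimator with N={n_avg} needs windows of at "
                f"least {n_avg + 1} A-lines, got {window_length}")
        for w, s in enumerate(starts):
            seg = mscan.samples[s:s + n_avg + 1, :]
            acc = np.sum(seg[1:] * np.conj(seg[:-1]), axis=0)
            zero = acc == 0
            if np.any(zero):
                logger.warning("doppler_image: %d undefined-phase windows at "
                               "window %d flagged NaN", int(zero.sum()), w)
            with np.errstate(invalid="ignore"):
                theta[w] = np.where(zero, np.nan, np.angle(acc))
    velocity = np.where(np.isnan(theta), np.nan,
                        phase_to_velocity(np.nan_to_num(theta), config))
    return VelocityMap(axial_velocity=velocity, window_start_index=starts,
                       window_length=window_length, estimator=estimator,
                       theta_rad=theta)


def complex_average(samples: np.ndarray, group: int) -> np.ndarray:
    """Average consecutive groups of A-lines in the complex domain.

    Each output A-line is the complex mean of ``group`` consecutive input
    A-lines; a trailing remainder that does not fill a group is dropped
    (logged). Coherent signal is preserved while independent complex
    noise power is reduced by the group size; the structural magnitude
    image is ``abs`` of the result.
    """
    if group < 1:
        raise ValueError("group must be >= 1")
    arr = np.asarray(samples, dtype=np.complex128)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n_groups = arr.shape[0] // group
    if n_groups == 0:
        raise ValueError(
            f"group {group} exceeds the number of A-lines {arr.shape[0]}")
    dropped = arr.shape[0] - n_groups * group
    if dropped:
        logger.info("complex_average: dropping %d trailing A-lines", dropped)
    out = arr[:n_groups * group].reshape(n_groups, group, -1).mean(axis=1)
    return out[:, 0] if squeeze else out
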