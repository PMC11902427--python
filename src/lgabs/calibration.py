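"""Model development: averaged force curves and keypoint extraction.

Repeated captures at a few assistance percentages are reduced to one
averaged chest-force curve per percentage (force vs flexion angle for the
passive mode, force vs ascent speed for the active mode).  From each curve
the compact keypoint parameters are extracted: the per-side maximum torque
and torque ratios at the characteristic angles (passive), or the
three-piece hinge parameters (active).  Percentage scaling then completes
the full table family.

The active hinge is fitted deterministically: an exhaustive search over
cut-index pairs partitions the grid into zero / linear / plateau regions,
with the closed-form least-squares line and plateau level computed per
partition from prefix sums; samples adjacent to the recovered breakpoints
(which mix two regimes) are excluded and the fit repeated once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import medfilt

from .kinematics import CaptureSeries, activation_mask, annotate
from .model import (
    ActiveKeypointTable,
    ActiveRow,
    AssistanceConfig,
    BodyDimensions,
    ExoskeletonSpec,
    InputError,
    LgabsError,
    PassiveKeypointTable,
    scale_active_percentages,
    scale_passive_percentages,
)
from .statics import G

__all__ = [
    "CalibrationError",
    "AveragedCurve",
    "CalibrationReport",
    "normalize_and_average",
    "passive_trace",
    "active_trace",
    "extract_passive_anchor",
    "extract_active_anchor",
    "build_spec",
    "calibrate",
]

DEFAULT_GRID_SIZE = 200


class CalibrationError(LgabsError):
    """The averaged curve does not support keypoint extraction."""


@dataclass(frozen=True)
class AveragedCurve:
    """A normalized, averaged chest-force curve.

    ``abscissa`` is a strictly increasing grid (flexion degrees for the
    passive mode, ascent speed deg/s for the active mode); ``ordinate`` is
    the mean chest force in kgf across the source traces and
    ``dispersion`` its pointwise standard deviation.
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    n_source_curves: int
    dispersion: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "abscissa", np.asarray(self.abscissa, dtype=float))
        object.__setattr__(self, "ordinate", np.asarray(self.ordinate, dtype=float))
        object.__setattr__(self, "dispersion", np.asarray(self.dispersion, dtype=float))
        if np.any(np.diff(self.abscissa) <= 0):
            raise InputError("abscissa must be strictly increasing")
        if self.n_source_curves < 1:
            raise InputError("need at least one source curve")


def _resample(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, half_width: float, degree: int = 3
) -> np.ndarray:
    """Local polynomial least-squares (LOESS-style) resampling of a trace.

    Each grid value is the degree-``degree`` polynomial fitted to the trace
    points within ``half_width`` of the grid point, evaluated there; the
    window widens until it holds at least ``degree + 2`` points.  The
    estimator reproduces any trace that is locally polynomial of that
    degree exactly and averages measurement noise, and — unlike a global
    interpolant — keeps the influence of a kink in the underlying law
    confined to its own window.  The degree should match the curve
    family's section order: cubic for the flexion curves, linear for the
    piecewise-linear speed curves (where a higher degree can extrapolate
    wildly across sampling gaps).
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    min_pts = degree + 2
    if xs.size < min_pts:
        raise InputError(f"trace needs at least {min_pts} points")
    span = float(xs[-1] - xs[0])
    out = np.empty(grid.size)
    for k, g in enumerate(grid):
        w = half_width
        while True:
            lo = np.searchsorted(xs, g - w, side="left")
            hi = np.searchsorted(xs, g + w, side="right")
            if lo == 0 and hi == xs.size:
                break
            if hi - lo >= min_pts:
                # the fit is only well-posed with degree+1 separated abscissas
                distinct = 1 + int(np.sum(np.diff(xs[lo:hi]) > 1e-6 * span))
                if distinct >= degree + 1:
                    break
            w *= 1.6
        xc = xs[lo:hi] - g
        basis = np.vander(xc, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(basis, ys[lo:hi], rcond=None)
        out[k] = coef[0]
    return out


def normalize_and_average(
    curves: Sequence[tuple[np.ndarray, np.ndarray]],
    grid_size: int = DEFAULT_GRID_SIZE,
    clean_median_kernel: int = 1,
    clip_range: tuple[float, float] | None = None,
    loess_half_width: float | None = None,
    loess_degree: int = 3,
) -> AveragedCurve:
    """Resample traces onto a common grid and average them pointwise.

    The grid spans the intersection of the traces' abscissa ranges; each
    trace is resampled by local cubic least squares with window half-width
    ``loess_half_width`` (default: 1% of the common span).  Optional
    cleaning: an odd-width median filter on each trace's ordinate and
    clipping of the ordinate to ``clip_range``.
    """
    if len(curves) < 1:
        raise InputError("need at least one trace")
    lows, highs = [], []
    prepared = []
    for x, y in curves:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2:
            raise InputError("each trace needs at least 2 points")
        if clean_median_kernel > 1:
            k = clean_median_kernel + (clean_median_kernel + 1) % 2  # force odd
            y = medfilt(y, k)
        if clip_range is not None:
            y = np.clip(y, *clip_range)
        prepared.append((x, y))
        lows.append(float(x.min()))
        highs.append(float(x.max()))
    lo, hi = max(lows), min(highs)
    if not lo < hi:
        raise InputError(f"trace abscissa ranges are disjoint (intersection [{lo}, {hi}])")
    grid = np.linspace(lo, hi, grid_size)
    if loess_half_width is None:
        loess_half_width = (hi - lo) / 100.0
    stack = np.vstack(
        [_resample(x, y, grid, loess_half_width, loess_degree) for x, y in prepared]
    )
    return AveragedCurve(
        abscissa=grid,
        ordinate=stack.mean(axis=0),
        n_source_curves=len(curves),
        dispersion=stack.std(axis=0),
    )


# ---------------------------------------------------------------------------
# trace extraction from captures


def passive_trace(capture: CaptureSeries) -> tuple[np.ndarray, np.ndarray]:
    """(flexion angle, chest force) pairs of a passive characterization capture.

    A single curve serves ascent and descent (hysteresis treated as
    negligible), so all frames contribute.
    """
    if capture.measured_force is None:
        raise InputError("capture has no measured force channel")
    return capture.theta_c.copy(), capture.measured_force.copy()


def active_trace(
    capture: CaptureSeries, psi_a: float
) -> tuple[np.ndarray, np.ndarray]:
    """(ascent speed, chest force) pairs on the assisted ascending frames."""
    if capture.measured_force is None:
        raise InputError("capture has no measured force channel")
    ann = annotate(capture)
    mask = activation_mask(ann, psi_a)
    if not mask.any():
        raise CalibrationError("capture has no assisted ascending frames")
    return ann.ascent_speed[mask], capture.measured_force[mask]


# ---------------------------------------------------------------------------
# anchor extraction


def _force_to_torque(force_kgf: np.ndarray, d_tt: float) -> np.ndarray:
    """Total chest force (kgf) to per-side torque (N·m) via the chest lever arm."""
    return force_kgf * G / 2.0 * d_tt


def _section_fit_eval(
    x: np.ndarray, y: np.ndarray, lo: float, hi: float, at: Sequence[float]
) -> np.ndarray | None:
    """Cubic least squares over grid points in ``(lo, hi)``, evaluated at ``at``."""
    m = (x >= lo) & (x <= hi)
    if m.sum() < 6:
        return None
    c = 0.5 * (lo + hi)
    coef, *_ = np.linalg.lstsq(np.vander(x[m] - c, 4, increasing=True), y[m], rcond=None)
    return np.polynomial.polynomial.polyval(np.asarray(at, dtype=float) - c, coef)


def extract_passive_anchor(
    curve: AveragedCurve,
    characteristic_angles: Sequence[float],
    d_tt: float,
    exclude_radius: float | None = None,
) -> tuple[float, np.ndarray]:
    """Maximum torque and torque ratios at the characteristic angles.

    The chest force is converted to per-side torque through ``d_tt``.  The
    curve family is a spline *per section* between characteristic angles,
    so its derivative may jump exactly at those angles; each section is
    therefore fitted by a cubic on the grid points at least
    ``exclude_radius`` away from the bounding angles (default: 2.5% of the
    curve span) and the torque at each angle is the mean of its adjacent
    sections' fits evaluated there.  The maximum torque is the torque at
    the last characteristic angle; the ratios are each angle's torque over
    that maximum, clipped to [0, 1] and made non-decreasing, which absorbs
    noise-level violations.
    """
    ang = np.asarray(characteristic_angles, dtype=float)
    x = curve.abscissa
    lo, hi = x[0], x[-1]
    if ang.min() < lo - 1e-9 or ang.max() > hi + 1e-9:
        raise CalibrationError(
            f"characteristic angles {ang} outside curve range [{lo:.2f}, {hi:.2f}]"
        )
    tau_grid = _force_to_torque(curve.ordinate, d_tt)
    grid_h = float(np.median(np.diff(x)))
    delta = exclude_radius if exclude_radius is not None else max(0.025 * (hi - lo), 3 * grid_h)
    estimates: dict[int, list[float]] = {i: [] for i in range(ang.size)}
    for k in range(ang.size - 1):
        vals = _section_fit_eval(x, tau_grid, ang[k] + delta, ang[k + 1] - delta, ang[k : k + 2])
        if vals is None:  # short section: fall back to its full width
            vals = _section_fit_eval(x, tau_grid, ang[k], ang[k + 1], ang[k : k + 2])
        if vals is not None:
            estimates[k].append(float(vals[0]))
            estimates[k + 1].append(float(vals[1]))
    # beyond the last characteristic angle the curve is clamped constant,
    # which pins the maximum torque from the right as well; the region mean
    # is the constant's best (and extrapolation-free) estimate
    tail = (x >= ang[-1] + delta) & (x <= hi - delta)
    if tail.sum() >= 6:
        estimates[ang.size - 1].append(float(tau_grid[tail].mean()))
    if any(len(v) == 0 for v in estimates.values()):
        raise CalibrationError("curve does not cover every characteristic-angle section")
    tau = np.array([np.mean(estimates[i]) for i in range(ang.size)])
    tau_max = float(tau[-1])
    if tau_max <= 0:
        raise CalibrationError(f"non-positive maximum torque ({tau_max:.4g} N·m)")
    ratios = np.clip(tau / tau_max, 0.0, 1.0)
    ratios = np.maximum.accumulate(ratios)
    ratios[-1] = 1.0
    return tau_max, ratios


def _hinge_cut_fit(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Exhaustive cut-pair least squares for the 0 / affine / plateau hinge.

    For every pair of cut indices ``(i, j)`` the model is: 0 on ``[0, i)``,
    the unconstrained regression line on ``[i, j)``, and the mean level on
    ``[j, n)``.  The line's zero crossing gives ``vel_lim`` and its
    intersection with the plateau gives ``vel_max``; both have closed
    forms from prefix sums, so the search is exact and deterministic.
    Returns ``(sse, tau_a_max, vel_lim, vel_max)`` of the best admissible
    pair.
    """
    n = x.size
    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg(c: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return c[j] - c[i]

    best = (np.inf, np.nan, np.nan, np.nan)
    min_pts = 3  # per region: keeps every regression well-posed
    for i in range(min_pts, n - 2 * min_pts + 1):
        j = np.arange(i + min_pts, n - min_pts + 1)
        ii = np.full(j.shape, i)
        m = seg(c1, ii, j)
        sx, sy = seg(cx, ii, j), seg(cy, ii, j)
        sxx, sxy, syy = seg(cxx, ii, j), seg(cxy, ii, j), seg(cyy, ii, j)
        denom = m * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (m * sxy - sx * sy) / denom
            inter = (sy - slope * sx) / m
            sse_lin = (
                syy - 2 * slope * sxy - 2 * inter * sy
                + slope**2 * sxx + 2 * slope * inter * sx + inter**2 * m
            )
            mp = seg(c1, j, np.full(j.shape, n))
            sp = seg(cy, j, np.full(j.shape, n))
            spp = seg(cyy, j, np.full(j.shape, n))
            level = sp / mp
            sse_plat = spp - sp * sp / mp
        sse_zero = cyy[i]
        sse = sse_zero + sse_lin + sse_plat
        ok = (slope > 0) & (level > 0) & np.isfinite(sse)
        if not ok.any():
            continue
        sse = np.where(ok, sse, np.inf)
        k = int(np.argmin(sse))
        if sse[k] < best[0]:
            vel_lim = -inter[k] / slope[k]
            vel_max = (level[k] - inter[k]) / slope[k]
            best = (float(sse[k]), float(level[k]), float(vel_lim), float(vel_max))
    if not np.isfinite(best[0]):
        raise CalibrationError("hinge fit failed: no admissible zero/linear/plateau split")
    return best


def extract_active_anchor(
    curve: AveragedCurve, d_tt: float, exclude_radius: float | None = None
) -> tuple[float, float, float, float]:
    """Hinge parameters ``(tau_a_max, vel_lim, slope, intercept)`` from a curve.

    Grid points within ``exclude_radius`` (default: 5% of the speed span)
    of the first-pass breakpoints mix two regimes of the underlying law,
    so they are excluded and the cut fit repeated once.  Raises
    :class:`CalibrationError` when the curve shows no plateau (the fitted
    saturation speed falls at the end of the data).
    """
    x = curve.abscissa
    tau = _force_to_torque(curve.ordinate, d_tt)
    _, tau_a_max, vel_lim, vel_max = _hinge_cut_fit(x, tau)
    span = x[-1] - x[0]
    if vel_max > x[-1] - 0.02 * span:
        raise CalibrationError(
            f"no plateau detectable: fitted saturation speed {vel_max:.2f} deg/s "
            f"reaches the end of the data range ({x[-1]:.2f} deg/s)"
        )
    h = float(np.median(np.diff(x)))
    radius = exclude_radius if exclude_radius is not None else max(0.05 * span, 2 * h)
    keep = (np.abs(x - vel_lim) > radius) & (np.abs(x - vel_max) > radius)
    if keep.sum() >= 9:
        _, tau_a_max, vel_lim, vel_max = _hinge_cut_fit(x[keep], tau[keep])
    if tau_a_max <= 0 or vel_max <= vel_lim:
        raise CalibrationError(
            f"degenerate hinge fit (tau_a_max={tau_a_max:.4g}, "
            f"vel_lim={vel_lim:.4g}, vel_max={vel_max:.4g})"
        )
    slope = tau_a_max / (vel_max - vel_lim)
    return float(tau_a_max), float(vel_lim), float(slope), float(-slope * vel_lim)


# ---------------------------------------------------------------------------
# spec assembly


@dataclass(frozen=True)
class CalibrationReport:
    """Anchors and residual diagnostics produced alongside a calibrated spec."""

    passive_anchors: dict[int, float]
    passive_ratios: dict[int, tuple[float, ...]]
    active_anchors: dict[int, tuple[float, float, float]]
    residuals: dict[str, float] = field(default_factory=dict)


_DEFAULT_RATIOS = (0.0, 0.25, 0.5, 0.75, 1.0)


def build_spec(
    characteristic_angles: Sequence[float],
    passive_anchors: Mapping[int, tuple[float, Sequence[float]]] | None,
    active_anchors: Mapping[int, tuple[float, float, float]] | None,
    psi_a: float,
    body: BodyDimensions,
    device_weight: float = 0.0,
    shoulder_fraction: float = 0.5,
) -> ExoskeletonSpec:
    """Assemble a full device spec from calibrated anchors.

    ``passive_anchors`` maps percentage to ``(tau_max, ratios)``;
    ``active_anchors`` maps percentage to ``(tau_a_max, vel_lim,
    vel_max)``.  Missing percentages are filled by even scaling; a missing
    mode yields an all-zero table for that mode.  The returned spec is set
    to full assistance on the calibrated modes; callers re-select
    percentages per simulation.
    """
    angles = tuple(float(a) for a in characteristic_angles)
    if passive_anchors:
        tau_map = scale_passive_percentages({p: v[0] for p, v in passive_anchors.items()})
        ratio_stack = np.vstack([np.asarray(v[1], dtype=float) for v in passive_anchors.values()])
        ratios = tuple(ratio_stack.mean(axis=0))
        passive = PassiveKeypointTable(angles, ratios, tau_map)
    else:
        passive = PassiveKeypointTable(
            angles, _DEFAULT_RATIOS, {p: 0.0 for p in range(0, 101, 10)}
        )
    if active_anchors:
        active = scale_active_percentages(dict(active_anchors))
    else:
        active = ActiveKeypointTable({p: ActiveRow(0.0, 0.0, 0.0, 0.0) for p in range(0, 101, 10)})
    assistance = AssistanceConfig(
        eta_p=100 if passive_anchors else 0,
        eta_a=100 if active_anchors else 0,
        psi_a=psi_a,
    )
    return ExoskeletonSpec(
        passive_table=passive,
        active_table=active,
        assistance=assistance,
        body=body,
        device_weight=device_weight,
        shoulder_fraction=shoulder_fraction,
    )


def calibrate(
    passive_captures: Mapping[int, Sequence[CaptureSeries]] | None,
    active_captures: Mapping[int, Sequence[CaptureSeries]] | None,
    characteristic_angles: Sequence[float],
    psi_a: float,
    body: BodyDimensions,
    device_weight: float = 0.0,
    shoulder_fraction: float = 0.5,
    grid_size: int = DEFAULT_GRID_SIZE,
    clean_median_kernel: int = 1,
) -> tuple[ExoskeletonSpec, CalibrationReport]:
    """Full calibration: captures grouped by percentage in, device spec out."""
    p_anchors: dict[int, tuple[float, Sequence[float]]] = {}
    p_ratio_rep: dict[int, tuple[float, ...]] = {}
    for pct, caps in (passive_captures or {}).items():
        curve = normalize_and_average(
            [passive_trace(c) for c in caps], grid_size, clean_median_kernel
        )
        tau_max, ratios = extract_passive_anchor(curve, characteristic_angles, body.d_tt)
        p_anchors[int(pct)] = (tau_max, ratios)
        p_ratio_rep[int(pct)] = tuple(ratios)
    a_anchors: dict[int, tuple[float, float, float]] = {}
    for pct, caps in (active_captures or {}).items():
        curve = normalize_and_average(
            [active_trace(c, psi_a) for c in caps],
            grid_size,
            clean_median_kernel,
            loess_degree=1,
        )
        tau_a, vel_lim, slope, _ = extract_active_anchor(curve, body.d_tt)
        a_anchors[int(pct)] = (tau_a, vel_lim, vel_lim + tau_a / slope)
    spec = build_spec(
        characteristic_angles,
        p_anchors or None,
        a_anchors or None,
        psi_a,
        body,
        device_weight,
        shoulder_fraction,
    )
    report = CalibrationReport(
        passive_anchors={p: v[0] for p, v in p_anchors.items()},
        passive_ratios=p_ratio_rep,
        active_anchors=a_anchors,
    )
    return spec, report
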