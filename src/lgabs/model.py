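"""Parametric torque model of an active lumbar exoskeleton.

The device assists trunk extension through two superposed mechanisms,
each scaled by a user-selected percentage (0–100 in steps of ten):

* **Passive assistance** — a spring-like torque that grows with the lumbar
  flexion angle ``theta_c`` (degrees from the global vertical).  The curve
  family is pinned at five *characteristic angles* by torque ratios, and a
  per-percentage maximum torque stretches the family vertically.  Sections
  between the keypoints are interpolated with shape-preserving cubic
  splines so that monotone keypoints yield a monotone curve.

* **Active assistance** — a motor torque that depends on the trunk's
  *ascent* (extension) speed.  For each percentage the law is a three-piece
  hinge: zero below a threshold speed ``vel_lim``, affine through
  ``(vel_lim, 0)`` up to ``(vel_max, tau_a_max)``, and constant
  ``tau_a_max`` above.  It engages only when the trunk rises from a flexion
  deeper than the activation angle ``psi_a``.

All torques are per-side (the device is bilaterally symmetric); total
device torque is twice the per-side value.  Torques are in N·m, angles in
degrees, speeds in deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "VALID_PERCENTAGES",
    "LgabsError",
    "ValidationError",
    "InputError",
    "AssistanceConfig",
    "PassiveKeypointTable",
    "ActiveRow",
    "ActiveKeypointTable",
    "BodyDimensions",
    "ExoskeletonSpec",
    "passive_torque",
    "active_torque",
    "total_torque",
    "scale_passive_percentages",
    "scale_active_percentages",
]

#: Assistance levels the device UI can select.
VALID_PERCENTAGES: tuple[int, ...] = tuple(range(0, 101, 10))


class LgabsError(Exception):
    """Base class for package errors."""


class ValidationError(LgabsError):
    """A domain object violates its invariants."""


class InputError(LgabsError):
    """A caller-supplied argument is outside the operation's domain."""


def _check_percentage(eta: int, name: str) -> int:
    if eta not in VALID_PERCENTAGES:
        raise InputError(
            f"{name} must be a multiple of ten in 0–100, got {eta!r}"
        )
    return int(eta)


@dataclass(frozen=True)
class AssistanceConfig:
    """User-selected assistance levels and the active activation angle.

    Parameters
    ----------
    eta_p, eta_a:
        Passive and active assistance percentages, each in
        {0, 10, ..., 100}.
    psi_a:
        Activation angle in degrees: active assistance engages only when
        ascending from a flexion deeper than this angle.
    """

    eta_p: int
    eta_a: int
    psi_a: float

    def __post_init__(self) -> None:
        _check_percentage(self.eta_p, "eta_p")
        _check_percentage(self.eta_a, "eta_a")
        if not np.isfinite(self.psi_a) or self.psi_a < 0:
            raise ValidationError(f"psi_a must be finite and >= 0, got {self.psi_a}")


@dataclass(frozen=True)
class PassiveKeypointTable:
    """Keypoints defining the passive torque-vs-flexion curve family.

    ``characteristic_angles`` (deg, strictly increasing) and
    ``torque_ratios`` (fractions of the maximum torque, non-decreasing,
    last = 1) pin the curve shape; ``tau_max`` maps each percentage to its
    per-side maximum torque in N·m.
    """

    characteristic_angles: tuple[float, ...]
    torque_ratios: tuple[float, ...]
    tau_max: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "characteristic_angles", tuple(float(a) for a in self.characteristic_angles)
        )
        object.__setattr__(self, "torque_ratios", tuple(float(r) for r in self.torque_ratios))
        object.__setattr__(
            self, "tau_max", {int(k): float(v) for k, v in dict(self.tau_max).items()}
        )
        ang = np.asarray(self.characteristic_angles)
        rat = np.asarray(self.torque_ratios)
        if ang.size != 5 or rat.size != 5:
            raise ValidationError("expected exactly 5 characteristic angles and 5 ratios")
        if not np.all(np.diff(ang) > 0):
            raise ValidationError("characteristic angles must be strictly increasing")
        if rat.min() < 0 or rat.max() > 1:
            raise ValidationError("torque ratios must lie in [0, 1]")
        if not np.isclose(rat[-1], 1.0, rtol=0, atol=1e-12):
            raise ValidationError("last torque ratio must equal 1")
        if np.any(np.diff(rat) < 0):
            raise ValidationError("torque ratios must be non-decreasing")
        for eta, tau in self.tau_max.items():
            _check_percentage(eta, "tau_max key")
            if tau < 0:
                raise ValidationError(f"tau_max[{eta}] must be >= 0, got {tau}")
        if 0 in self.tau_max and self.tau_max[0] != 0.0:
            raise ValidationError("tau_max at 0% must be 0")
        etas = sorted(self.tau_max)
        taus = [self.tau_max[e] for e in etas]
        if np.any(np.diff(taus) < 0):
            raise ValidationError("tau_max must be non-decreasing in the percentage")

    def max_torque(self, eta_p: int) -> float:
        """Per-side maximum torque (N·m) at percentage ``eta_p``."""
        _check_percentage(eta_p, "eta_p")
        if eta_p == 0:
            return 0.0
        try:
            return self.tau_max[eta_p]
        except KeyError:
            raise InputError(
                f"no max torque stored for eta_p={eta_p}; available: {sorted(self.tau_max)}"
            ) from None


@dataclass(frozen=True)
class ActiveRow:
    """One percentage's active law: hinge through (vel_lim, 0)–(vel_max, tau_a_max).

    ``slope`` (N·m per deg/s) and ``intercept`` (N·m) describe the affine
    middle section; the intercept always equals ``-slope * vel_lim``.
    """

    tau_a_max: float
    vel_lim: float
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.tau_a_max < 0:
            raise ValidationError(f"tau_a_max must be >= 0, got {self.tau_a_max}")
        if self.tau_a_max > 0:
            if self.slope <= 0:
                raise ValidationError(f"slope must be > 0, got {self.slope}")
            if not np.isclose(self.intercept, -self.slope * self.vel_lim, rtol=1e-9, atol=1e-9):
                raise ValidationError(
                    "intercept must equal -slope*vel_lim "
                    f"(got {self.intercept}, expected {-self.slope * self.vel_lim})"
                )
            if self.vel_max <= self.vel_lim:
                raise ValidationError("derived vel_max must exceed vel_lim")
        if self.vel_lim < 0:
            raise ValidationError(f"vel_lim must be >= 0, got {self.vel_lim}")

    @property
    def vel_max(self) -> float:
        """Ascent speed (deg/s) at which the torque saturates at tau_a_max."""
        if self.tau_a_max == 0:
            return self.vel_lim
        return (self.tau_a_max - self.intercept) / self.slope

    @classmethod
    def from_breakpoints(cls, tau_a_max: float, vel_lim: float, vel_max: float) -> "ActiveRow":
        """Build a row from its two breakpoints; slope/intercept are derived."""
        if tau_a_max == 0:
            return cls(0.0, float(vel_lim), 0.0, 0.0)
        if vel_max <= vel_lim:
            raise ValidationError(f"vel_max ({vel_max}) must exceed vel_lim ({vel_lim})")
        slope = tau_a_max / (vel_max - vel_lim)
        return cls(float(tau_a_max), float(vel_lim), slope, -slope * vel_lim)


@dataclass(frozen=True)
class ActiveKeypointTable:
    """Per-percentage rows of the active piecewise-linear torque family."""

    rows: Mapping[int, ActiveRow]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", {int(k): v for k, v in dict(self.rows).items()})
        for eta in self.rows:
            _check_percentage(eta, "active row key")
        if 0 in self.rows and self.rows[0].tau_a_max != 0.0:
            raise ValidationError("tau_a_max at 0% must be 0")
        etas = sorted(self.rows)
        taus = [self.rows[e].tau_a_max for e in etas]
        if np.any(np.diff(taus) < 0):
            raise ValidationError("tau_a_max must be non-decreasing in the percentage")

    def row(self, eta_a: int) -> ActiveRow:
        _check_percentage(eta_a, "eta_a")
        if eta_a == 0:
            return ActiveRow(0.0, 0.0, 0.0, 0.0)
        try:
            return self.rows[eta_a]
        except KeyError:
            raise InputError(
                f"no active row stored for eta_a={eta_a}; available: {sorted(self.rows)}"
            ) from None


@dataclass(frozen=True)
class BodyDimensions:
    """Lever arms from the trochanter to the chest pad (d_tt) and leg pad (d_mt), metres."""

    d_tt: float
    d_mt: float

    def __post_init__(self) -> None:
        if not (self.d_tt > 0 and self.d_mt > 0):
            raise ValidationError(
                f"lever arms must be > 0 (got d_tt={self.d_tt}, d_mt={self.d_mt})"
            )


@dataclass(frozen=True)
class ExoskeletonSpec:
    """A complete device description: torque tables, assistance setting, body fit.

    ``device_weight`` is the device mass in kgf; ``shoulder_fraction`` is the
    share of that weight borne at the shoulders (the rest rests on the pelvis).
    """

    passive_table: PassiveKeypointTable
    active_table: ActiveKeypointTable
    assistance: AssistanceConfig
    body: BodyDimensions
    device_weight: float = 0.0
    shoulder_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.device_weight < 0:
            raise ValidationError(f"device_weight must be >= 0, got {self.device_weight}")
        if not 0 <= self.shoulder_fraction <= 1:
            raise ValidationError(
                f"shoulder_fraction must be in [0, 1], got {self.shoulder_fraction}"
            )


# ---------------------------------------------------------------------------
# torque laws


def _passive_spline(table: PassiveKeypointTable, tau_max: float) -> PchipInterpolator:
    ang = np.asarray(table.characteristic_angles)
    tau = np.asarray(table.torque_ratios) * tau_max
    # PCHIP is shape-preserving on each interval between knots, which is the
    # section-wise monotone interpolation the curve family requires.
    return PchipInterpolator(ang, tau, extrapolate=False)


def passive_torque(
    theta_c: float | np.ndarray,
    table: PassiveKeypointTable,
    eta_p: int,
) -> float | np.ndarray:
    """Per-side passive torque (N·m) at lumbar flexion ``theta_c`` (deg).

    The curve interpolates the five keypoints
    ``(angle_i, ratio_i * tau_max(eta_p))`` with a shape-preserving cubic
    per section.  Below the first characteristic angle the torque is 0;
    beyond the last it is clamped at the last keypoint's value.
    """
    tau_max = table.max_torque(eta_p)
    theta = np.asarray(theta_c, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise InputError("theta_c must be finite")
    if tau_max == 0.0:
        out = np.zeros_like(theta)
        return float(out) if np.isscalar(theta_c) else out

    ang = table.characteristic_angles
    spline = _passive_spline(table, tau_max)
    out = spline(theta)
    first_ratio_zero = table.torque_ratios[0] == 0.0
    below = theta < ang[0]
    # Anchored-at-zero curves vanish below the first knot; otherwise the
    # device still exerts the first keypoint's torque near upright posture
    # only if the table says so — default clamps to 0 when ratio_0 == 0,
    # else holds the first keypoint's value.
    out = np.where(below, 0.0 if first_ratio_zero else table.torque_ratios[0] * tau_max, out)
    out = np.where(theta > ang[-1], tau_max * table.torque_ratios[-1], out)
    return float(out) if np.isscalar(theta_c) else out


def active_torque(
    ascent_speed: float | np.ndarray,
    table: ActiveKeypointTable,
    eta_a: int,
) -> float | np.ndarray:
    """Per-side active torque (N·m) at trunk ``ascent_speed`` (deg/s, >= 0).

    Zero below the threshold speed, affine through ``(vel_lim, 0)`` and
    ``(vel_max, tau_a_max)`` between, and saturated at ``tau_a_max`` above.
    ``ascent_speed`` is a magnitude: callers rectify sign upstream (0 while
    descending or holding).
    """
    row = table.row(eta_a)
    speed = np.asarray(ascent_speed, dtype=float)
    if np.any(speed < 0):
        raise InputError("ascent_speed must be non-negative (rectify sign upstream)")
    if row.tau_a_max == 0.0:
        out = np.zeros_like(speed)
        return float(out) if np.isscalar(ascent_speed) else out
    out = np.clip(row.slope * speed + row.intercept, 0.0, row.tau_a_max)
    return float(out) if np.isscalar(ascent_speed) else out


def total_torque(
    theta_c: float | np.ndarray,
    ascent_speed: float | np.ndarray,
    active_enabled: bool | np.ndarray,
    spec: ExoskeletonSpec,
) -> float | np.ndarray:
    """Per-side combined torque: passive plus (gated) active contribution."""
    tau_p = passive_torque(theta_c, spec.passive_table, spec.assistance.eta_p)
    tau_a = active_torque(ascent_speed, spec.active_table, spec.assistance.eta_a)
    gate = np.asarray(active_enabled, dtype=bool)
    out = np.asarray(tau_p) + np.where(gate, np.asarray(tau_a), 0.0)
    scalar = np.isscalar(theta_c) and np.isscalar(ascent_speed) and np.ndim(active_enabled) == 0
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# percentage scaling


def _even_fill(anchors: Mapping[int, float]) -> dict[int, float]:
    """Fill all multiples of ten by even spacing between anchors (0 -> 0)."""
    pts = dict(anchors)
    pts.setdefault(0, 0.0)
    etas = sorted(pts)
    vals = [pts[e] for e in etas]
    out: dict[int, float] = {}
    for eta in VALID_PERCENTAGES:
        if eta in pts:
            out[eta] = pts[eta]  # anchors reproduced bit-exactly
        elif eta > etas[-1]:
            # no basis for extrapolating beyond the strongest calibrated
            # level: hold its value
            out[eta] = pts[etas[-1]]
        else:
            out[eta] = float(np.interp(eta, etas, vals))
    return out


def scale_passive_percentages(anchors: Mapping[int, float]) -> dict[int, float]:
    """Complete the passive ``tau_max`` mapping for all multiples of ten.

    The gaps between calibrated anchors are distributed evenly across the
    intermediate percentages; below the lowest anchor the torque falls
    evenly to 0 at 0%.  Anchors themselves are reproduced exactly.
    """
    anchors = {int(k): float(v) for k, v in dict(anchors).items()}
    if not anchors:
        raise ValidationError("need at least one passive anchor")
    for eta in anchors:
        _check_percentage(eta, "anchor percentage")
    etas = sorted(anchors)
    taus = [anchors[e] for e in etas]
    if np.any(np.diff(taus) < 0):
        raise ValidationError("anchor max torques must be non-decreasing in the percentage")
    if 0 in anchors and anchors[0] != 0.0:
        raise ValidationError("anchor at 0% must be 0")
    return _even_fill(anchors)


def scale_active_percentages(
    anchor_rows: Mapping[int, Sequence[float]],
) -> ActiveKeypointTable:
    """Build the full active table from ``{eta_a: (tau_a_max, vel_lim, vel_max)}`` anchors.

    ``tau_a_max``, ``vel_lim`` and ``vel_max`` are each spread evenly across
    the intermediate percentages; every generated row's slope and intercept
    are then re-derived from its own ``(vel_lim, 0)``–``(vel_max, tau_a_max)``
    line so the hinge invariants hold by construction.
    """
    rows = {int(k): tuple(float(x) for x in v) for k, v in dict(anchor_rows).items()}
    if not rows:
        raise ValidationError("need at least one active anchor row")
    for eta, vals in rows.items():
        _check_percentage(eta, "anchor percentage")
        if len(vals) != 3:
            raise ValidationError(
                f"anchor row for {eta} must be (tau_a_max, vel_lim, vel_max), got {vals}"
            )
        if vals[0] > 0 and vals[2] <= vals[1]:
            raise ValidationError(f"anchor row for {eta}: vel_max must exceed vel_lim")
    etas = sorted(rows)
    taus = [rows[e][0] for e in etas]
    if np.any(np.diff(taus) < 0):
        raise ValidationError("anchor tau_a_max must be non-decreasing in the percentage")

    tau_map = _even_fill({e: rows[e][0] for e in etas})
    # Velocity thresholds interpolate between anchors but have no physical
    # zero at 0% — hold the nearest anchor's value outside the span.
    lim_known = {e: rows[e][1] for e in etas}
    max_known = {e: rows[e][2] for e in etas}
    full_rows: dict[int, ActiveRow] = {}
    for eta in VALID_PERCENTAGES:
        if eta in rows:
            tau_a, v_lim, v_max = rows[eta]
        else:
            tau_a = tau_map[eta]
            v_lim = float(np.interp(eta, etas, [lim_known[e] for e in etas]))
            v_max = float(np.interp(eta, etas, [max_known[e] for e in etas]))
        if tau_a == 0.0:
            full_rows[eta] = ActiveRow(0.0, v_lim, 0.0, 0.0)
        else:
            if v_max <= v_lim:
                raise ValidationError(
                    f"degenerate row at {eta}%: vel_lim={v_lim} >= vel_max={v_max}"
                )
            full_rows[eta] = ActiveRow.from_breakpoints(tau_a, v_lim, v_max)
    return ActiveKeypointTable(full_rows)
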