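"""Exoskeleton-aware ergonomic risk scoring for the lumbar joint.

A motion-capture risk method of the kind used in industrial ergonomics
scores every posture on angle, angular acceleration, force, torque and
grip, sums the per-posture risks into a *risk per minute* percentage, and
colors it green / yellow / red.  The internal score functions of such
methods are calibrated empirically and not public; this module ships
configurable monotone piecewise-linear score maps with the documented
contract every property here relies on (non-negative, non-decreasing in
their physical input), and implements the device-specific delta: the
gravitational lumbar demand is reduced by the assistance torque before the
force and torque scores are recomputed, while all other scores stay
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .kinematics import CaptureSeries
from .model import InputError, LgabsError, ValidationError
from .statics import G

__all__ = [
    "ScoreMap",
    "RiskConfig",
    "PostureScores",
    "RiskResult",
    "lumbar_demand",
    "recompute_with_exo",
    "score_posture",
    "risk_per_minute",
    "color_band",
    "assess",
]


class ConfigError(LgabsError):
    """A risk configuration violates its contract."""


@dataclass(frozen=True)
class ScoreMap:
    """A monotone piecewise-linear map from a physical quantity to a score.

    ``knots_x`` strictly increasing, ``knots_y`` non-negative and
    non-decreasing; evaluation clamps outside the knot span.
    """

    knots_x: tuple[float, ...]
    knots_y: tuple[float, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.knots_x, dtype=float)
        y = np.asarray(self.knots_y, dtype=float)
        if x.size != y.size or x.size < 2:
            raise ConfigError("score map needs matching knot arrays with >= 2 knots")
        if np.any(np.diff(x) <= 0):
            raise ConfigError("score map knots_x must be strictly increasing")
        if np.any(y < 0) or np.any(np.diff(y) < 0):
            raise ConfigError("score map knots_y must be non-negative and non-decreasing")

    def __call__(self, value: np.ndarray | float) -> np.ndarray | float:
        return np.interp(value, self.knots_x, self.knots_y)


@dataclass(frozen=True)
class RiskConfig:
    """Score maps, weights and scaling of the lumbar risk computation.

    ``repetitions_per_minute`` scales the summed per-posture risk to the
    task's pace over the workday; ``score_weights`` weight the five scores
    in the per-posture combination.
    """

    angle_map: ScoreMap = ScoreMap((0.0, 20.0, 45.0, 90.0), (0.0, 1.0, 3.0, 6.0))
    acceleration_map: ScoreMap = ScoreMap((0.0, 50.0, 200.0, 600.0), (0.0, 0.5, 2.0, 4.0))
    force_map: ScoreMap = ScoreMap((0.0, 50.0, 150.0, 400.0), (0.0, 1.0, 3.5, 8.0))
    torque_map: ScoreMap = ScoreMap((0.0, 25.0, 75.0, 200.0), (0.0, 1.0, 3.5, 8.0))
    grip_map: ScoreMap = ScoreMap((0.0, 10.0, 30.0), (0.0, 0.5, 2.0))
    score_weights: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    repetitions_per_minute: float = 1.0
    risk_scale: float = 1.0
    trunk_mass: float = 35.0  # kg, torso + head + arms share carried by the lumbar joint
    trunk_com_distance: float = 0.25  # m, lumbar joint to trunk centre of mass
    hand_load: float = 0.0  # kg
    hand_lever: float = 0.45  # m

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.score_weights):
            raise ConfigError("score weights must be non-negative")
        if self.repetitions_per_minute < 0 or self.risk_scale < 0:
            raise ConfigError("rates and scales must be non-negative")


@dataclass(frozen=True)
class PostureScores:
    """Per-frame dimensionless scores of the five risk factors."""

    angle_score: np.ndarray
    angular_acceleration_score: np.ndarray
    force_score: np.ndarray
    torque_score: np.ndarray
    grip_score: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "angle_score",
            "angular_acceleration_score",
            "force_score",
            "torque_score",
            "grip_score",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class RiskResult:
    """Risk-per-minute percentage, its color band, and per-posture breakdown."""

    risk_per_minute: float
    per_posture_risks: np.ndarray
    color_band: str


def lumbar_demand(
    capture: CaptureSeries,
    trunk_mass: float,
    trunk_com_distance: float,
    hand_load: float = 0.0,
    hand_lever: float = 0.0,
) -> np.ndarray:
    """Static gravitational moment (N·m) about the lumbar joint per frame.

    The trunk's weight acts at its centre of mass and any hand-held load at
    the hand lever; both moment arms scale with ``sin(theta_c)``, so the
    demand is zero upright and maximal at horizontal trunk.
    """
    if trunk_mass <= 0 or trunk_com_distance <= 0:
        raise InputError("anthropometrics must be positive")
    lever = trunk_mass * G * trunk_com_distance + hand_load * G * hand_lever
    return lever * np.sin(np.radians(capture.theta_c))


def recompute_with_exo(demand: np.ndarray, exo_torque_total: np.ndarray) -> np.ndarray:
    """Residual lumbar demand after subtracting the device's total torque.

    Clamped at zero: over-assistance is modeled as a fully unloaded joint,
    never a reversed one.  Only the force and torque scores downstream see
    this change.
    """
    demand = np.asarray(demand, dtype=float)
    tau = np.asarray(exo_torque_total, dtype=float)
    if demand.shape != tau.shape:
        raise InputError(
            f"demand and torque series lengths differ ({demand.shape} vs {tau.shape})"
        )
    return np.maximum(0.0, demand - tau)


def score_posture(
    capture: CaptureSeries,
    demand: np.ndarray,
    config: RiskConfig,
    grip_force: np.ndarray | float = 0.0,
) -> PostureScores:
    """Score every frame on the five factors.

    Angle and acceleration scores come from the capture kinematics, force
    and torque scores from the (possibly assistance-reduced) lumbar
    demand, grip from the hand force; each through its monotone map.
    """
    theta = capture.theta_c
    accel = np.gradient(np.gradient(theta, capture.time), capture.time)
    force_n = np.asarray(demand, dtype=float) / max(config.trunk_com_distance, 1e-9)
    return PostureScores(
        angle_score=np.asarray(config.angle_map(np.abs(theta)), dtype=float),
        angular_acceleration_score=np.asarray(
            config.acceleration_map(np.abs(accel)), dtype=float
        ),
        force_score=np.asarray(config.force_map(force_n), dtype=float),
        torque_score=np.asarray(config.torque_map(np.asarray(demand, dtype=float)), dtype=float),
        grip_score=np.asarray(config.grip_map(grip_force) * np.ones_like(theta), dtype=float),
    )


def color_band(risk: float) -> str:
    """Color band of a risk-per-minute percentage.

    Green below 25, yellow from 25 up to but excluding 40, red at 40 and
    above.
    """
    if risk < 0:
        raise InputError(f"risk must be >= 0, got {risk}")
    if risk < 25.0:
        return "green"
    if risk < 40.0:
        return "yellow"
    return "red"


def risk_per_minute(
    scores: PostureScores,
    config: RiskConfig,
    duration: float,
) -> RiskResult:
    """Combine per-posture scores into the risk-per-minute percentage.

    Each posture's risk is the weighted sum of its five scores; the
    per-capture total is the posture sum normalized by the number of
    postures, scaled by the repetition rate and ``risk_scale``, yielding a
    percentage that grows linearly with task pace.
    """
    if duration <= 0:
        raise InputError(f"duration must be > 0, got {duration}")
    w = config.score_weights
    per_posture = (
        w[0] * scores.angle_score
        + w[1] * scores.angular_acceleration_score
        + w[2] * scores.force_score
        + w[3] * scores.torque_score
        + w[4] * scores.grip_score
    )
    n = per_posture.size
    total = float(per_posture.sum() / max(n, 1) * config.repetitions_per_minute * config.risk_scale)
    return RiskResult(
        risk_per_minute=total,
        per_posture_risks=per_posture,
        color_band=color_band(total),
    )


def assess(
    capture: CaptureSeries,
    exo_torque_total: np.ndarray | None,
    config: RiskConfig,
) -> RiskResult:
    """Lumbar risk of a capture, with or without device assistance.

    With ``exo_torque_total`` given (total device torque series, N·m) the
    force and torque scores are recomputed from the assistance-reduced
    demand; angle, acceleration and grip scores are identical to the
    unassisted evaluation by construction.
    """
    demand = lumbar_demand(
        capture,
        config.trunk_mass,
        config.trunk_com_distance,
        config.hand_load,
        config.hand_lever,
    )
    if exo_torque_total is not None:
        demand = recompute_with_exo(demand, exo_torque_total)
    scores = score_posture(capture, demand, config)
    duration = float(capture.time[-1] - capture.time[0])
    return risk_per_minute(scores, config, duration)
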