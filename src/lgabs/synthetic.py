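"""Seeded generators for flexion captures and load-cell readings.

These emulate the structure of a characterization session for a lumbar
assistance device: slow single flexion–extension cycles for the passive
mode, repeated brisk ascents for the active mode, and free mixed movement
(with optional half-ascents) for hybrid validation — all driven by a known
ground-truth device spec so that every downstream stage can be tested
against the truth without any recorded data.

Load-cell emulation reproduces the two measurement artifacts such rigs
show: taring at the deepest flexion posture (which offsets subsequent
readings) and contamination of the descent phase by the force the wearer
exerts to lower the trunk, which the cells pick up but the device does not
produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .kinematics import CaptureSeries
from .model import AssistanceConfig, ExoskeletonSpec, ValidationError
from .simulate import simulate_capture

__all__ = [
    "MotionProfile",
    "CellSimConfig",
    "SyntheticCapture",
    "generate_motion",
    "generate_loadcell",
    "generate_capture_set",
]

#: Reference descent speed (deg/s) at which the contamination amplitude is
#: read; contamination scales linearly with descent speed.
CONTAMINATION_REF_SPEED = 30.0


@dataclass(frozen=True)
class MotionProfile:
    """Shape of a synthetic flexion–extension capture.

    ``peak_flexion`` deg, ``period`` seconds per cycle, ``hold_fraction``
    the share of each cycle spent holding peak flexion,
    ``mid_ascent_pause`` the share of a cycle inserted as a pause halfway
    up the ascent (0 disables), ``noise_sd_angle`` the white angle noise in
    degrees.
    """

    n_cycles: int = 1
    peak_flexion: float = 80.0
    period: float = 4.0
    hold_fraction: float = 0.1
    sample_rate: float = 60.0
    noise_sd_angle: float = 0.0
    mid_ascent_pause: float = 0.0
    lead_in: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_flexion <= 0:
            raise ValidationError(f"peak_flexion must be > 0, got {self.peak_flexion}")
        if self.period <= 0:
            raise ValidationError(f"period must be > 0, got {self.period}")
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not 0 <= self.hold_fraction < 1:
            raise ValidationError(f"hold_fraction must be in [0, 1), got {self.hold_fraction}")


@dataclass(frozen=True)
class CellSimConfig:
    """Load-cell channel emulation parameters (forces in kgf).

    ``descent_contamination_amp`` is the extra force registered while
    lowering the trunk at the reference descent speed
    (:data:`CONTAMINATION_REF_SPEED`); ``cell_capacity`` is per cell, two
    cells are summed, and readings are clipped at twice the summed span.
    """

    noise_sd_force: float = 0.25
    tare_at_peak: bool = False
    descent_contamination_amp: float = 0.0
    cell_capacity: float = 50.0

    def __post_init__(self) -> None:
        if self.cell_capacity <= 0:
            raise ValidationError(f"cell_capacity must be > 0, got {self.cell_capacity}")
        if self.noise_sd_force < 0:
            raise ValidationError(f"noise_sd_force must be >= 0, got {self.noise_sd_force}")


@dataclass(frozen=True)
class SyntheticCapture:
    """One generated capture plus the ground-truth configuration behind it."""

    name: str
    capture: CaptureSeries
    assistance: AssistanceConfig
    mode: str


def _cycle_theta(
    profile: MotionProfile, rng: np.random.Generator | None, randomize: bool
) -> np.ndarray:
    """Angle samples of one flexion–extension cycle (without noise)."""
    fs = profile.sample_rate
    peak = profile.peak_flexion
    period = profile.period
    if randomize and rng is not None:
        peak = peak * rng.uniform(0.6, 1.0)
        period = period * rng.uniform(0.8, 1.3)
    t_hold = profile.hold_fraction * period
    t_move = (period - t_hold) / 2.0
    n_move = max(2, int(round(t_move * fs)))
    n_hold = int(round(t_hold * fs))
    s = np.linspace(0.0, 1.0, n_move, endpoint=False)
    down = peak * (1.0 - np.cos(np.pi * s)) / 2.0
    hold = np.full(n_hold, peak)
    pause = profile.mid_ascent_pause
    if randomize and rng is not None and pause > 0:
        pause = pause if rng.random() < 0.5 else 0.0
    if pause > 0:
        # stop halfway up, dwell, then finish the ascent
        s1 = np.linspace(0.0, 0.5, n_move // 2, endpoint=False)
        up1 = peak * (1.0 + np.cos(np.pi * s1)) / 2.0
        n_pause = max(1, int(round(pause * period * fs)))
        dwell = np.full(n_pause, peak / 2.0)
        s2 = np.linspace(0.5, 1.0, n_move - n_move // 2, endpoint=False)
        up2 = peak * (1.0 + np.cos(np.pi * s2)) / 2.0
        up = np.concatenate([up1, dwell, up2])
    else:
        s_up = np.linspace(0.0, 1.0, n_move, endpoint=False)
        up = peak * (1.0 + np.cos(np.pi * s_up)) / 2.0
    return np.concatenate([down, hold, up])


def generate_motion(profile: MotionProfile) -> CaptureSeries:
    """Raised-cosine flexion–extension cycles with optional pauses and noise.

    Deterministic under a fixed ``profile.seed``.  A short upright lead-in
    and lead-out bracket the cycles so phase segmentation sees complete
    cycles.
    """
    rng = np.random.default_rng(profile.seed)
    fs = profile.sample_rate
    n_pad = max(2, int(round(profile.lead_in * fs)))
    parts = [np.zeros(n_pad)]
    randomize = profile.n_cycles > 1 and profile.mid_ascent_pause > 0
    for _ in range(profile.n_cycles):
        parts.append(_cycle_theta(profile, rng, randomize))
    parts.append(np.zeros(n_pad))
    theta = np.concatenate(parts)
    if profile.noise_sd_angle > 0:
        theta = theta + rng.normal(0.0, profile.noise_sd_angle, theta.size)
    time = np.arange(theta.size) / fs
    return CaptureSeries(time=time, theta_c=theta, sample_rate=fs)


def generate_loadcell(
    capture: CaptureSeries,
    truth: ExoskeletonSpec,
    cfg: CellSimConfig,
    seed: int = 0,
) -> np.ndarray:
    """Emulated load-cell sum (kgf) for a capture under a ground-truth spec.

    The true chest force comes from the forward model; Gaussian noise,
    speed-proportional descent contamination, and (optionally) a taring
    offset fixed at the deepest-flexion frame are layered on top.  Readings
    are clipped at twice the summed cell span, with a warning.
    """
    rng = np.random.default_rng(seed)
    sim = simulate_capture(capture, truth)
    force = sim.chest_force_kgf.copy()
    if cfg.descent_contamination_amp > 0:
        descending = sim.annotation.phase == "descend"
        descent_speed = np.maximum(0.0, sim.annotation.velocity)
        force = force + np.where(
            descending,
            cfg.descent_contamination_amp * descent_speed / CONTAMINATION_REF_SPEED,
            0.0,
        )
    if cfg.tare_at_peak:
        force = force - force[int(np.argmax(capture.theta_c))]
    if cfg.noise_sd_force > 0:
        force = force + rng.normal(0.0, cfg.noise_sd_force, force.size)
    limit = 2.0 * 2.0 * cfg.cell_capacity
    if np.any(np.abs(force) > limit):
        warnings.warn("load-cell reading clipped at twice the summed capacity", stacklevel=2)
        force = np.clip(force, -limit, limit)
    return force


_PASSIVE_PROFILE = MotionProfile(n_cycles=1, peak_flexion=90.0, period=12.0, hold_fraction=0.1)
_ACTIVE_PROFILE = MotionProfile(n_cycles=5, peak_flexion=70.0, period=3.0, hold_fraction=0.15)
_HYBRID_PROFILE = MotionProfile(
    n_cycles=6, peak_flexion=75.0, period=3.0, hold_fraction=0.1, mid_ascent_pause=0.15
)


def generate_capture_set(
    truth: ExoskeletonSpec,
    percentages: Sequence[int],
    reps: int,
    mode: Literal["passive", "active", "hybrid"],
    seed: int = 0,
    cell_cfg: CellSimConfig | None = None,
    noise_sd_angle: float = 0.0,
) -> list[SyntheticCapture]:
    """A set of captures mirroring a characterization session's design.

    ``passive``: ``reps`` slow single flexion–extension cycles per
    percentage (active set to 0).  ``active``: ``reps`` captures of five
    brisk ascents per percentage (passive set to 0).  ``hybrid``: one free
    mixed-movement capture per (eta_p, eta_a) pair in ``percentages``
    (pairs given as tuples), with randomized cycles and optional
    half-ascents.  All randomness derives from ``seed``.
    """
    cfg = cell_cfg if cell_cfg is not None else CellSimConfig(noise_sd_force=0.0)
    seq = np.random.SeedSequence(seed)
    out: list[SyntheticCapture] = []

    def _one(profile: MotionProfile, assist: AssistanceConfig, name: str, child) -> None:
        s_motion, s_cells = child.spawn(2)
        motion_seed = int(s_motion.generate_state(1)[0] % (2**31))
        cells_seed = int(s_cells.generate_state(1)[0] % (2**31))
        cap = generate_motion(replace(profile, noise_sd_angle=noise_sd_angle, seed=motion_seed))
        spec = replace(truth, assistance=assist)
        force = generate_loadcell(cap, spec, cfg, cells_seed)
        cap = CaptureSeries(cap.time, cap.theta_c, cap.sample_rate, force)
        out.append(SyntheticCapture(name=name, capture=cap, assistance=assist, mode=mode))

    if mode in ("passive", "active"):
        profile = _PASSIVE_PROFILE if mode == "passive" else _ACTIVE_PROFILE
        children = seq.spawn(len(percentages) * reps)
        i = 0
        for pct in percentages:
            for rep in range(1, reps + 1):
                assist = (
                    AssistanceConfig(eta_p=int(pct), eta_a=0, psi_a=truth.assistance.psi_a)
                    if mode == "passive"
                    else AssistanceConfig(eta_p=0, eta_a=int(pct), psi_a=truth.assistance.psi_a)
                )
                _one(profile, assist, f"{pct}.{rep:02d}", children[i])
                i += 1
    elif mode == "hybrid":
        pairs = [p if isinstance(p, tuple) else (int(p), int(p)) for p in percentages]
        children = seq.spawn(len(pairs))
        for child, (eta_p, eta_a) in zip(children, pairs):
            assist = AssistanceConfig(eta_p=int(eta_p), eta_a=int(eta_a), psi_a=truth.assistance.psi_a)
            _one(_HYBRID_PROFILE, assist, f"{eta_p}.{eta_a}", child)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return out
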