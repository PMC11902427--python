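"""Sagittal-plane static resolution of the device torque into body forces.

The device exerts a hip torque ``tau_e`` on each side.  Through the rigid
frame this becomes a chest-pad push ``F_C = tau_e / d_tt`` that helps the
spine back to vertical, a thigh-pad reaction ``F_Lg = tau_e / d_mt``, and a
forward pelvis push ``F_R`` that closes the horizontal force balance of the
device free body.  Pad forces transferred to skeletal reference points
carry the couple of their offset (``T_C`` at the chest, ``T_K`` at the
knee).  The device weight is split between shoulders and pelvis.

Internally forces are N and torques N·m; chest forces are reported in kgf
(divide by g) because that is the load-cell unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BodyDimensions, ValidationError

__all__ = [
    "G",
    "ExoForceState",
    "resolve_forces",
    "chest_force_total",
    "transfer_to_joint",
    "equilibrium_residual",
    "n_to_kgf",
    "kgf_to_n",
]

#: Standard gravity, m/s^2 — converts kgf to N.
G = 9.80665


def n_to_kgf(force_n: float | np.ndarray) -> float | np.ndarray:
    """Convert newtons to kilogram-force."""
    return force_n / G


def kgf_to_n(force_kgf: float | np.ndarray) -> float | np.ndarray:
    """Convert kilogram-force to newtons."""
    return force_kgf * G


@dataclass(frozen=True)
class ExoForceState:
    """Per-side device forces (N) and weight shares for one frame or series.

    All force fields are per-side; left/right are symmetric so totals are
    twice the per-side value.  ``w_e_shoulder`` and ``w_e_pelvis`` are the
    device-weight shares in N and sum to the full device weight.
    """

    tau_e: float | np.ndarray
    f_c: float | np.ndarray
    f_lg: float | np.ndarray
    f_r: float | np.ndarray
    w_e_shoulder: float
    w_e_pelvis: float
    body: BodyDimensions


def resolve_forces(
    tau_e_per_side: float | np.ndarray,
    body: BodyDimensions,
    device_weight: float = 0.0,
    shoulder_fraction: float = 0.5,
) -> ExoForceState:
    """Resolve a per-side torque (N·m) into the free-body pad forces.

    The chest and leg pads act at their lever arms, so
    ``f_c = tau_e / d_tt`` and ``f_lg = tau_e / d_mt``; the pelvis force
    closes the horizontal balance of the device free body,
    ``f_r = f_c + f_lg`` (chest and leg reactions point the same way on
    the device, the pelvis push opposes them).  The device weight
    (kgf) splits ``shoulder_fraction`` to the shoulders and the remainder
    to the pelvis.
    """
    if not (0.0 <= shoulder_fraction <= 1.0):
        raise ValidationError(f"shoulder_fraction must be in [0, 1], got {shoulder_fraction}")
    if device_weight < 0:
        raise ValidationError(f"device_weight must be >= 0, got {device_weight}")
    tau = np.asarray(tau_e_per_side, dtype=float)
    if not np.all(np.isfinite(tau)):
        raise ValidationError("tau_e must be finite")
    f_c = tau / body.d_tt
    f_lg = tau / body.d_mt
    f_r = f_c + f_lg
    scalar = np.isscalar(tau_e_per_side)
    w = device_weight * G
    return ExoForceState(
        tau_e=float(tau) if scalar else tau,
        f_c=float(f_c) if scalar else f_c,
        f_lg=float(f_lg) if scalar else f_lg,
        f_r=float(f_r) if scalar else f_r,
        w_e_shoulder=shoulder_fraction * w,
        w_e_pelvis=(1.0 - shoulder_fraction) * w,
        body=body,
    )


def chest_force_total(state: ExoForceState) -> float | np.ndarray:
    """Total (left + right) chest force in kgf — comparable to the load-cell sum."""
    return n_to_kgf(2.0 * np.asarray(state.f_c)) if np.ndim(state.f_c) else n_to_kgf(2.0 * state.f_c)


def transfer_to_joint(
    force: float | np.ndarray, pad_offset: float | np.ndarray
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Move a pad force to a joint reference point.

    Returns the unchanged force plus the induced couple
    ``offset x force`` — in the sagittal plane the cross product collapses
    to the scalar moment ``pad_offset * force`` (N·m).  This is the ``T_C``
    (chest) / ``T_K`` (knee) term.
    """
    return force, np.multiply(pad_offset, force)


def equilibrium_residual(state: ExoForceState) -> tuple[float, float]:
    """Net horizontal force and net moment about the hip of the device free body.

    The device receives the body's reactions: chest and thigh press back on
    the frame with ``-f_c`` and ``-f_lg`` at lever arms ``d_tt`` and
    ``d_mt``, and the actuator torque ``tau_e`` plus the pelvis reaction
    ``f_r`` act at the hip.  The moment balance per side is
    ``tau_e - f_c*d_tt`` on the torso link and ``tau_e - f_lg*d_mt`` on the
    thigh link; the force balance is ``f_r - f_c - f_lg``.  Both vanish for
    a consistent state; returned values are the maxima of the absolute
    residuals over frames.
    """
    tau = np.asarray(state.tau_e, dtype=float)
    f_c = np.asarray(state.f_c, dtype=float)
    f_lg = np.asarray(state.f_lg, dtype=float)
    f_r = np.asarray(state.f_r, dtype=float)
    moment_res = np.maximum(
        np.abs(tau - f_c * state.body.d_tt), np.abs(tau - f_lg * state.body.d_mt)
    )
    force_res = np.abs(f_r - f_c - f_lg)
    return float(np.max(force_res)), float(np.max(moment_res))
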