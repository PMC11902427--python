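"""Lumbar-flexion capture kinematics: velocity, phases, cycles, activation.

Sign convention: ``theta_c`` is 0 upright and grows with forward flexion,
so *descending* into flexion means ``d(theta_c)/dt > 0`` and *ascending*
(trunk extension, the motion the motor assists) means
``d(theta_c)/dt < 0``.  The active law consumes the non-negative ascent
speed ``max(0, -d(theta_c)/dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import InputError, ValidationError

__all__ = [
    "CaptureSeries",
    "PhaseAnnotation",
    "estimate_velocity",
    "segment_phases",
    "activation_mask",
    "annotate",
    "DEFAULT_HOLD_THRESHOLD",
    "DEFAULT_SMOOTHING_WINDOW",
]

DEFAULT_HOLD_THRESHOLD = 2.0  # deg/s
DEFAULT_SMOOTHING_WINDOW = 0.25  # s


@dataclass(frozen=True)
class CaptureSeries:
    """A uniformly sampled lumbar-flexion recording.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing and uniform.
    theta_c:
        Lumbar flexion angle in degrees relative to the global vertical.
    sample_rate:
        Sampling frequency in Hz.
    measured_force:
        Optional chest force in kgf (the two load cells already summed).
    """

    time: np.ndarray
    theta_c: np.ndarray
    sample_rate: float
    measured_force: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "theta_c", np.asarray(self.theta_c, dtype=float))
        if self.measured_force is not None:
            object.__setattr__(
                self, "measured_force", np.asarray(self.measured_force, dtype=float)
            )
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValidationError("time must be a 1-D array with at least 2 samples")
        if self.theta_c.shape != self.time.shape:
            raise ValidationError("theta_c and time must have equal length")
        if self.measured_force is not None and self.measured_force.shape != self.time.shape:
            raise ValidationError("measured_force and time must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sample_rate)) > 1e-6:
            raise ValidationError("time must be uniform at 1/sample_rate to within 1e-6 s")

    def __len__(self) -> int:
        return int(self.time.size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float | None = None) -> "CaptureSeries":
        """Build from a capture DataFrame (columns ``time_s``, ``theta_c_deg``,
        optional ``force_chest_kgf`` or ``cell_left_kgf`` + ``cell_right_kgf``)."""
        if "time_s" not in df or "theta_c_deg" not in df:
            raise InputError("capture frame needs columns time_s and theta_c_deg")
        force = None
        if "force_chest_kgf" in df:
            force = df["force_chest_kgf"].to_numpy(float)
        elif "cell_left_kgf" in df and "cell_right_kgf" in df:
            force = df["cell_left_kgf"].to_numpy(float) + df["cell_right_kgf"].to_numpy(float)
        t = df["time_s"].to_numpy(float)
        if sample_rate is None:
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["theta_c_deg"].to_numpy(float), float(sample_rate), force)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time, "theta_c_deg": self.theta_c}
        if self.measured_force is not None:
            data["force_chest_kgf"] = self.measured_force
        return pd.DataFrame(data)


@dataclass(frozen=True)
class PhaseAnnotation:
    """Per-frame movement phases and cycle bookkeeping for a capture.

    ``phase`` holds ``"descend"`` / ``"ascend"`` / ``"hold"`` labels,
    ``ascent_speed`` the rectified extension speed in deg/s, ``cycle_id``
    the enclosing flexion cycle (-1 outside any cycle) and
    ``cycle_peak_flexion`` each cycle's maximum flexion angle in degrees.
    """

    phase: np.ndarray
    ascent_speed: np.ndarray
    velocity: np.ndarray
    cycle_id: np.ndarray
    cycle_peak_flexion: np.ndarray
    partial_cycles: tuple[int, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return int(self.phase.size)


def estimate_velocity(
    capture: CaptureSeries, smoothing_window: float = DEFAULT_SMOOTHING_WINDOW
) -> np.ndarray:
    """Angular velocity d(theta_c)/dt in deg/s from the sampled angle.

    A centred moving average over ``smoothing_window`` seconds is applied
    to the angle before a central finite difference (one-sided at the
    endpoints).  Linear signals pass through unchanged, so ramps recover
    their slope exactly away from the smoothing transient.
    """
    n_win = max(2, int(round(smoothing_window * capture.sample_rate)))
    if len(capture) < n_win:
        raise InputError(
            f"capture ({len(capture)} samples) shorter than smoothing window ({n_win})"
        )
    # odd-length symmetric window keeps the filter zero-phase
    if n_win % 2 == 0:
        n_win += 1
    pad = n_win // 2
    theta = capture.theta_c
    padded = np.concatenate(
        [
            # reflect about the end values so linear trends continue through
            2 * theta[0] - theta[pad:0:-1],
            theta,
            2 * theta[-1] - theta[-2 : -pad - 2 : -1],
        ]
    )
    kernel = np.full(n_win, 1.0 / n_win)
    smooth = np.convolve(padded, kernel, mode="valid")
    return np.gradient(smooth, capture.time)


def _find_cycle_boundaries(theta: np.ndarray, peaks: np.ndarray) -> list[tuple[int, int]]:
    """Cycles span from one flexion *minimum* preceding a peak to the next.

    Boundaries are placed at the angle minima between consecutive peaks so
    that each cycle contains exactly one flexion maximum with its descend
    and ascend limbs.
    """
    if peaks.size == 0:
        return []
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(a + np.argmin(theta[a : b + 1])))
    bounds.append(theta.size - 1)
    return [(bounds[i], bounds[i + 1]) for i in range(len(peaks))]


def segment_phases(
    capture: CaptureSeries,
    velocity: np.ndarray | None = None,
    hold_threshold: float = DEFAULT_HOLD_THRESHOLD,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
) -> PhaseAnnotation:
    """Label each frame descend / ascend / hold and segment flexion cycles.

    Frames with velocity above ``+hold_threshold`` descend (into flexion),
    below ``-hold_threshold`` ascend, the rest hold.  Cycles are delimited
    at the flexion minima between successive flexion peaks; each cycle
    records its peak flexion, and leading/trailing partial cycles are kept
    but flagged in ``partial_cycles``.
    """
    from scipy.signal import find_peaks

    if velocity is None:
        velocity = estimate_velocity(capture, smoothing_window)
    v = np.asarray(velocity, dtype=float)
    if v.shape != capture.time.shape:
        raise InputError("velocity must align with the capture")

    phase = np.where(v > hold_threshold, "descend", np.where(v < -hold_threshold, "ascend", "hold"))
    ascent_speed = np.maximum(0.0, -v)

    theta = capture.theta_c
    span = float(theta.max() - theta.min())
    # flexion maxima separated by a meaningful fraction of the motion range
    prominence = max(1.0, 0.2 * span) if span > 0 else None
    peaks, _ = find_peaks(theta, prominence=prominence)
    cycle_id = np.full(theta.size, -1, dtype=int)
    peak_flexion: list[float] = []
    partial: list[int] = []
    segments = _find_cycle_boundaries(theta, peaks)
    for cid, (lo, hi) in enumerate(segments):
        cycle_id[lo : hi + 1] = cid
        peak_flexion.append(float(theta[lo : hi + 1].max()))
        # a cycle whose boundary sits at the capture edge may be truncated
        if lo == 0 or hi == theta.size - 1:
            partial.append(cid)
    return PhaseAnnotation(
        phase=phase,
        ascent_speed=ascent_speed,
        velocity=v,
        cycle_id=cycle_id,
        cycle_peak_flexion=np.asarray(peak_flexion, dtype=float),
        partial_cycles=tuple(partial),
    )


def activation_mask(annotation: PhaseAnnotation, psi_a: float) -> np.ndarray:
    """Frames where the active assistance engages.

    True exactly on ascend-labeled frames whose enclosing cycle reached a
    peak flexion deeper than the activation angle ``psi_a``; an interrupted
    ascent re-engages on each ascending segment of the same cycle.
    """
    ascend = annotation.phase == "ascend"
    if annotation.cycle_peak_flexion.size == 0:
        return np.zeros(len(annotation), dtype=bool)
    deep = np.zeros(len(annotation), dtype=bool)
    in_cycle = annotation.cycle_id >= 0
    deep[in_cycle] = annotation.cycle_peak_flexion[annotation.cycle_id[in_cycle]] > psi_a
    return ascend & deep


def annotate(
    capture: CaptureSeries,
    hold_threshold: float = DEFAULT_HOLD_THRESHOLD,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
) -> PhaseAnnotation:
    """Convenience: velocity estimation followed by phase segmentation."""
    v = estimate_velocity(capture, smoothing_window)
    return segment_phases(capture, v, hold_threshold, smoothing_window)
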