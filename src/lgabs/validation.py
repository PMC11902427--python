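"""Model verification: simulated-vs-measured force and risk comparisons.

The headline check compares the chest force the model predicts for a
capture with the force the load cells recorded, per capture, as a mean
absolute difference in kgf.  For active captures the measured signal also
contains the force the wearer exerts to lower the trunk (the cells keep
reading during descent); the *ascending-only* filter removes those frames
so only device-produced force is compared.  Risk comparison runs the same
risk pipeline twice: once on the model's torque and once on the torque
implied by the measured chest force through the chest lever arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import risk as risk_mod
from .kinematics import CaptureSeries, PhaseAnnotation
from .model import ExoskeletonSpec, InputError
from .risk import RiskConfig
from .simulate import SimulationResult, simulate_capture
from .statics import G
from .synthetic import SyntheticCapture

__all__ = [
    "mean_abs_diff",
    "active_mod_filter",
    "compare_forces",
    "compare_risk",
    "CaptureValidation",
    "ValidationReport",
    "validate_set",
]


def mean_abs_diff(simulated: np.ndarray, measured: np.ndarray) -> float:
    """Mean per-frame absolute difference between two force series (kgf).

    Absolute differences are used so deviations of opposite sign cannot
    cancel.
    """
    simulated = np.asarray(simulated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if simulated.shape != measured.shape:
        raise InputError(
            f"series lengths differ ({simulated.shape} vs {measured.shape})"
        )
    return float(np.mean(np.abs(simulated - measured)))


def active_mod_filter(measured: np.ndarray, annotation: PhaseAnnotation) -> np.ndarray:
    """Zero the measured force outside ascending frames.

    The load cells keep registering the wearer's lowering effort during
    descent; only ascending frames carry device-produced force, so all
    other frames are zeroed (ascending frames pass through untouched).
    """
    measured = np.asarray(measured, dtype=float)
    if measured.size != len(annotation):
        raise InputError("measured series and annotation lengths differ")
    return np.where(annotation.phase == "ascend", measured, 0.0)


def compare_forces(
    sim: SimulationResult, apply_active_mod: bool = False
) -> float:
    """Mean absolute simulated-vs-measured chest force difference (kgf)."""
    if sim.capture.measured_force is None:
        raise InputError("capture has no measured force channel")
    measured = sim.capture.measured_force
    simulated = sim.chest_force_kgf
    if apply_active_mod:
        measured = active_mod_filter(measured, sim.annotation)
        simulated = active_mod_filter(simulated, sim.annotation)
    return mean_abs_diff(simulated, measured)


def compare_risk(
    capture: CaptureSeries,
    spec: ExoskeletonSpec,
    config: RiskConfig,
    apply_active_mod: bool = False,
) -> tuple[float, float, float]:
    """(simulated risk %, experimental-data risk %, difference).

    The simulated branch feeds the model's total torque into the risk
    pipeline; the experimental branch converts the measured chest force
    back to total torque through the chest lever arm
    (``tau = F/2 * d_tt`` per side).  Both branches share every other part
    of the pipeline, so differences isolate the force channel.
    """
    if capture.measured_force is None:
        raise InputError("capture has no measured force channel")
    sim = simulate_capture(capture, spec)
    measured = capture.measured_force
    if apply_active_mod:
        measured = active_mod_filter(measured, sim.annotation)
    tau_measured_total = measured * G / 2.0 * spec.body.d_tt * 2.0
    # assistance cannot be negative: a negative cell reading is wearer effort
    tau_measured_total = np.maximum(0.0, tau_measured_total)
    r_sim = risk_mod.assess(capture, sim.tau_e_total, config).risk_per_minute
    r_exp = risk_mod.assess(capture, tau_measured_total, config).risk_per_minute
    return r_sim, r_exp, r_sim - r_exp


@dataclass(frozen=True)
class CaptureValidation:
    """Per-capture verification metrics."""

    name: str
    mode: str
    mean_abs_force_diff_kgf: float
    simulated_risk_pct: float
    experimental_risk_pct: float

    @property
    def risk_diff_pct(self) -> float:
        # recomputed, never stored independently
        return self.simulated_risk_pct - self.experimental_risk_pct


@dataclass(frozen=True)
class ValidationReport:
    """Aggregate verification over a capture set."""

    captures: tuple[CaptureValidation, ...]
    diff_convention: str = "absolute per-frame difference, mean over frames"

    @property
    def force_diff_mean(self) -> float:
        return float(np.mean([c.mean_abs_force_diff_kgf for c in self.captures]))

    @property
    def force_diff_sd(self) -> float:
        return float(np.std([c.mean_abs_force_diff_kgf for c in self.captures]))

    @property
    def risk_diff_mean(self) -> float:
        return float(np.mean([abs(c.risk_diff_pct) for c in self.captures]))

    @property
    def risk_diff_sd(self) -> float:
        return float(np.std([abs(c.risk_diff_pct) for c in self.captures]))

    def to_dict(self) -> dict:
        return {
            "diff_convention": self.diff_convention,
            "aggregate": {
                "force_diff_mean_kgf": self.force_diff_mean,
                "force_diff_sd_kgf": self.force_diff_sd,
                "risk_diff_mean_pct": self.risk_diff_mean,
                "risk_diff_sd_pct": self.risk_diff_sd,
            },
            "captures": [
                {
                    "name": c.name,
                    "mode": c.mode,
                    "mean_abs_force_diff_kgf": c.mean_abs_force_diff_kgf,
                    "simulated_risk_pct": c.simulated_risk_pct,
                    "experimental_risk_pct": c.experimental_risk_pct,
                    "risk_diff_pct": c.risk_diff_pct,
                }
                for c in self.captures
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        lines = [
            f"{'capture':<10} {'mode':<11} {'|dF| kgf':>9} {'S risk %':>9} {'ED risk %':>10} {'dRisk %':>8}"
        ]
        for c in self.captures:
            lines.append(
                f"{c.name:<10} {c.mode:<11} {c.mean_abs_force_diff_kgf:9.3f} "
                f"{c.simulated_risk_pct:9.3f} {c.experimental_risk_pct:10.3f} "
                f"{c.risk_diff_pct:8.3f}"
            )
        lines.append(
            f"aggregate force diff {self.force_diff_mean:.3f} ± {self.force_diff_sd:.3f} kgf; "
            f"risk diff {self.risk_diff_mean:.3f} ± {self.risk_diff_sd:.3f} %"
        )
        return "\n".join(lines)


def validate_set(
    captures: Sequence[SyntheticCapture],
    spec: ExoskeletonSpec,
    config: RiskConfig | None = None,
) -> ValidationReport:
    """Run force and risk verification over a capture set.

    Active-mode captures are compared under the ascending-only convention
    (reported with mode ``active_mod``); passive and hybrid captures are
    compared unfiltered, mirroring a characterization campaign's
    protocol.
    """
    from dataclasses import replace

    config = config if config is not None else RiskConfig()
    rows = []
    for sc in captures:
        cap_spec = replace(spec, assistance=sc.assistance)
        sim = simulate_capture(sc.capture, cap_spec)
        use_mod = sc.mode == "active"
        fdiff = compare_forces(sim, apply_active_mod=use_mod)
        r_sim, r_exp, _ = compare_risk(sc.capture, cap_spec, config, apply_active_mod=use_mod)
        rows.append(
            CaptureValidation(
                name=sc.name,
                mode="active_mod" if use_mod else sc.mode,
                mean_abs_force_diff_kgf=fdiff,
                simulated_risk_pct=r_sim,
                experimental_risk_pct=r_exp,
            )
        )
    return ValidationReport(captures=tuple(rows))
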