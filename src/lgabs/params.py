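"""Parameter-file and capture-CSV serialization.

The exoskeleton parameter file is versioned YAML with blocks::

    schema: 1
    passive:
      characteristic_angles: [..5 values..]   # deg
      torque_ratios: [..5 values..]           # fractions of max torque
      tau_max: {"0": 0.0, "10": ..., "100": ...}   # N·m per side
    active:
      psi_a: 20.0                             # deg
      rows: {"100": {tau_a_max: ..., vel_lim: ..., slope: ..., intercept: ...}, ...}
    body: {d_tt: 0.45, d_mt: 0.35}            # m
    device: {weight_kgf: 7.0, shoulder_fraction: 0.5}

Loading validates every table invariant.  Capture CSVs carry the columns
``time_s``, ``theta_c_deg`` and optionally ``force_chest_kgf`` (or the two
cell columns ``cell_left_kgf``/``cell_right_kgf``, summed on load).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .kinematics import CaptureSeries
from .model import (
    ActiveKeypointTable,
    ActiveRow,
    AssistanceConfig,
    BodyDimensions,
    ExoskeletonSpec,
    InputError,
    PassiveKeypointTable,
)

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "save_capture",
    "load_capture",
    "default_synthetic_spec",
]

SCHEMA_VERSION = 1


def spec_to_dict(spec: ExoskeletonSpec) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "passive": {
            "characteristic_angles": list(spec.passive_table.characteristic_angles),
            "torque_ratios": list(spec.passive_table.torque_ratios),
            "tau_max": {str(k): float(v) for k, v in sorted(spec.passive_table.tau_max.items())},
        },
        "active": {
            "psi_a": float(spec.assistance.psi_a),
            "rows": {
                str(k): {
                    "tau_a_max": r.tau_a_max,
                    "vel_lim": r.vel_lim,
                    "slope": r.slope,
                    "intercept": r.intercept,
                }
                for k, r in sorted(spec.active_table.rows.items())
            },
        },
        "assistance": {"eta_p": spec.assistance.eta_p, "eta_a": spec.assistance.eta_a},
        "body": {"d_tt": spec.body.d_tt, "d_mt": spec.body.d_mt},
        "device": {
            "weight_kgf": spec.device_weight,
            "shoulder_fraction": spec.shoulder_fraction,
        },
    }


def spec_from_dict(data: dict) -> ExoskeletonSpec:
    if data.get("schema") != SCHEMA_VERSION:
        raise InputError(
            f"unsupported parameter-file schema {data.get('schema')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    p = data["passive"]
    passive = PassiveKeypointTable(
        tuple(p["characteristic_angles"]),
        tuple(p["torque_ratios"]),
        {int(k): float(v) for k, v in p["tau_max"].items()},
    )
    a = data["active"]
    active = ActiveKeypointTable(
        {
            int(k): ActiveRow(r["tau_a_max"], r["vel_lim"], r["slope"], r["intercept"])
            for k, r in a["rows"].items()
        }
    )
    assist = data.get("assistance", {})
    assistance = AssistanceConfig(
        eta_p=int(assist.get("eta_p", 100)),
        eta_a=int(assist.get("eta_a", 100)),
        psi_a=float(a["psi_a"]),
    )
    b = data["body"]
    d = data.get("device", {})
    return ExoskeletonSpec(
        passive_table=passive,
        active_table=active,
        assistance=assistance,
        body=BodyDimensions(float(b["d_tt"]), float(b["d_mt"])),
        device_weight=float(d.get("weight_kgf", 0.0)),
        shoulder_fraction=float(d.get("shoulder_fraction", 0.5)),
    )


def save_spec(spec: ExoskeletonSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path: str | Path) -> ExoskeletonSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_capture(capture: CaptureSeries, path: str | Path) -> None:
    capture.to_frame().to_csv(path, index=False)


def load_capture(path: str | Path, sample_rate: float | None = None) -> CaptureSeries:
    return CaptureSeries.from_frame(pd.read_csv(path), sample_rate)


def default_synthetic_spec(psi_a: float = 20.0) -> ExoskeletonSpec:
    """A plausible synthetic device description used as ground truth.

    These numbers are invented for simulation studies — they describe a
    generic active lumbar device of realistic scale (peak passive torque
    ~25 N·m per side at full assistance, active saturation ~20 N·m), not
    any measured commercial device.
    """
    from .model import scale_active_percentages, scale_passive_percentages

    passive = PassiveKeypointTable(
        characteristic_angles=(0.0, 20.0, 40.0, 60.0, 80.0),
        torque_ratios=(0.0, 0.20, 0.50, 0.80, 1.0),
        tau_max=scale_passive_percentages({40: 10.0, 70: 17.5, 100: 25.0}),
    )
    active = scale_active_percentages(
        {
            40: (8.0, 22.0, 55.0),
            70: (14.0, 18.5, 50.0),
            100: (20.0, 15.0, 45.0),
        }
    )
    return ExoskeletonSpec(
        passive_table=passive,
        active_table=active,
        assistance=AssistanceConfig(eta_p=100, eta_a=100, psi_a=psi_a),
        body=BodyDimensions(d_tt=0.45, d_mt=0.35),
        device_weight=7.0,
        shoulder_fraction=0.5,
    )
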