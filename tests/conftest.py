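import numpy as np
import pytest

from lgabs import default_synthetic_spec
from lgabs.model import AssistanceConfig
from lgabs.synthetic import CellSimConfig, generate_capture_set


@pytest.fixture(scope="session")
def truth_spec():
    """The bundled synthetic ground-truth device description."""
    return default_synthetic_spec()


@pytest.fixture(scope="session")
def noise_free_sets(truth_spec):
    """Noise-free passive/active capture sets at the calibrated percentages."""
    cfg = CellSimConfig(noise_sd_force=0.0)
    passive = generate_capture_set(truth_spec, [100, 70, 40], 3, "passive", seed=1, cell_cfg=cfg)
    active = generate_capture_set(truth_spec, [100, 70, 40], 3, "active", seed=2, cell_cfg=cfg)
    return passive, active


def group_by_percentage(captures, mode):
    groups = {}
    for sc in captures:
        pct = sc.assistance.eta_p if mode == "passive" else sc.assistance.eta_a
        groups.setdefault(pct, []).append(sc.capture)
    return groups
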