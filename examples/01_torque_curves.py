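"""Evaluate the device's torque laws across assistance percentages.

Builds the bundled synthetic device description and prints the per-side
passive torque at a few flexion angles and the active torque at a few
ascent speeds.  Passive torque grows with flexion and with the passive
percentage; active torque is zero below the threshold speed, ramps
linearly, and saturates at the percentage's maximum.
"""

import numpy as np

from lgabs import active_torque, default_synthetic_spec, passive_torque

spec = default_synthetic_spec()

print("passive torque per side [N·m] vs lumbar flexion")
angles = [0, 20, 40, 60, 80]
print("  theta_c:", "  ".join(f"{a:>6}" for a in angles))
for eta in (40, 70, 100):
    taus = [passive_torque(a, spec.passive_table, eta) for a in angles]
    print(f"  eta_p={eta:>3}%:", "  ".join(f"{t:6.2f}" for t in taus))

print("\nactive torque per side [N·m] vs ascent speed")
speeds = [5, 15, 25, 45, 70]
print("  speed:  ", "  ".join(f"{s:>6}" for s in speeds))
for eta in (40, 70, 100):
    taus = [active_torque(s, spec.active_table, eta) for s in speeds]
    print(f"  eta_a={eta:>3}%:", "  ".join(f"{t:6.2f}" for t in taus))

row = spec.active_table.row(100)
print(
    f"\nat 100% active the law engages above {row.vel_lim:.0f} deg/s and "
    f"saturates at {row.tau_a_max:.0f} N·m beyond {row.vel_max:.0f} deg/s."
)
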