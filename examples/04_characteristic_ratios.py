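"""Why fixed characteristic ratios fail: the stiffness sweep.

Simulates 120/80 with a stiff (exponents halved), normal, and compliant
(exponents doubled) artery and reads the oscillation ratio at the true
systolic and diastolic points off the figure-style envelope (per-beat
cuff-pressure range vs measured beat-mean pressure).
"""

from oscillobp import diastolic_ratio_sweep

ratios = diastolic_ratio_sweep()
print(f"{'scenario':24s} {'systolic %':>10s} {'diastolic %':>11s}")
for name, (sys_r, dia_r) in ratios.items():
    print(f"{name:24s} {sys_r:10.1f} {dia_r:11.1f}")

# The diastolic ratio slides from the mid-90s down to the mid-70s as the
# artery gets more compliant, so no single falling-side fraction can mark
# diastolic pressure across patients; the systolic ratio moves too.
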