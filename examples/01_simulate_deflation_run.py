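"""Simulate one oscillometric cuff deflation and look at the oscillations.

The standard scenario: true pressure 120/80 mmHg at 80 beats/min, cuff
inflated to 150 mmHg and vented at 3 mmHg/s for 40 s, brachial-artery
segment with stiffness exponents a = 0.11, b = 0.03 /mmHg.
"""

import numpy as np

from oscillobp import (
    ArteryModel,
    CuffModel,
    PressureWaveform,
    extract_envelope,
    highpass_filter,
    simulate_run,
)

rec = simulate_run(ArteryModel(), CuffModel(), PressureWaveform())
rec = rec.with_oscillations(highpass_filter(rec))
env = extract_envelope(rec)

osc = rec.osc[~np.isnan(rec.osc)]
print(f"samples: {rec.t.size} over {rec.duration:.0f} s at {rec.sample_rate:.0f} Hz")
print(f"cuff pressure: {rec.P[0]:.1f} -> {rec.P[-1]:.1f} mmHg")
print(f"oscillation range: {osc.min():+.3f} .. {osc.max():+.3f} mmHg")
print(f"beats in envelope: {len(env)}")
print(f"peak oscillation amplitude: {env.peak_amp:.3f} mmHg "
      f"at cuff pressure {env.P_max:.1f} mmHg")

# The peak of the envelope marks mean arterial pressure (100 mmHg here):
# oscillations are largest when the beat's pressure swing straddles zero
# transmural pressure, i.e. when cuff pressure is near the waveform mean.
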