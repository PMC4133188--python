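"""From a click recording to a flow-rate curve.

Renders a synthetic audio recording of a pen injection (one click per 10 µL),
detects the clicks, and converts the inter-click intervals to flow rates.
"""

import numpy as np

from penpress import detect_clicks, flow_from_clicks
from penpress.synthetic import default_spring_family, render_click_wav, simulate_injection
from penpress.units import UL, UL_PER_S

# simulate a 240 µL injection in air and render it as audio
spring = default_spring_family()(np.random.default_rng(0), 240 * UL)
injection = simulate_injection(spring, "air", dose=240 * UL, jitter_sd=0.0, seed=1)
audio, rate = render_click_wav(injection.clicks, snr_db=20, seed=2)

train = detect_clicks(audio, rate)
flow = flow_from_clicks(train, truncate_tail=0)

print(f"detected {train.n_clicks} clicks "
      f"({train.dose / UL:.0f} µL at 10 µL per click)")
print(f"flow decelerates from {flow.Q[0] / UL_PER_S:.1f} "
      f"to {flow.Q[-1] / UL_PER_S:.1f} µL/s over {flow.t_mid[-1]:.2f} s")
# The deceleration is the torsion spring untwisting: each successive 10 µL
# takes a little longer, and the flow rate is 10 µL / (inter-click interval).
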