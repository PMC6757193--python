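"""Forward simulation of active mouth opening on the synthetic jaw.

Generates the default synthetic anatomy, ramps the opener muscles
(lateral pterygoid + submental group) to maximum over 0.25 s and logs
the inter-incisal gap.  Takes a few minutes on one core.
"""
import warnings

import numpy as np

from tmjsim import SimConfig, generate_anatomy, incisal_gap, run

warnings.simplefilter("ignore")
bundle = generate_anatomy()
cfg = SimConfig(dt=1e-3, duration=0.35, output_every=50)
result = run(bundle.system, cfg, bundle.tasks["open"])
g = result.column("gap_mm")
for t, gap in zip(result.times, g):
    print(f"  t = {t*1e3:5.0f} ms   gap = {gap:6.2f} mm")
print(f"stable: {result.stable}; peak disk von Mises {result.peak_von_mises/1e3:.0f} kPa")
print("The gap rises monotonically during the ramp and flattens as the")
print("passive closer forces and joint geometry balance the openers.")
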