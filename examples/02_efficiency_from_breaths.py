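"""Gross mechanical efficiency from breath-by-breath gas exchange.

Simulates a session of spirometry (3 x 4 min blocks) at a known efficiency
of 5%, recovers the energy expenditure through the oxygen energetic
equivalent e = 4.940*RER + 16.040 kJ/L, and applies the RER > 1.0 screen.
"""

import numpy as np

from handrim import SimulationConfig, session_physiology, SpiroSeries
from handrim.synthetic import simulate_spirometry

cfg = SimulationConfig(seed=7, gme_true=5.0, rer_true=0.90)
rng = np.random.default_rng(7)
po = 21.0  # external power output, W

parts, windows = [], []
for b in range(3):
    t0 = b * (cfg.block_duration + cfg.rest_between_blocks)
    parts.append(simulate_spirometry(cfg, po, rng=rng, t0=t0))
    windows.append((t0, t0 + cfg.block_duration))
series = SpiroSeries(np.concatenate([p.time for p in parts]),
                     np.concatenate([p.vo2 for p in parts]),
                     np.concatenate([p.vco2 for p in parts]),
                     np.concatenate([p.hr for p in parts]))

out = session_physiology(series, windows, [po] * 3)
print(f"session means (last minute of each block, averaged over blocks):")
print(f"  EE  {out['ee']:6.1f} W   (true {po / 0.05:.0f} W)")
print(f"  RER {out['rer']:6.3f}    HR {out['hr']:5.1f} bpm")
print(f"  GME {out['gme']:6.2f} %  (true 5.00 %)")
print("GME = PO/EE*100: the fraction of metabolic power converted to "
      "external work. Sessions with mean RER > 1.0 would be discarded "
      f"(here discarded={out['discarded']}).")
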