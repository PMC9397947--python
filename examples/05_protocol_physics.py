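"""Protocol physics: friction load, coast-down calibration, compliance.

The ergometer brakes the wheelchair with rolling friction F = mu*m*g, so
holding the commanded speed costs P = mu*m*g*v; a free coast-down
decelerates at mu*g, which is how mu is calibrated in the first place.
"""

import numpy as np

from handrim import ProtocolConfig, coast_down_mu, speed_compliance, theoretical_power

cfg = ProtocolConfig()
p = theoretical_power(cfg.mu, cfg.mass, cfg.target_speed)
print(f"target load: mu={cfg.mu}, m={cfg.mass} kg, v={cfg.target_speed} m/s"
      f" -> P = {p:.1f} W (protocol nominal: {round(p)} W)")

rng = np.random.default_rng(0)
t = np.linspace(0.0, 5.0, 501)
v = 3.0 - cfg.mu * 9.81 * t + rng.normal(0.0, 0.01, t.size)
mu_hat = coast_down_mu(t, v)
print(f"coast-down fit over a noisy 5 s deceleration: mu = {mu_hat:.5f} "
      f"(true {cfg.mu})")

for speed in (2.78, 2.60, 2.95):
    ok = speed_compliance(speed, cfg)
    print(f"session mean speed {speed:.2f} m/s -> "
          f"{'compliant' if ok else 'outside the +/-5% band'}")
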