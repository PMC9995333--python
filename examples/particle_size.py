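"""Mean particle diameter from the variance-to-mean ratio of optical noise.

Builds a beam-attenuation sample series from a first-principles simulation
of 200-um particles drifting through the transmissometer volume, then
inverts the variance-to-mean statistics back to a diameter.
"""

import numpy as np

from floatpump.size import CP_PRESET, mean_diameter, mean_diameter_profile
from floatpump.synthetic import simulate_counting_signal

# the worked value: var/mean = 1e-3 m-1 with the transmissometer geometry
d = mean_diameter(1e-3, CP_PRESET)
print(f"var/mean 1e-3 m-1  ->  D = {d * 1e6:.0f} um")

# recover a known diameter from simulated counting noise
signal = simulate_counting_signal(200e-6, CP_PRESET, n_samples=600,
                                  mean_signal=0.1, seed=1)
d_hat = mean_diameter_profile(signal, CP_PRESET)
print(f"simulated 200-um particles: recovered D = {d_hat * 1e6:.0f} um "
      f"({100 * d_hat / 200e-6:.0f}% of truth)")
print("The estimator reads particle size from the 'spikiness' of the optical")
print("signal; the recovery is biased a few percent low by the median detrend.")
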