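"""Generate the reference test signals and a labelled CP-like pair.

Builds the 1 Hz sinusoid and the 1 Hz + 2 Hz composite used to
characterise the transform, adds 25 dB noise and a 0.3 Hz breathing
component, and synthesises one dicrotic and one non-dicrotic
corneal-pulse-like signal.
"""

import numpy as np
from scipy.signal import find_peaks

from odp import SynthConfig, add_breathing, add_noise, harmonic, simulate_cp

cfg = SynthConfig()  # 10 s at 400 Hz, unit amplitude
sine = harmonic(cfg)
composite = harmonic(SynthConfig(component_freqs=(1.0, 2.0), component_amps=(1.0, 0.5)))
print(f"1 Hz signal:        n={sine.n}, power={np.mean(sine.samples**2):.3f}")
print(f"1+2 Hz composite:   n={composite.n}, power={np.mean(composite.samples**2):.3f}")

noisy = add_noise(sine, snr_db=25.0, seed=0)
achieved = 10 * np.log10(
    np.mean(sine.samples**2) / np.mean((noisy.samples - sine.samples) ** 2)
)
print(f"25 dB AWGN:         achieved SNR = {achieved:.2f} dB")

breathing = add_breathing(sine, freq=0.3, amp=0.5)
print(f"breathing added:    sample range {breathing.samples.min():.2f} "
      f"to {breathing.samples.max():.2f} (was -1 to 1)")

noiseless = SynthConfig(snr_db=np.inf, breathing_amp=0.0)
for dic in (True, False):
    sig = simulate_cp(dic, noiseless, jitter=0.0, seed=1)
    peaks, _ = find_peaks(sig.samples[400:800])  # one interior cycle
    print(f"{sig.label:>13s} cycle: {len(peaks)} local maxima "
          "(double peak marks the dicrotic wave)" if dic else
          f"{sig.label:>13s} cycle: {len(peaks)} local maximum")
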