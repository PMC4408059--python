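"""Wavelet scalogram of the 1 Hz reference signal.

Transforms the derivative of the 1 Hz sinusoid on scales 800-2500 and
locates the modulus-plane maxima: there are two per cycle and they fall
at the raw signal's extrema, which is the signature pattern the texture
features encode.
"""

import numpy as np
from scipy.signal import find_peaks

from odp import ScaleGrid, SynthConfig, harmonic, heatmaps, transform
from odp.signals import derivative

sig = harmonic(SynthConfig())
grid = ScaleGrid(800, 2500, 8)
res = transform(derivative(sig), grid)
mod = heatmaps(res)["modulus"].values

print("scale  maxima-times [s] (signal extrema are at 0.25, 0.75, 1.25, ...)")
for i, s in enumerate(res.scales):
    cols = np.where(res.valid_mask[i])[0]
    lo, hi = cols[0], cols[-1]
    pk, _ = find_peaks(mod[i, lo : hi + 1], prominence=1e-3 * mod[i].max())
    times = (pk + lo) / res.fs
    print(f"{s:5d}  {np.round(times[:8], 3)}")

print("\nEach row shows two maxima per 1 s cycle, aligned with the")
print("maxima and minima of the raw signal (within a few ms).")
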