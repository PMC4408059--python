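"""GLCM texture features of a dicrotic vs a non-dicrotic signal.

Extracts the 16-feature vector (4 CWT planes x 4 Haralick statistics,
N = 8 levels, offset L = 25 pixels = 0.0625 s) for one signal of each
class and prints the features that separate them.
"""

from odp import DEFAULT_CP_CONFIG, signal_features, simulate_cp

dic = simulate_cp(True, DEFAULT_CP_CONFIG, seed=3)
non = simulate_cp(False, DEFAULT_CP_CONFIG, seed=4)

fv_d = signal_features(dic)
fv_n = signal_features(non)

print(f"{'feature':<22s} {'dicrotic':>10s} {'non-dicrotic':>13s}")
for name in fv_d.names:
    print(f"{name:<22s} {fv_d[name]:>10.4f} {fv_n[name]:>13.4f}")

print("\nThe dicrotic signal's phase plane is less homogeneous (more")
print("sign blocks per cycle from the second peak), which is the basis")
print(f"of the univariate rule: phase_homogeneity {fv_d['phase_homogeneity']:.3f}"
      f" (dicrotic) vs {fv_n['phase_homogeneity']:.3f} (non-dicrotic).")
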