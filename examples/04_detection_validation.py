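"""Detector training and bootstrap 632+ validation on a small dataset.

Builds 30 labelled synthetic signals per class, runs backward feature
selection, and compares the 632+ accuracy of the random forest, the
conditional inference tree and the fixed univariate homogeneity rule.
A smaller dataset than the full study keeps this example quick.
"""

from odp import (
    DEFAULT_CP_CONFIG,
    ScaleGrid,
    backward_select,
    bootstrap_632plus,
    build_dataset,
    make_dataset,
)

signals = make_dataset(30, DEFAULT_CP_CONFIG, jitter=0.05, seed=42)
data = build_dataset(signals, ScaleGrid(200, 1000, 32))

selected = backward_select(data, "random_forest", seed=42, inner_B=50)
print(f"backward selection kept {len(selected)} feature(s): {selected}")

for kind in ("random_forest", "conditional_tree", "homogeneity_threshold"):
    rep = bootstrap_632plus(data, kind, B=100, seed=42,
                            selected_features=selected if kind == "random_forest" else None)
    print(f"{kind:<22s} 632+ accuracy = {rep.accuracy_632plus:.3f} "
          f"(sd {rep.sd:.3f}, B={rep.n_bootstrap})")

print("\nThe multivariate detectors separate the classes; the fixed")
print("threshold rule (tau = 0.428, calibrated on real recordings) is")
print("uninformative on this synthetic population, as a single feature")
print("with a fixed cut generalises poorly.")
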