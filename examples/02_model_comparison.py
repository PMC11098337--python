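"""Compare the three constitutive models on one radial profile at t = 50 s.

LS_THERMOELASTIC couples heat to deformation through the thermal modulus;
CATTANEO_VERNOTTE keeps only the finite-speed (relaxing) heat flux;
CLASSICAL_PENNES is the parabolic bioheat limit (optionally with perfusion).
"""

import numpy as np

from thermotumor import run_variant, skin_tumor_preset

cfg = skin_tumor_preset()
R = cfg.geometry.tumor_radius
radii = np.array([0.0, 0.5 * R, R, 1.1 * R, 1.3 * R])

profiles = {
    name: run_variant(cfg, name, radii, [50.0]).T[:, 0]
    for name in ("LS_THERMOELASTIC", "CATTANEO_VERNOTTE", "CLASSICAL_PENNES")
}

print("r/R     " + "".join(f"{n:>20s}" for n in profiles))
for i, r in enumerate(radii):
    row = "".join(f"{profiles[n][i]:20.3f}" for n in profiles)
    print(f"{r / R:5.2f}  {row}")
print()
print(
    "The thermoelastic model runs coolest inside the tumor: the dilatation\n"
    "coupling raises the effective heat capacity by 1 + gamma^2 T0 /\n"
    "(rho c (lambda + 2 mu)) ~ 1.58, so the same absorbed power produces a\n"
    "smaller rise than either conduction-only model predicts."
)
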