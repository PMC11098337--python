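"""Cross-validate the semi-analytic solver against the finite-difference oracle.

The same coupled problem is solved twice — by the Laplace-domain modal
construction and by a brute-force explicit staggered-grid integrator — and
the interface temperature histories are compared.  A short window and a
modest grid keep this example quick; the full 80-s grid-refined comparison
(error < 1%) runs in the acceptance script.
"""

import numpy as np

from thermotumor import FDGrid, fd_solve, run, skin_tumor_preset

cfg = skin_tumor_preset()
R = cfg.geometry.tumor_radius
radii = np.array([0.5 * R, R, 2.0 * R])
times = np.linspace(2.0, 20.0, 7)

sa = run(cfg, radii, times)
fd = fd_solve(cfg, FDGrid(r_max=10 * R, nr=100), radii, times)
scale = np.max(np.abs(sa.T - 37.0))

print("t [s]   T_analytic(R) [C]   T_fd(R) [C]")
for j, t in enumerate(times):
    print(f"{t:5.0f}   {sa.T[1, j]:17.4f}   {fd.T[1, j]:11.4f}")
err = np.max(np.abs(fd.T - sa.T)) / scale
print(f"\nL-inf relative difference over all samples: {err:.3%}")
print(
    "Two entirely independent discretizations of the same coupled equations\n"
    "agree to a few percent on a coarse grid (and to <1% grid-refined),\n"
    "which validates both the modal Laplace construction and the inversion."
)
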