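"""Independent reference: pure-conduction composite sphere with relaxation.

This module solves the *decoupled* problem — Cattaneo–Vernotte (or Fourier)
heat conduction in a uniformly heated sphere embedded in an unbounded medium,
with temperature and flux continuity at the interface — directly from the
closed-form two-constant Laplace solution:

    θ̄₁(r) = A·sinh(m₁ r)/r + θ̄_p,      m₁² = a₁/k₁
    θ̄₂(r) = B·exp(−m₂ r)/r,            m₂² = a₂/k₂,  a = ρ c_E (s + τ0 s²)

It shares nothing with the modal machinery in :mod:`thermotumor.laplace`
(no biquadratic operator, no 4×4 interface system) and exists purely as a
verification yardstick for the coupled solver in its γ → 0 limit.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import InversionSettings, ModelConfig, volumetric_power
from .inversion import _invert_sampled

__all__ = ["cv_sphere_transformed", "cv_sphere_temperature"]


def _thermal_wavenumber(props, s: complex) -> complex:
    a = props.density * props.specific_heat * (s + props.relaxation_time * s * s)
    m = complex(np.sqrt(a / props.conductivity))
    if m.real < 0:
        m = -m
    return m


def cv_sphere_transformed(config: ModelConfig, r: np.ndarray, s: complex) -> np.ndarray:
    """θ̄(r, s) of the conduction-only composite sphere (step source).

    The two amplitudes follow from temperature and conductive-flux
    continuity at r = R; sinh/cosh ratios are evaluated through scaled
    exponentials so large |m·R| cannot overflow.
    """
    r = np.asarray(r, dtype=float)
    p1, p2 = config.tumor, config.tissue
    R = config.geometry.tumor_radius
    m1 = _thermal_wavenumber(p1, s)
    m2 = _thermal_wavenumber(p2, s)
    Q_L = volumetric_power(config.source)
    a1 = p1.density * p1.specific_heat * (s + p1.relaxation_time * s * s)
    theta_p = (1.0 + p1.relaxation_time * s) * (Q_L / s) / a1

    # Scaled unknowns: As = A sinh(m1 R)/R (tumor value at R), Bs = B e^{-m2 R}/R.
    #   continuity:  As + theta_p = Bs
    #   k1 A (m1 cosh(m1 R)/R - sinh(m1 R)/R^2) = k2 B e^{-m2 R}(-m2/R - 1/R^2)
    # In scaled form, with coth(m1 R) evaluated stably:
    #   k1 As (m1 coth(m1 R) - 1/R) = -k2 Bs (m2 + 1/R)
    z = m1 * R
    coth = (1.0 + np.exp(-2.0 * z)) / -np.expm1(-2.0 * z)
    g1 = p1.conductivity * (m1 * coth - 1.0 / R)
    g2 = -p2.conductivity * (m2 + 1.0 / R)
    As = g2 * theta_p / (g1 - g2)
    Bs = As + theta_p

    out = np.empty(r.shape, dtype=complex)
    inside = r <= R
    if np.any(inside):
        ri = r[inside]
        # sinh(m1 r)/sinh(m1 R) * (R/r), scaled; series for small m1 r
        small = np.abs(m1 * ri) < 1e-2
        ratio = np.empty(ri.shape, dtype=complex)
        if np.any(small):
            rs = ri[small]
            z2 = (m1 * rs) ** 2
            f = m1 * (1.0 + z2 / 6.0 + z2 * z2 / 120.0)  # sinh(m1 r)/r
            ratio[small] = f * 2.0 * R * np.exp(-z) / -np.expm1(-2.0 * z)
        big = ~small
        if np.any(big):
            rb = ri[big]
            ratio[big] = (
                np.exp(m1 * (rb - R))
                * (R / rb)
                * (-np.expm1(-2.0 * m1 * rb))
                / -np.expm1(-2.0 * z)
            )
        out[inside] = As * ratio + theta_p
    if np.any(~inside):
        ro = r[~inside]
        out[~inside] = Bs * np.exp(-m2 * (ro - R)) * R / ro
    return out


def cv_sphere_temperature(
    config: ModelConfig,
    radii: Sequence[float],
    times: Sequence[float],
    settings: InversionSettings | None = None,
) -> np.ndarray:
    """Time-domain temperature (°C) of the conduction-only reference.

    Returns an array shaped (len(radii), len(times)).
    """
    settings = settings or config.inversion
    radii = np.asarray(radii, dtype=float)
    times = np.asarray(times, dtype=float)

    def sample_at(s_arr: np.ndarray) -> dict[str, np.ndarray]:
        buf = np.empty((len(s_arr), len(radii)), dtype=complex)
        for j, s in enumerate(s_arr):
            buf[j] = cv_sphere_transformed(config, radii, complex(s))
        return {"theta": buf}

    out = _invert_sampled(sample_at, times, settings)
    return out["theta"] + config.body_temp
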