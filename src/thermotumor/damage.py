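"""Arrhenius thermal-damage integral over simulated temperature histories.

Cumulative damage is Ω(t) = ∫₀ᵗ B·exp(−Ea/(Rg·T(t'))) dt' with T in kelvin;
Ω = 1 conventionally marks the onset of irreversible thermal injury.  The
integral is evaluated by trapezoidal quadrature on the supplied time grid
(exact for constant temperature).  Note the exponent is the standard
Moritz–Henriques form −Ea/(Rg·T): damage kinetics are an activated process,
so the rate *grows* with temperature and the integrand stays finite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import DamageParams, KELVIN_OFFSET
from .results import DamageProfile, SpatiotemporalField

__all__ = ["damage_rate", "arrhenius_damage", "damage_at_radii"]


def damage_rate(T_kelvin, params: DamageParams | None = None) -> np.ndarray:
    """Instantaneous damage rate B·exp(−Ea/(Rg·T)) in s⁻¹ (T in kelvin).

    Evaluated as exp(ln B − Ea/(Rg·T)) so extreme magnitudes of B cannot
    overflow intermediate products.
    """
    params = params or DamageParams()
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive kelvin")
    log_rate = np.log(params.frequency_factor) - params.activation_energy / (
        params.gas_constant * T
    )
    return np.exp(log_rate)


def arrhenius_damage(
    times: Sequence[float],
    T_kelvin: Sequence[float],
    params: DamageParams | None = None,
    radius: float = float("nan"),
) -> DamageProfile:
    """Cumulative damage Ω(t) along one temperature history.

    ``times`` must be strictly increasing, starting anywhere ≥ 0; Ω is
    measured from the first supplied instant (Ω(times[0]) = 0).
    """
    params = params or DamageParams()
    t = np.asarray(times, dtype=float)
    T = np.asarray(T_kelvin, dtype=float)
    if t.ndim != 1 or t.shape != T.shape:
        raise ValueError("times and temperatures must be 1-D and equal length")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    rate = damage_rate(T, params)
    omega = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
    )
    return DamageProfile(
        radius=radius,
        times=t,
        omega=omega,
        params_snapshot=params.model_dump(mode="json"),
    )


def damage_at_radii(
    field: SpatiotemporalField,
    radii: Sequence[float] | None = None,
    params: DamageParams | None = None,
) -> list[DamageProfile]:
    """Damage profiles at chosen radii of a simulated field.

    Radii must lie on (or within grid-rounding of) the field's radial grid;
    by default the first grid point just outside the tumor interface is used
    — the normal-tissue location at greatest risk.  Field temperatures are
    °C and are converted to kelvin here.
    """
    params = params or DamageParams()
    grid = np.asarray(field.radii, dtype=float)
    if radii is None:
        cfg = field.config_snapshot or {}
        R = cfg.get("geometry", {}).get("tumor_radius", float(np.median(grid)))
        outside = grid[grid > R]
        if outside.size == 0:
            raise ValueError("field grid has no point outside the tumor radius")
        radii = [float(outside.min())]
    out = []
    for r in radii:
        i = int(np.argmin(np.abs(grid - r)))
        spacing = np.max(np.diff(grid)) if grid.size > 1 else max(abs(r), 1.0)
        if abs(grid[i] - r) > spacing:
            raise ValueError(f"radius {r} lies outside the field grid")
        T_K = field.T[i] + KELVIN_OFFSET
        out.append(
            arrhenius_damage(field.times, T_K, params, radius=float(grid[i]))
        )
    return out
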