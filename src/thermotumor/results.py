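"""Result containers for time-domain simulation output."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd


@dataclass
class SpatiotemporalField:
    """Time-domain fields on an (r, t) grid.

    Arrays are shaped ``(len(radii), len(times))``.  ``T`` is absolute
    temperature in °C, ``u`` radial displacement in m, ``e`` the cubical
    dilatation (dimensionless), ``sigma_rr`` radial stress in Pa and ``q_r``
    radial heat flux in W·m⁻².
    """

    radii: np.ndarray
    times: np.ndarray
    T: np.ndarray
    u: np.ndarray
    e: np.ndarray
    sigma_rr: np.ndarray
    q_r: np.ndarray
    model_variant: str = "LS_THERMOELASTIC"
    config_snapshot: Optional[dict] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nr, nt = len(self.radii), len(self.times)
        for name in ("T", "u", "e", "sigma_rr", "q_r"):
            arr = getattr(self, name)
            if arr.shape != (nr, nt):
                raise ValueError(
                    f"field {name} has shape {arr.shape}, expected {(nr, nt)}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table with one row per (r, t) grid point."""
        r = np.repeat(self.radii, len(self.times))
        t = np.tile(self.times, len(self.radii))
        return pd.DataFrame(
            {
                "variant": self.model_variant,
                "r_m": r,
                "t_s": t,
                "T_C": self.T.ravel(),
                "u_m": self.u.ravel(),
                "e": self.e.ravel(),
                "sigma_rr_Pa": self.sigma_rr.ravel(),
                "q_r_Wm2": self.q_r.ravel(),
            }
        )

    def at_radius(self, r: float) -> dict[str, Any]:
        """Fields at the grid radius nearest ``r`` (exact match not required)."""
        i = int(np.argmin(np.abs(self.radii - r)))
        return {
            "r": float(self.radii[i]),
            "times": self.times,
            "T": self.T[i],
            "u": self.u[i],
            "e": self.e[i],
            "sigma_rr": self.sigma_rr[i],
            "q_r": self.q_r[i],
        }


@dataclass
class DamageProfile:
    """Cumulative Arrhenius damage Ω(t) at one radius."""

    radius: float
    times: np.ndarray
    omega: np.ndarray
    params_snapshot: Optional[dict] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_m": self.radius, "t_s": self.times, "omega": self.omega}
        )
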