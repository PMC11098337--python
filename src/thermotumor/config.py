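"""Parameter and configuration layer for the thermoelastic bioheat solver.

The physical scenario is a solid spherical tumor of radius ``R`` embedded in an
unbounded region of normal tissue.  Nanoparticles confined to the tumor absorb
laser light and act as a uniform volumetric heat source switched on at ``t=0``.
Heat conduction follows the Cattaneo–Vernotte law with a single relaxation time
``tau0`` and is two-way coupled to linear elastic deformation through the
thermal modulus ``gamma`` (Lord–Shulman generalized thermoelasticity).

Models here are deliberately permissive at construction time: range and
consistency rules are checked by :func:`validate_config`, which reports every
violation instead of raising on the first one.  Unknown keys in configuration
files are rejected (``extra="forbid"``).
"""

from __future__ import annotations

import enum
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

__all__ = [
    "TissueProperties",
    "LaserSource",
    "DamageParams",
    "Geometry",
    "InversionSettings",
    "ModelVariant",
    "ModelConfig",
    "skin_tumor_preset",
    "thermal_modulus",
    "volumetric_power",
    "validate_config",
    "default_radial_grid",
    "default_times",
    "KELVIN_OFFSET",
]

KELVIN_OFFSET = 273.15

#: Volumetric power of the laser/nanoparticle source chosen for the default
#: demonstration scenario (W·m⁻³).  The model is linear in the source, so this
#: value was fixed once, by bisection on the interface temperature of the
#: default scenario, such that T(R, 80 s) ≈ 42.5 °C — the midpoint of the
#: 40–45 °C therapeutic hyperthermia window.  It is expressed below as
#: irradiance in W·cm⁻² at absorption coefficient 10 cm⁻¹ (volumetric power
#: Q_L ≈ 8.909e5 W·m⁻³).
DEFAULT_IRRADIANCE_W_CM2 = 0.08908548
DEFAULT_ABSORPTION_CM1 = 10.0


class TissueProperties(BaseModel):
    """Thermophysical and elastic constants of one homogeneous medium.

    Units: ``density`` kg·m⁻³, ``specific_heat`` J·kg⁻¹·K⁻¹, ``conductivity``
    W·m⁻¹·K⁻¹, Lamé constants Pa, ``thermal_modulus`` Pa·K⁻¹ (the isotropic
    thermal stress coefficient γ = α_t(3λ+2μ)), ``relaxation_time`` s.
    """

    model_config = ConfigDict(extra="forbid")

    density: float
    specific_heat: float
    conductivity: float
    lame_lambda: float
    lame_mu: float
    thermal_modulus: float
    relaxation_time: float


class LaserSource(BaseModel):
    """Laser/nanoparticle heat source, uniform over the tumor sphere.

    ``irradiance`` is in W·cm⁻² and ``absorption_coeff`` in cm⁻¹, the units in
    which laser protocols are quoted; the derived volumetric power
    ``Q_L = alpha * I`` is converted once to SI (see :func:`volumetric_power`).
    The absorption coefficient of a nanoparticle-laden tumor may equivalently
    be supplied as ``N * C_abs`` (particle number density × absorption
    cross-section).  The temporal profile is a Heaviside step at ``t = 0``,
    constant thereafter.
    """

    model_config = ConfigDict(extra="forbid")

    irradiance: float = DEFAULT_IRRADIANCE_W_CM2
    absorption_coeff: float = DEFAULT_ABSORPTION_CM1

    @property
    def volumetric_power(self) -> float:
        """Q_L in W·m⁻³."""
        return volumetric_power(self)


class DamageParams(BaseModel):
    """Arrhenius thermal-damage kinetics.

    ``frequency_factor`` B (s⁻¹), ``activation_energy`` Ea (J·mol⁻¹) and
    ``gas_constant`` Rg (J·mol⁻¹·K⁻¹) enter the damage integral
    Ω(t) = ∫ B·exp(−Ea/(Rg·T)) dt with T in kelvin.
    """

    model_config = ConfigDict(extra="forbid")

    frequency_factor: float = 3.1e98
    activation_energy: float = 6.28e5
    gas_constant: float = 8.313


class Geometry(BaseModel):
    """Tumor radius and the (r, t) evaluation grid.

    ``eval_radii`` may span both media; radii are in metres, times in seconds
    and must be strictly increasing.  When omitted they default to 61 radii on
    [0, 5R] refined near the interface and 1-s steps on [1, 120] s.
    """

    model_config = ConfigDict(extra="forbid")

    tumor_radius: float = 0.02
    eval_radii: Optional[list[float]] = None
    eval_times: Optional[list[float]] = None

    def radii(self) -> np.ndarray:
        if self.eval_radii is not None:
            return np.asarray(self.eval_radii, dtype=float)
        return default_radial_grid(self.tumor_radius)

    def times(self) -> np.ndarray:
        if self.eval_times is not None:
            return np.asarray(self.eval_times, dtype=float)
        return default_times()


class InversionSettings(BaseModel):
    """Controls for the numerical inverse Laplace transform.

    ``method`` selects the Fourier-series (Durbin) inversion with Korrektur
    ("fourier", default) or the fixed-Talbot rule ("talbot", used as a
    cross-check).  ``series_terms`` is the number of Fourier terms N;
    ``contour_shift`` is the dimensionless product c·t_max fixing the Bromwich
    abscissa; ``acceleration`` toggles Wynn-epsilon convergence acceleration
    of the Fourier tail; ``rel_tolerance`` is the target relative accuracy
    used when reporting convergence warnings.
    """

    model_config = ConfigDict(extra="forbid")

    method: str = "fourier"
    series_terms: int = 200
    contour_shift: float = 4.6
    acceleration: bool = True
    rel_tolerance: float = 1e-6


class ModelVariant(str, enum.Enum):
    """Which heat-conduction constitutive model drives the run."""

    LS_THERMOELASTIC = "LS_THERMOELASTIC"  # Cattaneo flux + dilatation coupling
    CATTANEO_VERNOTTE = "CATTANEO_VERNOTTE"  # Cattaneo flux, no coupling
    CLASSICAL_PENNES = "CLASSICAL_PENNES"  # Fourier flux, optional perfusion


class ModelConfig(BaseModel):
    """Complete scenario description.

    ``body_temp`` is in °C (converted to kelvin internally where an absolute
    temperature is required: the γT0 coupling term and the damage integral).
    ``perfusion_coeff`` is the lumped blood-perfusion heat-sink coefficient
    w_b·ρ_b·c_b in W·m⁻³·K⁻¹; it is honored only by the CLASSICAL_PENNES
    variant — the generalized model neglects perfusion, which is defensible
    for small superficial skin carcinomas where perfusion is low.
    """

    model_config = ConfigDict(extra="forbid")

    tumor: TissueProperties
    tissue: TissueProperties
    source: LaserSource = LaserSource()
    geometry: Geometry = Geometry()
    body_temp: float = 37.0
    model_variant: ModelVariant = ModelVariant.LS_THERMOELASTIC
    perfusion_coeff: float = 0.0
    inversion: InversionSettings = InversionSettings()

    @property
    def body_temp_kelvin(self) -> float:
        return self.body_temp + KELVIN_OFFSET


def thermal_modulus(lame_lambda: float, lame_mu: float, alpha_t: float) -> float:
    """Thermal modulus γ = α_t·(3λ + 2μ) in Pa·K⁻¹.

    ``alpha_t`` is the coefficient of linear thermal expansion (K⁻¹); a
    negative value is rejected.
    """
    if alpha_t < 0:
        raise ValueError("thermal expansion coefficient alpha_t must be >= 0")
    if lame_lambda + 2.0 * lame_mu <= 0:
        raise ValueError("lambda + 2*mu must be positive")
    return alpha_t * (3.0 * lame_lambda + 2.0 * lame_mu)


def volumetric_power(source: LaserSource) -> float:
    """Volumetric heat source Q_L = α·I in W·m⁻³.

    α in cm⁻¹ times I in W·cm⁻² gives W·cm⁻³; one cm⁻³ is 10⁻⁶ m³, hence the
    single factor 10⁶ converting to W·m⁻³.
    """
    return source.absorption_coeff * source.irradiance * 1.0e6


def default_radial_grid(tumor_radius: float, n: int = 61) -> np.ndarray:
    """Radial evaluation grid on [0, 5R], refined near the interface r = R.

    Half the points cover the tumor with sine clustering toward r = R; the
    rest cover (R, 5R] with geometrically growing spacing away from R.
    """
    R = tumor_radius
    n_in = n // 2 + 1
    n_out = n - n_in
    inner = R * np.sin(np.linspace(0.0, np.pi / 2.0, n_in))
    # geometric spacing from ~R/(n_in) up to 5R
    x = np.linspace(0.0, 1.0, n_out + 1)[1:]
    stretch = (np.exp(2.0 * x) - 1.0) / (np.exp(2.0) - 1.0)
    outer = R + 4.0 * R * stretch
    return np.concatenate([inner, outer])


def default_times(t_end: float = 120.0, dt: float = 1.0) -> np.ndarray:
    return np.arange(dt, t_end + dt / 2, dt)


def skin_tumor_preset() -> ModelConfig:
    """Reference parameter set: gold-nanoparticle-laden skin tumor in normal tissue.

    Thermophysical and elastic constants for a 2-cm-radius spherical skin
    carcinoma with absorbed gold nanoparticles embedded in normal skin, with a
    thermal relaxation time of 2 s in both media (biological tissue relaxation
    times are reported in the 1–100 s range).  Thermal moduli are 15 kPa·K⁻¹
    (tumor) and 5 kPa·K⁻¹ (tissue).  The laser source strength is a package
    default chosen so the interface reaches the therapeutic window (see
    :data:`DEFAULT_IRRADIANCE_W_CM2`); it is not part of the reference set.
    """
    tumor = TissueProperties(
        density=1660.0,
        specific_heat=2540.0,
        conductivity=0.778,
        lame_lambda=28571.0,
        lame_mu=0.4,
        thermal_modulus=15.0e3,
        relaxation_time=2.0,
    )
    tissue = TissueProperties(
        density=1000.0,
        specific_heat=3720.0,
        conductivity=0.642,
        lame_lambda=10000.0,
        lame_mu=0.4,
        thermal_modulus=5.0e3,
        relaxation_time=2.0,
    )
    return ModelConfig(
        tumor=tumor,
        tissue=tissue,
        source=LaserSource(),
        geometry=Geometry(tumor_radius=0.02),
        body_temp=37.0,
    )


def _check_tissue(name: str, p: TissueProperties, out: list[str]) -> None:
    if not p.density > 0:
        out.append(f"{name}.density must be positive")
    if not p.specific_heat > 0:
        out.append(f"{name}.specific_heat must be positive")
    if not p.conductivity > 0:
        out.append(f"{name}.conductivity must be positive")
    if not p.lame_lambda + 2.0 * p.lame_mu > 0:
        out.append(f"{name}: lame_lambda + 2*lame_mu must be positive")
    if p.relaxation_time < 0:
        out.append(f"{name}.relaxation_time must be >= 0")
    if p.thermal_modulus < 0:
        out.append(f"{name}.thermal_modulus must be >= 0")


def validate_config(config: ModelConfig) -> list[str]:
    """Check every invariant of a scenario; return one message per violation.

    An empty list means the configuration is valid.  This is a reporting
    operation: it never raises.
    """
    v: list[str] = []
    _check_tissue("tumor", config.tumor, v)
    _check_tissue("tissue", config.tissue, v)

    s = config.source
    if s.irradiance < 0:
        v.append("source.irradiance must be >= 0")
    if s.absorption_coeff < 0:
        v.append("source.absorption_coeff must be >= 0")

    g = config.geometry
    if not g.tumor_radius > 0:
        v.append("geometry.tumor_radius must be positive")
    if g.eval_radii is not None and any(r < 0 for r in g.eval_radii):
        v.append("geometry.eval_radii must be >= 0")
    if g.eval_times is not None:
        t = np.asarray(g.eval_times, dtype=float)
        if t.size and t.min() <= 0:
            v.append("geometry.eval_times must be positive")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            v.append("geometry.eval_times must be strictly increasing")

    if not (0.0 < config.body_temp < 100.0):
        v.append("body_temp must lie in (0, 100) °C")
    if config.perfusion_coeff < 0:
        v.append("perfusion_coeff must be >= 0")

    inv = config.inversion
    if inv.series_terms < 16:
        v.append("inversion.series_terms must be >= 16")
    if not inv.rel_tolerance > 0:
        v.append("inversion.rel_tolerance must be positive")
    if inv.method not in ("fourier", "talbot"):
        v.append("inversion.method must be 'fourier' or 'talbot'")
    if not math.isfinite(inv.contour_shift) or inv.contour_shift <= 0:
        v.append("inversion.contour_shift must be positive")
    return v
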