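"""Laplace-domain semi-analytic solution of the coupled thermoelastic bioheat problem.

Geometry: a homogeneous tumor sphere (medium 1, ``0 <= r <= R``) carrying a
uniform step heat source, embedded in an unbounded homogeneous tissue
(medium 2, ``r >= R``).  In each medium the transformed excess temperature
``theta = T - T0`` and cubical dilatation ``e`` satisfy

    k ∇²θ̄ = a θ̄ + b ē − (1 + τ0 s) Q̄,          a = ρ c_E (s + τ0 s²) [+ w (1+τ0 s)]
    ((λ+2μ) ∇² − ρ s²) ē = γ ∇²θ̄,               b = γ T0 (s + τ0 s²)

Eliminating ``ē`` gives a biquadratic modal operator ∇⁴ − P∇² + Q whose
squared roots carry one *mode* each.  A mode is a joint (θ, e) eigenvector;
its direction is the null vector of the 2×2 dispersion matrix, which stays
well defined in the decoupled limit γ → 0 (the mode degenerates to either a
pure conduction or a pure elastic wave).  Radial shapes are the spherically
symmetric Helmholtz solutions — half-order modified Bessel functions in their
elementary forms ``sinh(mr)/r`` (regular, tumor) and ``exp(-nr)/r``
(decaying, tissue) — normalized to 1 at the interface for overflow safety.

Four interface-continuity conditions (temperature, displacement, heat flux,
radial stress) determine the mode amplitudes A1, A2 (tumor) and B1, B2
(tissue) at every complex frequency s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LaserSource, ModelConfig, TissueProperties, volumetric_power

__all__ = [
    "CharacteristicRoots",
    "InterfaceCoefficients",
    "TransformedFieldSet",
    "biquadratic_coefficients",
    "characteristic_roots",
    "radial_basis_regular",
    "radial_basis_decaying",
    "particular_temperature",
    "assemble_interface_system",
    "solve_coefficients",
    "transformed_fields",
]

_FIELDS = ("theta", "e", "u", "q_r", "sigma_rr")


@dataclass
class CharacteristicRoots:
    """Principal square roots (Re > 0) of the modal operator, both media."""

    m1: complex
    m2: complex
    n1: complex
    n2: complex


@dataclass
class InterfaceCoefficients:
    """Mode amplitudes at one complex frequency, with continuity residuals."""

    A1: complex
    A2: complex
    B1: complex
    B2: complex
    s: complex
    residuals: dict[str, float]


def biquadratic_coefficients(
    props: TissueProperties,
    s: complex,
    T0_kelvin: float,
    coupled: bool = True,
    perfusion: float = 0.0,
) -> tuple[complex, complex]:
    """Coefficients (P, Q) of the modal operator ∇⁴ − P ∇² + Q.

    With ``a = ρ c_E (s + τ0 s²) + w (1 + τ0 s)`` and
    ``b = γ T0 (s + τ0 s²)``:

        P = a/k + ρ s²/(λ+2μ) + b γ / (k (λ+2μ))
        Q = a ρ s² / (k (λ+2μ))

    The coupling contribution to P is dropped when ``coupled`` is false.
    ``perfusion`` is the lumped blood heat-sink coefficient w (W·m⁻³·K⁻¹).
    """
    if np.real(s) <= 0:
        raise ValueError("biquadratic coefficients require Re(s) > 0")
    lam2mu = props.lame_lambda + 2.0 * props.lame_mu
    if lam2mu <= 0:
        raise ValueError("lambda + 2*mu must be positive")
    tau0 = props.relaxation_time
    a = props.density * props.specific_heat * (s + tau0 * s * s)
    a = a + perfusion * (1.0 + tau0 * s)
    b = props.thermal_modulus * T0_kelvin * (s + tau0 * s * s)
    k = props.conductivity
    P = a / k + props.density * s * s / lam2mu
    if coupled:
        P = P + b * props.thermal_modulus / (k * lam2mu)
    Q = a * props.density * s * s / (k * lam2mu)
    return complex(P), complex(Q)


def characteristic_roots(
    P: complex, Q: complex, thermal_sq: complex | None = None
) -> tuple[complex, complex]:
    """Principal square roots (m1, m2) of x² − P x + Q.

    ``m1`` is the root continuously connected to the pure-conduction root
    ``a/k`` in the decoupled limit; ``thermal_sq`` supplies that reference
    value (without it, the larger-|x| root is labeled thermal, which is the
    correct assignment for soft-tissue parameters).  A nearly degenerate
    discriminant is regularized by a relative 1e-8 perturbation of P.
    """
    if Q == 0:
        raise ValueError("degenerate operator: Q must be nonzero")
    disc = P * P - 4.0 * Q
    if abs(disc) < 1e-16 * abs(P) ** 2:
        P = P * (1.0 + 1e-8)
        disc = P * P - 4.0 * Q
    sq = np.sqrt(disc)
    # pick the sign that avoids cancellation in P ± sq
    if (P.conjugate() * sq).real < 0:
        sq = -sq
    x1 = 0.5 * (P + sq)
    x2 = Q / x1
    if thermal_sq is not None:
        if abs(x2 - thermal_sq) < abs(x1 - thermal_sq):
            x1, x2 = x2, x1
    elif abs(x2) > abs(x1):
        x1, x2 = x2, x1

    def principal(x: complex) -> complex:
        m = complex(np.sqrt(x))
        if m.real < 0 or (m.real == 0 and m.imag < 0):
            m = -m
        return m

    return principal(x1), principal(x2)


def _em1(z: np.ndarray) -> np.ndarray:
    """1 - exp(-z), accurate for small z."""
    return -np.expm1(-z)


def _regular_shapes(m: complex, r: np.ndarray, R: float):
    """Normalized regular basis φ = [sinh(mr)/r] / [sinh(mR)/R] and derivatives.

    Returns (φ, φ', φ'/r); all three finite at r = 0.  Written in
    exponent-scaled form so that |m| R up to ~1e4 cannot overflow.
    """
    r = np.asarray(r, dtype=float)
    phi = np.empty(r.shape, dtype=complex)
    dphi = np.empty(r.shape, dtype=complex)
    dphi_r = np.empty(r.shape, dtype=complex)

    denomR = _em1(2.0 * m * R)  # sinh(mR) = e^{mR} * denomR / 2
    inv_norm = 2.0 * R * np.exp(-m * R) / denomR  # 1 / (sinh(mR)/R), scaled

    small = np.abs(m * r) < 1e-2
    if np.any(small):
        rs = r[small]
        z2 = (m * rs) ** 2
        # sinh(mr)/r and its derivative, Maclaurin in (mr)^2
        f = m * (1.0 + z2 / 6.0 + z2 * z2 / 120.0)
        df_r = m**3 * (1.0 / 3.0 + z2 / 30.0 + z2 * z2 / 840.0)
        phi[small] = f * inv_norm
        dphi[small] = df_r * rs * inv_norm
        dphi_r[small] = df_r * inv_norm
    big = ~small
    if np.any(big):
        rb = r[big]
        scale = np.exp(m * (rb - R)) * R / denomR
        e2 = np.exp(-2.0 * m * rb)
        phi[big] = scale * _em1(2.0 * m * rb) / rb
        d = m * (1.0 + e2) / rb - _em1(2.0 * m * rb) / rb**2
        dphi[big] = scale * d
        dphi_r[big] = scale * d / rb
    return phi, dphi, dphi_r


def _decaying_shapes(n: complex, r: np.ndarray, R: float):
    """Normalized decaying basis ψ = exp(-n(r-R)) R/r and derivatives."""
    r = np.asarray(r, dtype=float)
    psi = np.exp(-n * (r - R)) * R / r
    dpsi = -psi * (n + 1.0 / r)
    return psi, dpsi, dpsi / r


def radial_basis_regular(m: complex, r, R: float):
    """φ(m, r): regular (tumor-side) radial basis, equal to 1 at r = R."""
    if np.any(np.asarray(r, dtype=float) < 0):
        raise ValueError("radius must be nonnegative")
    phi, _, _ = _regular_shapes(m, np.atleast_1d(np.asarray(r, dtype=float)), R)
    return phi if np.ndim(r) else complex(phi[0])


def radial_basis_decaying(n: complex, r, R: float):
    """ψ(n, r): decaying (tissue-side) radial basis, equal to 1 at r = R."""
    if np.real(n) <= 0:
        raise ValueError("decaying basis requires Re(n) > 0 (far-field decay)")
    rr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(rr < R) or R <= 0:
        raise ValueError("decaying basis is defined for r >= R > 0")
    psi, _, _ = _decaying_shapes(n, rr, R)
    return psi if np.ndim(r) else complex(psi[0])


def particular_temperature(
    source: LaserSource,
    props: TissueProperties,
    s: complex,
    perfusion: float = 0.0,
) -> complex:
    """Spatially uniform particular temperature of the step source.

    For Q̄ = Q_L/s the particular solution is θ̄_p = (1+τ0 s) Q̄ / a; without
    perfusion this reduces to Q_L/(ρ c_E s²), the transform of the adiabatic
    linear heating ramp Q_L·t/(ρ c_E).
    """
    if np.real(s) <= 0:
        raise ValueError("particular solution requires Re(s) > 0")
    Q_L = volumetric_power(source)
    if Q_L == 0.0:
        return 0.0 + 0.0j
    tau0 = props.relaxation_time
    a = props.density * props.specific_heat * (s + tau0 * s * s)
    a = a + perfusion * (1.0 + tau0 * s)
    return (1.0 + tau0 * s) * (Q_L / s) / a


class _Medium:
    """Per-medium modal data at one complex frequency."""

    def __init__(
        self,
        props: TissueProperties,
        s: complex,
        T0K: float,
        perfusion: float = 0.0,
    ):
        self.props = props
        self.s = s
        lam2mu = props.lame_lambda + 2.0 * props.lame_mu
        tau0 = props.relaxation_time
        self.a = props.density * props.specific_heat * (s + tau0 * s * s)
        self.a = self.a + perfusion * (1.0 + tau0 * s)
        self.b = props.thermal_modulus * T0K * (s + tau0 * s * s)
        self.P, self.Q = biquadratic_coefficients(
            props, s, T0K, coupled=True, perfusion=perfusion
        )
        thermal_sq = self.a / props.conductivity
        self.roots = characteristic_roots(self.P, self.Q, thermal_sq)
        self.lam2mu = lam2mu
        # flux prefactor per the Cattaneo law: q̄ = -k θ̄' / (1 + τ0 s)
        self.flux_coeff = -props.conductivity / (1.0 + tau0 * s)
        self.dirs = [self._mode_direction(m * m) for m in self.roots]

    def _mode_direction(self, x: complex) -> tuple[complex, complex]:
        """(θ, e) null direction of the dispersion matrix at squared root x.

        Rows of the matrix are the transformed heat and motion equations;
        the null vector is taken from the better-conditioned row and scaled
        to unit max-abs component.
        """
        p = self.props
        k = p.conductivity
        row_heat = (k * x - self.a, -self.b)  # (θ, e) coefficients
        row_mot = (p.thermal_modulus * x, -(self.lam2mu * x - p.density * self.s**2))
        # null vector of a single row (α, β) is (-β, α)
        v1 = np.array([-row_heat[1], row_heat[0]])
        v2 = np.array([-row_mot[1], row_mot[0]])
        v = v1 if np.abs(v1).max() >= np.abs(v2).max() else v2
        v = v / v[np.argmax(np.abs(v))]
        return complex(v[0]), complex(v[1])

    def mode_fields(self, j: int, r: np.ndarray, R: float, regular: bool):
        """Unit-amplitude fields of mode j at radii r.

        Returns dict of arrays for θ, e, u, q_r, σ_rr; the stress uses the
        Helmholtz identity φ'' = x φ − 2 φ'/r to avoid second derivatives.
        """
        m = self.roots[j]
        x = m * m
        d_theta, d_e = self.dirs[j]
        if regular:
            phi, dphi, dphi_r = _regular_shapes(m, r, R)
        else:
            phi, dphi, dphi_r = _decaying_shapes(m, r, R)
        p = self.props
        u = (d_e / x) * dphi
        sigma = (self.lam2mu * d_e - p.thermal_modulus * d_theta) * phi
        sigma = sigma - 4.0 * p.lame_mu * (d_e / x) * dphi_r
        return {
            "theta": d_theta * phi,
            "e": d_e * phi,
            "u": u,
            "q_r": self.flux_coeff * d_theta * dphi,
            "sigma_rr": sigma,
        }


def _build_media(config: ModelConfig, s: complex) -> tuple[_Medium, _Medium]:
    T0K = config.body_temp_kelvin
    w = config.perfusion_coeff
    return (
        _Medium(config.tumor, s, T0K, perfusion=w),
        _Medium(config.tissue, s, T0K, perfusion=w),
    )


def assemble_interface_system(
    config: ModelConfig,
    roots: CharacteristicRoots | None,
    s: complex,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuity system M @ (A1, A2, B1, B2) = rhs at r = R.

    Rows enforce continuity of θ̄, ū, q̄_r and σ̄_rr across the interface in
    the interface-normalized mode bases; the right-hand side carries the
    uniform particular solution of the heated tumor (−θ̄_p in the temperature
    row, +γ₁θ̄_p in the stress row, since σ̄_p = −γ₁θ̄_p).

    ``roots`` may be supplied for inspection symmetry but the modal data are
    rebuilt from the configuration; pass None normally.
    """
    med1, med2 = _build_media(config, s)
    R = config.geometry.tumor_radius
    rR = np.array([R], dtype=float)
    M = np.zeros((4, 4), dtype=complex)
    for j in (0, 1):
        f1 = med1.mode_fields(j, rR, R, regular=True)
        f2 = med2.mode_fields(j, rR, R, regular=False)
        for i, name in enumerate(("theta", "u", "q_r", "sigma_rr")):
            M[i, j] = f1[name][0]
            M[i, 2 + j] = -f2[name][0]
    theta_p = particular_temperature(
        config.source, config.tumor, s, perfusion=config.perfusion_coeff
    )
    rhs = np.array(
        [-theta_p, 0.0, 0.0, config.tumor.thermal_modulus * theta_p],
        dtype=complex,
    )
    return M, rhs


def solve_coefficients(
    system: tuple[np.ndarray, np.ndarray], s: complex | None = None
) -> InterfaceCoefficients:
    """Row-equilibrated direct solve of the 4×4 interface system."""
    M, rhs = system
    scale = np.max(np.abs(M), axis=1)
    scale[scale == 0.0] = 1.0
    Ms = M / scale[:, None]
    rs = rhs / scale
    try:
        sol = np.linalg.solve(Ms, rs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular interface system at s={s}: {exc}"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(f"non-finite interface solution at s={s}")
    resid = np.abs(Ms @ sol - rs)
    den = max(float(np.max(np.abs(rs))), float(np.max(np.abs(sol))), 1e-300)
    residuals = {
        name: float(resid[i]) / den
        for i, name in enumerate(("theta", "u", "q_r", "sigma_rr"))
    }
    return InterfaceCoefficients(
        A1=complex(sol[0]),
        A2=complex(sol[1]),
        B1=complex(sol[2]),
        B2=complex(sol[3]),
        s=complex(s) if s is not None else 0j,
        residuals=residuals,
    )


class _SolutionAtS:
    """Fully determined Laplace-domain solution at one complex frequency."""

    def __init__(self, config: ModelConfig, s: complex):
        self.s = s
        self.config = config
        self.med1, self.med2 = _build_media(config, s)
        self.R = config.geometry.tumor_radius
        self.theta_p = particular_temperature(
            config.source, config.tumor, s, perfusion=config.perfusion_coeff
        )
        M = np.zeros((4, 4), dtype=complex)
        rR = np.array([self.R], dtype=float)
        for j in (0, 1):
            f1 = self.med1.mode_fields(j, rR, self.R, regular=True)
            f2 = self.med2.mode_fields(j, rR, self.R, regular=False)
            for i, name in enumerate(("theta", "u", "q_r", "sigma_rr")):
                M[i, j] = f1[name][0]
                M[i, 2 + j] = -f2[name][0]
        rhs = np.array(
            [-self.theta_p, 0.0, 0.0, config.tumor.thermal_modulus * self.theta_p],
            dtype=complex,
        )
        self.coeffs = solve_coefficients((M, rhs), s)
        self.roots = CharacteristicRoots(
            m1=self.med1.roots[0],
            m2=self.med1.roots[1],
            n1=self.med2.roots[0],
            n2=self.med2.roots[1],
        )

    def continuity_residuals(self) -> dict[str, float]:
        """Relative jumps of the five continuity quantities at r = R."""
        rR = np.array([self.R], dtype=float)
        t_side = self.sample(rR, side="tumor")
        n_side = self.sample(rR, side="tissue")
        out = {}
        for name in _FIELDS:
            x1, x2 = t_side[name][0], n_side[name][0]
            den = max(abs(x1), abs(x2), 1e-300)
            out[name] = abs(x1 - x2) / den
        return out

    def sample(self, r: np.ndarray, side: str | None = None) -> dict[str, np.ndarray]:
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("radius must be nonnegative")
        out = {name: np.zeros(r.shape, dtype=complex) for name in _FIELDS}
        if side is None:
            in_tumor = r <= self.R
        elif side == "tumor":
            in_tumor = np.ones(r.shape, dtype=bool)
        else:
            in_tumor = np.zeros(r.shape, dtype=bool)
        amps = (self.coeffs.A1, self.coeffs.A2, self.coeffs.B1, self.coeffs.B2)
        if np.any(in_tumor):
            rt = r[in_tumor]
            for j, amp in enumerate(amps[:2]):
                f = self.med1.mode_fields(j, rt, self.R, regular=True)
                for name in _FIELDS:
                    out[name][in_tumor] += amp * f[name]
            out["theta"][in_tumor] += self.theta_p
            out["sigma_rr"][in_tumor] += (
                -self.config.tumor.thermal_modulus * self.theta_p
            )
        if np.any(~in_tumor):
            rn = r[~in_tumor]
            for j, amp in enumerate(amps[2:]):
                f = self.med2.mode_fields(j, rn, self.R, regular=False)
                for name in _FIELDS:
                    out[name][~in_tumor] += amp * f[name]
        return out


class TransformedFieldSet:
    """Evaluator of the five Laplace-domain fields at any (r, s).

    Radii at or inside the tumor radius use the regular tumor branch (plus
    the uniform particular solution); larger radii use the decaying tissue
    branch.  Solutions are cached per complex frequency so that inversion
    nodes shared between radii are solved once.
    """

    def __init__(self, config: ModelConfig, variant: str | None = None):
        self.config = config
        self.variant = variant or config.model_variant.value
        self._cache: dict[complex, _SolutionAtS] = {}

    def at(self, s: complex) -> _SolutionAtS:
        s = complex(s)
        if np.real(s) <= 0:
            raise ValueError("field evaluation requires Re(s) > 0")
        sol = self._cache.get(s)
        if sol is None:
            sol = _SolutionAtS(self.config, s)
            if len(self._cache) > 4096:
                self._cache.clear()
            self._cache[s] = sol
        return sol

    def sample(self, r, s: complex) -> dict[str, np.ndarray]:
        """All five fields at radii ``r`` (array) and one frequency ``s``."""
        return self.at(s).sample(np.asarray(r, dtype=float))


def transformed_fields(config: ModelConfig, variant: str | None = None) -> TransformedFieldSet:
    """Build the Laplace-domain evaluator for a scenario."""
    return TransformedFieldSet(config, variant)
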