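# Methods

This note documents the model, the numerical choices and the design
decisions behind `thermotumor`, and states what the verification suite does
and does not demonstrate.

## Physical model and assumptions

A solid tumor sphere of radius `R` (medium 1) is embedded in an unbounded
normal tissue (medium 2). Both media are homogeneous, isotropic and linear
thermoelastic with temperature-independent properties. Nanoparticles
confined to the tumor absorb laser light, giving a spatially uniform
volumetric source `Q_L = α I` (α in cm⁻¹ times I in W·cm⁻² is W·cm⁻³; the
single factor 10⁶ converts to W·m⁻³) switched on as a Heaviside step at
`t = 0` and constant thereafter. Spherical symmetry reduces the problem to
the radial coordinate: `u = (u_r, 0, 0)` and `curl u = 0`.

Heat conduction follows the Cattaneo–Vernotte law
`q + τ₀ ∂q/∂t = −k ∇T`, which gives heat a finite propagation speed
`c_th = √(k/(ρ c_E τ₀))` — about 0.3 mm/s for the reference constants —
and the temperature couples to the mechanical dilatation `e = ∇·u` through
the thermal modulus `γ = α_t(3λ + 2μ)` (Lord–Shulman generalized
thermoelasticity). Working with the excess temperature `θ = T − T₀` makes
the initial conditions homogeneous and cancels the static `T₀` terms from
the stress at the interface. The governing equations per medium are

    k ∇²θ = (∂_t + τ₀ ∂_t²)(ρ c_E θ + γ T₀ e) − (1 + τ₀ ∂_t) Q
    (λ + 2μ) ∇e − γ ∇θ = ρ ∂²u/∂t²

with `T₀` the absolute body temperature (310.15 K) where it multiplies γ.
Blood perfusion and metabolic heat are omitted from the generalized model —
defensible for small superficial skin carcinomas, where both are low; a
lumped perfusion sink `w_b ρ_b c_b (T − T₀)` is retained as an option in the
classical Pennes comparison model only. Temperature, radial displacement,
radial heat flux and radial stress `σ_rr = λe + 2μ ∂u/∂r − γθ` are
continuous at `r = R`; the tumor branch is regular at the origin and the
tissue branch decays as `r → ∞`.

### The step source's impulsive term

`(1 + τ₀ ∂_t)` acting on the Heaviside source contributes `τ₀ Q_L δ(t)`.
In the Laplace domain this is automatic (`Q̄ = Q_L/s`, multiplied by
`1 + τ₀ s`); in the time domain it is equivalent to the initial rate
`θ̇(0⁺) = Q_L/(ρ c_E)` in the heated region, which is how the
finite-difference solver realizes it. The spatially uniform particular
solution is `θ̄_p = (1 + τ₀ s) Q̄ / a = Q_L/(ρ c_E s²)` — the transform of
the adiabatic heating ramp `Q_L t/(ρ c_E)` — with zero particular
dilatation, displacement and flux, and particular stress `−γ θ̄_p`.

## Laplace-domain modal construction

Transforming with homogeneous initial conditions and writing
`a = ρ c_E (s + τ₀ s²)` (plus `w(1 + τ₀ s)` when a perfusion coefficient
`w` is active) and `b = γ T₀ (s + τ₀ s²)`:

    k ∇²θ̄ = a θ̄ + b ē − (1 + τ₀ s) Q̄            (heat)
    ((λ+2μ) ∇² − ρ s²) ē = γ ∇²θ̄                 (motion, divergence form)

Applying the motion operator to the heat equation and eliminating `ē`:

    k ∇²((λ+2μ)∇² − ρs²) θ̄ − a ((λ+2μ)∇² − ρs²) θ̄ − b γ ∇²θ̄
        = −(1 + τ₀ s) ((λ+2μ)∇² − ρs²) Q̄ .

Dividing by `k(λ+2μ)` gives the modal operator `∇⁴ − P∇² + Q` with

    P = a/k + ρs²/(λ+2μ) + b γ/(k (λ+2μ)),     Q = a ρ s² / (k (λ+2μ)).

For a uniform source the right-hand side reduces to
`(1+τ₀s) ρs² Q̄/(k(λ+2μ))`, reproducing `θ̄_p` above. With γ = 0 the
operator factors exactly into the conduction root `a/k` and the elastic
root `ρs²/(λ+2μ)` — the basis of the decoupling checks.

The two squared roots of `x² − Px + Q` are computed with the
cancellation-free quadratic formula (`x₁ = (P + sign-matched √disc)/2`,
`x₂ = Q/x₁`); a nearly vanishing discriminant is regularized by a relative
`1e−8` perturbation of `P`. The root continuously connected to `a/k` is
labeled thermal. Each root carries a joint (θ, e) **mode direction**, the
null vector of the 2×2 dispersion matrix

    [ kx − a        −b                  ]
    [ γx            −((λ+2μ)x − ρs²)    ]

taken from the better-conditioned row and scaled to unit max-abs component.
This parametrization stays well defined in the γ → 0 limit, where the modes
degenerate into a pure conduction wave (e-component → 0) and a pure elastic
wave (θ-component → 0); the 4×4 interface system then block-diagonalizes
instead of becoming singular, so no special-casing is needed anywhere.

Radial shapes are the spherically symmetric Helmholtz solutions. The
half-order modified Bessel functions reduce to elementary forms —
`I_{1/2}(z)/√r ∝ sinh(mr)/r` (regular) and `K_{1/2}(z)/√r ∝ e^{−nr}/r`
(decaying) — which the code uses directly, normalized to 1 at `r = R` and
evaluated through exponent-scaled hyperbolic expressions (`expm1`-based) so
that `|m|R` up to ~10⁴ neither overflows nor loses accuracy; a Maclaurin
branch covers `|mr| < 0.01`, including the origin. Derivatives needed for
displacement, flux and stress come from the same scaled forms; second
derivatives are eliminated with the Helmholtz identity
`φ'' = x φ − 2φ'/r`. Per unit mode amplitude, with direction `(d_θ, d_e)`
and shape φ:

    θ̄ = d_θ φ,   ē = d_e φ,   ū = (d_e/x) φ',
    q̄_r = −k d_θ φ'/(1 + τ₀ s),
    σ̄_rr = ((λ+2μ) d_e − γ d_θ) φ − 4μ (d_e/x) φ'/r .

The four continuity rows (θ, u, q_r, σ_rr at `r = R`) are assembled in the
interface-normalized bases, row-equilibrated and solved directly; the
solution's continuity residuals are re-evaluated and exposed (they sit at
machine precision, far below the 1e−9 requirement, for every inversion
node). Solutions are cached per complex frequency, so the s-nodes shared by
all radii and all five fields are solved exactly once.

### Heat-flux constitutive form

Transforming the Cattaneo law gives `q̄ = −k θ̄′/(1 + τ₀ s)`, and that is
what the package reports. The alternative placement `q̄ = −k(1+τ₀s) θ̄′`
circulates in parts of the hyperbolic-bioheat literature but is not the
transform of the flux law underlying the model; because both media share
the same τ₀ here, the factor cancels from the interface condition either
way, so the choice affects only the magnitude of the reported flux, not the
temperature/stress solution.

## Numerical inverse Laplace transform

The default inverter is the Fourier-series (Durbin) method on the shifted
Bromwich line `s_k = c + ikπ/T`, with `c = 4.6/t_max`, half-period
`T = 2 t_max` and `N = 200` terms, plus three refinements:

* **Time blocking.** The plain series degrades for `t ≪ t_max`, so times
  are grouped into blocks with `t_max/t ≤ 8` and each block gets its own
  node set. Node sets cost only linear solves, which are shared across all
  radii and fields.
* **Wynn-epsilon acceleration** of the last 99 complex partial sums —
  equivalent to Padé resummation of the Fourier series in
  `z = e^{iπt/T}` — with stalled differences poisoned to ∞ so converged
  (e.g. identically zero) series fall back to the plain sum.
* **Alias correction.** The periodization alias `e^{−2cT} f(t + 2T)` is
  estimated by a second, unaccelerated pass with its own larger period and
  subtracted. (Subtracting a same-period re-evaluation would be
  algebraically a no-op, since the discrete series is exactly periodic.)

On six closed-form pairs spanning ramps, exponentials, a constant, a
cosine and an algebraic branch point, the scaled error
(`max|f̂−f| / max|f|` over t ∈ [1, 120] s) is ~1e−8 or better — the
double-precision floor for several pairs — against a 1e−5 requirement.
Because errors sit at that floor, the "refining N must not increase the
error" property is checked with a small additive roundoff allowance
(1e−11). A per-point error estimate (difference between two epsilon window
depths, or the last-term magnitude when acceleration is off) drives
convergence warnings against the configured tolerance; a conjugate-symmetry
probe (`F(s̄) = conj F(s)` for real signals) is reported as the imaginary
residue of the reconstruction. The fixed-Talbot rule is implemented as an
independent cross-check; its order is clamped to M ≤ 56 because the contour
weights grow like `e^{2M/5}` and larger rules lose more to double-precision
cancellation than they gain in truncation. Talbot is not used on transforms
with imaginary-axis poles or jumps, where the `cross_check` helper flags
the disagreement. All inversion is deterministic.

## Reduced models and the default scenario

`CATTANEO_VERNOTTE` zeroes both thermal moduli (keeping τ₀);
`CLASSICAL_PENNES` additionally zeroes τ₀ and honors the perfusion
coefficient. Both run through the same modal pipeline. The full model's
γ = 0 limit is verified to 1e−12 against an *independently coded* 2×2
composite-sphere conduction solution (`conduction.py`), and the CV → Pennes
limit converges linearly in τ₀ as it should.

The coupling strength for the reference constants is large:
`δ = γ²T₀/(ρ c_E (λ+2μ)) ≈ 0.58` in the tumor, so the quasi-static
dilatation raises the effective heat capacity by the factor `1 + δ ≈ 1.58`.
Before any wavefront arrives from the interface the tumor interior heats
along the exact ramp `Q_L t/(ρ c_E (1+δ))`, a closed form the tests check
to 1e−5. This is also why the thermoelastic model predicts visibly lower
tumor temperatures than the conduction-only variants.

The reference parameter set (`skin_tumor_preset`) uses literature soft-
tissue constants for a nanoparticle-laden skin tumor (ρ = 1660 kg·m⁻³,
c_E = 2540 J·kg⁻¹K⁻¹, k = 0.778 W·m⁻¹K⁻¹, λ = 28 571 Pa, μ = 0.4 Pa,
τ₀ = 2 s) and normal tissue (1000, 3720, 0.642, 10 000 Pa, 0.4 Pa, 2 s),
with `R = 0.02 m` and `T₀ = 37 °C`. Two interpretation notes: the elastic
rows labeled "linear thermal expansion" in kPa in the source tables are
dimensionally consistent only as thermal moduli, so the preset sets
γ₁ = 15 kPa·K⁻¹ and γ₂ = 5 kPa·K⁻¹ (γ is directly settable, and
`thermal_modulus()` serves users who have α_t instead); and μ = 0.4 Pa is
implemented exactly as tabulated even though 0.4 kPa would be more
plausible for tissue — both Lamé constants are ordinary configuration
fields, so either reading is one line away. The laser irradiance of the
reference tables is never stated; the package default
(0.08908548 W·cm⁻² at α = 10 cm⁻¹, i.e. Q_L ≈ 8.909e5 W·m⁻³) is the
package's own choice, fixed once by bisection on the interface temperature
so that `T(R, 80 s) = 42.5 °C`, the midpoint of the 40–45 °C therapeutic
window, and recorded in `config.py`.

## Arrhenius damage

Damage is integrated in the time domain on the inverted temperature
history, `Ω(t) = ∫₀ᵗ B e^{−E_a/(R_g T)} dt′` with `T` in kelvin and
defaults `B = 3.1e98 s⁻¹`, `E_a = 6.28e5 J·mol⁻¹`, `R_g = 8.313`.
The exponent is the standard Moritz–Henriques activated-kinetics form
`−E_a/(R_g T)`; the sign-flipped variant that sometimes appears in print
would overflow astronomically and is recorded here as an erratum note.
The rate is evaluated as `exp(ln B − E_a/(R_g T))` so the extreme magnitude
of `B` cannot overflow intermediates. Trapezoidal quadrature on the
supplied grid is exact for constant temperature (the closed form
`B t e^{−E_a/(R_g T)}` is reproduced to ~1e−15) and second-order otherwise.
The default evaluation radius is the first grid point on the
normal-tissue side of the interface — the healthy location at greatest
risk. On the default scenario Ω(80 s) ≈ 7e−5: far below the Ω = 1 injury
threshold, and (for what it is worth, given the uncalibrated source) the
same order of magnitude as published damage tabulations for this geometry.

## Finite-difference verification solver

`fdtd.py` integrates the same coupled equations explicitly on a staggered
uniform grid over `[0, 10R]`: displacement on faces, temperature and
dilatation on cell centers, exact finite-volume weights for the spherical
divergences, conservative stress form `ρü = ∂σ_rr/∂r + 2(σ_rr−σ_θθ)/r`,
harmonic-mean conductivity at the interface face (which falls exactly on a
face for the default grids), central second-order time integration for
both fields (forward Euler for the parabolic τ₀ = 0 limit), and the
consistent initial kick for the step source. The flux output integrates
the Cattaneo ODE alongside. The time step honors the elastic CFL
(`c_el = √((λ+2μ)/ρ) ≈ 4.15 m/s` dominates), the thermal-wave CFL and the
diffusive limit, with safety factor 0.7 — the largest found stable for the
strongly coupled reference problem, where the γ coupling tightens the plain
elastic limit.

Outer boundary: the temperature clamp is rigorous (the thermal wave never
reaches `10R` within the simulated window), but elastic waves cross the
domain in ~50 ms, so a displacement clamp is *not* justified by finite
propagation speed. It is justified differently: at the driving frequencies
the elastic wavelength (~80 m) dwarfs the domain, the elastic response is
quasi-static, and the outer condition barely matters — a rigid clamp and a
zero-dilatation outflow condition (`∂(r²u)/∂r = 0`, the correct
quasi-static far field) change the temperature by ~0.02 %. Both are
implemented; the clamp is the default and the equivalence is a test.

Against the semi-analytic solution the FD solver agrees to 1.5 % (L∞,
relative to the peak rise) at `dr = 2 mm` and 0.78 % at `dr = 1 mm` over
t ∈ [5, 80] s at r ∈ {R/2, R, 2R}; nested-grid Richardson order is ≈ 1.3
(the pure-Fourier single-medium configuration converges at order 2; the
interface averaging is first-order). This two-sided agreement between
entirely independent discretizations is the package's central correctness
gate. The verification problem sizes (grids of 50–200 cells, 16 sampled
times to 80 s) were chosen as the smallest that put the comparison safely
inside its 2 % gate while keeping the whole suite quick to run.

## What the checks do and do not show

The verification suite establishes internal correctness — the modal
construction solves the stated equations (FD cross-check), the decoupled
limits are exact (independent conduction solution), the inversion is
accurate (closed-form pairs, Talbot, mpmath oracles) and the qualitative
physics is right (causal wavefronts, monotone heating, linearity in the
source, exact adiabatic ramps). It does not validate the model against
real tissue: properties are constant (no temperature dependence, no phase
change), the source is uniform and step-like (no beam profile, no optical
attenuation), perfusion and metabolism are neglected in the main model,
the geometry is a perfect sphere in an infinite medium, and the linear
thermoelastic description is itself questionable at the strain levels the
reference constants imply (γθ/(λ+2μ) is order one for a 10 K rise).

One reported qualitative trend is *contradicted* by the governing
equations: the claim that a larger relaxation time lowers the temperature
near the heat source and raises it farther away. The C-V dispersion
relation forces the opposite — raising τ₀ slows the thermal wave,
traps heat at and inside the interface and cools every tissue radius —
monotonically across τ₀ ∈ [0.5, 100] s in our sweeps, with the
pre-wavefront interior exactly τ₀-independent. The package asserts the
correct signs in its property tests and keeps a separate acceptance test
documenting the discrepancy with the reported trend.

## Degenerate inputs and tie-breaks

Zero source: all amplitudes vanish identically and the pipeline returns
the body temperature exactly (the epsilon accelerator's stalled-difference
guard keeps all-zero series at zero). Double modal roots: relative 1e−8
perturbation of P. Singular interface systems: reported with the offending
`s` (none occur on the default contours). `Q = 0` (static limit) and
non-positive `Re(s)` are rejected with clear messages. Radii exactly at
`R` evaluate on the tumor side; the tissue-side value agrees to inversion
tolerance and both are exposed for testing.
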