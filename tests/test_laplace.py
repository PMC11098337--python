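import mpmath as mp
import numpy as np
import pytest

from thermotumor.config import LaserSource, skin_tumor_preset
from thermotumor.inversion import _nodes
from thermotumor.laplace import (
    assemble_interface_system,
    biquadratic_coefficients,
    characteristic_roots,
    particular_temperature,
    radial_basis_decaying,
    radial_basis_regular,
    solve_coefficients,
    transformed_fields,
)

T0K = 310.15


class TestBiquadratic:
    def test_decoupled_factorization(self, preset):
        """With gamma = 0 the operator factors into conduction x elasticity."""
        p = preset.tumor.model_copy()
        p.thermal_modulus = 0.0
        s = 1.0 + 0.0j
        P, Q = biquadratic_coefficients(p, s, T0K)
        a_k = p.density * p.specific_heat * (s + p.relaxation_time * s * s) / p.conductivity
        el = p.density * s * s / (p.lame_lambda + 2 * p.lame_mu)
        assert P == pytest.approx(a_k + el, rel=1e-14)
        assert Q == pytest.approx(a_k * el, rel=1e-14)

    def test_fourier_limit(self, preset):
        """tau0 = 0 reduces the thermal part of P to rho c s / k."""
        p = preset.tumor.model_copy()
        p.thermal_modulus = 0.0
        p.relaxation_time = 0.0
        s = 2.0 + 0.0j
        P, _ = biquadratic_coefficients(p, s, T0K)
        el = p.density * s * s / (p.lame_lambda + 2 * p.lame_mu)
        assert P - el == pytest.approx(
            p.density * p.specific_heat * s / p.conductivity, rel=1e-14
        )

    def test_roots_satisfy_quadratic(self, preset):
        """Reference tumor parameters: both modal roots have tiny residual."""
        P, Q = biquadratic_coefficients(preset.tumor, 1.0 + 0j, T0K)
        m1, m2 = characteristic_roots(P, Q)
        for m in (m1, m2):
            x = m * m
            resid = abs(x * x - P * x + Q) / max(abs(x * x), abs(Q))
            assert resid < 1e-10

    def test_nonpositive_real_part_rejected(self, preset):
        with pytest.raises(ValueError):
            biquadratic_coefficients(preset.tumor, -1.0 + 0j, T0K)


class TestCharacteristicRoots:
    def test_factored_quadratic(self):
        m1, m2 = characteristic_roots(5.0 + 0j, 6.0 + 0j)
        assert sorted([m1.real**2, m2.real**2]) == pytest.approx([2.0, 3.0])

    def test_decoupling_identity(self, preset):
        """gamma = 0: thermal and elastic squared roots are known in closed form."""
        p = preset.tumor.model_copy()
        p.thermal_modulus = 0.0
        s = 1.0 + 0.0j
        P, Q = biquadratic_coefficients(p, s, T0K)
        a_k = p.density * p.specific_heat * (1 + p.relaxation_time) / p.conductivity
        m1, m2 = characteristic_roots(P, Q, thermal_sq=a_k)
        assert m1 * m1 == pytest.approx(a_k, rel=1e-12)
        assert m2 * m2 == pytest.approx(
            p.density / (p.lame_lambda + 2 * p.lame_mu), rel=1e-12
        )

    def test_vieta_identities_random(self):
        """Sum/product of squared roots reproduce (P, Q) on 1000 random draws."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            P = complex(*rng.normal(0, 10, 2))
            Q = complex(*rng.normal(0, 10, 2))
            if abs(Q) < 1e-6:
                continue
            m1, m2 = characteristic_roots(P, Q)
            x1, x2 = m1 * m1, m2 * m2
            assert abs(x1 + x2 - P) <= 1e-12 * max(abs(P), abs(x1), abs(x2))
            assert abs(x1 * x2 - Q) <= 1e-12 * max(abs(Q), abs(x1 * x2))
            assert m1.real >= 0 and m2.real >= 0


class TestRadialBases:
    R = 0.02

    def test_normalization_at_interface(self):
        for m in (3.0 + 0j, 200.0 + 40j, 5e3 + 1e3j):
            assert radial_basis_regular(m, self.R, self.R) == pytest.approx(1.0)
            assert radial_basis_decaying(m, self.R, self.R) == pytest.approx(1.0)

    def test_small_argument_limit_is_one(self):
        """As m -> 0, sinh(mr)/r / (sinh(mR)/R) -> 1 at every radius."""
        for r in (0.0, 0.004, 0.013, 0.02):
            v = radial_basis_regular(1e-8 + 0j, r, self.R)
            assert v == pytest.approx(1.0, rel=1e-10)

    def test_regular_against_half_order_bessel(self):
        """phi equals I_{1/2}(mr)/sqrt(r) normalized at R (mpmath oracle)."""
        m = 37.0 + 11.0j
        for r in (0.003, 0.011, 0.019):
            shape = lambda x: mp.besseli(mp.mpf(1) / 2, m * x) / mp.sqrt(x)
            expected = complex(shape(r) / shape(self.R))
            assert radial_basis_regular(m, r, self.R) == pytest.approx(
                expected, rel=1e-12
            )

    def test_regular_sinh_value(self):
        # m=1, r=2, R=1 -> sinh(2)/2 / sinh(1)
        v = radial_basis_regular(1.0 + 0j, 2.0, 1.0)
        assert v == pytest.approx(np.sinh(2.0) / 2.0 / np.sinh(1.0), rel=1e-14)

    def test_decaying_against_half_order_bessel(self):
        """psi equals K_{1/2}(nr)/sqrt(r) normalized at R (closed form)."""
        n = 55.0 + 7.0j
        for r in (0.021, 0.05, 0.11):
            shape = lambda x: mp.besselk(mp.mpf(1) / 2, n * x) / mp.sqrt(x)
            expected = complex(shape(r) / shape(self.R))
            assert radial_basis_decaying(n, r, self.R) == pytest.approx(
                expected, rel=1e-12
            )

    def test_decaying_closed_form(self):
        n = 80.0
        assert radial_basis_decaying(n + 0j, 2 * self.R, self.R) == pytest.approx(
            np.exp(-n * self.R) / 2.0, rel=1e-14
        )

    def test_decaying_monotone_for_real_n(self):
        r = np.linspace(self.R, 10 * self.R, 50)
        v = np.abs(radial_basis_decaying(12.0 + 0j, r, self.R))
        assert np.all(np.diff(v) < 0)

    def test_overflow_safety_huge_arguments(self):
        """|m| R up to ~1e4 wavelengths must not overflow either basis."""
        m = 5.0e5 + 1e5j  # |m| * R = 1e4
        r = np.linspace(0, self.R, 7)
        v = radial_basis_regular(m, r, self.R)
        assert np.all(np.isfinite(v))
        assert abs(v[-1] - 1.0) < 1e-12
        w = radial_basis_decaying(m, np.linspace(self.R, 5 * self.R, 7), self.R)
        assert np.all(np.isfinite(w))

    def test_decaying_requires_positive_real_part(self):
        with pytest.raises(ValueError):
            radial_basis_decaying(-3.0 + 0j, 0.05, self.R)


class TestParticularSolution:
    def test_zero_source(self, preset):
        src = LaserSource(irradiance=0.0)
        assert particular_temperature(src, preset.tumor, 1.0 + 0j) == 0.0

    def test_closed_form(self, preset):
        """theta_p = Q_L / (rho c s^2): transform of the adiabatic ramp."""
        src = preset.source
        s = 0.3 + 0.8j
        Q_L = src.volumetric_power
        rc = preset.tumor.density * preset.tumor.specific_heat
        assert particular_temperature(src, preset.tumor, s) == pytest.approx(
            Q_L / (rc * s * s), rel=1e-12
        )

    def test_ramp_inversion(self, preset):
        """Inverting theta_p reproduces Q_L t / (rho c) at t = 60 s."""
        from thermotumor.inversion import invert

        src = preset.source
        rc = preset.tumor.density * preset.tumor.specific_heat
        f = invert(lambda s: particular_temperature(src, preset.tumor, s), [60.0])
        assert f[0] == pytest.approx(src.volumetric_power * 60.0 / rc, rel=1e-8)


class TestInterfaceSystem:
    def test_zero_source_zero_rhs(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.source.irradiance = 0.0
        _, rhs = assemble_interface_system(cfg, None, 1.0 + 0.5j)
        assert np.all(rhs == 0)

    def test_residuals_small_across_s(self, preset):
        """Solving then re-evaluating continuity gives < 1e-9 relative jumps."""
        fs = transformed_fields(preset)
        for s in (0.04 + 0j, 1.0 + 2.0j, 0.1 + 5.0j, 3.0 + 0.3j):
            res = fs.at(s).continuity_residuals()
            for name in ("theta", "u", "q_r", "sigma_rr"):
                assert res[name] < 1e-9, (s, name, res)

    def test_residuals_at_inversion_nodes(self, preset):
        """Continuity holds at every node the default inversion actually uses."""
        fs = transformed_fields(preset)
        s_nodes, _, _ = _nodes(120.0, preset.inversion)
        for s in s_nodes[:: len(s_nodes) // 20]:
            res = fs.at(complex(s)).continuity_residuals()
            assert max(res[n] for n in ("theta", "u", "q_r", "sigma_rr")) < 1e-9

    def test_solve_zero_rhs_gives_zero(self, preset):
        M, _ = assemble_interface_system(preset, None, 2.0 + 1.0j)
        c = solve_coefficients((M, np.zeros(4, dtype=complex)), 2.0 + 1.0j)
        assert c.A1 == c.A2 == c.B1 == c.B2 == 0

    def test_solve_scales_linearly(self, preset):
        M, rhs = assemble_interface_system(preset, None, 1.0 + 0.2j)
        c1 = solve_coefficients((M, rhs), 1.0)
        c3 = solve_coefficients((M, 3.0 * rhs), 1.0)
        for a, b in zip((c1.A1, c1.A2, c1.B1, c1.B2), (c3.A1, c3.A2, c3.B1, c3.B2)):
            assert b == pytest.approx(3.0 * a, rel=1e-12)

    def test_solver_matches_dense_inverse_on_random_systems(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            M = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
            rhs = rng.normal(size=4) + 1j * rng.normal(size=4)
            c = solve_coefficients((M, rhs), 0.0)
            direct = np.linalg.inv(M) @ rhs
            got = np.array([c.A1, c.A2, c.B1, c.B2])
            assert np.max(np.abs(got - direct)) < 1e-12 * max(1.0, np.max(np.abs(direct)))

    def test_singular_system_names_s(self):
        M = np.zeros((4, 4), dtype=complex)
        with pytest.raises(np.linalg.LinAlgError, match="3j"):
            solve_coefficients((M, np.ones(4, dtype=complex)), 2.0 + 3.0j)


class TestTransformedFields:
    def test_zero_source_all_fields_vanish(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.source.irradiance = 0.0
        fs = transformed_fields(cfg)
        r = np.array([0.0, 0.01, 0.02, 0.05])
        vals = fs.sample(r, 0.7 + 1.1j)
        for name, v in vals.items():
            assert np.all(v == 0), name

    def test_temperature_continuous_at_interface(self, preset):
        fs = transformed_fields(preset)
        R = preset.geometry.tumor_radius
        sol = fs.at(0.9 + 1.7j)
        t1 = sol.sample(np.array([R]), side="tumor")["theta"][0]
        t2 = sol.sample(np.array([R]), side="tissue")["theta"][0]
        assert abs(t1 - t2) / abs(t1) < 1e-9

    def test_tissue_branch_decays(self, preset):
        fs = transformed_fields(preset)
        R = preset.geometry.tumor_radius
        for s in (0.05 + 0j, 0.5 + 0j, 2.0 + 0j):
            v2 = abs(fs.sample(np.array([2 * R]), s)["theta"][0])
            v5 = abs(fs.sample(np.array([5 * R]), s)["theta"][0])
            assert v5 < v2

    def test_far_field_dominated_by_slowest_decay(self, preset):
        """|theta(r)| <= |theta(R)|·|psi(n_min, r)| outside the tumor."""
        fs = transformed_fields(preset)
        R = preset.geometry.tumor_radius
        for s in (0.1 + 0j, 0.3 + 1.0j, 2.0 + 0.5j):
            sol = fs.at(s)
            n_min = min((sol.roots.n1, sol.roots.n2), key=lambda z: z.real)
            thR = abs(sol.sample(np.array([R]), side="tissue")["theta"][0])
            for r in (1.5 * R, 3 * R, 8 * R):
                th = abs(sol.sample(np.array([r]))["theta"][0])
                bound = thR * abs(radial_basis_decaying(n_min, r, R))
                assert th <= bound * (1 + 1e-9)

    def test_decoupled_temperature_ignores_elastic_moduli(self, preset):
        """gamma = 0: perturbing the Lame constants leaves theta unchanged."""
        base = preset.model_copy(deep=True)
        base.tumor.thermal_modulus = 0.0
        base.tissue.thermal_modulus = 0.0
        pert = base.model_copy(deep=True)
        pert.tumor.lame_lambda *= 1.7
        pert.tissue.lame_mu = 123.0
        r = np.array([0.0, 0.013, 0.02, 0.04])
        for s in (0.2 + 0j, 1.0 + 1.0j):
            t1 = transformed_fields(base).sample(r, s)["theta"]
            t2 = transformed_fields(pert).sample(r, s)["theta"]
            denom = np.max(np.abs(t1))
            assert np.max(np.abs(t1 - t2)) < 1e-12 * denom

    def test_linearity_in_source(self, preset):
        doubled = preset.model_copy(deep=True)
        doubled.source.irradiance *= 2.0
        r = np.array([0.005, 0.02, 0.03])
        s = 0.6 + 0.9j
        v1 = transformed_fields(preset).sample(r, s)
        v2 = transformed_fields(doubled).sample(r, s)
        for name in ("theta", "u", "sigma_rr"):
            np.testing.assert_allclose(v2[name], 2.0 * v1[name], rtol=1e-12)

    def test_negative_radius_rejected(self, preset):
        fs = transformed_fields(preset)
        with pytest.raises(ValueError):
            fs.sample(np.array([-0.01]), 1.0 + 0j)
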