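import numpy as np
import pytest

from thermotumor import simulate
from thermotumor.config import ModelVariant


class TestFullRun:
    def test_zero_source_stays_at_body_temperature(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.source.irradiance = 0.0
        R = cfg.geometry.tumor_radius
        f = simulate.run(cfg, [0.0, R, 3 * R], [10.0, 50.0])
        assert np.max(np.abs(f.T - 37.0)) < 1e-3
        assert np.max(np.abs(f.u)) < 1e-12
        assert np.max(np.abs(f.sigma_rr)) < 1e-9

    def test_temperature_increases_with_time(self, demo_field):
        """At fixed r inside the heated region, T grows monotonically in t."""
        R = 0.02
        heated = demo_field.radii <= 1.1 * R
        T = demo_field.T[heated]
        assert np.all(np.diff(T, axis=1) > -1e-9)

    def test_temperature_decreases_with_radius_in_tissue(self, demo_field):
        """Beyond the heated core, T falls monotonically with r at fixed t."""
        outside = demo_field.radii >= 0.02
        T = demo_field.T[outside]
        assert np.all(np.diff(T, axis=0) < 1e-9)

    def test_interface_two_sided_agreement(self, demo_field):
        """Tumor-side and tissue-side evaluations at r = R coincide."""
        R = 0.02
        i = int(np.argmin(np.abs(demo_field.radii - R)))
        assert demo_field.radii[i] == R
        assert demo_field.radii[i + 1] == np.nextafter(R, np.inf)
        scale = np.max(np.abs(demo_field.T - 37.0))
        assert np.max(np.abs(demo_field.T[i] - demo_field.T[i + 1])) < 1e-6 * scale

    def test_far_field_is_quiet(self, demo_field):
        """Finite propagation speed: 10R sees under 1% of the interface rise."""
        R = 0.02
        iR = int(np.argmin(np.abs(demo_field.radii - R)))
        far = int(np.argmin(np.abs(demo_field.radii - 10 * R)))
        assert np.all(
            np.abs(demo_field.T[far] - 37.0)
            < 0.01 * np.abs(demo_field.T[iR] - 37.0)
        )

    def test_center_follows_coupled_adiabatic_ramp(self, preset):
        """Before any wavefront arrives the center heats at Q_L/(ρc(1+δ)).

        δ = γ²T0/(ρ c_E (λ+2μ)) is the quasi-static thermoelastic coupling
        factor: the fast elastic mode instantaneously equilibrates the
        dilatation, raising the effective heat capacity.
        """
        p = preset.tumor
        delta = (
            p.thermal_modulus**2
            * preset.body_temp_kelvin
            / (p.density * p.specific_heat * (p.lame_lambda + 2 * p.lame_mu))
        )
        f = simulate.run(preset, [0.0], [10.0, 30.0, 50.0])
        Q_L = preset.source.volumetric_power
        slope = Q_L / (p.density * p.specific_heat * (1.0 + delta))
        for t, T in zip(f.times, f.T[0]):
            assert T - 37.0 == pytest.approx(slope * t, rel=1e-5)

    def test_joint_and_single_radius_runs_identical(self, preset):
        R = preset.geometry.tumor_radius
        radii = np.array([0.5 * R, R, 2 * R])
        joint = simulate.run(preset, radii, [50.0])
        for i, r in enumerate(radii):
            single = simulate.run(preset, [r], [50.0])
            assert joint.T[i, 0] == single.T[0, 0]


class TestVariants:
    def test_ls_with_zero_coupling_equals_cattaneo(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.tumor.thermal_modulus = 0.0
        cfg.tissue.thermal_modulus = 0.0
        R = preset.geometry.tumor_radius
        r = np.linspace(0.2 * R, 2 * R, 7)
        t = [20.0, 60.0]
        a = simulate.run(cfg, r, t)
        b = simulate.run_variant(preset, ModelVariant.CATTANEO_VERNOTTE, r, t)
        np.testing.assert_allclose(a.T, b.T, rtol=1e-9)

    def test_cattaneo_converges_to_pennes_as_tau_vanishes(self, preset):
        R = preset.geometry.tumor_radius
        r = np.linspace(0.2 * R, 1.8 * R, 8)
        t = np.linspace(5, 80, 8)
        pennes = simulate.run_variant(preset, "CLASSICAL_PENNES", r, t)
        errs = []
        for tau in (1.0, 0.1, 0.01):
            cfg = preset.model_copy(deep=True)
            cfg.tumor.relaxation_time = tau
            cfg.tissue.relaxation_time = tau
            cv = simulate.run_variant(cfg, "CATTANEO_VERNOTTE", r, t)
            errs.append(np.max(np.abs(cv.T - pennes.T)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3 * np.max(np.abs(pennes.T - 37))

    def test_cattaneo_lags_pennes_at_early_times(self, preset):
        """Finite heat speed: beyond the wavefront CV is cold, Pennes is not."""
        R = preset.geometry.tumor_radius
        r = [R + 1e-3]  # ahead of the C-V wavefront for t < ~3.4 s
        t = [1.0, 2.0]
        cv = simulate.run_variant(preset, "CATTANEO_VERNOTTE", r, t)
        pn = simulate.run_variant(preset, "CLASSICAL_PENNES", r, t)
        assert np.all(pn.T - 37.0 > 1e-3)
        assert np.all(np.abs(cv.T - 37.0) < 1e-6)
        assert np.all(pn.T > cv.T + 1e-3)

    def test_perfusion_only_honored_by_pennes(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.perfusion_coeff = 2000.0
        R = preset.geometry.tumor_radius
        r = [0.5 * R, R]
        t = [40.0]
        ls_with = simulate.run_variant(cfg, "LS_THERMOELASTIC", r, t)
        ls_without = simulate.run_variant(preset, "LS_THERMOELASTIC", r, t)
        np.testing.assert_array_equal(ls_with.T, ls_without.T)
        pn_with = simulate.run_variant(cfg, "CLASSICAL_PENNES", r, t)
        pn_without = simulate.run_variant(preset, "CLASSICAL_PENNES", r, t)
        assert np.all(pn_with.T < pn_without.T)

    def test_unknown_variant_rejected(self, preset):
        with pytest.raises(ValueError):
            simulate.run_variant(preset, "MAGIC_MODEL")


class TestSweeps:
    def test_irradiance_sweep_is_pointwise_linear(self, preset):
        cfg = preset.model_copy(deep=True)
        R = cfg.geometry.tumor_radius
        cfg.geometry.eval_radii = [0.5 * R, R, 1.5 * R]
        cfg.geometry.eval_times = [20.0, 60.0]
        I0 = cfg.source.irradiance
        f1, f2 = simulate.sweep(cfg, "irradiance", [I0, 2 * I0])
        for a, b in (
            (f1.T - 37.0, f2.T - 37.0),
            (f1.u, f2.u),
            (f1.sigma_rr, f2.sigma_rr),
        ):
            np.testing.assert_allclose(
                b, 2.0 * a, rtol=1e-6, atol=1e-9 * np.max(np.abs(a))
            )

    def test_time_sweep_interface_strictly_increases(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.geometry.eval_radii = [cfg.geometry.tumor_radius]
        (field,) = simulate.sweep(cfg, "time", [50.0, 60.0, 70.0, 80.0])
        assert np.all(np.diff(field.T[0]) > 0)

    def test_relaxation_sweep_traps_heat_inside(self, preset):
        """Larger τ0 slows heat escape: hotter at the interface, cooler beyond.

        This is the C-V dispersion consequence (wave speed √(k/ρcτ0) falls
        with τ0), concentrated around the tumor surface.
        """
        cfg = preset.model_copy(deep=True)
        R = cfg.geometry.tumor_radius
        cfg.geometry.eval_radii = [R, 1.25 * R]
        cfg.geometry.eval_times = [50.0]
        lo, hi = simulate.sweep(cfg, "relaxation_time", [1.0, 4.0])
        assert hi.T[0, 0] > lo.T[0, 0]  # interface: hotter with larger tau0
        assert hi.T[1, 0] < lo.T[1, 0]  # tissue: cooler with larger tau0

    def test_sweep_frame_is_tidy(self, preset):
        cfg = preset.model_copy(deep=True)
        cfg.geometry.eval_radii = [0.01]
        cfg.geometry.eval_times = [30.0]
        fields = simulate.sweep(cfg, "irradiance", [0.05, 0.1])
        df = simulate.sweep_frame(fields, "irradiance", [0.05, 0.1])
        assert list(df["sweep_value"].unique()) == [0.05, 0.1]
        assert {"r_m", "t_s", "T_C", "sigma_rr_Pa"} <= set(df.columns)

    def test_empty_sweep_rejected(self, preset):
        with pytest.raises(ValueError):
            simulate.sweep(preset, "irradiance", [])
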