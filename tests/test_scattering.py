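"""Mie surrogate: oracles, geometry reduction, and voltage trends."""

import numpy as np
import pytest

from electroscatter.scattering import (
    AntennaGeometry,
    MediumOptics,
    equivalent_sphere_radius,
    mie_cross_section,
    mie_efficiency,
    scattering_spectrum_vs_bias,
    scattering_vs_bias,
    sensitivity_vs_bias,
    wiscombe_order,
)
from electroscatter.permittivity import default_wavelength_grid, voltage_to_doping

WL = default_wavelength_grid()
BIASES = np.round(np.arange(-0.8, 0.2001, 0.05), 3)


class TestMie:
    def test_index_matched_particle_scatters_nothing(self):
        assert mie_cross_section(300.0, 1.33 + 0j, 1.33, 640.0) == 0.0

    @pytest.mark.parametrize("x", [0.01, 0.05, 0.1])
    def test_rayleigh_limit(self, x):
        """Series agrees with the Rayleigh closed form for small spheres."""
        m, n_med, lam = 1.5, 1.33, 640.0
        a = x * lam / (2 * np.pi * n_med)
        sigma = mie_cross_section(a, m * n_med, n_med, lam)
        k = 2 * np.pi * n_med / lam
        rayleigh = (8 / 3) * np.pi * k**4 * a**6 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        assert sigma == pytest.approx(rayleigh, rel=0.01)

    @pytest.mark.parametrize("x", [0.5, 5.0, 25.0])
    @pytest.mark.parametrize("m", [1.2 + 0j, 1.5 + 0.2j, 0.9 + 0.05j])
    def test_truncation_convergence(self, x, m):
        q_default = mie_efficiency(x, m)
        q_more = mie_efficiency(x, m, n_max=wiscombe_order(x) + 30)
        assert q_default == pytest.approx(q_more, rel=1e-6)

    def test_rejects_nan_and_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            mie_cross_section(float("nan"), 1.5, 1.33, 640.0)
        with pytest.raises(ValueError):
            mie_cross_section(100.0, complex(float("nan"), 0), 1.33, 640.0)
        with pytest.raises(ValueError):
            mie_cross_section(-5.0, 1.5, 1.33, 640.0)


class TestEquivalentRadius:
    def test_hemisphere_only(self):
        # 1000-nm cap, vanishing stem: r = (V_hemisphere * 3/(4 pi))^(1/3)
        g = AntennaGeometry(cap_diameter=1000.0, stem_diameter=1e-6, stem_height=1e-6)
        expected = (0.5) ** (1 / 3) * 500.0  # hemisphere of radius 500
        assert equivalent_sphere_radius(g) == pytest.approx(expected, rel=1e-6)
        assert equivalent_sphere_radius(g) == pytest.approx(396.85, abs=0.1)

    def test_stem_only_degenerate_case(self):
        g = AntennaGeometry(cap_diameter=250.0, stem_diameter=250.0, stem_height=50.0)
        v = (2 / 3) * np.pi * 125.0**3 + np.pi * 125.0**2 * 50.0
        assert equivalent_sphere_radius(g) == pytest.approx(
            (3 * v / (4 * np.pi)) ** (1 / 3)
        )

    def test_linear_scaling(self):
        g1 = AntennaGeometry(1000.0, 250.0, 50.0)
        g2 = AntennaGeometry(2000.0, 500.0, 100.0)
        assert equivalent_sphere_radius(g2) == pytest.approx(
            2 * equivalent_sphere_radius(g1)
        )

    def test_invariants(self):
        with pytest.raises(ValueError):
            AntennaGeometry(cap_diameter=100.0, stem_diameter=250.0)


class TestVoltageTrends:
    def test_deterministic(self, default_model):
        g = AntennaGeometry()
        s1 = scattering_vs_bias(g, [-0.5, -0.5], default_model, 640.0)
        assert s1[0] == s1[1]

    @pytest.mark.parametrize("cap", [750.0, 1000.0, 1500.0])
    def test_sigma_at_640_monotone_in_bias(self, default_model, cap):
        """Dedoping (negative bias) brightens: sigma non-increasing in V."""
        g = AntennaGeometry(cap_diameter=cap)
        sigma = scattering_vs_bias(g, BIASES, default_model, 640.0)
        assert np.all(np.diff(sigma) <= 1e-9 * sigma[:-1].clip(min=1))

    def test_larger_cap_scatters_more_everywhere(self, default_model):
        small = AntennaGeometry(cap_diameter=750.0)
        large = AntennaGeometry(cap_diameter=1500.0)
        for v in (-0.8, -0.4, 0.2):
            s_small = scattering_spectrum_vs_bias(small, [v], default_model, WL)[v]
            s_large = scattering_spectrum_vs_bias(large, [v], default_model, WL)[v]
            assert np.all(s_large.sigma_sc > s_small.sigma_sc)

    def test_cap_growth_never_decreases_sigma(self, default_model):
        caps = [600.0, 800.0, 1000.0, 1200.0, 1500.0, 1800.0]
        for v in (-0.8, -0.4, 0.0, 0.2):
            spectra = [
                scattering_spectrum_vs_bias(
                    AntennaGeometry(cap_diameter=c), [v], default_model, WL
                )[v].sigma_sc
                for c in caps
            ]
            for lo, hi in zip(spectra[:-1], spectra[1:]):
                assert np.all(hi >= lo)

    def test_sigma_nonnegative_for_all_dopings(self, default_model):
        g = AntennaGeometry()
        for v in BIASES:
            spec = scattering_spectrum_vs_bias(g, [v], default_model, WL)[float(v)]
            assert np.all(spec.sigma_sc >= 0)

    def test_pipeline_associativity(self, default_model):
        """Per-bias spectra equal spectra from pre-tabulated doping levels."""
        g = AntennaGeometry()
        biases = [-0.6, -0.3, 0.0]
        direct = scattering_spectrum_vs_bias(g, biases, default_model, WL)
        from electroscatter.permittivity import index_from_permittivity
        from electroscatter.scattering import equivalent_sphere_radius

        r = equivalent_sphere_radius(g)
        for v in biases:
            doping = voltage_to_doping(v, default_model.calibration)
            eps = default_model.spectrum_at_doping(doping, WL)
            n, k = index_from_permittivity(eps.eps)
            sigma = [
                mie_cross_section(r, complex(ni, ki), np.sqrt(1.77), wl)
                for ni, ki, wl in zip(n, k, WL)
            ]
            assert np.allclose(direct[v].sigma_sc, sigma)

    def test_warns_outside_characterized_window(self, default_model):
        with pytest.warns(UserWarning):
            scattering_vs_bias(AntennaGeometry(), [-1.5, 0.0, 0.2], default_model)


class TestSensitivity:
    def test_requires_three_biases(self, default_model):
        with pytest.raises(ValueError):
            sensitivity_vs_bias(AntennaGeometry(), [-0.5, -0.4], default_model)

    def test_flat_transfer_gives_zero(self, default_model):
        """Clamping the doping (zero-width sigmoid far away) flattens dsigma/dV."""
        from electroscatter.permittivity import DopingCalibration, PermittivityModel

        clamped = PermittivityModel(
            default_model.doped,
            default_model.dedoped,
            DopingCalibration(v_half=50.0, v_width=0.01),  # doping ~ 0 everywhere
        )
        sens = sensitivity_vs_bias(AntennaGeometry(), BIASES, clamped, 640.0)
        peak = max(abs(v) for v in sens.values())
        scale = scattering_vs_bias(AntennaGeometry(), [-0.5], clamped, 640.0)[0]
        assert peak < 1e-9 * scale

    def test_peak_sensitivity_bias_window(self, default_model):
        """|dsigma/dV| is maximal between -0.6 and -0.4 V for the default cap."""
        sens = sensitivity_vs_bias(
            AntennaGeometry(),
            np.round(np.arange(-0.8, 0.2001, 0.01), 3),
            default_model,
            640.0,
        )
        v_peak = max(sens, key=lambda v: abs(sens[v]))
        assert -0.6 <= v_peak <= -0.4

    def test_finite_difference_matches_chain_rule(self, default_model):
        """Central differences at 10-mV step vs analytic logistic derivative."""
        g = AntennaGeometry()
        v0 = -0.45
        biases = [v0 - 0.01, v0, v0 + 0.01]
        sens = sensitivity_vs_bias(g, biases, default_model, 640.0)[v0]
        # analytic: dsigma/dV = dsigma/dc * dc/dV with dsigma/dc from a fine
        # central difference in doping space (the mixing is smooth in c)
        cal = default_model.calibration
        c0 = voltage_to_doping(v0, cal)
        dc = 1e-6
        r = equivalent_sphere_radius(g)
        from electroscatter.permittivity import index_from_permittivity

        def sigma_at(c):
            eps = default_model.spectrum_at_doping(c, [640.0])
            n, k = index_from_permittivity(eps.eps[0])
            return mie_cross_section(r, complex(n, k), np.sqrt(1.77), 640.0)

        dsigma_dc = (sigma_at(c0 + dc) - sigma_at(c0 - dc)) / (2 * dc)
        dc_dv = c0 * (1 - c0) / cal.v_width
        assert sens == pytest.approx(dsigma_dc * dc_dv, rel=0.01)
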