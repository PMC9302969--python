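"""Closed-form transfer functions: frozen values, limits and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qlin import (
    ChR2Kinetics,
    IlluminationSpec,
    QuasiLinearParams,
    admittance,
    admittance_components,
    alpha_kernel,
    cable_amplitude,
    cable_phase,
    chr2_transfer,
    propagation_constant,
    somatic_impedance,
    somatic_phase,
)
from qlin.errors import ConfigurationError, DegenerateModelError
from qlin.membrane import TransferComponents, alpha_kernel_peak_time

# random-but-stable quasi-linear parameter sets for property tests
PARAM_SETS = st.builds(
    QuasiLinearParams,
    tau_m=st.floats(5.0, 200.0),
    gamma_R=st.floats(0.5, 20.0),
    mu_n=st.floats(-0.45, 0.0),
    tau_n=st.floats(2.0, 500.0),
    mu_h=st.floats(0.0, 10.0),
    tau_h=st.floats(2.0, 5000.0),
)


class TestQuasiLinearParams:
    def test_rejects_nonpositive_time_constants_and_conductance(self):
        with pytest.raises(ValueError):
            QuasiLinearParams(tau_m=-1.0)
        with pytest.raises(ValueError):
            QuasiLinearParams(tau_m=10.0, tau_n=0.0)
        with pytest.raises(ValueError):
            QuasiLinearParams(tau_m=10.0, gamma_R=0.0)

    def test_rejects_dc_unstable_combination(self):
        # gamma_R + mu_n + mu_h <= 0 means a runaway linearized membrane
        with pytest.raises(ValueError, match="DC-unstable"):
            QuasiLinearParams(tau_m=10.0, gamma_R=1.0, mu_n=-1.5)


class TestAdmittance:
    def test_dc_limit_passive(self):
        comp = admittance_components(0.0, QuasiLinearParams.passive(tau_m=20.0))
        assert comp.alpha == pytest.approx(1.0)
        assert comp.beta == 0.0

    def test_dc_limit_general(self, row70):
        p = row70.params
        comp = admittance_components(0.0, p)
        assert comp.alpha == pytest.approx(p.gamma_R + p.mu_n + p.mu_h)
        assert comp.beta == 0.0

    def test_table_row_at_1hz_matches_independent_complex_evaluation(self, row70):
        # frozen from a direct evaluation of y(f) with an independent script
        comp = admittance_components(1.0, row70.params)
        assert comp.alpha == pytest.approx(2.5385, abs=2e-4)
        assert comp.beta == pytest.approx(0.1802, abs=2e-4)

    def test_rejects_nonfinite_frequency(self, row70):
        with pytest.raises(ValueError):
            admittance(np.nan, row70.params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params=PARAM_SETS, f=st.floats(0.0, 50.0))
    def test_components_match_complex_form(self, params, f):
        y = admittance(f, params)
        comp = admittance_components(f, params)
        assert comp.alpha == pytest.approx(y.real, rel=1e-12)
        assert comp.beta == pytest.approx(y.imag, rel=1e-12)


class TestSomaticPhaseAndImpedance:
    def test_passive_high_frequency_limit_quarter_cycle(self, passive_params):
        assert somatic_phase(1e7, passive_params) == pytest.approx(0.25, abs=1e-4)

    def test_passive_corner_frequency_eighth_cycle(self):
        p = QuasiLinearParams.passive(tau_m=26.1)
        f_corner = 1.0 / (2 * np.pi * p.tau_m * 1e-3)
        assert somatic_phase(f_corner, p) == pytest.approx(0.125, abs=1e-12)

    def test_resonant_row_has_negative_phase_at_low_frequency(self, row70):
        # frozen: beta(0.2 Hz) < 0 for the -70 mV set (independent evaluation)
        ph = somatic_phase(0.2, row70.params)
        assert ph == pytest.approx(-0.0347, abs=5e-4)

    def test_impedance_dc_equals_scale_for_unit_leak(self):
        p = QuasiLinearParams.passive(tau_m=10.0, amp_scale=2.5)
        assert somatic_impedance(0.0, p) == pytest.approx(2.5)

    def test_passive_impedance_strictly_decreasing(self, passive_params):
        f = np.linspace(0.0, 30.0, 200)
        z = somatic_impedance(f, passive_params)
        assert np.all(np.diff(z) < 0)

    def test_resonance_peak_near_one_hertz(self, row70):
        f = np.logspace(np.log10(0.1), np.log10(20), 4001)
        z = somatic_impedance(f, row70.params)
        assert f[np.argmax(z)] == pytest.approx(1.0, abs=0.5)

    def test_missing_amp_scale_is_configuration_error(self, row70):
        p = QuasiLinearParams.passive(tau_m=10.0)
        with pytest.raises(ConfigurationError):
            somatic_impedance(1.0, p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params=PARAM_SETS, f=st.floats(0.0, 50.0))
    def test_phase_and_modulus_agree_with_complex_arg(self, params, f):
        y = admittance(f, params)
        assert somatic_phase(f, params) == pytest.approx(
            np.angle(y) / (2 * np.pi), abs=1e-12)

    def test_less_negative_mu_n_reduces_phase_everywhere(self, row55):
        p = row55.params
        import dataclasses
        weaker = dataclasses.replace(p, mu_n=p.mu_n / 2)
        f = np.array([0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
        assert np.all(somatic_phase(f, weaker) < somatic_phase(f, p))


class TestPropagationConstant:
    def test_unit_alpha(self):
        pc = propagation_constant(TransferComponents(alpha=1.0, beta=0.0))
        assert pc.p == pytest.approx(1.0)
        assert pc.q == 0.0

    def test_degenerate_zero_raises(self):
        with pytest.raises(DegenerateModelError):
            propagation_constant(TransferComponents(alpha=0.0, beta=0.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(alpha=st.floats(-5.0, 10.0), beta=st.floats(-10.0, 10.0))
    def test_square_root_identities_and_sign(self, alpha, beta):
        if alpha == 0 and beta == 0:
            return
        pc = propagation_constant(TransferComponents(alpha=alpha, beta=beta))
        assert pc.p**2 - pc.q**2 == pytest.approx(alpha, abs=1e-9)
        assert 2 * pc.p * pc.q == pytest.approx(beta, abs=1e-9)
        assert pc.p >= 0
        if beta != 0:
            assert np.sign(pc.q) == np.sign(beta)


class TestCableTransfer:
    def test_phase_vanishes_for_tiny_extent(self, row70):
        ph = cable_phase(1.0, row70.params, IlluminationSpec(1e-9))
        assert ph == pytest.approx(0.0, abs=1e-6)

    def test_infinite_extent_limit(self, row70):
        y = admittance(2.0, row70.params)
        g = np.sqrt(y)
        expected = np.arctan2(g.imag, g.real) / (2 * np.pi)
        assert cable_phase(2.0, row70.params, IlluminationSpec(np.inf)) == \
            pytest.approx(expected, abs=1e-12)
        assert cable_phase(2.0, row70.params, IlluminationSpec(50.0)) == \
            pytest.approx(expected, abs=1e-10)

    def test_two_arctangent_forms_agree(self, row70):
        # phi_d as the difference of arctangents vs -arg of the complex transfer
        f = np.array([0.2, 0.7, 2.0, 9.0, 20.0])
        r = 0.83
        ph = cable_phase(f, row70.params, IlluminationSpec(r))
        y = admittance(f, row70.params)
        g = np.sqrt(y)
        transfer = (1.0 - np.exp(-g * r)) / g
        assert np.allclose(ph, -np.angle(transfer) / (2 * np.pi), atol=1e-12)

    def test_negative_beta_gives_negative_phase_for_long_cable(self, row70):
        # in the resonant low-frequency regime q<0, so the dendrite leads
        f = 0.2
        assert admittance(f, row70.params).imag < 0
        assert cable_phase(f, row70.params, IlluminationSpec(np.inf)) < 0

    def test_dc_amplitude_passive(self):
        p = QuasiLinearParams.passive(tau_m=20.0)
        r = 0.7
        assert cable_amplitude(0.0, p, IlluminationSpec(r)) == \
            pytest.approx(1 - np.exp(-r), abs=1e-12)
        assert cable_amplitude(0.0, p, IlluminationSpec(np.inf)) == pytest.approx(1.0)

    @pytest.mark.parametrize("label", ["soma_-55mV", "soma_-70mV", "cable_qlin_proximal",
                                       "cable_passive_proximal"])
    @pytest.mark.parametrize("f", [0.2, 1.0, 2.0])
    def test_amplitude_nondecreasing_in_extent(self, label, f):
        # illuminating more membrane recruits more current; holds whenever the
        # oscillatory part of exp(-g r) does not dominate (moderate q*r, i.e.
        # the sub-resonant frequencies used in the protocols)
        from qlin import preset

        params = preset(label).params
        rs = np.array([0.1, 0.3, 0.7, 1.5, 3.0])
        amps = [float(cable_amplitude(f, params, IlluminationSpec(r))) for r in rs]
        assert np.all(np.diff(amps) >= -1e-12)


class TestChR2Transfer:
    def test_dc_is_unity_and_zero_phase(self, kin):
        amp, ph = chr2_transfer(0.0, kin)
        assert amp == pytest.approx(1.0)
        assert ph == 0.0

    def test_quarter_cycle_at_denominator_zero(self, kin):
        f_star = 1.0 / (2 * np.pi * np.sqrt(kin.tau_r * kin.tau_d * 1e-6))
        _, ph = chr2_transfer(f_star, kin)
        assert ph == pytest.approx(0.25, abs=1e-9)

    def test_phase_continuous_and_nondecreasing(self, kin):
        f = np.linspace(0.0, 200.0, 5000)
        _, ph = chr2_transfer(f, kin)
        assert np.all(np.diff(ph) >= 0)
        assert ph[-1] < 0.5

    def test_matches_fft_of_sampled_kernel(self):
        # independent oracle: discrete Fourier transform of the time-domain kernel
        kin = ChR2Kinetics(tau_r=1.0, tau_d=10.0)
        dt = 0.01  # ms
        t = np.arange(0.0, 400.0, dt)
        k = alpha_kernel(t, 1.0, kin.tau_r, kin.tau_d)
        spec = np.fft.rfft(k) * dt
        freqs = np.fft.rfftfreq(len(k), d=dt * 1e-3)
        i = np.argmin(np.abs(freqs - 5.0))
        amp_o = np.abs(spec[i]) / np.abs(spec[0])
        ph_o = -np.angle(spec[i]) / (2 * np.pi)
        amp, ph = chr2_transfer(freqs[i], kin)
        assert amp == pytest.approx(amp_o, abs=1e-3)
        assert ph == pytest.approx(ph_o, abs=1e-3)


class TestAlphaKernel:
    def test_zero_at_origin_and_positive_after(self):
        t = np.linspace(0.0, 50.0, 500)
        k = alpha_kernel(t, 1.0, 1.0, 10.0)
        assert k[0] == 0.0
        assert np.all(k[1:] > 0)

    def test_peak_location_matches_brute_force_grid(self):
        tau_r, tau_d = 1.0, 10.0
        t = np.linspace(0.0, 60.0, 600001)
        k = alpha_kernel(t, 1.0, tau_r, tau_d)
        t_star = alpha_kernel_peak_time(tau_r, tau_d)
        assert t[np.argmax(k)] == pytest.approx(t_star, abs=1e-3)
        peak = np.exp(-t_star / tau_d) - np.exp(-t_star / tau_r)
        assert k.max() == pytest.approx(peak, abs=1e-9)

    def test_invalid_time_constant_order(self):
        with pytest.raises(ValueError):
            alpha_kernel(np.array([1.0]), 1.0, 10.0, 1.0)


class TestOptogeneticModel:
    def test_phase_is_sum_and_fast_kinetics_reduce_to_cable(self, row70):
        from qlin import optogenetic_model

        illum = IlluminationSpec(0.6)
        kin_fast = ChR2Kinetics(tau_r=1e-4, tau_d=2e-4)
        f = np.array([0.3, 1.0, 5.0, 20.0])
        _, ph = optogenetic_model(f, row70.params, illum, kin_fast)
        assert np.allclose(ph, cable_phase(f, row70.params, illum), atol=1e-4)
        kin = ChR2Kinetics(2.0, 18.0)
        _, ph2 = chr2_transfer(f, kin)
        _, ph_full = optogenetic_model(f, row70.params, illum, kin)
        assert np.allclose(ph_full, ph2 + cable_phase(f, row70.params, illum),
                           atol=1e-14)

    def test_quasilinear_dendrite_leads_passive_at_low_frequency(self):
        # the restorative term pulls the low-frequency phase below the passive one
        from qlin import optogenetic_model, preset

        row = preset("cable_qlin_proximal")
        illum = row.illumination
        kin = ChR2Kinetics(2.0, 18.0)
        _, ph_q = optogenetic_model(0.4, row.params, illum, kin)
        _, ph_p = optogenetic_model(
            0.4, row.params.without_nonlinearities(), illum, kin)
        assert ph_q < ph_p
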