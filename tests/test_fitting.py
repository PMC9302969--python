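"""Model fitting: round-trip identifiability, transient fits, and ANCOVA."""

import numpy as np
import pytest

from qlin import (
    CableModel,
    ChR2Kinetics,
    ChR2KineticsModel,
    SomaModel,
    compare_curves_ancova,
    fit_alpha_transient,
    preset,
)
from qlin.errors import FitFailureError
from qlin.fitting import results_to_frame
from qlin.membrane import alpha_kernel, cable_phase, chr2_transfer, somatic_phase
from qlin.sysid import TransferCurve, default_frequency_grid


def _soma_curve(params, magnitude=False):
    f = default_frequency_grid()
    mag = None
    if magnitude:
        from qlin.membrane import somatic_impedance
        mag = somatic_impedance(f, params)
    return TransferCurve(frequencies=f, phase=somatic_phase(f, params), magnitude=mag)


class TestChR2KineticsFit:
    def test_noiseless_kernel_recovered_to_a_tenth_percent(self):
        dt = 0.1
        t = np.arange(0.0, 120.0, dt)
        trace = alpha_kernel(t, 2.0, 1.0, 10.0)
        fit = ChR2KineticsModel(trace, dt).fit()
        assert fit.tau_r == pytest.approx(1.0, rel=1e-3)
        assert fit.tau_d == pytest.approx(10.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-3)
        assert fit.kinetics.tau_d > fit.kinetics.tau_r

    def test_noisy_pulse_average_recovered_within_five_percent(self, rng):
        # emulate a 250-trial pulse average: kernel + averaged white noise
        dt = 0.1
        t = np.arange(0.0, 120.0, dt)
        clean = alpha_kernel(t, 1.0, 1.0, 10.0)
        noise = rng.normal(0.0, 0.05 * clean.max(), size=(250, len(t))).mean(axis=0)
        fit = ChR2KineticsModel(clean + noise, dt).fit()
        assert fit.tau_r == pytest.approx(1.0, rel=0.05)
        assert fit.tau_d == pytest.approx(10.0, rel=0.05)

    def test_inward_transient_sign_detected(self):
        dt = 0.1
        t = np.arange(0.0, 120.0, dt)
        fit = ChR2KineticsModel(-alpha_kernel(t, 1.0, 2.0, 18.0), dt).fit()
        assert fit.sign == -1.0
        assert fit.tau_d == pytest.approx(18.0, rel=1e-3)

    def test_flat_trace_fails(self):
        with pytest.raises(FitFailureError):
            ChR2KineticsModel(np.zeros(500), 0.1).fit()


class TestSomaModelRoundTrip:
    @pytest.mark.parametrize("label", ["soma_-55mV", "soma_TTX"])
    def test_amplifying_only_rows_recovered_within_one_percent(self, label):
        row = preset(label)
        res = SomaModel(_soma_curve(row.params), scheme="amplifying_only",
                        gamma_R=row.params.gamma_R).fit(n_starts=20, seed=1)
        for name, truth in (("mu_n", row.params.mu_n), ("tau_n", row.params.tau_n),
                            ("tau_m", row.params.tau_m)):
            assert res.params[name] == pytest.approx(truth, rel=0.01), name
        assert res.converged

    @pytest.mark.parametrize("label", ["soma_-70mV", "soma_ZD7288"])
    def test_resonant_rows_recovered_within_one_percent(self, label):
        row = preset(label)
        res = SomaModel(_soma_curve(row.params), scheme="amplifying_plus_resonant",
                        gamma_R=row.params.gamma_R).fit(n_starts=20, seed=1)
        for name in ("mu_n", "tau_n", "mu_h", "tau_h", "tau_m"):
            assert res.params[name] == pytest.approx(
                getattr(row.params, name), rel=0.01), name
        # the flag marks a resonant fit with actual negative phases in the
        # data: true at -70 mV, false once HCN is blocked (ZD7288)
        expected_flag = bool(np.any(_soma_curve(row.params).phase < 0))
        assert res.flags["resonance_detected"] == expected_flag

    def test_passive_curve_fitted_with_amplifying_scheme_yields_tiny_mu_n(self):
        from qlin import QuasiLinearParams

        p = QuasiLinearParams.passive(tau_m=30.0, gamma_R=1.0)
        res = SomaModel(_soma_curve(p), scheme="amplifying_only",
                        gamma_R=1.0).fit(n_starts=10, seed=3)
        assert abs(res.params["mu_n"]) < 0.01

    def test_joint_magnitude_fit_recovers_impedance_scale(self, row70):
        res = SomaModel(_soma_curve(row70.params, magnitude=True),
                        scheme="amplifying_plus_resonant",
                        gamma_R=row70.params.gamma_R,
                        magnitude_weight=1.0).fit(n_starts=15, seed=2)
        assert res.params["amp_scale"] == pytest.approx(row70.params.amp_scale,
                                                        rel=0.02)

    def test_noisy_replicates_bracket_ground_truth(self, row55):
        # the spread of estimates over noisy replicates must cover the truth
        from qlin.datasets import gen_sweep_dataset
        from qlin.sysid import sweep_to_transfer_curve

        estimates = []
        for seed in range(10):
            recs, _ = gen_sweep_dataset(row55.params, n_cells=1, noise_sd_pa=10.0,
                                        seed=seed)
            curve = sweep_to_transfer_curve(recs[0])
            res = SomaModel(curve, scheme="amplifying_only",
                            gamma_R=row55.params.gamma_R).fit(n_starts=8, seed=seed)
            estimates.append(res.params["mu_n"])
        lo, hi = min(estimates), max(estimates)
        assert lo - 0.05 <= row55.params.mu_n <= hi + 0.05

    def test_curve_with_too_few_frequencies_rejected(self, row55):
        f = np.array([1.0, 2.0, 5.0])
        curve = TransferCurve(frequencies=f, phase=somatic_phase(f, row55.params))
        with pytest.raises(ValueError, match="6 frequencies"):
            SomaModel(curve)


class TestCableModelRoundTrip:
    def _curve(self, row, kin):
        f = default_frequency_grid()
        _, phc = chr2_transfer(f, kin)
        return TransferCurve(
            frequencies=f, phase=phc + cable_phase(f, row.params, row.illumination))

    def test_passive_row_extent_recovered_within_two_percent(self, kin):
        row = preset("cable_passive_proximal")
        res = CableModel(self._curve(row, kin), kin, scheme="passive").fit(
            n_starts=15, seed=1)
        assert res.params["extent_r"] == pytest.approx(row.extent_r, rel=0.02)
        assert res.params["tau_m"] == pytest.approx(row.params.tau_m, rel=0.02)

    def test_full_field_to_proximal_extent_ratio_recovered(self, kin):
        # truth generated with r_full = 2 x r_prox; fitted ratio within 10%
        from qlin import IlluminationSpec, QuasiLinearParams

        p = QuasiLinearParams.passive(tau_m=30.0)
        f = default_frequency_grid()
        _, phc = chr2_transfer(f, kin)
        fits = []
        for r in (0.5, 1.0):
            curve = TransferCurve(
                frequencies=f, phase=phc + cable_phase(f, p, IlluminationSpec(r)))
            fits.append(CableModel(curve, kin, scheme="passive").fit(
                n_starts=15, seed=2).params["extent_r"])
        assert fits[1] / fits[0] == pytest.approx(2.0, rel=0.10)

    @pytest.mark.parametrize("label", ["cable_qlin_proximal", "cable_qlin_full_field"])
    def test_quasi_linear_rows_recovered_within_five_percent(self, label, kin):
        row = preset(label)
        res = CableModel(self._curve(row, kin), kin, scheme="quasi_linear",
                         gamma_R=row.params.gamma_R).fit(n_starts=20, seed=1)
        assert res.params["extent_r"] == pytest.approx(row.extent_r, rel=0.05)
        for name in ("mu_n", "tau_n", "mu_h", "tau_h", "tau_m"):
            assert res.params[name] == pytest.approx(
                getattr(row.params, name), rel=0.05), name

    def test_passive_scheme_on_resonant_data_leaves_low_frequency_residual(self, kin):
        # the restorative dip at 0.4 Hz cannot be captured by a passive dendrite
        row = preset("cable_qlin_proximal")
        curve = self._curve(row, kin)
        res = CableModel(curve, kin, scheme="passive").fit(n_starts=15, seed=1)
        i04 = int(np.argmin(np.abs(curve.frequencies - 0.4)))
        others = np.delete(np.abs(res.resid), i04)
        assert abs(res.resid[i04]) > np.median(others)
        assert res.resid[i04] < 0  # measured phase dips below the passive fit


class TestAlphaTransientEdgeCases:
    def test_peak_value_is_fitted_curve_peak(self):
        t = np.linspace(0.0, 200.0, 2000)
        y = alpha_kernel(t, 3.0, 5.0, 50.0)
        fit = fit_alpha_transient(t, y)
        assert fit.peak_value == pytest.approx(y.max(), rel=1e-3)

    def test_scaling_linearity(self):
        t = np.linspace(0.0, 100.0, 1000)
        y = alpha_kernel(t, 1.0, 2.0, 20.0)
        f1 = fit_alpha_transient(t, y)
        f2 = fit_alpha_transient(t, 3.0 * y)
        assert f2.peak_value == pytest.approx(3.0 * f1.peak_value, rel=1e-6)


class TestAncova:
    def _noisy_curves(self, rng, offset=0.0, slope=0.0, n_rep=10, noise=0.01):
        f = default_frequency_grid()
        fa = np.tile(f, n_rep)
        ya = rng.normal(0.05 * np.log(fa), noise)
        fb = np.tile(f, n_rep)
        yb = rng.normal(0.05 * np.log(fb) + offset + slope * np.log(fb), noise)
        return fa, ya, fb, yb

    def test_identical_groups_not_significant(self, row70):
        f = default_frequency_grid()
        y = somatic_phase(f, row70.params)  # nonlinear in ln f, so SSE > 0
        cmp_ = compare_curves_ancova(f, y, f, y)
        assert cmp_.p_group > 0.99
        assert cmp_.p_interaction > 0.99

    def test_offset_five_noise_sd_detected(self, rng):
        fa, ya, fb, yb = self._noisy_curves(rng, offset=0.05, noise=0.01)
        cmp_ = compare_curves_ancova(fa, ya, fb, yb)
        assert cmp_.p_group < 0.001

    def test_slope_only_difference_hits_interaction_not_offset(self, rng):
        # centred ln f grid: a pure slope change leaves the group mean level
        # untouched, so only the interaction term should fire
        lnf0 = np.log(default_frequency_grid())
        lnf = np.tile(lnf0 - lnf0.mean(), 10)
        f = np.exp(lnf)
        ya = rng.normal(0.05 * lnf, 0.01)
        yb = rng.normal(0.05 * lnf + 0.03 * lnf, 0.01)
        cmp_ = compare_curves_ancova(f, ya, f, yb)
        assert cmp_.p_interaction < 0.001
        assert cmp_.p_group > 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compare_curves_ancova([1, 2], [0, 0], [1, 2, 3], [0, 0, 0])


class TestResultsSurface:
    def test_summary_and_frame_round_trip(self, row55):
        res = SomaModel(_soma_curve(row55.params), scheme="amplifying_only",
                        gamma_R=row55.params.gamma_R).fit(n_starts=5, seed=0)
        text = res.summary()
        assert "mu_n" in text and "fixed" in text and "free" in text
        df = results_to_frame([res], ["soma_-55mV"])
        assert df.loc[0, "curve_label"] == "soma_-55mV"
        assert df.loc[0, "mu_n"] == pytest.approx(row55.params.mu_n, rel=0.01)
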