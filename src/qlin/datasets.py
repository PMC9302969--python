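"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of (configuration, seed): the same inputs
reproduce the same dataset bit for bit.  The generating parameters are
returned alongside the data as a :class:`GroundTruth` record so every
analysis stage can be validated end to end without any external data.

The defaults emulate the experimental conditions of the source protocols:
2 mV somatic sinusoidal voltage commands over 0.2-20 Hz; sinusoidally
modulated 470 nm LED drive of a ChR2-bearing quasi-linear cable under
proximal vs. full-field illumination (LED command riding on its 40 mV
driver threshold); dF/F0 line scans of backpropagating-spike calcium
transients with a trapezoidal distance profile; sleep LFP with planted
slow waves and spindles plus modulated (TAN-like) and unmodulated
(SPN-like) spike trains; and EPSP/EPSC trial blocks with paired pulses and
a multiplicative drug effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calcium import LineScanRecording
from .lfp import EventSet, LFPRecording
from .membrane import ChR2Kinetics, IlluminationSpec, QuasiLinearParams, alpha_kernel
from .simulate import (
    CableDiscretization,
    LED_THRESHOLD_MV,
    chr2_photocurrent,
    simulate_cable_clamp,
    simulate_isopotential_clamp,
)
from .synaptic import TrialBlock
from .sysid import SweepProtocol, SweepRecording, build_sweep, default_frequency_grid

__all__ = [
    "GroundTruth",
    "DEFAULT_CHR2_KINETICS",
    "gen_sweep_dataset",
    "gen_optogenetic_dataset",
    "gen_calcium_dataset",
    "gen_lfp_dataset",
    "gen_epsp_dataset",
    "pink_noise",
]

#: literature-typical ChR2(H134R) on/off kinetics used when none are supplied
DEFAULT_CHR2_KINETICS = ChR2Kinetics(tau_r=2.0, tau_d=18.0, gain=1.0)


@dataclass
class GroundTruth:
    """The generating parameters of one synthetic dataset."""

    modality: str
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# electrical voltage-clamp sweeps

def gen_sweep_dataset(truth: QuasiLinearParams, n_cells: int = 10,
                      noise_sd_pa: float = 5.0, seed: int = 0,
                      frequencies: Optional[Sequence[float]] = None,
                      amplitude_mv: float = 2.0, sample_rate: float = 10000.0,
                      holding_mv: float = -70.0,
                      ) -> tuple[list[SweepRecording], GroundTruth]:
    """Voltage-clamp current responses of an isopotential quasi-linear soma.

    Each cell's response is the exact state-space integration of the
    membrane model plus additive white Gaussian current noise
    (``noise_sd_pa``, in pA).
    """
    rng = np.random.default_rng(seed)
    if frequencies is None:
        frequencies = default_frequency_grid()
    protocol, command = build_sweep(frequencies, amplitude_mv, sample_rate,
                                    modality="voltage_clamp_electrical")
    dt = 1000.0 / sample_rate
    clean = simulate_isopotential_clamp(truth, command, dt)
    recs = []
    for i in range(n_cells):
        noise = rng.normal(0.0, noise_sd_pa, size=len(command))
        recs.append(SweepRecording(
            protocol=protocol, command=command.copy(), response=clean + noise,
            holding_potential=holding_mv, cell_id=f"cell{i:02d}",
        ))
    gt = GroundTruth(modality="voltage_clamp_electrical", seed=seed, params={
        "qlin": truth, "noise_sd_pa": noise_sd_pa, "n_cells": n_cells,
        "amplitude_mv": amplitude_mv, "sample_rate": sample_rate,
    })
    return recs, gt


# ---------------------------------------------------------------------------
# optogenetic cable sweeps

def _led_sweep(frequencies, amplitude_mv, sample_rate, modality):
    return build_sweep(frequencies, amplitude_mv, sample_rate, modality=modality,
                       offset=LED_THRESHOLD_MV + amplitude_mv)


def gen_optogenetic_dataset(truth: QuasiLinearParams, r_prox: float = 0.5,
                            r_full: float = 1.0,
                            kin: ChR2Kinetics = DEFAULT_CHR2_KINETICS,
                            gains: tuple[float, float] = (1.0, 1.0),
                            noise_sd: float = 0.0, seed: int = 0,
                            frequencies: Optional[Sequence[float]] = None,
                            sample_rate: float = 2500.0,
                            n_compartments: int = 200, total_length: float = 5.0,
                            led_amplitudes_mv: tuple[float, float] = (480.0, 30.0),
                            ) -> tuple[SweepRecording, SweepRecording, GroundTruth]:
    """Paired proximal / full-field LED sweep responses of one membrane truth.

    The LED command (mV of driver voltage, minimum at the 40 mV threshold)
    is converted to an inward ChR2 photocurrent density and injected into
    all cable compartments within the illuminated electrotonic extent; the
    somatic clamp current is returned with additive noise.
    """
    rng = np.random.default_rng(seed)
    if frequencies is None:
        frequencies = default_frequency_grid()
    dt = 1000.0 / sample_rate
    disc = CableDiscretization(n_compartments=n_compartments,
                               total_length=total_length, dt=dt)
    out = []
    for extent, modality, gain, amp in zip(
        (r_prox, r_full), ("led_proximal", "led_full_field"), gains, led_amplitudes_mv,
    ):
        protocol, command = _led_sweep(frequencies, amp, sample_rate, modality)
        drive = chr2_photocurrent(command, kin, dt) * gain
        illum = IlluminationSpec(extent_r=extent,
                                 label="proximal" if modality == "led_proximal"
                                 else "full_field")
        resp = simulate_cable_clamp(truth, disc, drive, illum)
        resp = resp + rng.normal(0.0, noise_sd, size=len(resp))
        out.append(SweepRecording(protocol=protocol, command=command,
                                  response=resp, cell_id="cell00",
                                  condition=modality))
    gt = GroundTruth(modality="optogenetic", seed=seed, params={
        "qlin": truth, "kin": kin, "r_prox": r_prox, "r_full": r_full,
        "gains": gains, "noise_sd": noise_sd, "sample_rate": sample_rate,
        "n_compartments": n_compartments, "total_length": total_length,
    })
    return out[0], out[1], gt


# ---------------------------------------------------------------------------
# calcium line scans

def _trapezoid_amplitude(d_um: float, plateau: float, rise_end: float,
                         breakpoint: float, decay_slope: float,
                         somatic_fraction: float = 0.6) -> float:
    """bAP transient amplitude vs. distance: rise (surface-to-volume), plateau,
    then linear decay beyond the breakpoint (floored at 10% of plateau)."""
    if d_um <= rise_end:
        return plateau * (somatic_fraction + (1 - somatic_fraction) * d_um / rise_end)
    if d_um <= breakpoint:
        return plateau
    return max(plateau - decay_slope * (d_um - breakpoint), 0.1 * plateau)


def gen_calcium_dataset(plateau_amp_pct: float = 20.0, rise_end_um: float = 20.0,
                        breakpoint_um: float = 70.0,
                        decay_slope_pct_per_um: float = 0.3,
                        n_sites: int = 60, rate_hz: float = 1.0,
                        duration_s: float = 60.0, sample_rate: float = 500.0,
                        noise_sd_pct: float = 2.0, seed: int = 0,
                        n_cells: int = 8, max_distance_um: float = 150.0,
                        flat_profile: bool = False,
                        distal_step_frac: Optional[float] = None,
                        tau_r_ms: float = 20.0, tau_d_ms: float = 250.0,
                        ) -> tuple[list[LineScanRecording], GroundTruth]:
    """dF/F0 line-scan traces at known dendritic distances.

    Somatic spikes follow a pacemaker-like point process (gamma ISIs,
    CV ~ 0.1); each spike adds an alpha-function calcium transient whose
    amplitude follows the trapezoidal distance profile (or is flat when
    ``flat_profile`` for null tests, or a two-level step of relative size
    ``distal_step_frac`` beyond the breakpoint for planted proximal/distal
    comparisons), plus white indicator noise.
    """
    rng = np.random.default_rng(seed)
    recs = []
    shape = 100.0  # gamma shape: CV = 1/sqrt(shape) = 0.1, pacemaker-like
    dt_ms = 1000.0 / sample_rate
    n_samp = int(round(duration_s * sample_rate))
    kernel_t = np.arange(0.0, 10.0 * tau_d_ms, dt_ms)
    kernel = alpha_kernel(kernel_t, 1.0, tau_r_ms, tau_d_ms)
    kernel /= kernel.max()  # unit-peak transient
    for i in range(n_sites):
        d = float(rng.uniform(2.0, max_distance_um))
        if flat_profile:
            amp = plateau_amp_pct
        elif distal_step_frac is not None:
            amp = plateau_amp_pct * (1.0 - (distal_step_frac if d > breakpoint_um
                                            else 0.0))
        else:
            amp = _trapezoid_amplitude(d, plateau_amp_pct, rise_end_um,
                                       breakpoint_um, decay_slope_pct_per_um)
        isi = rng.gamma(shape, scale=1.0 / (rate_hz * shape),
                        size=int(duration_s * rate_hz * 3) + 10)
        spikes = np.cumsum(isi)
        spikes = spikes[(spikes > 1.0) & (spikes < duration_s - 2.0)]
        dff = rng.normal(0.0, noise_sd_pct, size=n_samp)
        for ts in spikes:
            j = int(round(ts * sample_rate))
            k = min(len(kernel), n_samp - j)
            dff[j:j + k] += amp * kernel[:k]
        recs.append(LineScanRecording(
            dff=dff, sample_rate=sample_rate, distance_um=d, spike_times=spikes,
            cell_id=f"cell{i % n_cells:02d}",
        ))
    gt = GroundTruth(modality="calcium_linescan", seed=seed, params={
        "plateau_amp_pct": plateau_amp_pct, "rise_end_um": rise_end_um,
        "breakpoint_um": breakpoint_um,
        "decay_slope_pct_per_um": decay_slope_pct_per_um,
        "flat_profile": flat_profile, "distal_step_frac": distal_step_frac,
        "rate_hz": rate_hz,
        "tau_r_ms": tau_r_ms, "tau_d_ms": tau_d_ms,
        "noise_sd_pct": noise_sd_pct,
    })
    return recs, gt


# ---------------------------------------------------------------------------
# sleep LFP with planted events and spike trains

def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Unit-SD noise with a 1/f**exponent power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n)
    return out / out.std()


@dataclass
class LFPDataset:
    lfp: LFPRecording
    tan_spikes: np.ndarray
    spn_spikes: np.ndarray
    true_slow_waves: EventSet
    true_spindles: EventSet
    truth: GroundTruth


def _biphasic_modulation(lag_s: np.ndarray, dip_frac: float, excite_frac: float,
                         dip_width_s: float = 0.15,
                         excite_offset_s: float = 0.35,
                         excite_width_s: float = 0.12) -> np.ndarray:
    """TAN-like rate modulation: central dip flanked by two excitation lobes."""
    dip = -dip_frac * np.exp(-0.5 * (lag_s / dip_width_s) ** 2)
    exc = excite_frac * (
        np.exp(-0.5 * ((lag_s - excite_offset_s) / excite_width_s) ** 2)
        + np.exp(-0.5 * ((lag_s + excite_offset_s) / excite_width_s) ** 2)
    )
    return dip + exc


def gen_lfp_dataset(duration_s: float = 300.0, sample_rate: float = 1000.0,
                    sw_rate_hz: float = 0.45, spindle_rate_hz: float = 0.05,
                    sw_amp_sd: float = 8.0, sw_duration_s: float = 0.8,
                    spindle_amp_sd: float = 6.0, spindle_freq_hz: float = 13.0,
                    spindle_duration_s: float = 1.0,
                    tan_baseline_hz: float = 5.0, tan_dip_frac: float = 0.8,
                    tan_excite_frac: float = 0.6, spn_rate_hz: float = 2.0,
                    noise_exponent: float = 1.0, seed: int = 0,
                    ) -> LFPDataset:
    """Sleep-like LFP: pink-noise background plus planted slow waves
    (half-cosine deflections, amplitude in background-SD units) and spindle
    bursts (Hann-windowed 10-17 Hz oscillations), with a TAN-like spike
    train biphasically modulated around slow-wave peaks and an unmodulated
    SPN-like train.

    The default slow-wave rate is set so that planted events make up
    roughly the top third of all 0.25-2 s half-waves of the background
    (matching the detector's retain-top-30% convention: the retained events
    are then the planted ones).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    lfp = pink_noise(n, rng, exponent=noise_exponent)

    # planted slow waves: half-cosine deflections on a jittered lattice
    n_sw = int(duration_s * sw_rate_hz)
    sw_peaks = []
    if n_sw:
        lattice = (np.arange(n_sw) + 0.5) * duration_s / n_sw
        jit = rng.uniform(-0.25, 0.25, size=n_sw) * duration_s / n_sw
        half = sw_duration_s / 2.0
        for tp in np.clip(lattice + jit, half + 1.0, duration_s - half - 1.0):
            i0 = int((tp - half) * sample_rate)
            i1 = int((tp + half) * sample_rate)
            t = np.arange(i1 - i0) / sample_rate
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfp[i0:i1] += sign * sw_amp_sd * np.sin(np.pi * t / sw_duration_s)
            sw_peaks.append((i0 + np.argmax(np.abs(
                sw_amp_sd * np.sin(np.pi * t / sw_duration_s)))) / sample_rate)
    sw_peaks = np.array(sorted(sw_peaks))
    true_sw = EventSet(kind="slow_wave", peak_times=sw_peaks,
                       amplitudes=np.full(len(sw_peaks), sw_amp_sd),
                       start_times=sw_peaks - sw_duration_s / 2,
                       end_times=sw_peaks + sw_duration_s / 2)

    # planted spindles: Hann-windowed sinusoidal bursts, kept clear of slow waves
    n_sp = int(duration_s * spindle_rate_hz)
    sp_peaks = []
    guard = 0.5 * (sw_duration_s + spindle_duration_s)
    for _ in range(n_sp * 4):
        if len(sp_peaks) >= n_sp:
            break
        tp = rng.uniform(2.0, duration_s - 2.0)
        if len(sw_peaks) and np.min(np.abs(sw_peaks - tp)) < guard:
            continue
        if sp_peaks and np.min(np.abs(np.array(sp_peaks) - tp)) < 2 * spindle_duration_s:
            continue
        i0 = int((tp - spindle_duration_s / 2) * sample_rate)
        i1 = int((tp + spindle_duration_s / 2) * sample_rate)
        t = np.arange(i1 - i0) / sample_rate
        env = np.hanning(i1 - i0)
        lfp[i0:i1] += spindle_amp_sd * env * np.sin(2 * np.pi * spindle_freq_hz * t)
        sp_peaks.append(tp)
    sp_peaks = np.array(sorted(sp_peaks))
    true_sp = EventSet(kind="spindle", peak_times=sp_peaks,
                       amplitudes=np.full(len(sp_peaks), spindle_amp_sd),
                       start_times=sp_peaks - spindle_duration_s / 2,
                       end_times=sp_peaks + spindle_duration_s / 2)

    # spike trains: inhomogeneous Poisson by thinning for the TAN-like unit
    t_grid = np.arange(n) / sample_rate
    mod = np.zeros(n)
    for tp in sw_peaks:
        m = np.abs(t_grid - tp) < 1.0
        mod[m] += _biphasic_modulation(t_grid[m] - tp, tan_dip_frac, tan_excite_frac)
    tan_rate = tan_baseline_hz * np.clip(1.0 + mod, 0.0, None)
    rmax = tan_rate.max() if len(tan_rate) else tan_baseline_hz
    n_cand = rng.poisson(rmax * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    keep = rng.random(n_cand) < tan_rate[np.minimum(
        (cand * sample_rate).astype(int), n - 1)] / rmax
    tan_spikes = cand[keep]
    spn_spikes = np.sort(rng.uniform(0.0, duration_s,
                                     size=rng.poisson(spn_rate_hz * duration_s)))

    rec = LFPRecording(signal=lfp, sample_rate=sample_rate, site_id="synthetic")
    gt = GroundTruth(modality="sleep_lfp", seed=seed, params={
        "sw_rate_hz": sw_rate_hz, "sw_amp_sd": sw_amp_sd,
        "sw_duration_s": sw_duration_s, "spindle_rate_hz": spindle_rate_hz,
        "spindle_amp_sd": spindle_amp_sd, "spindle_freq_hz": spindle_freq_hz,
        "tan_baseline_hz": tan_baseline_hz, "tan_dip_frac": tan_dip_frac,
        "tan_excite_frac": tan_excite_frac, "spn_rate_hz": spn_rate_hz,
        "noise_exponent": noise_exponent,
    })
    return LFPDataset(lfp=rec, tan_spikes=tan_spikes, spn_spikes=spn_spikes,
                      true_slow_waves=true_sw, true_spindles=true_sp, truth=gt)


# ---------------------------------------------------------------------------
# EPSP / EPSC trial blocks

def gen_epsp_dataset(amp_mv: float = 1.5, ppr: float = 0.7,
                     drug_factor: float = 0.84, n_trials: int = 25,
                     n_cells: int = 11, noise_sd: float = 0.3, seed: int = 0,
                     mode: str = "EPSP", paired: bool = False,
                     sample_rate: float = 10000.0,
                     resting_mv: float = -60.0, cell_cv: float = 0.2,
                     tau_r_ms: float = 2.0, tau_d_ms: float = 20.0,
                     ) -> tuple[list[TrialBlock], list[TrialBlock], GroundTruth]:
    """Pre/post drug trial blocks of alpha-shaped synaptic responses.

    Per-cell mean amplitudes are log-normally dispersed around ``amp_mv``
    (coefficient of variation ``cell_cv``); the post-drug condition scales
    every response by ``drug_factor``.  ``paired=True`` emits 64-trial
    paired-pulse blocks (two pulses 100 ms apart, second scaled by ``ppr``).
    """
    rng = np.random.default_rng(seed)
    stim = (0.1, 0.2) if paired else (0.1,)
    trial_len = int(round((stim[-1] + 0.15) * sample_rate))
    dt_ms = 1000.0 / sample_rate
    kt = np.arange(0.0, 10.0 * tau_d_ms, dt_ms)
    kernel = alpha_kernel(kt, 1.0, tau_r_ms, tau_d_ms)
    kernel /= kernel.max()
    if mode == "EPSC":
        kernel = -kernel
    n_tr = 64 if paired else n_trials

    baseline = resting_mv if mode == "EPSP" else 0.0

    def make_block(cell_amp: float, cell_id: str, condition: str) -> TrialBlock:
        traces = baseline + rng.normal(0.0, noise_sd, size=(n_tr, trial_len))
        for amp_i, t0 in zip((cell_amp, cell_amp * ppr), stim):
            j = int(round(t0 * sample_rate))
            k = min(len(kernel), trial_len - j)
            traces[:, j:j + k] += amp_i * kernel[:k]
        return TrialBlock(traces=traces, sample_rate=sample_rate, stim_times=stim,
                          mode=mode, cell_id=cell_id, condition=condition)

    pre_blocks, post_blocks = [], []
    for i in range(n_cells):
        cell_amp = amp_mv * rng.lognormal(mean=0.0, sigma=cell_cv)
        cid = f"cell{i:02d}"
        pre_blocks.append(make_block(cell_amp, cid, "pre"))
        post_blocks.append(make_block(cell_amp * drug_factor, cid, "post"))
    gt = GroundTruth(modality="synaptic_trials", seed=seed, params={
        "amp_mv": amp_mv, "ppr": ppr, "drug_factor": drug_factor,
        "n_trials": n_tr, "n_cells": n_cells, "noise_sd": noise_sd,
        "mode": mode, "paired": paired, "cell_cv": cell_cv,
    })
    return pre_blocks, post_blocks, gt
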