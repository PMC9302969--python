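"""Slow-wave and sleep-spindle detection in LFP, and peri-event firing rates.

Slow waves (0.5-4 Hz) are detected as filtered half-waves between
consecutive zero crossings with durations of 0.25-2 s; amplitude outliers
(> 5 SD above the mean) are treated as artifacts, and only the top 30% of
events by amplitude are retained.  Spindles (10-17 Hz) are detected from
the Hilbert envelope of the band-passed signal: core threshold 3 SD above
the mean, boundaries at 0.5 SD, duration 0.5-3 s, with a 20-30 Hz
control-band veto (4.5 SD) against broadband/high-frequency artifacts.
All thresholds are SD-relative, so detection is invariant to an overall
amplitude scale.

Peri-event conditional firing rates carry a percentile confidence band
built from the distribution of rate bins in flanking windows (|lag| >= 1 s),
the null for "is the rate modulated around the event peak?".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "LFPRecording",
    "SlowWaveConfig",
    "SpindleConfig",
    "EventSet",
    "ConditionalRate",
    "detect_slow_waves",
    "detect_spindles",
    "conditional_rate",
]


@dataclass
class LFPRecording:
    """A local-field-potential trace (mV) at a fixed sample rate."""

    signal: np.ndarray
    sample_rate: float
    site_id: Optional[str] = None
    sleep_stage_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sleep_stage_mask is not None:
            self.sleep_stage_mask = np.asarray(self.sleep_stage_mask, dtype=bool)
            if len(self.sleep_stage_mask) != len(self.signal):
                raise ValueError("sleep_stage_mask must match the signal length")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.sample_rate


@dataclass(frozen=True)
class SlowWaveConfig:
    band_hz: tuple[float, float] = (0.5, 4.0)
    filter_order: int = 2
    duration_s: tuple[float, float] = (0.25, 2.0)
    artifact_sd: float = 5.0
    top_fraction: float = 0.3


@dataclass(frozen=True)
class SpindleConfig:
    band_hz: tuple[float, float] = (10.0, 17.0)
    filter_order: int = 2
    core_sd: float = 3.0
    boundary_sd: float = 0.5
    duration_s: tuple[float, float] = (0.5, 3.0)
    control_band_hz: tuple[float, float] = (20.0, 30.0)
    control_sd: float = 4.5
    waveform_band_hz: tuple[float, float] = (4.0, 25.0)
    waveform_order: int = 4
    screen_band_power: bool = False
    screen_power_ratio: float = 0.5   # spindle-band vs control-band power ratio


@dataclass
class EventSet:
    """Detected events of one kind, with the config that produced them."""

    kind: str
    peak_times: np.ndarray
    amplitudes: np.ndarray
    start_times: np.ndarray
    end_times: np.ndarray
    config: object = None

    def __post_init__(self) -> None:
        for name in ("peak_times", "amplitudes", "start_times", "end_times"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.peak_times) == len(self.amplitudes)
                == len(self.start_times) == len(self.end_times)):
            raise ValueError("event arrays must be aligned")
        if len(self.peak_times) and not (
            np.all(self.start_times <= self.peak_times)
            and np.all(self.peak_times <= self.end_times)
        ):
            raise ValueError("require start <= peak <= end for every event")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class ConditionalRate:
    """Peri-trigger firing rate with a percentile confidence band."""

    bin_centers: np.ndarray
    rate: np.ndarray
    ci_low: float
    ci_high: float
    n_triggers: int
    flank_mask: np.ndarray = field(default_factory=lambda: np.array([]))


def _bandpass_sos(band: tuple[float, float], order: int, fs: float):
    return sps.butter(order, band, btype="bandpass", fs=fs, output="sos")


def _masked(values: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    return values if mask is None else values[mask]


def detect_slow_waves(lfp: LFPRecording, cfg: SlowWaveConfig = SlowWaveConfig()
                      ) -> EventSet:
    """Detect slow-wave half-wave events; see module docstring for the rules."""
    if lfp.duration_s < 60:
        raise ValueError("recording must be at least 60 s long")
    fs = lfp.sample_rate
    filt = sps.sosfiltfilt(_bandpass_sos(cfg.band_hz, cfg.filter_order, fs), lfp.signal)

    # half-waves between consecutive zero crossings of the filtered trace
    sign = np.sign(filt)
    sign[sign == 0] = 1
    zc = np.flatnonzero(np.diff(sign) != 0) + 1
    starts, ends, peaks, amps = [], [], [], []
    lo_d, hi_d = cfg.duration_s
    for a, b in zip(zc[:-1], zc[1:]):
        dur = (b - a) / fs
        if not (lo_d <= dur <= hi_d):
            continue
        seg = filt[a:b]
        if lfp.sleep_stage_mask is not None and not lfp.sleep_stage_mask[a:b].all():
            continue
        i_ext = a + int(np.argmax(np.abs(seg)))
        starts.append(a / fs)
        ends.append(b / fs)
        peaks.append(i_ext / fs)
        amps.append(abs(filt[i_ext]))
    amps = np.array(amps)
    starts, ends, peaks = np.array(starts), np.array(ends), np.array(peaks)

    if len(amps):
        # artifact rejection on the candidate amplitude distribution
        keep = amps <= amps.mean() + cfg.artifact_sd * amps.std()
        starts, ends, peaks, amps = starts[keep], ends[keep], peaks[keep], amps[keep]

    n_keep = int(np.floor(cfg.top_fraction * len(amps)))
    order = np.argsort(-amps, kind="stable")[:n_keep]
    order = np.sort(order)
    return EventSet(kind="slow_wave", peak_times=peaks[order], amplitudes=amps[order],
                    start_times=starts[order], end_times=ends[order], config=cfg)


def detect_spindles(lfp: LFPRecording, cfg: SpindleConfig = SpindleConfig()
                    ) -> EventSet:
    """Detect sleep spindles from the band-passed Hilbert envelope."""
    fs = lfp.sample_rate
    if fs < 200:
        raise ValueError("sample_rate must be >= 200 Hz for spindle detection")
    mask = lfp.sleep_stage_mask
    band = sps.sosfiltfilt(_bandpass_sos(cfg.band_hz, cfg.filter_order, fs), lfp.signal)
    env = np.abs(sps.hilbert(band))
    ctrl = sps.sosfiltfilt(_bandpass_sos(cfg.control_band_hz, cfg.filter_order, fs),
                           lfp.signal)
    ctrl_env = np.abs(sps.hilbert(ctrl))

    env_ref = _masked(env, mask)
    ctrl_ref = _masked(ctrl_env, mask)
    mu, sd = env_ref.mean(), env_ref.std()
    cmu, csd = ctrl_ref.mean(), ctrl_ref.std()

    if cfg.screen_band_power:
        # site screen: meaningful spindle-band activity relative to control band
        if np.mean(env_ref**2) < cfg.screen_power_ratio * np.mean(ctrl_ref**2):
            return EventSet(kind="spindle", peak_times=[], amplitudes=[],
                            start_times=[], end_times=[], config=cfg)

    core = env > mu + cfg.core_sd * sd
    bound = env > mu + cfg.boundary_sd * sd
    if mask is not None:
        core &= mask

    starts, ends, peaks, amps = [], [], [], []
    lo_d, hi_d = cfg.duration_s
    # boundary regions: contiguous runs above the 0.5 SD line
    edges = np.diff(bound.astype(int))
    run_starts = list(np.flatnonzero(edges == 1) + 1)
    run_ends = list(np.flatnonzero(edges == -1) + 1)
    if bound[0]:
        run_starts.insert(0, 0)
    if bound[-1]:
        run_ends.append(len(bound))
    for a, b in zip(run_starts, run_ends):
        if not core[a:b].any():
            continue
        dur = (b - a) / fs
        if not (lo_d <= dur <= hi_d):
            continue
        if ctrl_env[a:b].max() > cmu + cfg.control_sd * csd:
            continue  # high-frequency contamination: not a spindle
        i_pk = a + int(np.argmax(env[a:b]))
        starts.append(a / fs)
        ends.append(b / fs)
        peaks.append(i_pk / fs)
        amps.append(env[i_pk])
    return EventSet(kind="spindle", peak_times=peaks, amplitudes=amps,
                    start_times=starts, end_times=ends, config=cfg)


def spindle_waveform(lfp: LFPRecording, event_start_s: float, event_end_s: float,
                     cfg: SpindleConfig = SpindleConfig()) -> np.ndarray:
    """Reported waveform of one spindle (wide-band Butterworth filtered)."""
    fs = lfp.sample_rate
    sos = sps.butter(cfg.waveform_order, cfg.waveform_band_hz, btype="bandpass",
                     fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, lfp.signal)
    a, b = int(event_start_s * fs), int(event_end_s * fs)
    return filt[a:b]


def conditional_rate(spike_times: np.ndarray, triggers: np.ndarray,
                     bin_s: float = 0.02, window: tuple[float, float] = (-2.0, 2.0),
                     flank_s: float = 1.0) -> ConditionalRate:
    """Peri-trigger firing rate with a 99% percentile confidence band.

    The rate is the across-trigger histogram in spikes/s.  The band is the
    [0.5, 99.5] percentile range of the rate values in the flanking bins
    (|lag| >= ``flank_s``), computed conservatively (outward-rounding
    percentiles), so that under a stationary process roughly 1% (and by
    construction no more than ~2/(n_flank+1)) of independent bins fall
    outside it.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    triggers = np.asarray(triggers, dtype=float)
    if len(triggers) == 0:
        raise ValueError("need at least one trigger")
    lo, hi = window
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    for t in triggers:
        rel = spike_times[np.searchsorted(spike_times, t + lo):
                          np.searchsorted(spike_times, t + hi)] - t
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(triggers) * bin_s)
    flank = np.abs(centers) >= flank_s
    if flank.sum() < 10:
        raise ValueError("too few flanking bins to build a confidence band")
    ci_low = float(np.percentile(rate[flank], 0.5, method="lower"))
    ci_high = float(np.percentile(rate[flank], 99.5, method="higher"))
    return ConditionalRate(bin_centers=centers, rate=rate, ci_low=ci_low,
                           ci_high=ci_high, n_triggers=len(triggers),
                           flank_mask=flank)
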