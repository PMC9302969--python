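"""Sinusoidal sweep protocols and cross-correlation system identification.

A sweep is a concatenated sequence of single-frequency sinusoidal segments
(0.2-20 Hz by default, 2 mV amplitude for electrical commands).  Per
segment, the phase between command and response is read off the location of
the peak of their cross-correlation function (CCF) and the magnitude from
the CCF peak value.  The estimators are deliberately the simple,
experimentally motivated ones rather than direct Fourier demodulation.

Sign conventions (all phases in cycles, mapped to (-0.5, 0.5]):

* electrical (voltage-clamp) modality: the reported phase is the *negative*
  of the response lag, so a capacitive membrane (current leads voltage)
  reports a positive phase delay, matching ``arg y(f) / 2pi``;
* LED modalities: the photocurrent is inward, i.e. in antiphase with the
  LED command, so 0.5 cycles are subtracted from the raw CCF lag phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedPhaseError
from .simulate import LED_THRESHOLD_MV

__all__ = [
    "MODALITIES",
    "SweepSegment",
    "SweepProtocol",
    "SweepRecording",
    "TransferCurve",
    "default_frequency_grid",
    "build_sweep",
    "estimate_transfer_segment",
    "sweep_to_transfer_curve",
    "aggregate_transfer_curves",
]

MODALITIES = ("voltage_clamp_electrical", "led_proximal", "led_full_field")

#: frequency grid (Hz) used throughout when none is given; the exact set in
#: the 0.2-20 Hz band is a protocol configuration choice
DEFAULT_FREQUENCIES = (0.2, 0.4, 0.6, 0.8, 1.0, 1.4, 2.0, 3.0, 4.0, 5.0,
                       7.0, 10.0, 12.0, 15.0, 18.0, 20.0)


def default_frequency_grid() -> np.ndarray:
    return np.array(DEFAULT_FREQUENCIES)


@dataclass(frozen=True)
class SweepSegment:
    frequency: float
    duration: float
    amplitude: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        cycles = self.frequency * self.duration
        if not math.isclose(cycles, round(cycles), abs_tol=1e-9):
            raise ValueError(
                f"segment at {self.frequency} Hz: duration*frequency = {cycles} "
                "must be a whole number of cycles"
            )


@dataclass(frozen=True)
class SweepProtocol:
    segments: tuple[SweepSegment, ...]
    sample_rate: float
    modality: str = "voltage_clamp_electrical"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        freqs = [s.frequency for s in self.segments]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("segment frequencies must be strictly increasing")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([s.frequency for s in self.segments])

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment_slices(self) -> list[slice]:
        out, start = [], 0
        for seg in self.segments:
            n = int(round(seg.duration * self.sample_rate))
            out.append(slice(start, start + n))
            start += n
        return out

    def n_samples(self) -> int:
        return sum(int(round(s.duration * self.sample_rate)) for s in self.segments)

    def command_trace(self) -> np.ndarray:
        """Concatenated sinusoids; each segment starts at phase zero."""
        parts = []
        for seg in self.segments:
            n = int(round(seg.duration * self.sample_rate))
            t = np.arange(n) / self.sample_rate
            parts.append(seg.offset + seg.amplitude * np.sin(2 * np.pi * seg.frequency * t))
        return np.concatenate(parts)


@dataclass
class SweepRecording:
    """A protocol plus the command/response trace pair it produced."""

    protocol: SweepProtocol
    command: np.ndarray
    response: np.ndarray
    holding_potential: Optional[float] = None
    cell_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        n = self.protocol.n_samples()
        if len(self.command) != n or len(self.response) != n:
            raise ValueError(
                f"command/response length must equal protocol samples ({n}); "
                f"got {len(self.command)}, {len(self.response)}"
            )


@dataclass
class TransferCurve:
    """Per-frequency phase (cycles) and magnitude, optionally with SEMs.

    Magnitude units are GOhm for the electrical modality and pA per unit LED
    command for the optogenetic modalities.
    """

    frequencies: np.ndarray
    phase: np.ndarray
    magnitude: Optional[np.ndarray] = None
    phase_sem: Optional[np.ndarray] = None
    magnitude_sem: Optional[np.ndarray] = None
    n_cells: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude is not None:
            self.magnitude = np.asarray(self.magnitude, dtype=float)
        for name in ("phase", "magnitude", "phase_sem", "magnitude_sem"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.frequencies):
                raise ValueError(f"{name} is not aligned with frequencies")
        if np.any(self.phase <= -0.5) or np.any(self.phase > 0.5):
            raise ValueError("phases must lie in (-0.5, 0.5]")


def _segment_duration(f: float, allowed: Sequence[float], min_duration: float = 3.0) -> float:
    """Smallest allowed duration holding a whole number of cycles.

    Falls back to the smallest integer number of whole periods reaching
    ``min_duration`` when no allowed duration qualifies.
    """
    for d in sorted(allowed):
        if math.isclose(f * d, round(f * d), abs_tol=1e-9):
            return float(d)
    cycles = math.ceil(min_duration * f - 1e-9)
    return max(cycles, 1) / f


def build_sweep(frequencies: Sequence[float], amplitude: float, sample_rate: float,
                modality: str = "voltage_clamp_electrical",
                allowed_durations: Sequence[float] = (3.0, 5.0),
                offset: Optional[float] = None) -> tuple[SweepProtocol, np.ndarray]:
    """Build a sweep protocol and its command trace.

    For LED modalities the default command rides on the LED driver threshold:
    offset = threshold + amplitude, so the command minimum touches the
    threshold (darkest point of the cycle produces no light).
    """
    freqs = sorted(float(f) for f in frequencies)
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be positive")
    if offset is None:
        offset = LED_THRESHOLD_MV + amplitude if modality.startswith("led") else 0.0
    segments = tuple(
        SweepSegment(frequency=f, duration=_segment_duration(f, allowed_durations),
                     amplitude=amplitude, offset=offset)
        for f in freqs
    )
    protocol = SweepProtocol(segments=segments, sample_rate=sample_rate, modality=modality)
    return protocol, protocol.command_trace()


def _wrap_phase(phi: float) -> float:
    """Map to (-0.5, 0.5]."""
    phi = (phi + 0.5) % 1.0 - 0.5
    return 0.5 if phi == -0.5 else phi


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location and value via a parabola through 3 points."""
    if i == 0 or i == len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    val = b - 0.25 * (a - c) * delta
    return i + delta, val


def estimate_transfer_segment(command_seg: np.ndarray, response_seg: np.ndarray,
                              f: float, sample_rate: float,
                              modality: str = "voltage_clamp_electrical"
                              ) -> tuple[float, float]:
    """Phase (cycles) and magnitude of one single-frequency segment.

    The first full cycle is discarded as a settling transient (when more
    than one whole cycle is available); the CCF is
    the mean lagged product over the remaining whole cycles (circular, which
    is exact for a periodic steady state); the peak is refined by parabolic
    interpolation and the lag search restricted to +/- half a period.
    """
    if modality not in MODALITIES + ("raw_lag",):
        raise ValueError(f"modality must be one of {MODALITIES} or 'raw_lag'")
    x = np.asarray(command_seg, dtype=float)
    y = np.asarray(response_seg, dtype=float)
    if x.shape != y.shape:
        raise ValueError("command and response segments must have equal length")
    n_cycle = sample_rate / f
    n_skip = int(math.ceil(n_cycle))
    m_whole = int((len(x) - n_skip) * f / sample_rate)
    if m_whole < 1:
        # a segment holding exactly one period (the lowest protocol
        # frequency) is used whole; there is no cycle to spare
        n_skip = 0
        m_whole = int(len(x) * f / sample_rate)
    if m_whole < 1:
        raise ValueError("segment must hold at least one whole cycle")
    n_use = int(round(m_whole * n_cycle))
    x = x[n_skip:n_skip + n_use]
    y = y[n_skip:n_skip + n_use]
    if np.all(y == y[0]):
        raise UndefinedPhaseError("response is constant; phase undefined")
    x = x - x.mean()
    y = y - y.mean()

    ccf = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n=n_use) / n_use
    max_lag = int(round(n_cycle / 2))
    lags = np.arange(-max_lag, max_lag + 1)
    vals = ccf[lags % n_use]
    order = np.argsort(-vals, kind="stable")
    # break exact ties toward the smaller |lag|
    best = min((i for i in order[: np.sum(vals == vals[order[0]])]),
               key=lambda i: abs(lags[i]))
    pk, ccf_max = _parabolic_refine(vals, int(best))
    lag_samples = lags[0] + pk
    raw = f * lag_samples / sample_rate

    amp_cmd = math.sqrt(2.0 * np.mean(x**2))
    if modality == "voltage_clamp_electrical":
        phase = _wrap_phase(-raw)
        magnitude = amp_cmd**2 / (2.0 * ccf_max)
    elif modality == "raw_lag":
        # positive delay = positive phase, no antiphase correction
        phase = _wrap_phase(raw)
        magnitude = 2.0 * ccf_max / amp_cmd**2
    else:
        phase = _wrap_phase(raw - 0.5)
        magnitude = 2.0 * ccf_max / amp_cmd**2
    return phase, magnitude


def sweep_to_transfer_curve(rec: SweepRecording) -> TransferCurve:
    """Per-frequency phase/magnitude estimates for one recording."""
    phases, mags = [], []
    for seg, sl in zip(rec.protocol.segments, rec.protocol.segment_slices()):
        phi, mag = estimate_transfer_segment(
            rec.command[sl], rec.response[sl], seg.frequency,
            rec.protocol.sample_rate, rec.protocol.modality,
        )
        phases.append(phi)
        mags.append(mag)
    return TransferCurve(
        frequencies=rec.protocol.frequencies,
        phase=np.array(phases),
        magnitude=np.array(mags),
        metadata={"modality": rec.protocol.modality, "cell_id": rec.cell_id,
                  "condition": rec.condition},
    )


def aggregate_transfer_curves(curves: Sequence[TransferCurve]) -> TransferCurve:
    """Mean +/- SEM across per-cell transfer curves on a common grid."""
    if not curves:
        raise ValueError("need at least one curve")
    f0 = curves[0].frequencies
    for c in curves[1:]:
        if not np.allclose(c.frequencies, f0):
            raise ValueError("curves must share a frequency grid")
    ph = np.stack([c.phase for c in curves])
    mg = (np.stack([c.magnitude for c in curves])
          if all(c.magnitude is not None for c in curves) else None)
    n = len(curves)
    sem = lambda a: a.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(len(f0))
    return TransferCurve(
        frequencies=f0,
        phase=ph.mean(axis=0),
        magnitude=None if mg is None else mg.mean(axis=0),
        phase_sem=sem(ph),
        magnitude_sem=None if mg is None else sem(mg),
        n_cells=n,
        metadata=dict(curves[0].metadata),
    )
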