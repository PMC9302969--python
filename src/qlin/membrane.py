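"""Closed-form quasi-linear membrane and cable transfer functions.

The quasi-linear approximation linearizes a neuron's voltage-gated
conductances around a holding potential.  The resulting membrane admittance
(relative to leak, and up to an impedance scale) is

    y(f) = gamma_R + i*omega*tau + mu_n / (1 + i*omega*tau_n)
                                 + mu_h / (1 + i*omega*tau_h),

with omega = 2*pi*f.  A negative ``mu_n`` (regenerative current, e.g. a
persistent sodium current) amplifies low frequencies; a positive ``mu_h``
with a slow time constant (restorative current, e.g. HCN) produces a
subhertz impedance resonance and a negative lobe in the phase delay.

A semi-infinite dendritic cable with a homogeneous quasi-linear membrane,
driven over an electrotonic extent ``r`` from the (clamped) soma, transfers
distributed drive to the soma with the complex factor (1 - exp(-g*r)) / g,
where g = sqrt(alpha + i*beta) is the propagation constant.  Optogenetic
drive is additionally low-pass filtered by channelrhodopsin-2 kinetics,
whose kernel is the difference-of-exponentials ("alpha function")
A*(exp(-t/tau_d) - exp(-t/tau_r)).

All phases are expressed in cycles (i.e. radians / 2*pi), positive meaning
the response lags the drive.  Time constants are in milliseconds,
frequencies in hertz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DegenerateModelError

__all__ = [
    "QuasiLinearParams",
    "TransferComponents",
    "PropagationConstant",
    "ChR2Kinetics",
    "IlluminationSpec",
    "admittance",
    "admittance_components",
    "somatic_phase",
    "somatic_impedance",
    "propagation_constant",
    "cable_phase",
    "cable_amplitude",
    "chr2_transfer",
    "optogenetic_model",
    "alpha_kernel",
    "alpha_kernel_peak_time",
]

#: milliseconds per second; time constants are stored in ms, frequencies in Hz
_MS = 1e-3


@dataclass(frozen=True)
class QuasiLinearParams:
    """One quasi-linear membrane model.

    Parameters
    ----------
    tau_m : float
        Membrane time constant in ms (> 0).
    gamma_R : float
        Total conductance relative to leak (> 0).
    mu_n : float
        Amplification parameter (dimensionless, typically <= 0).
    tau_n : float
        Kinetic time constant of the amplifying term, ms.
    mu_h : float
        Resonance parameter (dimensionless, typically >= 0).
    tau_h : float
        Kinetic time constant of the restorative term, ms.
    amp_scale : float, optional
        Impedance scale in GOhm; required only for absolute impedance.
    """

    tau_m: float
    gamma_R: float = 1.0
    mu_n: float = 0.0
    tau_n: float = 1.0
    mu_h: float = 0.0
    tau_h: float = 1.0
    amp_scale: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_n", "tau_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.gamma_R > 0:
            raise ValueError(f"gamma_R must be positive, got {self.gamma_R}")
        if not (self.gamma_R + self.mu_n + self.mu_h > 0):
            raise ValueError(
                "DC-unstable parameter set: gamma_R + mu_n + mu_h = "
                f"{self.gamma_R + self.mu_n + self.mu_h} <= 0"
            )
        if self.amp_scale is not None and not self.amp_scale > 0:
            raise ValueError(f"amp_scale must be positive, got {self.amp_scale}")

    @classmethod
    def passive(cls, tau_m: float, gamma_R: float = 1.0,
                amp_scale: Optional[float] = None) -> "QuasiLinearParams":
        """A passive membrane: mu_n = mu_h = 0."""
        return cls(tau_m=tau_m, gamma_R=gamma_R, amp_scale=amp_scale)

    def without_nonlinearities(self) -> "QuasiLinearParams":
        """Same leak/capacitance but mu_n = mu_h = 0 (passive variant)."""
        return replace(self, mu_n=0.0, mu_h=0.0)


@dataclass(frozen=True)
class TransferComponents:
    """Real (alpha) and imaginary (beta) parts of the normalized admittance."""

    alpha: np.ndarray | float
    beta: np.ndarray | float


@dataclass(frozen=True)
class PropagationConstant:
    """Real and imaginary parts p, q of sqrt(alpha + i*beta), Re > 0."""

    p: np.ndarray | float
    q: np.ndarray | float


@dataclass(frozen=True)
class ChR2Kinetics:
    """Channelrhodopsin-2 kernel parameters: rise/decay times (ms) and gain."""

    tau_r: float
    tau_d: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_r < self.tau_d):
            raise ValueError(
                f"require 0 < tau_r < tau_d, got tau_r={self.tau_r}, tau_d={self.tau_d}"
            )


@dataclass(frozen=True)
class IlluminationSpec:
    """Illuminated electrotonic extent r measured from the soma.

    ``extent_r`` is in units of the dendritic space constant; ``np.inf``
    describes whole-arbor (full-field) illumination of a semi-infinite cable.
    """

    extent_r: float
    label: str = "proximal"

    _LABELS = ("proximal", "full_field")

    def __post_init__(self) -> None:
        if not self.extent_r > 0:
            raise ValueError(f"extent_r must be positive, got {self.extent_r}")
        if self.label not in self._LABELS:
            raise ValueError(f"label must be one of {self._LABELS}, got {self.label!r}")


def _check_freq(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("frequencies must be finite and non-negative")
    return f


def admittance(f, params: QuasiLinearParams) -> np.ndarray:
    """Complex normalized admittance y(f); see module docstring."""
    f = _check_freq(f)
    w = 2 * np.pi * f
    return (
        params.gamma_R
        + 1j * w * params.tau_m * _MS
        + params.mu_n / (1 + 1j * w * params.tau_n * _MS)
        + params.mu_h / (1 + 1j * w * params.tau_h * _MS)
    )


def admittance_components(f, params: QuasiLinearParams) -> TransferComponents:
    """alpha(f), beta(f): real and imaginary parts of the admittance."""
    y = admittance(f, params)
    return TransferComponents(alpha=y.real, beta=y.imag)


def somatic_phase(f, params: QuasiLinearParams):
    """Phase delay of an isopotential quasi-linear soma, in cycles.

    Equals arg y(f) / 2*pi, in (-0.5, 0.5).  Positive values mean the clamp
    current leads the voltage command by that fraction of a cycle (the
    convention in which a capacitive membrane has positive phase).
    """
    y = admittance(f, params)
    if np.any(y == 0):
        raise DegenerateModelError("admittance is zero; phase undefined")
    return np.angle(y) / (2 * np.pi)


def somatic_impedance(f, params: QuasiLinearParams):
    """|Z(f)| = amp_scale / |y(f)| in GOhm."""
    if params.amp_scale is None:
        raise ConfigurationError("amp_scale (GOhm) is required for absolute impedance")
    return params.amp_scale / np.abs(admittance(f, params))


def propagation_constant(comp: TransferComponents) -> PropagationConstant:
    """Principal square root g = p + i*q of alpha + i*beta, with p > 0.

    The principal branch maps sign(q) = sign(beta), which is what makes the
    cable phase negative in the resonant (beta < 0) regime and the
    semi-infinite solution exp(-g*x) decay with distance.
    """
    z = np.asarray(comp.alpha, dtype=float) + 1j * np.asarray(comp.beta, dtype=float)
    if np.any(z == 0):
        raise DegenerateModelError("alpha + i*beta = 0; propagation constant undefined")
    g = np.sqrt(z)
    return PropagationConstant(p=g.real, q=g.imag)


def _gamma(f, params: QuasiLinearParams) -> np.ndarray:
    comp = admittance_components(f, params)
    pc = propagation_constant(comp)
    return np.asarray(pc.p) + 1j * np.asarray(pc.q)


def cable_phase(f, params: QuasiLinearParams, illum: IlluminationSpec):
    """Dendritic phase delay (cycles) for drive over electrotonic extent r.

    phi_d = (1/2pi) * [atan2(q, p) - atan2(sin(q r), exp(p r) - cos(q r))],
    i.e. minus the argument of the cable transfer (1 - exp(-g r)) / g.
    For r -> inf this tends to atan2(q, p) / 2pi.
    """
    r = illum.extent_r
    g = _gamma(f, params)
    p, q = g.real, g.imag
    lead = np.arctan2(q, p)
    if math.isinf(r):
        return lead / (2 * np.pi)
    # exp(p*r) can overflow for large p*r; the limit is then the r->inf form
    with np.errstate(over="ignore"):
        second = np.arctan2(np.sin(q * r), np.exp(p * r) - np.cos(q * r))
    return (lead - second) / (2 * np.pi)


def cable_amplitude(f, params: QuasiLinearParams, illum: IlluminationSpec, gain: float = 1.0):
    """|1 - exp(-g r)| / |g|: relative amplitude of the cable transfer.

    ``gain`` converts the dimensionless modulus into the caller's units
    (e.g. pA per unit LED drive).
    """
    r = illum.extent_r
    g = _gamma(f, params)
    if math.isinf(r):
        return gain / np.abs(g)
    return gain * np.abs(1.0 - np.exp(-g * r)) / np.abs(g)


def chr2_transfer(f, kin: ChR2Kinetics):
    """Amplitude (normalized to 1 at DC) and phase delay (cycles) of ChR2.

    These are the modulus and argument of the Fourier transform of the
    difference-of-exponentials kernel, which factorizes as
    1 / ((1 + i*w*tau_r)(1 + i*w*tau_d)).  The phase is continuous in f,
    passing through 0.25 cycles where 1 - tau_r*tau_d*w^2 = 0, and tends to
    0.5 cycles as f -> inf.
    """
    f = _check_freq(f)
    w = 2 * np.pi * f
    tr = kin.tau_r * _MS
    td = kin.tau_d * _MS
    re = 1.0 - tr * td * w**2
    im = w * (tr + td)
    amplitude = 1.0 / np.sqrt(re**2 + im**2)
    # im >= 0 for f >= 0, so atan2 lands in [0, pi]: already continuous,
    # monotone in f, no unwrapping needed.
    phase = np.arctan2(im, re) / (2 * np.pi)
    return amplitude, phase


def optogenetic_model(f, params: QuasiLinearParams, illum: IlluminationSpec,
                      kin: ChR2Kinetics, gain: float = 1.0):
    """Full optogenetic transfer: ChR2 kinetics in series with the cable.

    Returns (amplitude, phase); the phase is the exact sum of the ChR2 phase
    and the dendritic phase, and the amplitude the product of the two
    component amplitudes times ``gain``.
    """
    a_c, phi_c = chr2_transfer(f, kin)
    phi_d = cable_phase(f, params, illum)
    a_d = cable_amplitude(f, params, illum)
    return gain * a_c * a_d, phi_c + phi_d


def alpha_kernel(t, amplitude: float, tau_r: float, tau_d: float):
    """Difference-of-exponentials kernel A*(exp(-t/tau_d) - exp(-t/tau_r)).

    Zero at t = 0 (and for t < 0), positive for positive ``amplitude`` when
    tau_r < tau_d; peaks at :func:`alpha_kernel_peak_time`.
    """
    if not (0 < tau_r < tau_d):
        raise ValueError(f"require 0 < tau_r < tau_d, got {tau_r}, {tau_d}")
    t = np.asarray(t, dtype=float)
    out = amplitude * (np.exp(-t / tau_d) - np.exp(-t / tau_r))
    return np.where(t >= 0, out, 0.0)


def alpha_kernel_peak_time(tau_r: float, tau_d: float) -> float:
    """t* = tau_r*tau_d / (tau_d - tau_r) * ln(tau_d / tau_r)."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
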