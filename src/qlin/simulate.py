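"""Time-domain simulators realizing the same physics as :mod:`qlin.membrane`.

These brute-force integrators serve two purposes: they are independent
numerical oracles for the closed-form transfer functions, and they are the
backbone of the synthetic-data generators.  The membrane is linear by
construction (quasi-linear approximation), so every simulator here is a
linear time-invariant system; doubling the drive must exactly double the
response.

Units follow the rest of the package: voltages in mV, time constants and
``dt`` in ms, currents in pA when an impedance scale (GOhm) is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.sparse import diags_array
from scipy.sparse.linalg import splu

from .membrane import ChR2Kinetics, IlluminationSpec, QuasiLinearParams, alpha_kernel

__all__ = [
    "CableDiscretization",
    "simulate_isopotential_clamp",
    "simulate_cable_clamp",
    "chr2_photocurrent",
    "LED_THRESHOLD_MV",
]

#: LED driver voltage threshold in mV: commands at or below this produce no light.
LED_THRESHOLD_MV = 40.0


@dataclass(frozen=True)
class CableDiscretization:
    """Numerical grid for the compartmental cable.

    ``n_compartments`` interior compartments span ``total_length``
    electrotonic units; the somatic end is voltage-clamped (Dirichlet at the
    perturbation value, normally 0) and the distal end is sealed (Neumann).
    A sealed end at L >= 5 approximates the semi-infinite cable because end
    effects decay as exp(-2 p L).
    """

    n_compartments: int = 400
    total_length: float = 5.0
    dt: float = 0.1
    clamp_value: float = 0.0

    def __post_init__(self) -> None:
        if self.n_compartments < 50:
            raise ValueError("n_compartments must be >= 50")
        if not self.total_length > 0:
            raise ValueError("total_length must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def dx(self) -> float:
        return self.total_length / self.n_compartments

    @property
    def positions(self) -> np.ndarray:
        """Electrotonic positions of compartment centers, soma at x=0 excluded."""
        return self.dx * np.arange(1, self.n_compartments + 1)


def _check_dt(dt: float, params: QuasiLinearParams) -> None:
    taus = [params.tau_m]
    if params.mu_n != 0.0:
        taus.append(params.tau_n)
    if params.mu_h != 0.0:
        taus.append(params.tau_h)
    limit = min(taus) / 20.0
    if dt >= limit:
        raise ValueError(
            f"dt={dt} ms too coarse for time constants; require dt < {limit:.4g} ms"
        )


def _gating_filter(v: np.ndarray, mu: float, tau: float, dt: float) -> np.ndarray:
    """Exact exponential update of tau*dw/dt = mu*v - w, trapezoidal in v.

    Implemented as a first-order IIR filter so long traces stay cheap:
    w[n] = a*w[n-1] + (1-a)*mu*(v[n] + v[n-1])/2 with a = exp(-dt/tau).
    """
    if mu == 0.0:
        return np.zeros_like(v)
    a = np.exp(-dt / tau)
    c = (1.0 - a) * mu / 2.0
    return sps.lfilter([c, c], [1.0, -a], v)


def simulate_isopotential_clamp(params: QuasiLinearParams, v_command: np.ndarray,
                                dt: float) -> np.ndarray:
    """Clamp current (pA) of an isopotential quasi-linear membrane.

    Integrates i(t) = (1/Amp) * (gamma_R*v + tau_m*dv/dt + w_n + w_h) with
    tau_k*dw_k/dt = mu_k*v - w_k.  ``v_command`` is the voltage perturbation
    around the holding potential, in mV.  If ``amp_scale`` is unset the
    current is returned in normalized units (Amp = 1 GOhm).
    """
    v = np.asarray(v_command, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("v_command must be finite")
    _check_dt(dt, params)
    w_n = _gating_filter(v, params.mu_n, params.tau_n, dt)
    w_h = _gating_filter(v, params.mu_h, params.tau_h, dt)
    dvdt = np.gradient(v, dt)
    amp = params.amp_scale if params.amp_scale is not None else 1.0
    return (params.gamma_R * v + params.tau_m * dvdt + w_n + w_h) / amp


def simulate_cable_clamp(params: QuasiLinearParams, disc: CableDiscretization,
                         drive: np.ndarray, illum: IlluminationSpec) -> np.ndarray:
    """Somatic clamp current of a compartmental quasi-linear cable.

    The cable PDE in electrotonic units,

        tau_m dV/dt = -gamma_R V - w_n - w_h + d^2V/dX^2 + I(X, t),

    is discretized on ``disc`` with the soma clamped (V=0 perturbation) and
    the far end sealed, and integrated with a Crank-Nicolson step for the
    stiff diffusion part; the slow gating variables w_k are advanced with
    exact exponential updates.  ``drive`` is either a 1-D trace applied
    uniformly to all compartments with position <= ``illum.extent_r`` or a
    (n_compartments, n_t) array of per-compartment current densities; a 2-D
    drive must itself vanish beyond the illuminated extent.

    Returns the axial current flowing into the clamped somatic node,
    V[1]/dx per unit axial conductance (arbitrary but consistent units; the
    phase and relative amplitude are the meaningful outputs).
    """
    _check_dt(disc.dt, params)
    if not disc.total_length > (0 if np.isinf(illum.extent_r) else illum.extent_r):
        raise ValueError("total_length must exceed the illuminated extent")
    n = disc.n_compartments
    x = disc.positions
    mask = x <= illum.extent_r

    drive = np.asarray(drive, dtype=float)
    if drive.ndim == 1:
        n_t = drive.shape[0]
        dense = np.zeros((n,), dtype=bool)
        dense[mask] = True
    elif drive.ndim == 2:
        if drive.shape[0] != n:
            raise ValueError(
                f"2-D drive must have {n} rows (one per compartment), got {drive.shape[0]}"
            )
        if np.any(drive[~mask] != 0):
            raise ValueError("drive is nonzero beyond the illuminated extent")
        n_t = drive.shape[1]
        dense = None
    else:
        raise ValueError("drive must be 1-D or 2-D")

    dx2 = disc.dx**2
    dt = disc.dt
    # Laplacian with Dirichlet at the soma (ghost value 0) and sealed far end.
    main = np.full(n, -2.0 / dx2)
    main[-1] = -1.0 / dx2
    off = np.full(n - 1, 1.0 / dx2)
    lap = diags_array([off, main, off], offsets=[-1, 0, 1], format="csc")
    eye = diags_array([np.ones(n)], offsets=[0], format="csc")
    # Crank-Nicolson operators for tau_m dV/dt = L V - gamma_R V + s(t)
    lin = lap - params.gamma_R * eye
    lhs = splu(((params.tau_m / dt) * eye - 0.5 * lin).tocsc())
    rhs_op = ((params.tau_m / dt) * eye + 0.5 * lin).tocsc()

    a_n = np.exp(-dt / params.tau_n)
    a_h = np.exp(-dt / params.tau_h)

    v = np.zeros(n)
    w_n = np.zeros(n)
    w_h = np.zeros(n)
    out = np.empty(n_t)
    out[0] = 0.0
    for k in range(1, n_t):
        if dense is not None:
            src = np.where(dense, 0.5 * (drive[k - 1] + drive[k]), 0.0)
        else:
            src = 0.5 * (drive[:, k - 1] + drive[:, k])
        rhs = rhs_op @ v - (w_n + w_h) + src
        v_new = lhs.solve(rhs)
        v_mid = 0.5 * (v + v_new)
        w_n = a_n * w_n + (1 - a_n) * params.mu_n * v_mid
        w_h = a_h * w_h + (1 - a_h) * params.mu_h * v_mid
        v = v_new
        out[k] = v[0] / disc.dx
    return out


def chr2_photocurrent(led_command: np.ndarray, kin: ChR2Kinetics, dt: float,
                      threshold: float = LED_THRESHOLD_MV) -> np.ndarray:
    """ChR2 current density evoked by an LED driver-voltage command.

    The suprathreshold part of the command, (led - threshold)_+, is convolved
    with the unit-area difference-of-exponentials kernel and scaled by
    ``kin.gain``.  The output is *inward* (negative), which is why downstream
    phase estimation applies the half-cycle antiphase correction.
    """
    led = np.asarray(led_command, dtype=float)
    if np.any(led < 0):
        raise ValueError("led_command must be non-negative")
    rect = np.clip(led - threshold, 0.0, None)
    t = np.arange(0.0, 14.0 * kin.tau_d, dt)
    kernel = alpha_kernel(t, 1.0, kin.tau_r, kin.tau_d)
    kernel /= kernel.sum() * dt
    out = sps.fftconvolve(rect, kernel)[: led.shape[0]] * dt
    return -kin.gain * out
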