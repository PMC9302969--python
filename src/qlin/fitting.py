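"""Least-squares fitting of quasi-linear models to transfer curves.

The module follows the Model/Results idiom: build a model object from data,
call ``.fit()``, get a results object carrying estimates, approximate
standard errors, diagnostics and a ``summary()`` table.

Three models are provided:

* :class:`ChR2KineticsModel` - fit the difference-of-exponentials kernel to
  a pulse-averaged photocurrent transient (rise/decay times of ChR2);
* :class:`SomaModel` - fit the isopotential quasi-linear phase delay (and
  optionally log-impedance) to a measured transfer curve;
* :class:`CableModel` - fit the ChR2-kinetics-plus-quasi-linear-cable phase
  model to an optogenetic transfer curve, estimating the illuminated
  electrotonic extent ``r`` and the membrane parameters.

Identifiability note: the phase of the quasi-linear admittance is invariant
to scaling (gamma_R, mu_n, mu_h, tau) by a common factor, and the free
impedance scale absorbs the same factor in the magnitude.  Phase fits
therefore keep ``gamma_R`` *fixed* (supplied by the caller, e.g. from a DC
input-resistance measurement, or left at its default); the remaining
parameters are then identifiable.  See docs/methods.md.

Curve-level statistical comparison (:func:`compare_curves_ancova`) follows
the standard ANCOVA on the natural logarithm of frequency: the response is
modelled as y ~ ln(f) * group and F-tests are reported for the group offset
and the group x ln(f) interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import FitFailureError
from .membrane import (
    ChR2Kinetics,
    IlluminationSpec,
    QuasiLinearParams,
    alpha_kernel,
    alpha_kernel_peak_time,
    cable_phase,
    chr2_transfer,
    somatic_phase,
)
from .sysid import TransferCurve

__all__ = [
    "FitResults",
    "SomaModel",
    "CableModel",
    "ChR2KineticsModel",
    "AlphaTransientFit",
    "fit_alpha_transient",
    "CurveComparison",
    "compare_curves_ancova",
    "results_to_frame",
]

# fitting bounds (natural units); taus and r are searched in log10 space
_BOUNDS = {
    "mu_n": (-20.0, 0.0),
    "mu_h": (0.0, 20.0),
    "tau_n": (1.0, 20000.0),
    "tau_h": (1.0, 20000.0),
    "gamma_R": (1e-6, 50.0),
    "tau_m": (1.0, 500.0),
    "extent_r": (1e-3, 5.0),
}
_LOG_PARAMS = {"tau_n", "tau_h", "tau_m", "extent_r"}


def _to_internal(name: str, value: float) -> float:
    return math.log10(value) if name in _LOG_PARAMS else value


def _from_internal(name: str, value: float) -> float:
    return 10.0**value if name in _LOG_PARAMS else value


class _MultiStartMixin:
    """Shared multi-start least-squares driver (Latin hypercube starts)."""

    free_names: tuple[str, ...]

    def _residuals(self, values: dict[str, float]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _bounds_internal(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free_names:
            a, b = self._bounds[name]
            lo.append(_to_internal(name, a))
            hi.append(_to_internal(name, b))
        return np.array(lo), np.array(hi)

    def _run_multistart(self, n_starts: int, seed: int,
                        extra_starts: Sequence[np.ndarray] = ()):
        lo, hi = self._bounds_internal()
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        starts = [lo + s * (hi - lo) for s in sampler.random(n_starts)]
        starts = list(extra_starts) + starts

        def fun(theta: np.ndarray) -> np.ndarray:
            values = {n: _from_internal(n, v) for n, v in zip(self.free_names, theta)}
            return self._residuals(values)

        best, best_idx = None, -1
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(fun, np.clip(x0, lo, hi), bounds=(lo, hi),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best, best_idx = sol, i
        if best is None:
            raise FitFailureError("all starts failed")
        values = {n: _from_internal(n, v) for n, v in zip(self.free_names, best.x)}
        se = _standard_errors(best, self.free_names)
        return values, best, best_idx, se


def _standard_errors(sol, names: tuple[str, ...]) -> dict[str, float]:
    """Approximate SEs from the Jacobian at the optimum (internal coords
    back-propagated through the log10 transform); NaN when singular."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (2 * sol.cost / dof)
        diag = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        diag = np.full(n, np.nan)
    out = {}
    for i, name in enumerate(names):
        if name in _LOG_PARAMS:
            out[name] = diag[i] * math.log(10) * _from_internal(name, sol.x[i])
        else:
            out[name] = diag[i]
    return out


@dataclass
class FitResults:
    """Estimates, uncertainties and diagnostics from one model fit."""

    model_name: str
    scheme: str
    params: dict[str, float]
    bse: dict[str, float]
    free_names: tuple[str, ...]
    residual_norm: float
    n_obs: int
    n_starts: int
    best_start: int
    converged: bool
    flags: dict = field(default_factory=dict)
    fittedvalues: Optional[np.ndarray] = None
    resid: Optional[np.ndarray] = None

    @property
    def free_mask(self) -> dict[str, bool]:
        return {k: (k in self.free_names) for k in self.params}

    def qlin_params(self, amp_scale: Optional[float] = None) -> QuasiLinearParams:
        p = self.params
        return QuasiLinearParams(
            tau_m=p["tau_m"], gamma_R=p.get("gamma_R", 1.0),
            mu_n=p.get("mu_n", 0.0), tau_n=p.get("tau_n", 1.0),
            mu_h=p.get("mu_h", 0.0), tau_h=p.get("tau_h", 1.0),
            amp_scale=amp_scale if amp_scale is not None else p.get("amp_scale"),
        )

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit results ({self.scheme})",
            "=" * 58,
            f"{'parameter':<12}{'estimate':>14}{'std err':>12}{'status':>10}",
            "-" * 58,
        ]
        for name, val in self.params.items():
            se = self.bse.get(name, float("nan"))
            status = "free" if name in self.free_names else "fixed"
            se_s = f"{se:>12.4g}" if status == "free" and np.isfinite(se) else f"{'-':>12}"
            lines.append(f"{name:<12}{val:>14.5g}{se_s}{status:>10}")
        lines += [
            "-" * 58,
            f"n obs: {self.n_obs}   residual norm: {self.residual_norm:.4g}   "
            f"starts: {self.n_starts} (best #{self.best_start})   "
            f"converged: {self.converged}",
        ]
        for k, v in self.flags.items():
            lines.append(f"note: {k} = {v}")
        return "\n".join(lines)


class SomaModel(_MultiStartMixin):
    """Quasi-linear fit of an isopotential soma to a transfer curve.

    Parameters
    ----------
    curve : TransferCurve
        Measured per-frequency phases (cycles), optionally magnitudes (GOhm).
    scheme : {"amplifying_only", "amplifying_plus_resonant"}
        Whether the restorative (mu_h, tau_h) term is included.
    gamma_R : float
        Total conductance relative to leak, held fixed during the fit (see
        the identifiability note in the module docstring).
    magnitude_weight : float
        Weight of the log-magnitude residual term; 0 (default) fits phases
        only, which is the better-conditioned observable.  The impedance
        scale is profiled out analytically when magnitudes are used.
    """

    SCHEMES = ("amplifying_only", "amplifying_plus_resonant")

    def __init__(self, curve: TransferCurve, scheme: str = "amplifying_plus_resonant",
                 gamma_R: float = 1.0, magnitude_weight: float = 0.0):
        if scheme not in self.SCHEMES:
            raise ValueError(f"scheme must be one of {self.SCHEMES}")
        if len(curve.frequencies) < 6:
            raise ValueError("need at least 6 frequencies to fit the soma model")
        if magnitude_weight > 0 and curve.magnitude is None:
            raise ValueError("magnitude_weight > 0 requires curve.magnitude")
        self.curve = curve
        self.scheme = scheme
        self.gamma_R = float(gamma_R)
        self.magnitude_weight = float(magnitude_weight)
        self.free_names = (("mu_n", "tau_n", "tau_m")
                           if scheme == "amplifying_only"
                           else ("mu_n", "tau_n", "mu_h", "tau_h", "tau_m"))
        self._bounds = dict(_BOUNDS)
        # keep the DC-stability invariant gamma_R + mu_n + mu_h > 0 inside
        # the box: with mu_h >= 0 it suffices to bound mu_n above -gamma_R
        lo = max(_BOUNDS["mu_n"][0], -self.gamma_R + 1e-2)
        self._bounds["mu_n"] = (lo, _BOUNDS["mu_n"][1])

    def _params_from(self, values: dict[str, float]) -> QuasiLinearParams:
        return QuasiLinearParams(
            tau_m=values["tau_m"], gamma_R=self.gamma_R,
            mu_n=values.get("mu_n", 0.0), tau_n=values.get("tau_n", 1.0),
            mu_h=values.get("mu_h", 0.0), tau_h=values.get("tau_h", 1.0),
        )

    def _residuals(self, values: dict[str, float]) -> np.ndarray:
        p = self._params_from(values)
        f = self.curve.frequencies
        res = somatic_phase(f, p) - self.curve.phase
        if self.magnitude_weight > 0:
            from .membrane import admittance
            log_absy = np.log(np.abs(admittance(f, p)))
            log_mag = np.log(self.curve.magnitude)
            log_amp = np.mean(log_mag + log_absy)  # profiled impedance scale
            res_mag = (log_amp - log_absy) - log_mag
            res = np.concatenate([res, math.sqrt(self.magnitude_weight) * res_mag])
        return res

    def fit(self, n_starts: int = 20, seed: int = 0) -> FitResults:
        values, sol, best_idx, se = self._run_multistart(n_starts, seed)
        p = self._params_from(values)
        fitted = somatic_phase(self.curve.frequencies, p)
        params = {"mu_n": p.mu_n, "mu_h": p.mu_h, "tau_n": p.tau_n,
                  "tau_h": p.tau_h, "gamma_R": p.gamma_R, "tau_m": p.tau_m}
        flags = {}
        if self.magnitude_weight > 0:
            from .membrane import admittance
            log_absy = np.log(np.abs(admittance(self.curve.frequencies, p)))
            params["amp_scale"] = float(np.exp(np.mean(np.log(self.curve.magnitude)
                                                       + log_absy)))
        if self.scheme == "amplifying_plus_resonant":
            flags["resonance_detected"] = bool(p.mu_h > 1e-2
                                               and np.any(self.curve.phase < 0))
        return FitResults(
            model_name="SomaModel", scheme=self.scheme, params=params, bse=se,
            free_names=self.free_names,
            residual_norm=float(np.linalg.norm(self._residuals(values))),
            n_obs=len(self.curve.frequencies), n_starts=n_starts,
            best_start=best_idx, converged=bool(sol.success), flags=flags,
            fittedvalues=fitted, resid=self.curve.phase - fitted,
        )


class CableModel(_MultiStartMixin):
    """ChR2-kinetics-plus-cable phase fit of an optogenetic transfer curve.

    The ChR2 kinetics are estimated independently (pulse experiments) and
    held fixed; the fit adjusts the illuminated electrotonic extent
    ``extent_r`` and, per scheme, the membrane time constant alone
    (``passive``) or the full quasi-linear parameter set with ``gamma_R``
    fixed (``quasi_linear``).  Proximal and full-field curves are fitted
    independently.
    """

    SCHEMES = ("passive", "quasi_linear")

    def __init__(self, curve: TransferCurve, kinetics: ChR2Kinetics,
                 scheme: str = "quasi_linear", gamma_R: float = 1.0):
        if scheme not in self.SCHEMES:
            raise ValueError(f"scheme must be one of {self.SCHEMES}")
        if len(curve.frequencies) < 4:
            raise ValueError("need at least 4 frequencies to fit the cable model")
        self.curve = curve
        self.kinetics = kinetics
        self.scheme = scheme
        self.gamma_R = 1.0 if scheme == "passive" else float(gamma_R)
        self.free_names = (("tau_m", "extent_r") if scheme == "passive"
                           else ("mu_n", "tau_n", "mu_h", "tau_h", "tau_m", "extent_r"))
        self._bounds = dict(_BOUNDS)
        lo = max(_BOUNDS["mu_n"][0], -self.gamma_R + 1e-2)
        self._bounds["mu_n"] = (lo, _BOUNDS["mu_n"][1])

    def _params_from(self, values: dict[str, float]) -> QuasiLinearParams:
        return QuasiLinearParams(
            tau_m=values["tau_m"], gamma_R=self.gamma_R,
            mu_n=values.get("mu_n", 0.0), tau_n=values.get("tau_n", 1.0),
            mu_h=values.get("mu_h", 0.0), tau_h=values.get("tau_h", 1.0),
        )

    def _model_phase(self, values: dict[str, float]) -> np.ndarray:
        p = self._params_from(values)
        illum = IlluminationSpec(extent_r=values["extent_r"], label="proximal")
        f = self.curve.frequencies
        _, phi_c = chr2_transfer(f, self.kinetics)
        return phi_c + cable_phase(f, p, illum)

    def _residuals(self, values: dict[str, float]) -> np.ndarray:
        return self._model_phase(values) - self.curve.phase

    def fit(self, n_starts: int = 20, seed: int = 0) -> FitResults:
        values, sol, best_idx, se = self._run_multistart(n_starts, seed)
        p = self._params_from(values)
        fitted = self._model_phase(values)
        params = {"mu_n": p.mu_n, "mu_h": p.mu_h, "tau_n": p.tau_n,
                  "tau_h": p.tau_h, "gamma_R": p.gamma_R, "tau_m": p.tau_m,
                  "extent_r": values["extent_r"]}
        return FitResults(
            model_name="CableModel", scheme=self.scheme, params=params, bse=se,
            free_names=self.free_names,
            residual_norm=float(np.linalg.norm(self._residuals(values))),
            n_obs=len(self.curve.frequencies), n_starts=n_starts,
            best_start=best_idx, converged=bool(sol.success),
            fittedvalues=fitted, resid=self.curve.phase - fitted,
        )


# ---------------------------------------------------------------------------
# alpha-function transient fitting (ChR2 pulses, calcium STAs)

@dataclass
class AlphaTransientFit:
    """Fitted difference-of-exponentials transient."""

    amplitude: float          # kernel scale A (sign-free magnitude)
    tau_r: float              # ms
    tau_d: float              # ms
    peak_value: float         # value of the fitted curve at its peak
    peak_time: float          # ms
    sign: float               # +1 upward transient, -1 inward/downward
    residual_norm: float
    converged: bool

    @property
    def kinetics(self) -> ChR2Kinetics:
        return ChR2Kinetics(tau_r=self.tau_r, tau_d=self.tau_d, gain=self.amplitude)


def fit_alpha_transient(t_ms: np.ndarray, y: np.ndarray, n_starts: int = 8,
                        seed: int = 0) -> AlphaTransientFit:
    """Least-squares fit of A*(exp(-t/tau_d) - exp(-t/tau_r)) to a transient.

    ``t_ms`` is time from transient onset in ms.  The dominant deflection
    may be positive or negative; its sign is detected and A is kept
    positive (tau_r < tau_d enforced by parameterization).  A flat trace
    raises :class:`FitFailureError`.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have equal shapes")
    span = np.ptp(y)
    if span == 0 or not np.isfinite(span):
        raise FitFailureError("flat or non-finite trace; no transient to fit")
    sgn = 1.0 if abs(y.max()) >= abs(y.min()) else -1.0
    z = sgn * y
    zmax = z.max()
    if zmax <= 0:
        raise FitFailureError("no positive-going deflection after sign detection")

    t_peak = max(t[int(np.argmax(z))], 2 * (t[1] - t[0]) if len(t) > 1 else 1.0)

    def fun(theta):
        log_tr, log_delta, log_a = theta
        tr = 10.0**log_tr
        td = tr + 10.0**log_delta
        return alpha_kernel(t, 10.0**log_a, tr, td) - z

    # data-driven start plus jittered Latin-hypercube starts
    tr0, td0 = t_peak / 3.0, max(3.0 * t_peak, t_peak + 1.0)
    peak0 = (math.exp(-alpha_kernel_peak_time(tr0, td0) / td0)
             - math.exp(-alpha_kernel_peak_time(tr0, td0) / tr0))
    x0 = np.array([math.log10(tr0), math.log10(td0 - tr0), math.log10(zmax / peak0)])
    lo = np.array([-2.0, -1.0, math.log10(zmax) - 3.0])
    hi = np.array([3.0, 4.5, math.log10(zmax) + 3.0])
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = [x0] + [lo + s * (hi - lo) for s in sampler.random(n_starts)]

    best = None
    for s in starts:
        try:
            sol = least_squares(fun, np.clip(s, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("alpha-transient fit failed from all starts")
    tr = 10.0**best.x[0]
    td = tr + 10.0**best.x[1]
    a = 10.0**best.x[2]
    tp = alpha_kernel_peak_time(tr, td)
    peak = a * (math.exp(-tp / td) - math.exp(-tp / tr))
    return AlphaTransientFit(
        amplitude=a, tau_r=tr, tau_d=td, peak_value=peak, peak_time=tp, sign=sgn,
        residual_norm=float(np.sqrt(2 * best.cost)), converged=bool(best.success),
    )


class ChR2KineticsModel:
    """Fit ChR2 rise/decay kinetics to a pulse-averaged photocurrent.

    ``trace`` is the average current response to brief LED pulses (inward
    photocurrents are handled by sign detection); ``dt`` is the sample
    interval in ms.  ``fit()`` returns an :class:`AlphaTransientFit`; its
    ``.kinetics`` property is the :class:`~qlin.membrane.ChR2Kinetics`
    bundle used by the cable model.
    """

    def __init__(self, trace: np.ndarray, dt: float):
        self.trace = np.asarray(trace, dtype=float)
        if not dt > 0:
            raise ValueError("dt must be positive")
        self.dt = float(dt)

    def fit(self, n_starts: int = 8, seed: int = 0) -> AlphaTransientFit:
        t = np.arange(len(self.trace)) * self.dt
        return fit_alpha_transient(t, self.trace, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# curve-level statistics

@dataclass(frozen=True)
class CurveComparison:
    """ANCOVA of two response-vs-ln(frequency) curves."""

    f_group: float
    p_group: float
    f_interaction: float
    p_interaction: float
    n_a: int
    n_b: int


def compare_curves_ancova(f_a, y_a, f_b, y_b) -> CurveComparison:
    """F-tests for group offset and group x ln(f) interaction.

    Fits y ~ ln(f) * group by ordinary least squares over the pooled points
    and reports type-II F statistics, the standard test for a difference
    between two frequency-response curves sampled on (possibly unequal)
    frequency grids.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    f_a, y_a = np.ravel(f_a), np.ravel(y_a)
    f_b, y_b = np.ravel(f_b), np.ravel(y_b)
    if len(f_a) < 3 or len(f_b) < 3:
        raise ValueError("need at least 3 points per group")
    if f_a.max() < f_b.min() or f_b.max() < f_a.min():
        raise ValueError("groups must span overlapping frequency ranges")
    df = pd.DataFrame({
        "lnf": np.log(np.concatenate([f_a, f_b])),
        "y": np.concatenate([y_a, y_b]),
        "group": ["a"] * len(f_a) + ["b"] * len(f_b),
    })
    model = smf.ols("y ~ lnf * C(group)", data=df).fit()
    table = anova_lm(model, typ=2)
    g = table.loc["C(group)"]
    i = table.loc["lnf:C(group)"]

    def _clean(v: float) -> float:
        return float(v) if np.isfinite(v) else 1.0

    return CurveComparison(
        f_group=float(g["F"]), p_group=_clean(g["PR(>F)"]),
        f_interaction=float(i["F"]), p_interaction=_clean(i["PR(>F)"]),
        n_a=len(f_a), n_b=len(f_b),
    )


def results_to_frame(results: Sequence[FitResults], labels: Sequence[str]) -> pd.DataFrame:
    """Tabulate fit results in the published-table layout (one row per curve)."""
    rows = []
    for label, res in zip(labels, results):
        p = res.params
        rows.append({
            "curve_label": label,
            "mu_n": p.get("mu_n", np.nan), "mu_h": p.get("mu_h", np.nan),
            "tau_n_ms": p.get("tau_n", np.nan), "tau_h_ms": p.get("tau_h", np.nan),
            "gamma_R": p.get("gamma_R", np.nan), "tau_ms": p.get("tau_m", np.nan),
            "r": p.get("extent_r", np.nan), "amp_GOhm": p.get("amp_scale", np.nan),
            "residual": res.residual_norm,
        })
    return pd.DataFrame(rows)
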