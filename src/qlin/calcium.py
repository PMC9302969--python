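"""Spike-triggered averaging of dendritic calcium line scans.

Backpropagating action potentials (bAPs) leave a calcium footprint whose
amplitude, as a function of distance from the soma, reports how far
regenerative sodium channels support the spike.  The pipeline is: per-site
spike-triggered average (STA) of the dF/F0 trace, alpha-function fit of the
STA (the fitted peak is the amplitude measure, less biased than the raw
maximum), a 35 um moving average of amplitude vs. distance, and a
proximal/distal comparison across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import FitFailureError, InsufficientDataError
from .fitting import fit_alpha_transient

__all__ = [
    "LineScanRecording",
    "STAPoint",
    "DistanceProfile",
    "spike_triggered_average",
    "sta_amplitude",
    "distance_profile",
    "profile_breakpoint",
    "proximal_distal_test",
]


@dataclass
class LineScanRecording:
    """One dendritic line-scan site: dF/F0 trace (%) plus somatic spike times."""

    dff: np.ndarray
    sample_rate: float
    distance_um: float
    spike_times: np.ndarray
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.distance_um < 0:
            raise ValueError("distance_um must be non-negative")
        span = len(self.dff) / self.sample_rate
        if np.any((self.spike_times < 0) | (self.spike_times > span)):
            raise ValueError("spike_times must lie within the trace span")


@dataclass
class STAPoint:
    """Amplitude of the bAP calcium transient at one dendritic location."""

    distance_um: float
    amplitude: float              # peak of the fitted alpha function, % dF/F0
    A: float
    tau_r: float
    tau_d: float
    n_spikes: int
    cell_id: Optional[str] = None
    ok: bool = True


@dataclass
class DistanceProfile:
    """Moving-average amplitude profile along the dendrite."""

    eval_um: np.ndarray
    amplitude: np.ndarray
    window_um: float
    n_points: np.ndarray = field(default_factory=lambda: np.array([]))


def spike_triggered_average(rec: LineScanRecording,
                            window: tuple[float, float] = (0.2, 0.6),
                            min_spikes: int = 10,
                            baseline_s: float = 0.2):
    """STA of the dF/F0 trace around somatic spikes.

    ``window`` is (pre_s, post_s); only spikes whose full window lies inside
    the trace are used (truncated windows are dropped, and the usable count
    is returned).  Each segment is baseline-subtracted by its mean over the
    last ``baseline_s`` seconds before the spike.

    Returns ``(t_rel_s, sta, n_used)``.
    """
    pre_s, post_s = window
    fs = rec.sample_rate
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_base = max(int(round(baseline_s * fs)), 1)
    segs = []
    for ts in rec.spike_times:
        i = int(round(ts * fs))
        if i - n_pre < 0 or i + n_post > len(rec.dff):
            continue
        seg = rec.dff[i - n_pre:i + n_post].astype(float)
        seg = seg - seg[max(n_pre - n_base, 0):n_pre].mean()
        segs.append(seg)
    if len(segs) < min_spikes:
        raise InsufficientDataError(
            f"only {len(segs)} usable spikes (< {min_spikes})"
        )
    sta = np.mean(segs, axis=0)
    t_rel = (np.arange(-n_pre, n_post)) / fs
    return t_rel, sta, len(segs)


def sta_amplitude(t_rel_s: np.ndarray, sta: np.ndarray, distance_um: float = np.nan,
                  n_spikes: int = 0, cell_id: Optional[str] = None) -> STAPoint:
    """Alpha-function fit of the post-spike STA; amplitude = fitted peak.

    Fitting the smooth kernel and reading its peak is less biased by noise
    than taking the raw maximum of the STA.  A failed fit returns a point
    flagged ``ok=False`` (excluded downstream).
    """
    post = t_rel_s >= 0
    t_ms = t_rel_s[post] * 1000.0
    y = np.asarray(sta, dtype=float)[post]
    try:
        fit = fit_alpha_transient(t_ms, y)
    except FitFailureError:
        return STAPoint(distance_um=distance_um, amplitude=np.nan, A=np.nan,
                        tau_r=np.nan, tau_d=np.nan, n_spikes=n_spikes,
                        cell_id=cell_id, ok=False)
    return STAPoint(distance_um=distance_um, amplitude=fit.sign * fit.peak_value,
                    A=fit.amplitude, tau_r=fit.tau_r, tau_d=fit.tau_d,
                    n_spikes=n_spikes, cell_id=cell_id, ok=True)


def distance_profile(points: Sequence[STAPoint], window_um: float = 35.0
                     ) -> DistanceProfile:
    """Centered moving average of STA amplitude vs. distance.

    Evaluated at each point's own distance; windows shrink at the edges
    (only available data are averaged, nothing is padded in).
    """
    pts = [p for p in points if p.ok and np.isfinite(p.amplitude)]
    if len(pts) < 5:
        raise InsufficientDataError("need at least 5 valid points")
    d = np.array([p.distance_um for p in pts])
    a = np.array([p.amplitude for p in pts])
    order = np.argsort(d, kind="stable")
    d, a = d[order], a[order]
    if d.max() - d.min() < 2 * window_um:
        raise InsufficientDataError(
            f"points span {d.max() - d.min():.0f} um < 2 windows ({2 * window_um:.0f} um)"
        )
    half = window_um / 2.0
    amp = np.empty_like(d)
    npts = np.empty(len(d), dtype=int)
    for i, x in enumerate(d):
        m = np.abs(d - x) <= half
        amp[i] = a[m].mean()
        npts[i] = int(m.sum())
    return DistanceProfile(eval_um=d, amplitude=amp, window_um=window_um, n_points=npts)


def profile_breakpoint(profile: DistanceProfile, rise_end_um: float = 20.0,
                       drop_frac: float = 0.10) -> float:
    """Distance at which the smoothed amplitude profile starts to decay.

    The knee is operationalized as the first evaluation point beyond the
    profile maximum where the smoothed amplitude falls ``drop_frac`` below
    the plateau median (the median of profile values within ``drop_frac``
    of the maximum, past the initial rise).
    """
    d, a = profile.eval_um, profile.amplitude
    past_rise = d >= rise_end_um
    if not past_rise.any():
        raise InsufficientDataError("no profile points beyond the rise region")
    peak = a[past_rise].max()
    plateau = float(np.median(a[past_rise & (a >= (1 - drop_frac) * peak)]))
    i_peak = np.flatnonzero(past_rise & (a == a[past_rise].max()))[0]
    level = (1 - drop_frac) * plateau
    below = np.flatnonzero((np.arange(len(d)) > i_peak) & (a < level))
    if len(below) == 0:
        raise InsufficientDataError("profile never drops below the plateau")
    j = below[0]
    if j == 0 or a[j - 1] <= level:
        return float(d[j])
    # linear interpolation of the crossing between the bracketing points
    frac = (a[j - 1] - level) / (a[j - 1] - a[j])
    return float(d[j - 1] + frac * (d[j] - d[j - 1]))


def proximal_distal_test(points: Sequence[STAPoint], boundary_um: float = 70.0
                         ) -> tuple[float, float]:
    """Median percentage difference of distal vs. proximal amplitudes and p.

    When cell identities are present, per-cell medians on each side of the
    boundary are compared (each cell contributing one proximal and one
    distal value) and the percentage change is the median over cells of
    100 * (distal - proximal) / proximal.  Without cell identities the
    pooled per-point amplitudes are compared.  The p-value is from the
    two-sided Wilcoxon rank-sum test between the proximal and distal value
    sets.
    """
    pts = [p for p in points if p.ok and np.isfinite(p.amplitude)]
    prox = [p for p in pts if p.distance_um <= boundary_um]
    dist = [p for p in pts if p.distance_um > boundary_um]
    if len(prox) < 3 or len(dist) < 3:
        raise InsufficientDataError("need >= 3 points on each side of the boundary")

    have_cells = all(p.cell_id is not None for p in pts)
    if have_cells:
        cells = sorted({p.cell_id for p in pts})
        prox_vals, dist_vals, pct = [], [], []
        for c in cells:
            pv = [p.amplitude for p in prox if p.cell_id == c]
            dv = [p.amplitude for p in dist if p.cell_id == c]
            if not pv or not dv:
                continue
            pm, dm = float(np.median(pv)), float(np.median(dv))
            prox_vals.append(pm)
            dist_vals.append(dm)
            if pm > 0:
                pct.append(100.0 * (dm - pm) / pm)
        if len(pct) < 3:
            raise InsufficientDataError("fewer than 3 cells with data on both sides")
        median_pct = float(np.median(pct))
        stat = stats.ranksums(dist_vals, prox_vals)
    else:
        pv = np.array([p.amplitude for p in prox])
        dv = np.array([p.amplitude for p in dist])
        pm = float(np.median(pv))
        median_pct = 100.0 * (float(np.median(dv)) - pm) / pm
        stat = stats.ranksums(dv, pv)
    return median_pct, float(stat.pvalue)
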