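"""Published fitted parameter sets for striatal cholinergic interneurons.

Each preset is one fitted quasi-linear model: four somatic fits from
voltage-clamp sinusoidal perturbation (at -55 mV, at -70 mV, in TTX and in
ZD7288) and four dendritic fits from optogenetic sinusoidal drive (proximal
vs. full-field illumination, passive and quasi-linear schemes).  The somatic
rows carry an impedance scale in GOhm; the dendritic rows carry the fitted
electrotonic extent of illumination ``r``.

These serve as realistic ground-truth parameter sets for the synthetic-data
generators and as the reference inputs for round-trip validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .membrane import IlluminationSpec, QuasiLinearParams

__all__ = ["PresetRow", "PUBLISHED_FITS", "preset"]


@dataclass(frozen=True)
class PresetRow:
    """One published parameter set.

    ``scheme`` names the matching fitting scheme: ``amplifying_only``,
    ``amplifying_plus_resonant`` (somatic), ``passive`` or ``quasi_linear``
    (cable).  ``extent_r`` is present for the cable rows only.
    """

    label: str
    params: QuasiLinearParams
    scheme: str
    extent_r: Optional[float] = None

    @property
    def illumination(self) -> IlluminationSpec:
        if self.extent_r is None:
            raise ValueError(f"preset {self.label!r} has no illumination extent")
        kind = "proximal" if "proximal" in self.label else "full_field"
        return IlluminationSpec(extent_r=self.extent_r, label=kind)


PUBLISHED_FITS: dict[str, PresetRow] = {
    "soma_-55mV": PresetRow(
        label="soma_-55mV",
        params=QuasiLinearParams(mu_n=-3.9189, tau_n=28.0, gamma_R=5.4296,
                                 tau_m=41.8, amp_scale=2.4728),
        scheme="amplifying_only",
    ),
    "soma_-70mV": PresetRow(
        label="soma_-70mV",
        params=QuasiLinearParams(mu_n=-3.3854, mu_h=1.5863, tau_n=11.6,
                                 tau_h=1077.8, gamma_R=5.8722, tau_m=26.1,
                                 amp_scale=1.4229),
        scheme="amplifying_plus_resonant",
    ),
    "soma_TTX": PresetRow(
        label="soma_TTX",
        params=QuasiLinearParams(mu_n=-2.0178, tau_n=31.7, gamma_R=3.4610,
                                 tau_m=19.4, amp_scale=1.3809),
        scheme="amplifying_only",
    ),
    "soma_ZD7288": PresetRow(
        label="soma_ZD7288",
        params=QuasiLinearParams(mu_n=-1.8988, mu_h=0.4844, tau_n=13.4,
                                 tau_h=9107.5, gamma_R=2.6111, tau_m=17.2,
                                 amp_scale=0.8323),
        scheme="amplifying_plus_resonant",
    ),
    "cable_passive_proximal": PresetRow(
        label="cable_passive_proximal",
        params=QuasiLinearParams.passive(tau_m=35.8),
        scheme="passive",
        extent_r=0.4360,
    ),
    "cable_passive_full_field": PresetRow(
        label="cable_passive_full_field",
        params=QuasiLinearParams.passive(tau_m=26.8),
        scheme="passive",
        extent_r=1.0651,
    ),
    "cable_qlin_proximal": PresetRow(
        label="cable_qlin_proximal",
        params=QuasiLinearParams(mu_n=-1.4763, mu_h=3.4400, tau_n=60.0,
                                 tau_h=551.2, gamma_R=3.3405, tau_m=33.6),
        scheme="quasi_linear",
        extent_r=0.5788,
    ),
    "cable_qlin_full_field": PresetRow(
        label="cable_qlin_full_field",
        params=QuasiLinearParams(mu_n=-0.8885, mu_h=1.6646, tau_n=49.2,
                                 tau_h=403.3, gamma_R=3.8850, tau_m=45.3),
        scheme="quasi_linear",
        extent_r=1.0646,
    ),
}


def preset(label: str) -> PresetRow:
    """Look up a preset row by label (KeyError lists the available labels)."""
    try:
        return PUBLISHED_FITS[label]
    except KeyError:
        raise KeyError(f"unknown preset {label!r}; available: {sorted(PUBLISHED_FITS)}") from None
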