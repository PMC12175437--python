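"""Extracellular volume fraction (ECV) from T1 mapping.

ECV estimates the interstitial (extracellular) fraction of the myocardium —
a marker of diffuse fibrosis — from the change in longitudinal relaxation
rate (1/T1) of myocardium relative to blood after a gadolinium bolus,
corrected for the blood cell fraction:

    ECV = (1 - HCT) * (ΔR1_myo / ΔR1_blood),
    ΔR1 = 1/T1_post - 1/T1_native

The implementation consumes scalar septal-ROI T1 values (milliseconds) and
the hematocrit; it performs no relaxometry or image processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["T1Panel", "compute_ecv", "ECV_PLAUSIBLE_RANGE"]

#: fraction range outside which a computed ECV triggers a plausibility warning
ECV_PLAUSIBLE_RANGE = (0.15, 0.60)


@dataclass(frozen=True)
class T1Panel:
    """Native and post-contrast T1 values (ms) plus hematocrit for one subject.

    Gadolinium shortens T1, so post-contrast values must not exceed the
    native ones (equality is the degenerate no-uptake limit).
    """

    t1_myo_native: float
    t1_myo_post: float
    t1_blood_native: float
    t1_blood_post: float
    hct: float

    def __post_init__(self) -> None:
        for name in ("t1_myo_native", "t1_myo_post", "t1_blood_native", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (got {getattr(self, name)})")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hct}")
        if self.t1_myo_post > self.t1_myo_native:
            raise ValueError("post-contrast myocardial T1 exceeds native T1")
        if self.t1_blood_post > self.t1_blood_native:
            raise ValueError("post-contrast blood T1 exceeds native T1")


def compute_ecv(panel: T1Panel, warn_implausible: bool = True) -> float:
    """Extracellular volume fraction from a :class:`T1Panel`.

    Returns the ECV as a fraction in [0, 1]-scale units (multiply by 100
    for the conventional percent rendering). Raises ``ValueError`` when the
    blood relaxation-rate change is non-positive, i.e. when the blood pool
    shows no contrast effect and the ratio is undefined.

    A result outside the physiologically plausible band (15-60%) emits a
    warning rather than an error: extreme values are suspicious but not
    arithmetically invalid.
    """
    d_r1_myo = 1.0 / panel.t1_myo_post - 1.0 / panel.t1_myo_native
    d_r1_blood = 1.0 / panel.t1_blood_post - 1.0 / panel.t1_blood_native
    if d_r1_blood <= 0:
        raise ValueError(
            "no blood contrast effect: blood 1/T1 did not increase post "
            "contrast, ECV is undefined"
        )
    ecv = (1.0 - panel.hct) * (d_r1_myo / d_r1_blood)
    lo, hi = ECV_PLAUSIBLE_RANGE
    if warn_implausible and not (lo <= ecv <= hi):
        warnings.warn(
            f"ECV {100 * ecv:.1f}% outside the plausible {100 * lo:.0f}-"
            f"{100 * hi:.0f}% band; check T1 inputs",
            stacklevel=2,
        )
    return float(ecv)
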