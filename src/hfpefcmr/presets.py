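"""Default study conditions for the synthetic cohort.

These constants define the cohort the generator emulates: a 35-subject
obese/overweight study population split into obese controls without
cardiovascular disease (n=6), T2DM (n=16) and HFpEF with T2DM (n=13),
with published-style group means and SDs for demographics, quantitative
CMR indices (MPR, ECV, LA volumetry and phasic strain) and circulating
biomarkers, the gadolinium dosing scheme of the dual-bolus protocol, the
immunoassay reportable ranges that censor biomarker values, and the
observed day-1/day-8 test-retest reliabilities. They are the fixed
reference conditions for the analysis scripts and the acceptance checks,
not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import GroupSpec, RetestSpec, VariableSpec

__all__ = [
    "ContrastProtocol",
    "CONTRAST_PROTOCOL",
    "GROUPS",
    "GROUP_SIZES",
    "GROUP_STATS",
    "FEMALE_COUNTS",
    "ASSAY_RANGES",
    "RETEST_ICC",
    "default_group_specs",
    "default_retest_specs",
]


@dataclass(frozen=True)
class ContrastProtocol:
    """Gadolinium dosing of the dual-bolus stress/rest perfusion exam.

    Each perfusion state (stress, rest) uses a dilute pre-bolus to image
    the AIF and a main bolus for tissue enhancement; a completion bolus
    afterwards tops the exam up to the full dose for post-contrast T1
    mapping. Doses in mmol/kg.
    """

    pre_bolus: float = 0.00375
    main_bolus: float = 0.0375
    completion_bolus: float = 0.0675
    n_pre: int = 2
    n_main: int = 2

    def total_dose(self) -> float:
        """Summed contrast dose over the whole exam (mmol/kg)."""
        return (
            self.n_pre * self.pre_bolus
            + self.n_main * self.main_bolus
            + self.completion_bolus
        )

    def aif_scaling_factor(self) -> float:
        """Bolus concentration ratio reconciling the dilute AIF with the
        full-bolus tissue curves."""
        return self.main_bolus / self.pre_bolus


CONTRAST_PROTOCOL = ContrastProtocol()

GROUPS = ("obese_control", "t2dm", "hfpef_t2dm")
GROUP_SIZES = {"obese_control": 6, "t2dm": 16, "hfpef_t2dm": 13}

#: female counts per group (sex is the one categorical Table-1-style row
#: the pipeline tests against)
FEMALE_COUNTS = {"obese_control": 2, "t2dm": 1, "hfpef_t2dm": 5}

#: immunoassay reportable ranges (ng/mL) used for truncation-resampling
ASSAY_RANGES = {
    "galectin3": (3.13, 100.0),
    "pentraxin3": (0.094, 192.0),
    "il1rl1": (1.6, 200.0),
}

#: per-variable (mean, sd) by group, observed scale; pentraxin3 is the
#: right-skewed biomarker drawn log-normal with these moments
GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"obese_control": (62, 2), "t2dm": (61, 11), "hfpef_t2dm": (68, 4)},
    "bmi": {"obese_control": (27.7, 1.3), "t2dm": (30.6, 3.1), "hfpef_t2dm": (32.3, 4.7)},
    "mpr": {"obese_control": (3.63, 1.62), "t2dm": (3.05, 1.41), "hfpef_t2dm": (2.27, 1.10)},
    "ecv_pct": {"obese_control": (26.73, 1.81), "t2dm": (25.03, 2.65), "hfpef_t2dm": (26.54, 3.14)},
    "la_min_vol": {"obese_control": (35, 17), "t2dm": (37, 13), "hfpef_t2dm": (64, 21)},
    "la_max_vol": {"obese_control": (63, 21), "t2dm": (65, 16), "hfpef_t2dm": (90, 25)},
    "la_reservoir": {"obese_control": (41, 12), "t2dm": (38, 11), "hfpef_t2dm": (25, 10)},
    "la_conduit": {"obese_control": (21.2, 6.3), "t2dm": (16.1, 4.8), "hfpef_t2dm": (11.0, 4.8)},
    "la_booster": {"obese_control": (19, 7), "t2dm": (22, 8), "hfpef_t2dm": (15, 5)},
    "galectin3": {"obese_control": (10.6, 3.7), "t2dm": (13.8, 3.3), "hfpef_t2dm": (16.1, 3.8)},
    "pentraxin3": {"obese_control": (0.21, 0.05), "t2dm": (0.52, 0.35), "hfpef_t2dm": (0.84, 0.67)},
    "il1rl1": {"obese_control": (28, 6), "t2dm": (28, 8), "hfpef_t2dm": (27, 10)},
}

#: day-1 vs day-8 reliabilities the retest generator targets
RETEST_ICC = {
    "mpr": 0.94,
    "ecv_pct": 0.49,
    "la_min_vol": 0.41,
    "la_max_vol": 0.56,
    "la_reservoir": 0.84,
    "la_conduit": 0.67,
    "la_booster": 0.41,
    "galectin3": 0.90,
    "pentraxin3": 0.93,
    "il1rl1": 0.87,
}

#: probability of a positive atrial-arrhythmia history per group
#: (3 of 35 subjects overall, all in the HFpEF group)
ARRHYTHMIA_P = {"obese_control": 0.0, "t2dm": 0.0, "hfpef_t2dm": 3 / 13}


def _variable_specs(group: str) -> dict[str, VariableSpec]:
    specs: dict[str, VariableSpec] = {}
    for var, per_group in GROUP_STATS.items():
        mean, sd = per_group[group]
        dist = "lognormal" if var == "pentraxin3" else "normal"
        lo, hi = ASSAY_RANGES.get(var, (None, None))
        # physical floors for strictly positive quantities
        if lo is None and var in ("mpr", "ecv_pct", "la_min_vol", "la_max_vol",
                                  "la_reservoir", "la_conduit", "la_booster"):
            lo = 1e-6
        specs[var] = VariableSpec(
            distribution=dist, location=mean, scale=sd, censor_low=lo, censor_high=hi
        )
    specs["sex"] = VariableSpec(
        "bernoulli", FEMALE_COUNTS[group] / GROUP_SIZES[group]
    )
    specs["arrhythmia_history"] = VariableSpec("bernoulli", ARRHYTHMIA_P[group])
    specs["hct"] = VariableSpec("normal", 0.42, 0.03, censor_low=0.25, censor_high=0.55)
    return specs


def default_group_specs(
    sizes: dict[str, int] | None = None,
) -> list[GroupSpec]:
    """The three-group cohort specification at the study sizes (or a
    caller-supplied size map, e.g. for convergence checks)."""
    sizes = sizes or GROUP_SIZES
    return [
        GroupSpec(group_name=g, n=sizes[g], variable_specs=_variable_specs(g))
        for g in GROUPS
    ]


def default_retest_specs() -> dict[str, RetestSpec]:
    """Retest specs at the observed reliabilities, no systematic day
    effect by default."""
    return {var: RetestSpec(target_icc=icc) for var, icc in RETEST_ICC.items()}
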