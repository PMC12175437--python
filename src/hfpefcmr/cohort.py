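"""Synthetic cohort tables with group structure and test-retest replicates.

The generator draws per-subject records for a three-group cohort (obese
controls without cardiovascular disease, T2DM, HFpEF with T2DM) from
per-variable distribution specs: normal, moment-matched log-normal (for
right-skewed biomarkers such as Pentraxin-3), or Bernoulli. Assay
reportable ranges censor biomarker values by truncation-resampling —
out-of-range subjects are redrawn rather than clipped, avoiding
probability atoms at the bounds.

Test-retest structure: for variables measured on day 1 and day 8, values
decompose into a subject-level latent component plus independent
visit-level Gaussian noise. The within-subject variance implied by a
target intraclass correlation rho is

    sigma_w^2 = sigma_b^2 * (1 - rho) / rho,

and an optional systematic day-8 offset (``rater_shift``) models a visit
effect, which depresses the absolute-agreement ICC(2,1) below the
consistency ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VariableSpec", "GroupSpec", "RetestSpec", "synth_cohort", "GROUP_NAMES"]

GROUP_NAMES = ("obese_control", "t2dm", "hfpef_t2dm")

_DISTRIBUTIONS = ("normal", "lognormal", "bernoulli")
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one variable within one group.

    ``location``/``scale`` are the mean and SD on the observed scale for
    both normal and log-normal variables (the log-normal is moment-
    matched); for Bernoulli, ``location`` is the success probability.
    """

    distribution: str
    location: float
    scale: float = 0.0
    censor_low: float | None = None
    censor_high: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in _DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.distribution == "lognormal" and self.location <= 0:
            raise ValueError("log-normal mean must be positive")
        if self.distribution == "bernoulli" and not 0.0 <= self.location <= 1.0:
            raise ValueError("Bernoulli probability must lie in [0, 1]")
        if (
            self.censor_low is not None
            and self.censor_high is not None
            and not self.censor_low < self.censor_high
        ):
            raise ValueError("censor_low must be below censor_high")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: its label, size and variable specs."""

    group_name: str
    n: int
    variable_specs: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group_name not in GROUP_NAMES:
            raise ValueError(f"group_name must be one of {GROUP_NAMES}")
        if self.n < 2:
            raise ValueError("groups entering variance-based statistics need n >= 2")


@dataclass(frozen=True)
class RetestSpec:
    """Test-retest structure for one variable.

    ``target_icc`` is the intended ICC absent a visit effect;
    ``between_sd`` overrides the group spec's scale as the between-
    subject SD when given; ``rater_shift`` is a systematic day-8 offset.
    """

    target_icc: float
    between_sd: float | None = None
    rater_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_icc <= 1.0:
            raise ValueError("target_icc must lie in (0, 1]")
        if self.between_sd is not None and self.between_sd < 0:
            raise ValueError("between_sd must be non-negative")

    def within_sd(self, between_sd: float) -> float:
        sd_b = self.between_sd if self.between_sd is not None else between_sd
        return sd_b * np.sqrt((1.0 - self.target_icc) / self.target_icc)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) matching the observed-scale mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def _draw_latent(rng: np.random.Generator, spec: VariableSpec, sd_override: float | None):
    if spec.distribution == "normal":
        sd = spec.scale if sd_override is None else sd_override
        return rng.normal(spec.location, sd)
    if spec.distribution == "lognormal":
        mu, sig = _lognormal_params(spec.location, spec.scale if sd_override is None else sd_override)
        return rng.lognormal(mu, sig)
    return float(rng.random() < spec.location)


def _in_range(spec: VariableSpec, values: list[float]) -> bool:
    lo = -np.inf if spec.censor_low is None else spec.censor_low
    hi = np.inf if spec.censor_high is None else spec.censor_high
    return all(lo <= v <= hi for v in values)


def synth_cohort(
    specs: list[GroupSpec],
    retest: dict[str, RetestSpec] | None = None,
    seed: int = 0,
    visit_days: tuple[int, ...] = (1, 8),
) -> pd.DataFrame:
    """Sample a subject-visit cohort table.

    One row per subject and visit day. Variables with a retest spec vary
    across visits per the latent-plus-noise model; all other variables
    are subject constants replicated across visits. Censoring bounds, when
    present, apply to every visit value via truncation-resampling of the
    whole subject draw (latent and visit noise together, so the day-1/
    day-8 correlation structure survives censoring). Deterministic for a
    fixed seed.
    """
    if not specs:
        raise ValueError("at least one group spec is required")
    var_names = list(specs[0].variable_specs)
    for g in specs[1:]:
        if list(g.variable_specs) != var_names:
            raise ValueError("variable set must be consistent across groups")
    retest = retest or {}
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    sid = 0
    for g in specs:
        for _ in range(g.n):
            sid += 1
            record: dict[str, dict[int, float]] = {}
            for name, vs in g.variable_specs.items():
                rt = retest.get(name)
                for attempt in range(_MAX_REDRAWS):
                    if rt is None:
                        latent = _draw_latent(rng, vs, None)
                        values = {day: latent for day in visit_days}
                    else:
                        sd_b = rt.between_sd if rt.between_sd is not None else vs.scale
                        latent = _draw_latent(rng, vs, sd_b)
                        sd_w = rt.within_sd(sd_b)
                        values = {}
                        for i, day in enumerate(visit_days):
                            noise = rng.normal(0.0, sd_w) if sd_w > 0 else 0.0
                            shift = rt.rater_shift if i > 0 else 0.0
                            values[day] = latent + noise + shift
                    if _in_range(vs, list(values.values())):
                        break
                else:
                    # pathological spec: fall back to clipping with a note
                    lo = -np.inf if vs.censor_low is None else vs.censor_low
                    hi = np.inf if vs.censor_high is None else vs.censor_high
                    values = {d: float(np.clip(v, lo, hi)) for d, v in values.items()}
                record[name] = values
            for day in visit_days:
                row = {
                    "subject_id": f"S{sid:03d}",
                    "group": g.group_name,
                    "visit_day": day,
                }
                row.update({name: record[name][day] for name in var_names})
                rows.append(row)
    return pd.DataFrame(rows)
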