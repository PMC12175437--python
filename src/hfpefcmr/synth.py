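"""Synthetic signal-level data: AIF curves, tissue responses, T1 panels
and LA trajectories.

Every generator is the exact forward model of the corresponding analysis
operation, so at zero noise each analysis stage recovers the generating
parameters (MBF, ECV, phasic strains) to machine precision — the central
round-trip contract the test suite relies on. All randomness flows through
explicit integer seeds.

The AIF is a peak-normalized gamma-variate — the standard parametric
family for bolus-passage curves — standing in for a measured blood-pool
curve; its amplitude is therefore directly the peak enhancement above
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import SignalCurve
from .ecv import T1Panel, compute_ecv
from .la import LATrajectory
from .perfusion import PerfusionStudy, fermi_response

__all__ = [
    "AIFParams",
    "TissueGenParams",
    "gamma_variate_aif",
    "synth_tissue_curve",
    "synth_perfusion_study",
    "synth_t1_panel",
    "synth_la_trajectory",
]


@dataclass(frozen=True)
class AIFParams:
    """Peak-normalized gamma-variate bolus parameters.

    The curve equals ``baseline`` before ``onset_time`` and afterwards
    rises to a single interior maximum of ``baseline + amplitude`` at
    ``onset_time + shape_alpha * scale_beta``.
    """

    onset_time: float = 8.0
    amplitude: float = 50.0
    shape_alpha: float = 3.0
    scale_beta: float = 2.0
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.shape_alpha <= 0:
            raise ValueError("shape_alpha must be positive")
        if self.scale_beta <= 0:
            raise ValueError("scale_beta must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")


@dataclass(frozen=True)
class TissueGenParams:
    """Ground-truth tissue parameters: flow plus Fermi shape.

    ``true_mbf`` (mL/g/min) sets the initial value of the impulse
    response; ``fermi_mu`` and ``fermi_k`` (seconds) its shoulder and
    decay width; ``noise_sd`` adds i.i.d. Gaussian noise in signal units.
    """

    true_mbf: float = 1.0
    fermi_mu: float = 4.0
    fermi_k: float = 1.2
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.true_mbf < 0:
            raise ValueError("true_mbf must be non-negative")
        if self.fermi_mu < 0:
            raise ValueError("fermi_mu must be non-negative")
        if self.fermi_k <= 0:
            raise ValueError("fermi_k must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_time_grid(duration: float = 60.0, dt: float = 0.5) -> np.ndarray:
    """Uniform acquisition grid (seconds): one sample per ~heartbeat at
    rest-like rates over a one-minute first-pass acquisition."""
    return np.arange(0.0, duration, dt)


def gamma_variate_aif(params: AIFParams, time_grid: np.ndarray) -> SignalCurve:
    """Sample the gamma-variate AIF on a uniform grid.

    value(t) = baseline for t < onset, else
    baseline + amplitude * ((t-onset)/(alpha*beta))^alpha
                         * exp(alpha - (t-onset)/beta).

    The grid must be uniform and must cover the onset time; the number of
    pre-onset samples defines the curve's baseline window.
    """
    t = np.asarray(time_grid, dtype=float)
    steps = np.diff(t)
    if t.size < 8 or np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
        raise ValueError("time_grid must be uniformly spaced and strictly increasing")
    if not (t[0] <= params.onset_time <= t[-1]):
        raise ValueError("time_grid does not cover the bolus onset time")
    v = np.full(t.size, params.baseline, dtype=float)
    m = t >= params.onset_time
    d = t[m] - params.onset_time
    alpha, beta = params.shape_alpha, params.scale_beta
    with np.errstate(divide="ignore"):
        v[m] = params.baseline + params.amplitude * (
            (d / (alpha * beta)) ** alpha * np.exp(alpha - d / beta)
        )
    n_pre = int(np.count_nonzero(t < params.onset_time))
    window = (0, max(n_pre, 2)) if n_pre >= 1 else None
    return SignalCurve(times=t, values=v, baseline_window=window)


def synth_tissue_curve(
    aif: SignalCurve,
    gen: TissueGenParams,
    seed: int,
    baseline: float | None = None,
) -> SignalCurve:
    """Forward-model a tissue curve: AIF convolved with a Fermi response.

    tissue(t) = dt * sum_tau aif_bs(tau) R_F(t - tau) + N(0, noise_sd),
    with the Fermi amplitude chosen so that R_F(0) = true_mbf (signal
    units are taken as proportional to contrast concentration, one signal
    unit per mL/g/min by convention). The AIF baseline is taken from its
    baseline window unless supplied explicitly.
    """
    if baseline is None:
        baseline, _ = aif.baseline_stats()
    aif_bs = aif.values - baseline
    dt = aif.dt
    amp = gen.true_mbf * (np.exp(-gen.fermi_mu / gen.fermi_k) + 1.0)
    lags = np.arange(aif.n) * dt
    r = fermi_response(lags, amp, gen.fermi_mu, gen.fermi_k)
    tissue = dt * np.convolve(aif_bs, r)[: aif.n]
    rng = np.random.default_rng(seed)
    if gen.noise_sd > 0:
        tissue = tissue + rng.normal(0.0, gen.noise_sd, size=tissue.size)
    return SignalCurve(times=aif.times.copy(), values=tissue, baseline_window=aif.baseline_window)


def synth_perfusion_study(
    rest: TissueGenParams,
    stress: TissueGenParams,
    aif: AIFParams,
    scaling_factor: float = 10.0,
    seed: int = 0,
    time_grid: np.ndarray | None = None,
) -> PerfusionStudy:
    """Assemble a dual-bolus study.

    The full-amplitude AIF drives both tissue curves; the stored AIF is
    the dilute pre-bolus (amplitude divided by ``scaling_factor``, the
    bolus concentration ratio — 10 for the 0.0375 / 0.00375 mmol/kg
    dosing convention). Rest and stress noise streams are split from the
    one seed, so equal seeds give bitwise-identical studies.
    """
    if scaling_factor <= 0:
        raise ValueError("scaling_factor must be positive")
    if time_grid is None:
        time_grid = default_time_grid()
    aif_high = gamma_variate_aif(aif, time_grid)
    aif_low = gamma_variate_aif(replace(aif, amplitude=aif.amplitude / scaling_factor), time_grid)
    seed_rest, seed_stress = np.random.SeedSequence(seed).generate_state(2) >> 1
    return PerfusionStudy(
        aif_low_bolus=aif_low,
        tissue_high_bolus_rest=synth_tissue_curve(aif_high, rest, int(seed_rest)),
        tissue_high_bolus_stress=synth_tissue_curve(aif_high, stress, int(seed_stress)),
        scaling_factor=scaling_factor,
    )


def synth_t1_panel(
    target_ecv: float,
    hct: float,
    anchors: dict | None = None,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> T1Panel:
    """Build a T1 panel whose computed ECV equals ``target_ecv`` exactly.

    Inverts the ECV relation for the post-contrast myocardial T1 given
    native myocardial and native/post blood anchors (ms):

        1/T1_myo_post = 1/T1_myo_native
                        + ECV/(1-HCT) * (1/T1_blood_post - 1/T1_blood_native)

    Optional Gaussian noise (ms) perturbs the post-contrast myocardial T1
    after inversion, breaking the identity by a controlled amount.
    """
    if not 0.0 <= target_ecv < 1.0:
        raise ValueError("target_ecv must lie in [0, 1)")
    if not 0.0 < hct < 1.0:
        raise ValueError("hematocrit must lie in (0, 1)")
    a = {"t1_myo_native": 1200.0, "t1_blood_native": 1800.0, "t1_blood_post": 350.0}
    if anchors:
        a.update(anchors)
    if min(a.values()) <= 0:
        raise ValueError("T1 anchors must be positive")
    d_r1_blood = 1.0 / a["t1_blood_post"] - 1.0 / a["t1_blood_native"]
    if d_r1_blood <= 0:
        raise ValueError("anchors give no blood contrast effect")
    inv_post = 1.0 / a["t1_myo_native"] + target_ecv / (1.0 - hct) * d_r1_blood
    if inv_post <= 0:
        raise ValueError("target ECV and anchors yield non-positive post-contrast T1")
    t1_myo_post = 1.0 / inv_post
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        t1_myo_post = max(t1_myo_post + rng.normal(0.0, noise_sd), 1.0)
        t1_myo_post = min(t1_myo_post, a["t1_myo_native"])
    return T1Panel(
        t1_myo_native=a["t1_myo_native"],
        t1_myo_post=t1_myo_post,
        t1_blood_native=a["t1_blood_native"],
        t1_blood_post=a["t1_blood_post"],
        hct=hct,
    )


def _half_cosine(n0: int, n1: int, y0: float, y1: float) -> np.ndarray:
    """Smooth monotone segment from (n0, y0) to (n1, y1), endpoint excluded."""
    idx = np.arange(n0, n1)
    return y0 + (y1 - y0) * 0.5 * (1.0 - np.cos(np.pi * (idx - n0) / (n1 - n0)))


def synth_la_trajectory(
    reservoir_pct: float,
    booster_pct: float,
    n_frames: int = 30,
    ref_length: float = 50.0,
    seed: int | None = None,
    max_volume_ml: float | None = None,
) -> LATrajectory:
    """Smooth periodic LA length/area trajectory with prescribed strains.

    The length curve starts at ``ref_length`` at LV end-diastole (frame
    0), peaks at ``ref_length * (1 + reservoir/100)`` at end-systole
    (~40% of the cycle), passes through ``ref_length * (1 + booster/100)``
    at the pre-atrial-contraction frame (~75%) and returns to the
    reference by the final frame; segments are half-cosines so the peak
    is the global maximum. Areas scale as length squared with view-
    specific constants; ``max_volume_ml`` rescales the geometry to hit a
    target biplane maximum volume.
    """
    if not 0.0 <= booster_pct <= reservoir_pct:
        raise ValueError("require 0 <= booster_pct <= reservoir_pct")
    if n_frames < 8:
        raise ValueError("need at least 8 frames per cycle")
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    peak = max(1, round(0.40 * (n_frames - 1)))
    pre_a = min(n_frames - 2, round(0.75 * (n_frames - 1)))
    if pre_a <= peak:
        pre_a = peak + 1
    s = np.empty(n_frames)
    s[:peak] = _half_cosine(0, peak, 0.0, reservoir_pct)
    s[peak:pre_a] = _half_cosine(peak, pre_a, reservoir_pct, booster_pct)
    s[pre_a : n_frames - 1] = _half_cosine(pre_a, n_frames - 1, booster_pct, 0.0)
    s[n_frames - 1] = 0.0
    lengths = ref_length * (1.0 + s / 100.0)
    # area ~ c * L^2 with mildly different view eccentricities
    c2, c4 = 0.55, 0.65
    if max_volume_ml is not None:
        # biplane V = 8/(3*pi) * c2*c4 * L^3 / 1000 at the peak length
        l_peak = lengths.max()
        scale = (max_volume_ml * 1000.0 * 3.0 * np.pi / (8.0 * c2 * c4 * l_peak**3)) ** (1.0 / 3.0)
        lengths = lengths * scale
    areas_2ch = c2 * lengths**2
    areas_4ch = c4 * lengths**2
    return LATrajectory(
        frame_times=np.arange(n_frames, dtype=float),
        lengths_2ch=lengths,
        lengths_4ch=lengths.copy(),
        areas_2ch=areas_2ch,
        areas_4ch=areas_4ch,
        ref_frame=0,
        pre_a_frame=int(pre_a),
    )


def verify_t1_roundtrip(target_ecv: float, hct: float) -> float:
    """Convenience check: ECV recomputed from an inverted panel."""
    return compute_ecv(synth_t1_panel(target_ecv, hct), warn_implausible=False)
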