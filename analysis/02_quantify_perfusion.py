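"""Quantify myocardial blood flow from synthetic dual-bolus studies.

For a subset of cohort subjects, forward-models rest/stress tissue
curves at each subject's target perfusion reserve, then recovers MBF and
MPR through first-pass extraction, smoothing, registration, AIF scaling
and Fermi-constrained deconvolution, and reports how well the generating
truth is recovered.
"""

import argparse
from pathlib import Path

from hfpefcmr.pipeline import PipelineConfig, generate_cohort, perfusion_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1234)
    ap.add_argument("--n-subjects", type=int, default=8,
                    help="cohort subjects given raw signal data")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed, n_perfusion_subjects=args.n_subjects)
    cohort = generate_cohort(cfg)
    perf = perfusion_stage(cfg, cohort)
    perf.to_csv(args.out / "perfusion_mbf.csv", index=False, float_format="%.10g")

    rel = ((perf.measured_mpr - perf.true_mpr).abs() / perf.true_mpr)
    print(f"quantified {len(perf)} dual-bolus studies "
          f"(tissue noise {100 * cfg.tissue_noise_frac:.0f}% of peak)")
    print(f"median |MPR error|: {100 * rel.median():.1f}%  "
          f"(worst {100 * rel.max():.1f}%)")
    print(f"all fits converged: {bool((perf.rest_converged & perf.stress_converged).all())}")
    print(f"table -> {args.out / 'perfusion_mbf.csv'}")


if __name__ == "__main__":
    main()
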