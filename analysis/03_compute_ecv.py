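"""Compute extracellular volume fraction from synthetic T1 panels.

Inverts each subject's target ECV and hematocrit into a native/post-
contrast T1 panel, recomputes ECV from the panel, and verifies the
round trip.
"""

import argparse
from pathlib import Path

from hfpefcmr.pipeline import PipelineConfig, ecv_stage, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1234)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed)
    cohort = generate_cohort(cfg)
    ecv = ecv_stage(cfg, cohort)
    ecv.to_csv(args.out / "ecv.csv", index=False, float_format="%.10g")

    err = (ecv.measured_ecv_pct - ecv.target_ecv_pct).abs()
    print(f"computed ECV for {len(ecv)} subjects")
    print(f"group-level mean ECV: {ecv.measured_ecv_pct.mean():.2f}% "
          f"(range {ecv.measured_ecv_pct.min():.2f}-{ecv.measured_ecv_pct.max():.2f}%)")
    print(f"max |inversion error|: {err.max():.2e} percentage points")
    print(f"table -> {args.out / 'ecv.csv'}")


if __name__ == "__main__":
    main()
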