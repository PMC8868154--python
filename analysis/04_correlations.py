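#!/usr/bin/env python
"""Repeated-measures correlations between biofeedback score and HRV.

Correlates the session-mean biofeedback score with LF-band breathing
coherence, LF power, and HF power across all sessions, treating subjects as
their own controls (subject-mean centering); subject 9 is excluded from
these HRV analyses.
"""

import argparse
from pathlib import Path

import pandas as pd

from breathloop import pipeline

HRV_EXCLUDED = ("9",)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/rmcorr.csv"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.metrics, dtype={"subject_id": str})
    params = pipeline.PipelineParams(hrv_excluded_subjects=HRV_EXCLUDED)
    rmcorr = pipeline.rmcorr_table(metrics, params)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    rmcorr.to_csv(args.out, index=False, float_format="%.4f")

    print(f"wrote {args.out}")
    for _, row in rmcorr.iterrows():
        print(
            f"  score vs {row['y']:24s} r({int(row['df'])}) = {row['r']:+.3f}, "
            f"p = {row['p_value']:.2g}  (n = {int(row['n_obs'])} sessions, "
            f"{int(row['n_subjects'])} subjects)"
        )


if __name__ == "__main__":
    main()
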