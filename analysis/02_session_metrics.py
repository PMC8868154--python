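#!/usr/bin/env python
"""Extract per-session metrics for every session in the cohort manifest.

Loads each session log, recomputes the biofeedback summaries (session mean,
baseline over the last 29 samples, control-of-self), HRV band powers,
breathing-LF coherence and heart-rate change, and the behavioral
signal-detection indices, then writes one tidy row per subject-session.
"""

import argparse
from pathlib import Path

import pandas as pd

from breathloop import pipeline
from breathloop.session_model import load_session, read_manifest

HRV_EXCLUDED = ("9",)  # unreliable R-peak detection; HRV analyses skip it


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", type=Path, default=Path("scratch/cohort/manifest.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/metrics.csv"))
    args = ap.parse_args()

    manifest = read_manifest(args.manifest)
    records = [load_session(p) for p in manifest["path"]]
    params = pipeline.PipelineParams(hrv_excluded_subjects=HRV_EXCLUDED)
    metrics = pd.DataFrame([pipeline.session_metrics(r, params) for r in records])

    args.out.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(args.out, index=False)

    by_phase = metrics.groupby("phase")["mean_biofeedback"].mean()
    print(f"wrote {len(metrics)} session rows to {args.out}")
    print(
        f"  mean biofeedback score: A sessions {by_phase['A']:.3f}, "
        f"B sessions {by_phase['B']:.3f} (biofeedback displayed)"
    )
    rises = metrics["hr_change"].dropna()
    print(f"  mean in-game HR rise over baseline: {rises.mean():+.1f} bpm (n={len(rises)})")
    print(f"  mean d': {metrics['d_prime'].mean():.2f}, "
          f"mean priming FA difference: {metrics['priming_fa_diff'].mean():+.3f}")


if __name__ == "__main__":
    main()
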