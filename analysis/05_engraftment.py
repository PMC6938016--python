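#!/usr/bin/env python
"""Engraftment calls for every (donor MAG, recipient) pair.

Combines marker clusters, within-cluster ANI and the detection time course
into the decision chain, then scores the calls against the planted truth.
"""

from pathlib import Path

import pandas as pd

from fmt_engraft.genome import AniResult
from fmt_engraft.tracking import call_engraftment, calls_to_frame

OUT = Path(__file__).resolve().parent.parent / "results"
DATA = OUT / "data"


def main() -> None:
    cl_df = pd.read_csv(OUT / "clusters.tsv", sep="\t")
    clusters = [set(g["mag_id"]) for _, g in cl_df.groupby("cluster")]
    ani_df = pd.read_csv(OUT / "ani.tsv", sep="\t")
    ani_results = {
        frozenset((r.mag_a, r.mag_b)): AniResult(
            r.mag_a, r.mag_b,
            None if pd.isna(r.ani) else float(r.ani),
            int(r.n_reciprocal_fragments), float(r.coverage_fraction),
            not pd.isna(r.ani),
        )
        for r in ani_df.itertuples()
    }
    detections = pd.read_csv(DATA / "detections.tsv", sep="\t")
    metrics = pd.read_csv(DATA / "mag_metrics.tsv", sep="\t")
    mag_subjects = dict(zip(metrics["mag_id"], metrics["subject"]))
    days = sorted(set(detections["day"]))

    calls = call_engraftment(
        clusters, ani_results, detections, mag_subjects,
        [d for d in days if d < 0], [d for d in days if d > 0],
    )
    frame = calls_to_frame(calls)
    frame.to_csv(OUT / "calls.tsv", sep="\t", index=False)
    print(frame["status"].value_counts().to_string())

    truth = pd.read_csv(DATA / "truth_engrafted.tsv", sep="\t")
    merged = frame.merge(truth, on=["donor_mag", "recipient"])
    called = merged["status"] == "engrafted"
    planted = merged["engrafted"]
    sens = (called & planted).sum() / planted.sum()
    spec = (~called & ~planted).sum() / (~planted).sum()
    print(
        f"against planted truth: sensitivity {sens:.3f}, "
        f"specificity {spec:.3f} over {len(merged)} pairs"
    )
    print(f"wrote {OUT / 'calls.tsv'}")


if __name__ == "__main__":
    main()
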