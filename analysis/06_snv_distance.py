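#!/usr/bin/env python
"""SNV-level confirmation: major-allele distance to the donor over time.

Generates converging SNV profiles for the same cohort parameters and
reports each recipient's major-allele distance to the donor reference
before and after the transplant.
"""

from pathlib import Path

from fmt_engraft.synthetic import SimulationConfig, simulate_snv_timeseries
from fmt_engraft.tracking import donor_similarity_trend

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    profiles, meta = simulate_snv_timeseries(config, n_positions=1000,
                                             q0=0.5)
    trend = donor_similarity_trend(profiles, "DONOR_d0", meta, min_depth=5)
    trend.to_csv(OUT / "snv_trend.tsv", sep="\t", index=False)
    rec = trend[trend.subject != "DONOR"]
    pre = rec.query("day < 0")["distance"]
    post = rec.query("day > 0")["distance"]
    print(
        f"median major-allele distance to donor: pre-FMT "
        f"{pre.median():.3f}, post-FMT {post.median():.3f} "
        f"({len(rec)} recipient samples, 1000 positions)"
    )
    print(f"wrote {OUT / 'snv_trend.tsv'}")


if __name__ == "__main__":
    main()
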