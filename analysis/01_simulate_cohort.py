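#!/usr/bin/env python
"""Generate the synthetic FMT cohort used by every downstream analysis.

Writes the taxon abundance table with sample metadata, the donor/recipient
MAG FASTAs with marker proteins and quality metrics, the donor-MAG coverage
detection time course, and the planted truth table under results/data/.
"""

from pathlib import Path

from fmt_engraft.io import write_mags
from fmt_engraft.synthetic import SimulationConfig, simulate_cohort, simulate_timeseries

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)

    table, _ = simulate_timeseries(config)
    table.to_tsv(OUT / "abundance.tsv", OUT / "metadata.tsv")
    print(
        f"abundance table: {len(table.taxa)} taxa x {len(table.samples)} "
        f"samples (donor + {config.n_recipients} recipients, days "
        f"{list(config.timepoints)})"
    )

    cohort = simulate_cohort(config)
    write_mags(cohort.all_mags, OUT / "mags", OUT / "mag_metrics.tsv")
    cohort.detections.to_csv(OUT / "detections.tsv", sep="\t", index=False)
    truth = cohort.truth.engrafted_frame()
    truth.to_csv(OUT / "truth_engrafted.tsv", sep="\t", index=False)
    n_planted = int(truth["engrafted"].sum())
    print(
        f"cohort: {len(cohort.donor_mags)} donor MAGs x "
        f"{config.n_recipients} recipients at {config.genome_length} bp; "
        f"{n_planted}/{len(truth)} (donor MAG, recipient) pairs planted "
        f"as engrafted"
    )


if __name__ == "__main__":
    main()
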