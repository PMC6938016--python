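#!/usr/bin/env python
"""Compositional convergence of recipients toward the donor.

Filters rare taxa, replaces zeros, and computes each sample's Aitchison
distance to the donor baseline plus a 2-D NMDS ordination of the full
distance matrix.  Reports the Spearman correlation between day and
distance for each recipient's post-FMT samples (negative = convergence).
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fmt_engraft.coda import (
    AbundanceTable,
    aitchison_distance,
    distance_to_donor,
    filter_rare_taxa,
    nmds,
    replace_zeros,
)

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent


def main() -> None:
    table = AbundanceTable.from_tsv(DATA / "abundance.tsv",
                                    DATA / "metadata.tsv")
    filtered = filter_rare_taxa(table, min_prop=0.001, min_samples=2)
    print(f"{len(filtered.taxa)}/{len(table.taxa)} taxa pass the rare filter")

    traj = distance_to_donor(filtered, "DONOR_d0")
    traj.to_csv(OUT / "trajectory.tsv", sep="\t", index=False)

    post = traj.query("role == 'recipient' and day > 0")
    for subject, grp in post.groupby("subject"):
        rho = stats.spearmanr(grp["day"], grp["distance"]).statistic
        print(
            f"{subject}: distance to donor {grp['distance'].iloc[0]:.2f} "
            f"(day {grp['day'].iloc[0]}) -> {grp['distance'].iloc[-1]:.2f} "
            f"(day {grp['day'].iloc[-1]}), Spearman rho = {rho:.2f}"
        )

    comps = replace_zeros(filtered)
    samples = list(comps)
    dm = np.zeros((len(samples), len(samples)))
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            dm[i, j] = dm[j, i] = aitchison_distance(comps[a],
                                                     comps[samples[j]])
    coords = nmds(dm, seed=0)
    ord_df = pd.DataFrame(coords, columns=["nmds1", "nmds2"])
    ord_df.insert(0, "sample_id", samples)
    ord_df = ord_df.merge(
        table.metadata.reset_index(names="sample_id"), on="sample_id"
    )
    ord_df.to_csv(OUT / "nmds.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'trajectory.tsv'} and {OUT / 'nmds.tsv'}")


if __name__ == "__main__":
    main()
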