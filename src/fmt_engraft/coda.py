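"""Compositional-data (CoDa) primitives for microbiome abundance tables.

Taxon count tables carry only relative information, so all comparisons here
live in Aitchison geometry: counts are closed to proportions, zeros are
replaced by a Bayesian-multiplicative estimate, and distances are Euclidean
distances between centred log-ratio (clr) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "Composition",
    "filter_rare_taxa",
    "replace_zeros",
    "clr",
    "clr_inverse",
    "aitchison_distance",
    "total_variance",
    "distance_to_donor",
    "nmds",
]


@dataclass
class Composition:
    """A vector of strictly positive proportions over named parts.

    Values must sum to 1 (closure); only ratios between parts are
    meaningful.
    """

    parts: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.parts) != self.values.size:
            raise ValueError("parts and values length mismatch")
        if np.any(self.values <= 0):
            raise ValueError("composition values must be strictly positive")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition must sum to 1 (got {self.values.sum()!r})"
            )

    @classmethod
    def close(cls, parts: list[str], raw: np.ndarray) -> "Composition":
        """Close a positive vector to the unit simplex."""
        raw = np.asarray(raw, dtype=float)
        return cls(list(parts), raw / raw.sum())


@dataclass
class AbundanceTable:
    """Samples x taxa count table with per-sample metadata.

    counts: DataFrame indexed by taxon, columns = sample ids, integer counts.
    metadata: DataFrame indexed by sample id with columns
        subject (str), day (int, relative to transplant; donor baseline = 0),
        role ("donor" | "recipient").
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def proportions(self) -> pd.DataFrame:
        """Column-wise relative abundances (zeros retained)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"all-zero samples: {bad}")
        return self.counts / totals

    def to_tsv(self, counts_path, metadata_path) -> None:
        self.counts.rename_axis("taxon").to_csv(counts_path, sep="\t")
        self.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "AbundanceTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        return cls(counts, meta)


def filter_rare_taxa(
    table: AbundanceTable, min_prop: float = 0.001, min_samples: int = 2
) -> AbundanceTable:
    """Keep taxa whose relative abundance reaches ``min_prop`` in at least
    ``min_samples`` samples; taxon order is preserved.
    """
    if not 0 <= min_prop < 1:
        raise ValueError("min_prop must be in [0, 1)")
    props = table.proportions()
    keep = (props >= min_prop).sum(axis=1) >= min_samples
    if min_prop == 0:
        keep[:] = True
    if not keep.any():
        raise ValueError(
            f"no taxa survive filtering (min_prop={min_prop}, "
            f"min_samples={min_samples})"
        )
    return AbundanceTable(table.counts.loc[keep], table.metadata)


def replace_zeros(
    table: AbundanceTable, prior_strength: float = 0.5
) -> dict[str, Composition]:
    """Bayesian-multiplicative zero replacement, one composition per sample.

    A zero cell in a sample with total count N over D parts becomes the
    posterior expectation s/(N + s*D) under a uniform Dirichlet prior of
    strength s per part; non-zero cells are rescaled multiplicatively so the
    sample still sums to 1, which preserves all ratios among originally
    non-zero parts.
    """
    if prior_strength <= 0:
        raise ValueError("prior_strength must be positive")
    counts = table.counts
    d = counts.shape[0]
    out: dict[str, Composition] = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        n = col.sum()
        if n == 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        zero = col == 0
        props = col / n
        repl = prior_strength / (n + prior_strength * d)
        vals = np.where(zero, repl, props * (1.0 - repl * zero.sum()))
        out[sample] = Composition(list(counts.index), vals)
    return out


def clr(x: Composition) -> np.ndarray:
    """Centred log-ratio transform: ln(x_i / g(x)); components sum to 0."""
    logs = np.log(x.values)
    return logs - logs.mean()


def clr_inverse(vec: np.ndarray, parts: list[str]) -> Composition:
    """Map a clr vector back to the simplex (softmax)."""
    raw = np.exp(np.asarray(vec, dtype=float))
    return Composition.close(parts, raw)


def aitchison_distance(x: Composition, y: Composition) -> float:
    """Euclidean distance between clr vectors; the natural CoDa metric."""
    if x.parts != y.parts:
        raise ValueError("compositions are over different parts")
    return float(np.linalg.norm(clr(x) - clr(y)))


def total_variance(comps: list[Composition]) -> float:
    """Metric (total) variance: mean squared Aitchison distance to the
    clr-mean composition, divisor n.
    """
    if len(comps) < 2:
        raise ValueError("total_variance needs at least 2 compositions")
    parts = comps[0].parts
    for c in comps[1:]:
        if c.parts != parts:
            raise ValueError("compositions are over different parts")
    mat = np.stack([clr(c) for c in comps])
    centred = mat - mat.mean(axis=0)
    return float((centred**2).sum(axis=1).mean())


def distance_to_donor(
    table: AbundanceTable,
    donor_sample: str,
    prior_strength: float = 0.5,
) -> pd.DataFrame:
    """Aitchison distance of every sample to a donor reference sample.

    Returns a DataFrame (sample_id, subject, day, role, distance) sorted by
    (subject, day).
    """
    if donor_sample not in table.samples:
        raise ValueError(f"unknown donor sample {donor_sample!r}")
    comps = replace_zeros(table, prior_strength)
    ref = comps[donor_sample]
    rows = []
    for sample, comp in comps.items():
        meta = table.metadata.loc[sample]
        rows.append(
            {
                "sample_id": sample,
                "subject": meta["subject"],
                "day": int(meta["day"]),
                "role": meta["role"],
                "distance": aitchison_distance(comp, ref),
            }
        )
    out = pd.DataFrame(rows).sort_values(["subject", "day"], kind="stable")
    return out.reset_index(drop=True)


def nmds(
    distance_matrix: np.ndarray, seed: int = 0, n_components: int = 2
) -> np.ndarray:
    """Non-metric multidimensional scaling of a precomputed distance matrix
    (rank-based embedding minimising Kruskal stress); used for ordination
    plots of sample trajectories.
    """
    import warnings

    from sklearn.manifold import MDS

    mds = MDS(
        n_components=n_components,
        metric=False,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress=True,
        n_init=4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return mds.fit_transform(np.asarray(distance_matrix, dtype=float))
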