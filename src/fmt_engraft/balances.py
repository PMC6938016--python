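"""Sequential binary partitions, ilr balances and the balance dendrogram.

A sequential binary partition (SBP) of D parts is a hierarchy of D-1 binary
splits; each split defines one ilr balance, a normalised log-ratio between
the geometric means of the two part groups.  Because the full set of
balances is an isometry of the Aitchison geometry, the total (metric)
variance of a sample set decomposes exactly into per-balance variances —
the vertical bars of a CoDa dendrogram.  The per-group (e.g. per-timepoint)
mean balances are the dendrogram's anchoring points and describe community
succession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import Composition, total_variance

__all__ = [
    "SbpNode",
    "SbpTree",
    "BalanceSummary",
    "variation_matrix",
    "build_sbp",
    "random_sbp",
    "ilr_balance",
    "decompose_variance",
    "export_dendrogram",
    "parse_newick_bipartitions",
]


@dataclass
class SbpNode:
    """One binary split: numerator part-group R, denominator part-group S."""

    name: str
    r_parts: tuple[str, ...]
    s_parts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.r_parts or not self.s_parts:
            raise ValueError(f"node {self.name}: empty R or S")
        if set(self.r_parts) & set(self.s_parts):
            raise ValueError(f"node {self.name}: R and S overlap")

    @property
    def parts(self) -> tuple[str, ...]:
        return self.r_parts + self.s_parts

    @property
    def coefficient(self) -> float:
        r, s = len(self.r_parts), len(self.s_parts)
        return float(np.sqrt(r * s / (r + s)))


@dataclass
class SbpTree:
    """Sequential binary partition over ``parts``: exactly D-1 nodes, ordered
    root first (node i's parts are the union of its children's parts)."""

    parts: tuple[str, ...]
    nodes: list[SbpNode] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.parts) - 1:
            raise ValueError(
                f"SBP over {len(self.parts)} parts needs "
                f"{len(self.parts) - 1} nodes, got {len(self.nodes)}"
            )


def variation_matrix(comps: list[Composition]) -> pd.DataFrame:
    """Log-ratio variation matrix t_ij = var(ln(x_i / x_j)) (divisor n)."""
    parts = comps[0].parts
    logs = np.log(np.stack([c.values for c in comps]))
    t = np.zeros((len(parts), len(parts)))
    for i in range(len(parts)):
        diff = logs[:, i][:, None] - logs
        t[i] = diff.var(axis=0)
    return pd.DataFrame(t, index=parts, columns=parts)


def build_sbp(comps: list[Composition]) -> SbpTree:
    """Data-driven SBP: Ward agglomeration on the variation matrix.

    Parts whose log-ratio varies least merge first, so the top splits of the
    resulting hierarchy separate the part groups that move most relative to
    each other.  Merges are deterministic: ties on merge cost are broken by
    the lexicographically smallest (min label, max label) pair, and each
    node's numerator R is the child cluster containing the lexicographically
    smallest part.
    """
    parts = comps[0].parts
    if len(parts) < 2:
        raise ValueError("build_sbp needs at least 2 parts")
    t = variation_matrix(comps).to_numpy()

    # Lance-Williams Ward on the variation matrix treated as squared
    # dissimilarity; clusters tracked as sorted label tuples.
    clusters: list[tuple[str, ...]] = [(p,) for p in parts]
    sizes = [1] * len(parts)
    d = t.astype(float).copy()
    merges: list[tuple[tuple[str, ...], tuple[str, ...]]] = []

    while len(clusters) > 1:
        best = None
        best_key = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ni, nj = sizes[i], sizes[j]
                cost = (ni * nj) / (ni + nj) * d[i, j]
                key = (cost, min(clusters[i][0], clusters[j][0]),
                       max(clusters[i][0], clusters[j][0]))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        merges.append((clusters[i], clusters[j]))
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams update for Ward
        new_row = np.empty(len(clusters))
        for k in range(len(clusters)):
            if k in (i, j):
                continue
            nk = sizes[k]
            new_row[k] = (
                (ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * d[i, j]
            ) / (ni + nj + nk)
        keep = [k for k in range(len(clusters)) if k not in (i, j)]
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [clusters[k] for k in keep] + [merged]
        sizes = [sizes[k] for k in keep] + [ni + nj]
        d_new = np.zeros((len(clusters), len(clusters)))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_row[keep]
        d_new[:-1, -1] = new_row[keep]
        d = d_new

    # Last merge is the root; number nodes root-first.
    nodes = []
    for idx, (a, b) in enumerate(reversed(merges)):
        r, s = (a, b) if min(a) < min(b) else (b, a)
        nodes.append(SbpNode(name=f"n{idx + 1}", r_parts=r, s_parts=s))
    return SbpTree(parts=tuple(parts), nodes=nodes)


def random_sbp(parts: list[str], rng: np.random.Generator) -> SbpTree:
    """A uniformly random sequential binary partition (recursive random
    splits); useful for checking properties that must hold for any SBP."""
    if len(parts) < 2:
        raise ValueError("random_sbp needs at least 2 parts")
    nodes: list[SbpNode] = []
    counter = [0]

    def split(group: list[str]) -> None:
        if len(group) == 1:
            return
        mask = rng.integers(0, 2, len(group)).astype(bool)
        if mask.all() or not mask.any():
            flip = rng.integers(0, len(group))
            mask[flip] = not mask[flip]
        left = [p for p, m in zip(group, mask) if m]
        right = [p for p, m in zip(group, mask) if not m]
        if min(right) < min(left):
            left, right = right, left
        counter[0] += 1
        nodes.append(
            SbpNode(f"n{counter[0]}", tuple(left), tuple(right))
        )
        split(left)
        split(right)

    split(list(parts))
    return SbpTree(parts=tuple(parts), nodes=nodes)


def ilr_balance(x: Composition, node: SbpNode) -> float:
    """b = sqrt(rs/(r+s)) * ln(g(x_R)/g(x_S)), g = geometric mean."""
    idx = {p: i for i, p in enumerate(x.parts)}
    try:
        r_vals = np.log([x.values[idx[p]] for p in node.r_parts])
        s_vals = np.log([x.values[idx[p]] for p in node.s_parts])
    except KeyError as exc:
        raise ValueError(f"node part {exc} absent from composition") from exc
    return node.coefficient * float(r_vals.mean() - s_vals.mean())


def ilr_coordinates(x: Composition, tree: SbpTree) -> np.ndarray:
    """Full ilr coordinate vector (one balance per node, root first)."""
    return np.array([ilr_balance(x, node) for node in tree.nodes])


@dataclass
class BalanceSummary:
    """Per-node balance variances, variance shares and per-group means."""

    table: pd.DataFrame  # node, r_parts, s_parts, variance, share
    group_means: pd.DataFrame  # node, group, mean_balance
    total_variance: float


def decompose_variance(
    comps: dict[str, Composition] | list[Composition],
    tree: SbpTree,
    groups: dict[str, object] | None = None,
) -> BalanceSummary:
    """Decompose total variance into per-balance components.

    ``groups`` maps sample id -> group label (e.g. sampling day); per-group
    mean balances are the anchoring points of the CoDa dendrogram.  The sum
    of node variances equals the total metric variance (ilr is an isometry).
    """
    if isinstance(comps, dict):
        sample_ids = list(comps)
        comp_list = [comps[s] for s in sample_ids]
    else:
        sample_ids = [str(i) for i in range(len(comps))]
        comp_list = list(comps)
    if groups is not None:
        missing = [s for s in sample_ids if s not in groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    bal = np.stack([ilr_coordinates(c, tree) for c in comp_list])
    variances = bal.var(axis=0)  # divisor n, matching total_variance
    total = float(variances.sum())
    shares = variances / total if total > 0 else np.zeros_like(variances)

    rows = []
    for k, node in enumerate(tree.nodes):
        rows.append(
            {
                "node": node.name,
                "r_parts": ",".join(node.r_parts),
                "s_parts": ",".join(node.s_parts),
                "variance": variances[k],
                "share": shares[k],
            }
        )
    table = pd.DataFrame(rows)

    mean_rows = []
    if groups is not None:
        labels = [groups[s] for s in sample_ids]
        for g in sorted(set(labels), key=str):
            mask = np.array([lab == g for lab in labels])
            means = bal[mask].mean(axis=0)
            for k, node in enumerate(tree.nodes):
                mean_rows.append(
                    {"node": node.name, "group": g, "mean_balance": means[k]}
                )
    group_means = pd.DataFrame(
        mean_rows, columns=["node", "group", "mean_balance"]
    )
    return BalanceSummary(
        table=table, group_means=group_means, total_variance=total
    )


def _newick_clause(node_parts: frozenset, children: dict) -> str:
    if len(node_parts) == 1:
        return next(iter(node_parts))
    left, right, name = children[node_parts]
    return (
        f"({_newick_clause(left, children)},"
        f"{_newick_clause(right, children)}){name}"
    )


def export_dendrogram(
    tree: SbpTree, summary: BalanceSummary
) -> tuple[str, pd.DataFrame]:
    """Serialise the balance dendrogram.

    Returns a Newick string whose internal node labels carry the variance
    share (``name|share=x``), and a tidy table (node, r_parts, s_parts,
    variance, share, group, mean_balance) with one row per node x group
    (group empty when no grouping was requested).
    """
    shares = dict(zip(summary.table["node"], summary.table["share"]))
    children: dict[frozenset, tuple[frozenset, frozenset, str]] = {}
    for node in tree.nodes:
        label = f"{node.name}|share={shares[node.name]:.6g}"
        children[frozenset(node.parts)] = (
            frozenset(node.r_parts),
            frozenset(node.s_parts),
            label,
        )
    newick = _newick_clause(frozenset(tree.parts), children) + ";"

    tidy = summary.table.copy()
    if len(summary.group_means):
        tidy = tidy.merge(summary.group_means, on="node")
    else:
        tidy["group"] = ""
        tidy["mean_balance"] = np.nan
    return newick, tidy


def parse_newick_bipartitions(newick: str) -> set[frozenset]:
    """Part bipartitions (as leaf sets below each internal node) of a Newick
    string; used to round-trip check exports."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    clades = set()
    for clade in tree.get_nonterminals():
        leaves = frozenset(t.name for t in clade.get_terminals())
        clades.add(leaves)
    return clades
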