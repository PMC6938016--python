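"""Readers/writers for the formats the pipeline touches, run configuration
and the end-to-end pipeline driver.

All tables are tab-delimited UTF-8 with a single header row; writers emit
deterministic row and column order so reruns are byte-identical and
manifest checksums are meaningful.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import balances as bal
from . import coda, genome, synthetic, tracking

logger = logging.getLogger("fmt_engraft")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_depth",
    "write_mags",
    "read_mags",
    "RunConfig",
    "run_pipeline",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (nucleotide or amino-acid) FASTA file as (id, sequence) pairs.

    Ids and sequences are preserved exactly; duplicate ids and text before
    the first header are rejected with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = next(
        (i for i, ln in enumerate(lines) if ln.strip()), None
    )
    if first_content is None:
        logger.warning("empty FASTA file: %s", path)
        return []
    if not lines[first_content].startswith(">"):
        raise ValueError(
            f"{path}:{first_content + 1}: expected FASTA header '>'"
        )
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seqs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_depth(
    path, contig_lengths: dict[str, int] | None = None
) -> dict[str, tuple[int, int]]:
    """Read a samtools-depth-style TSV (contig, 1-based position, depth)
    into per-contig (covered_bases, total_bases) summaries.

    Positions absent from the file count as depth 0 when ``contig_lengths``
    supplies the contig length; without lengths, the highest listed
    position defines the contig extent.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos", "depth"],
        comment="#",
    )
    if not np.issubdtype(df["depth"].dtype, np.integer):
        raise ValueError(f"{path}: non-integer depth values")
    if not np.issubdtype(df["pos"].dtype, np.integer):
        raise ValueError(f"{path}: non-integer positions")
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based")
    out: dict[str, tuple[int, int]] = {}
    for contig, grp in df.groupby("contig", sort=True):
        max_pos = int(grp["pos"].max())
        if contig_lengths is not None:
            if contig not in contig_lengths:
                raise ValueError(f"{path}: unknown contig {contig!r}")
            total = contig_lengths[contig]
            if max_pos > total:
                raise ValueError(
                    f"{path}: position {max_pos} exceeds length of "
                    f"{contig!r} ({total})"
                )
        else:
            total = max_pos
        covered = int((grp["depth"] >= 1).sum())
        out[str(contig)] = (covered, total)
    if contig_lengths is not None:
        for contig, total in contig_lengths.items():
            out.setdefault(contig, (0, total))
    return out


def write_mags(mags: list[genome.MagRecord], out_dir,
               metrics_path) -> None:
    """One multi-FASTA per MAG plus a shared marker FASTA and metrics TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker_records = []
    rows = []
    for mag in sorted(mags, key=lambda m: m.id):
        write_fasta(
            sorted(mag.contigs.items()), out_dir / f"{mag.id}.fasta"
        )
        for k in sorted(mag.markers):
            marker_records.append((f"{mag.id}_marker_{k}", mag.markers[k]))
        subject, day = mag.source if mag.source else ("", 0)
        rows.append(
            {
                "mag_id": mag.id,
                "completeness": mag.completeness,
                "contamination": mag.contamination,
                "total_length": mag.total_length,
                "subject": subject,
                "day": day,
            }
        )
    write_fasta(marker_records, out_dir / "markers.faa")
    pd.DataFrame(rows).to_csv(metrics_path, sep="\t", index=False)


def read_mags(mags_dir, markers_path=None, metrics_path=None
              ) -> list[genome.MagRecord]:
    """Load MAGs from a directory of per-MAG multi-FASTAs, with optional
    marker AA FASTA (ids ``MAGID_marker_k``) and quality-metrics TSV."""
    mags_dir = Path(mags_dir)
    mags: dict[str, genome.MagRecord] = {}
    for fasta in sorted(mags_dir.glob("*.fasta")):
        mag_id = fasta.stem
        contigs = dict(read_fasta(fasta))
        mags[mag_id] = genome.MagRecord(id=mag_id, contigs=contigs)
    if markers_path is not None:
        for name, seq in read_fasta(markers_path):
            mag_id, _, idx = name.rpartition("_marker_")
            if mag_id in mags:
                mags[mag_id].markers[int(idx)] = seq
    if metrics_path is not None:
        metrics = pd.read_csv(metrics_path, sep="\t")
        for row in metrics.itertuples():
            if row.mag_id in mags:
                mags[row.mag_id].completeness = float(row.completeness)
                mags[row.mag_id].contamination = float(row.contamination)
                mags[row.mag_id].source = (str(row.subject), int(row.day))
    return list(mags.values())


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_SCHEMA: dict[str, dict[str, type]] = {
    "simulate": {f.name: object for f in fields(synthetic.SimulationConfig)},
    "coda": {"min_prop": float, "min_samples": int, "prior_strength": float},
    "balances": {"group_by": str},
    "genomes": {
        "fragment_length": int,
        "ani_threshold": float,
        "min_completeness": float,
        "max_contamination": float,
        "min_length": int,
        "marker_cluster_threshold": float,
    },
    "tracking": {"presence_threshold": float, "min_depth": int},
}


@dataclass
class RunConfig:
    """Pipeline configuration: every tunable with its documented default.

    Loadable from an INI-style file with one section per stage; unknown
    sections or keys are rejected before any stage runs.
    """

    out_dir: Path = Path("fmt_engraft_out")
    seed: int = 0
    simulate: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    min_prop: float = 0.001
    min_samples: int = 2
    prior_strength: float = 0.5
    group_by: str = "day"
    fragment_length: int = 1020
    ani_threshold: float = 99.90
    min_completeness: float = 70.0
    max_contamination: float = 10.0
    min_length: int = 2_000_000
    marker_cluster_threshold: float = 1.0
    presence_threshold: float = 0.25
    min_depth: int = 5

    @classmethod
    def from_file(cls, path, out_dir=None, seed=None) -> "RunConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        kwargs: dict = {}
        sim_kwargs: dict = {}
        for section in parser.sections():
            if section == "run":
                for key, val in parser.items(section):
                    if key == "out_dir":
                        kwargs["out_dir"] = Path(val)
                    elif key == "seed":
                        kwargs["seed"] = int(val)
                    else:
                        raise ValueError(f"unknown key [run] {key}")
                continue
            if section not in _CONFIG_SCHEMA:
                raise ValueError(f"unknown config section [{section}]")
            for key, val in parser.items(section):
                if key not in _CONFIG_SCHEMA[section]:
                    raise ValueError(f"unknown key [{section}] {key}")
                if section == "simulate":
                    sim_kwargs[key] = _parse_sim_value(key, val)
                else:
                    typ = _CONFIG_SCHEMA[section][key]
                    kwargs[key] = typ(val)
        if out_dir is not None:
            kwargs["out_dir"] = Path(out_dir)
        if seed is not None:
            kwargs["seed"] = int(seed)
            sim_kwargs.setdefault("seed", int(seed))
        elif "seed" in kwargs:
            sim_kwargs.setdefault("seed", kwargs["seed"])
        kwargs["simulate"] = synthetic.SimulationConfig(**sim_kwargs)
        config = cls(**kwargs)
        _log_defaults(config, set(kwargs) | {"simulate"})
        return config


def _parse_sim_value(key: str, val: str):
    if key == "timepoints":
        return tuple(int(v) for v in val.replace(",", " ").split())
    hints = {f.name: f.type for f in fields(synthetic.SimulationConfig)}
    hint = str(hints[key])
    if "float" in hint:
        return float(val)
    return int(val)


def _log_defaults(config: RunConfig, explicit: set) -> None:
    for f in fields(RunConfig):
        if f.name not in explicit:
            logger.info(
                "config default used: %s = %r", f.name, getattr(config, f.name)
            )


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic analysis end to end.

    Stages: simulate -> convergence trajectory -> balance dendrogram ->
    genome comparison (markers, clusters, ANI) -> engraftment calls ->
    SNV distance trend.  Every artefact lands under ``config.out_dir`` with
    a manifest (parameters, seed, sha256 checksums); identical configs
    produce identical manifests.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    sim = config.simulate
    stage = "simulate"
    try:
        table, ts_truth = synthetic.simulate_timeseries(sim)
        table.to_tsv(out / "abundance.tsv", out / "metadata.tsv")
        written += [out / "abundance.tsv", out / "metadata.tsv"]
        cohort = synthetic.simulate_cohort(sim)
        emit(cohort.truth.engrafted_frame(), "truth_engrafted.tsv")

        stage = "coda-trajectory"
        filtered = coda.filter_rare_taxa(
            table, config.min_prop, config.min_samples
        )
        traj = coda.distance_to_donor(
            filtered, "DONOR_d0", config.prior_strength
        )
        emit(traj, "trajectory.tsv")

        stage = "balances"
        comps = coda.replace_zeros(filtered, config.prior_strength)
        tree = bal.build_sbp(list(comps.values()))
        groups = {
            s: int(table.metadata.loc[s, config.group_by])
            for s in comps
        }
        summary = bal.decompose_variance(comps, tree, groups)
        newick, tidy = bal.export_dendrogram(tree, summary)
        (out / "dendrogram.nwk").write_text(newick + "\n")
        written.append(out / "dendrogram.nwk")
        emit(tidy, "balances.tsv")

        stage = "compare-genomes"
        all_mags = cohort.all_mags
        # Synthetic genomes are desk-scale stand-ins for multi-Mbp MAGs, so
        # the published length gate is scaled down proportionally here; the
        # completeness/contamination gates apply as configured.
        eff_min_length = min(config.min_length, sim.genome_length // 2)
        if eff_min_length != config.min_length:
            logger.info(
                "length gate scaled to %d bp for synthetic genomes",
                eff_min_length,
            )
        gated = genome.quality_gate(
            all_mags,
            config.min_completeness,
            config.max_contamination,
            eff_min_length,
        )
        idm, _ = genome.identity_matrix(gated)
        idm.rename_axis("mag_id").to_csv(out / "marker_identity.tsv", sep="\t")
        written.append(out / "marker_identity.tsv")
        clusters = genome.cluster_by_markers(
            idm, config.marker_cluster_threshold
        )
        emit(
            pd.DataFrame(
                [
                    {"cluster": f"C{i + 1:03d}", "mag_id": m}
                    for i, cl in enumerate(clusters)
                    for m in sorted(cl)
                ]
            ),
            "clusters.tsv",
        )
        ani_results = {}
        ani_rows = []
        gated_by_id = {m.id: m for m in gated}
        for cl in clusters:
            members = sorted(cl)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    res = genome.ani(
                        gated_by_id[a], gated_by_id[b], config.fragment_length
                    )
                    ani_results[frozenset((a, b))] = res
                    ani_rows.append(
                        {
                            "mag_a": a,
                            "mag_b": b,
                            "ani": res.ani if res.has_signal else np.nan,
                            "n_reciprocal_fragments": res.n_reciprocal_fragments,
                            "coverage_fraction": res.coverage_fraction,
                        }
                    )
        emit(
            pd.DataFrame(
                ani_rows,
                columns=[
                    "mag_a", "mag_b", "ani", "n_reciprocal_fragments",
                    "coverage_fraction",
                ],
            ),
            "ani.tsv",
        )

        stage = "track"
        calls = tracking.call_engraftment(
            clusters,
            ani_results,
            cohort.detections,
            cohort.mag_subjects,
            sim.pre_days,
            sim.post_days,
            config.presence_threshold,
            config.ani_threshold,
        )
        emit(tracking.calls_to_frame(calls), "calls.tsv")
        emit(
            cohort.detections.sort_values(
                ["donor_mag", "recipient", "day"], kind="stable"
            ),
            "detections.tsv",
        )

        stage = "snv-distance"
        profiles, snv_meta = synthetic.simulate_snv_timeseries(sim)
        trend = tracking.donor_similarity_trend(
            profiles, "DONOR_d0", snv_meta, config.min_depth
        )
        emit(trend, "snv_trend.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "parameters": {
            f.name: str(getattr(config, f.name))
            for f in fields(RunConfig)
            if f.name != "simulate"
        },
        "simulate": {
            f.name: str(getattr(sim, f.name))
            for f in fields(synthetic.SimulationConfig)
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(written, key=lambda p: p.name)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
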