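"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume, so every
stage is testable without sequencing data:

* recipient taxon compositions converging toward a donor composition along
  the clr geodesic, with multinomial count noise;
* donor/recipient genome pairs with controlled genome-wide nucleotide
  identity, where shared (engrafted) strains receive synonymous-only
  changes inside marker-coding regions (marker proteins stay identical) and
  distinct strains mutate freely;
* Poisson per-position coverage giving controlled detection values before
  and after the transplant;
* paired SNV allele-count tables with a controlled major-allele
  disagreement fraction.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import AbundanceTable, Composition, clr_inverse
from .genome import MagRecord
from .tracking import CoverageProfile, SnvProfile, detection

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CohortData",
    "simulate_timeseries",
    "simulate_genomes",
    "simulate_coverage",
    "simulate_snv_profiles",
    "simulate_snv_timeseries",
    "simulate_family_shift",
    "simulate_cohort",
    "mutate_genome",
]

BASES = "ACGT"

# Codon prefixes that are four-fold degenerate at the third position: any
# third-base substitution is synonymous.  Marker-coding regions are built
# from these codons so that planted synonymous changes are easy to place.
FOURFOLD_PREFIXES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")
PREFIX_AA = dict(
    CT="L", GT="V", TC="S", CC="P", AC="T", GC="A", CG="R", GG="G"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Days are relative to the transplant (negative = before).  ``dispersion``
    is the multinomial read depth per abundance sample; ``shared_ani`` /
    ``distinct_ani`` control the planted nucleotide identity of engrafted
    vs recipient-own strain pairs, straddling the 99.90% strain threshold.
    """

    n_taxa: int = 50
    n_recipients: int = 3
    timepoints: tuple[int, ...] = (-7, 5, 30, 60, 120, 300)
    convergence_rate: float = 0.05  # per day
    dispersion: int = 100_000  # multinomial reads per sample
    clr_noise_sd: float = 0.3
    genome_length: int = 50_000  # bp per synthetic MAG (desk-scale)
    marker_count: int = 43
    marker_length: int = 100  # aa residues
    shared_strain_count: int = 10
    distinct_strain_count: int = 10
    shared_ani: float = 99.95
    distinct_ani: float = 99.0
    coverage_depth: float = 10.0  # mean fold-coverage when present
    seed: int = 0

    def __post_init__(self) -> None:
        if self.convergence_rate < 0:
            raise ValueError("convergence_rate must be >= 0")
        if not 99.90 < self.shared_ani <= 100.0:
            raise ValueError("shared_ani must be in (99.90, 100]")
        if self.distinct_ani > 99.5:
            raise ValueError("distinct_ani must be <= 99.5")
        for name in (
            "n_taxa",
            "n_recipients",
            "dispersion",
            "genome_length",
            "marker_count",
            "marker_length",
            "shared_strain_count",
            "distinct_strain_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        days = self.timepoints
        if not (any(d < 0 for d in days) and any(d > 0 for d in days)):
            raise ValueError(
                "timepoints need at least one pre- and one post-FMT day"
            )
        if self.coverage_depth < 0:
            raise ValueError("coverage_depth must be >= 0")

    @property
    def marker_region_length(self) -> int:
        return self.marker_count * self.marker_length * 3

    @property
    def pre_days(self) -> list[int]:
        return [d for d in self.timepoints if d < 0]

    @property
    def post_days(self) -> list[int]:
        return [d for d in self.timepoints if d > 0]

    @property
    def recipients(self) -> list[str]:
        return [f"V{i + 1}" for i in range(self.n_recipients)]


@dataclass
class SyntheticTruth:
    """Planted parameters recorded for recovery testing."""

    true_convergence_rate: float | None = None
    donor_composition: Composition | None = None
    engrafted_labels: dict[str, dict[str, bool]] = field(default_factory=dict)
    true_ani: dict[frozenset, float] = field(default_factory=dict)

    def engrafted_frame(self) -> pd.DataFrame:
        rows = [
            {"donor_mag": mag, "recipient": rec, "engrafted": flag}
            for mag, by_rec in sorted(self.engrafted_labels.items())
            for rec, flag in sorted(by_rec.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# abundance time series


def _softmax_composition(clr_vec: np.ndarray, taxa: list[str]) -> Composition:
    return clr_inverse(clr_vec, taxa)


def simulate_timeseries(
    config: SimulationConfig,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Recipient compositions converging toward the donor in clr space.

    The expected clr vector at post-FMT day t is
    ``(1 - w_t) * baseline + w_t * donor`` with ``w_t = 1 - exp(-lambda t)``;
    pre-FMT samples sit at the recipient baseline, donor samples around the
    donor composition.  Isotropic Gaussian noise is added on the clr scale
    and counts are drawn multinomially at the configured depth.
    """
    if config.dispersion <= 0:
        raise ValueError("multinomial depth (dispersion) must be positive")
    rng = np.random.default_rng(config.seed)
    taxa = [f"T{i + 1:03d}" for i in range(config.n_taxa)]
    donor_clr = rng.normal(0.0, 1.0, config.n_taxa)
    donor_clr -= donor_clr.mean()
    lam = config.convergence_rate

    counts: dict[str, np.ndarray] = {}
    meta_rows = []

    def draw_sample(name: str, mean_clr: np.ndarray, subject: str,
                    day: int, role: str) -> None:
        noisy = mean_clr + rng.normal(0.0, config.clr_noise_sd, config.n_taxa)
        comp = _softmax_composition(noisy, taxa)
        counts[name] = rng.multinomial(config.dispersion, comp.values)
        meta_rows.append(
            {"sample_id": name, "subject": subject, "day": day, "role": role}
        )

    draw_sample("DONOR_d0", donor_clr, "DONOR", 0, "donor")
    for rec in config.recipients:
        baseline = rng.normal(0.0, 1.0, config.n_taxa)
        baseline -= baseline.mean()
        for day in config.timepoints:
            if day <= 0:
                mean = baseline
            else:
                w = 1.0 - np.exp(-lam * day)
                mean = (1.0 - w) * baseline + w * donor_clr
            draw_sample(f"{rec}_d{day}", mean, rec, day, "recipient")

    count_df = pd.DataFrame(counts, index=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = AbundanceTable(count_df, meta)
    truth = SyntheticTruth(
        true_convergence_rate=lam,
        donor_composition=_softmax_composition(donor_clr, taxa),
    )
    return table, truth


# ---------------------------------------------------------------------------
# genomes and markers


def _random_genome(config: SimulationConfig, rng: np.random.Generator
                   ) -> np.ndarray:
    """Genome as base indices; the marker region occupies the start and is
    built from four-fold degenerate codons."""
    marker_nt = config.marker_region_length
    if marker_nt > config.genome_length:
        raise ValueError(
            f"marker regions ({marker_nt} bp) exceed genome length "
            f"({config.genome_length} bp)"
        )
    n_codons = config.marker_count * config.marker_length
    prefixes = rng.integers(0, len(FOURFOLD_PREFIXES), n_codons)
    thirds = rng.integers(0, 4, n_codons)
    marker = np.empty(marker_nt, dtype=np.int8)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for c, prefix in enumerate(prefixes):
        p = FOURFOLD_PREFIXES[prefix]
        marker[3 * c] = base_idx[p[0]]
        marker[3 * c + 1] = base_idx[p[1]]
        marker[3 * c + 2] = thirds[c]
    tail = rng.integers(0, 4, config.genome_length - marker_nt, dtype=np.int8)
    return np.concatenate([marker, tail])


def mutate_genome(
    genome: np.ndarray,
    rate: float,
    marker_nt: int,
    synonymous_only: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Substitute bases at ``rate`` per position; with ``synonymous_only``,
    hits inside the marker region snap to their codon's (four-fold
    degenerate) third position so the encoded protein is unchanged.
    Returns the mutant and the realised substitution count.
    """
    n_mut = rng.binomial(genome.size, rate)
    if n_mut == 0:
        return genome.copy(), 0
    positions = rng.choice(genome.size, n_mut, replace=False)
    if synonymous_only:
        in_marker = positions < marker_nt
        positions = positions.copy()
        positions[in_marker] = positions[in_marker] - (
            positions[in_marker] % 3
        ) + 2
        positions = np.unique(positions)
    mutant = genome.copy()
    shifts = rng.integers(1, 4, positions.size)
    mutant[positions] = (mutant[positions] + shifts) % 4
    return mutant, int(positions.size)


def _translate_markers(
    genome: np.ndarray, config: SimulationConfig
) -> dict[int, str]:
    table = {}
    codon_aa = {}
    for p in FOURFOLD_PREFIXES:
        for b in BASES:
            codon_aa[p + b] = PREFIX_AA[p]
    # non-fourfold codons (possible after nonsynonymous mutation) translate
    # by the standard code
    from Bio.Seq import Seq

    marker_len_nt = config.marker_length * 3
    for k in range(config.marker_count):
        seg = genome[k * marker_len_nt : (k + 1) * marker_len_nt]
        nts = "".join(BASES[i] for i in seg)
        aas = []
        for c in range(0, marker_len_nt, 3):
            codon = nts[c : c + 3]
            aas.append(codon_aa.get(codon) or str(Seq(codon).translate()))
        table[k] = "".join(aas)
    return table


def _to_contigs(mag_id: str, genome: np.ndarray) -> dict[str, str]:
    split = int(genome.size * 0.6)
    seq = "".join(BASES[i] for i in genome)
    return {
        f"{mag_id}_contig_1": seq[:split],
        f"{mag_id}_contig_2": seq[split:],
    }


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[list[MagRecord], dict[str, list[MagRecord]], SyntheticTruth]:
    """Donor MAGs plus per-recipient MAGs with planted strain identity.

    Shared (engrafted) strains: the recipient copy mutates at rate
    ``(100 - shared_ani)/100`` with synonymous-only marker changes, so the
    43 marker proteins stay identical while genome-wide identity sits just
    above the strain threshold.  Distinct strains mutate at
    ``(100 - distinct_ani)/100`` anywhere, so marker proteins diverge too.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_strains = config.shared_strain_count + config.distinct_strain_count
    marker_nt = config.marker_region_length
    truth = SyntheticTruth()

    donor_mags: list[MagRecord] = []
    recipient_mags: dict[str, list[MagRecord]] = {
        rec: [] for rec in config.recipients
    }
    for s in range(n_strains):
        shared = s < config.shared_strain_count
        donor_id = f"DONOR_MAG_{s + 1:02d}"
        genome = _random_genome(config, rng)
        donor_mags.append(
            MagRecord(
                id=donor_id,
                contigs=_to_contigs(donor_id, genome),
                completeness=float(rng.uniform(80, 99)),
                contamination=float(rng.uniform(0, 5)),
                markers=_translate_markers(genome, config),
                source=("DONOR", 0),
            )
        )
        truth.engrafted_labels[donor_id] = {}
        rate = (
            (100.0 - config.shared_ani) / 100.0
            if shared
            else (100.0 - config.distinct_ani) / 100.0
        )
        for rec in config.recipients:
            rec_id = f"{rec}_MAG_{s + 1:02d}"
            mutant, n_sub = mutate_genome(
                genome, rate, marker_nt, synonymous_only=shared, rng=rng
            )
            recipient_mags[rec].append(
                MagRecord(
                    id=rec_id,
                    contigs=_to_contigs(rec_id, mutant),
                    completeness=float(rng.uniform(80, 99)),
                    contamination=float(rng.uniform(0, 5)),
                    markers=_translate_markers(mutant, config),
                    source=(rec, max(config.post_days)),
                )
            )
            truth.engrafted_labels[donor_id][rec] = shared
            truth.true_ani[frozenset((donor_id, rec_id))] = 100.0 * (
                1.0 - n_sub / config.genome_length
            )
    return donor_mags, recipient_mags, truth


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(
    mag: MagRecord,
    present: bool,
    depth: float,
    seed: int,
    sample_id: str = "",
) -> CoverageProfile:
    """Per-position Poisson(depth) coverage when the strain is present in
    the sample, all zeros when absent."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    depths = {}
    for contig in sorted(mag.contigs):
        n = len(mag.contigs[contig])
        depths[contig] = (
            rng.poisson(depth, n) if present else np.zeros(n, dtype=np.int64)
        )
    return CoverageProfile(mag_id=mag.id, sample_id=sample_id, depths=depths)


# ---------------------------------------------------------------------------
# SNV profiles


def _profile_from_majors(
    majors: np.ndarray, positions: list[tuple[str, int]], depth: int,
    ref_id: str,
) -> SnvProfile:
    n = majors.size
    counts = np.zeros((n, 4))
    minor = depth // 5
    counts[np.arange(n), majors] = depth - minor
    if minor:
        second = (majors + 1) % 4
        counts[np.arange(n), second] += minor
    return SnvProfile(ref_id=ref_id, positions=positions, counts=counts)


def simulate_snv_profiles(
    n: int, q: float, depth: int = 20, seed: int = 0
) -> tuple[SnvProfile, SnvProfile]:
    """Two allele-count tables over the same ``n`` positions whose major
    alleles differ at exactly ``floor(q * n)`` positions."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = [("ref", i + 1) for i in range(n)]
    majors_a = rng.integers(0, 4, n)
    majors_b = majors_a.copy()
    m = int(np.floor(q * n))
    flip = rng.choice(n, m, replace=False)
    majors_b[flip] = (majors_b[flip] + rng.integers(1, 4, m)) % 4
    return (
        _profile_from_majors(majors_a, positions, depth, "ref"),
        _profile_from_majors(majors_b, positions, depth, "ref"),
    )


def simulate_snv_timeseries(
    config: SimulationConfig,
    n_positions: int = 1000,
    q0: float = 0.5,
    depth: int = 20,
) -> tuple[dict[str, SnvProfile], pd.DataFrame]:
    """Per-sample SNV profiles converging to the donor's major alleles.

    The recipient's disagreement fraction with the donor is ``q0`` before
    the transplant and decays as ``q0 * exp(-lambda * day)`` afterwards;
    disagreeing positions are nested (a fixed per-recipient permutation), so
    planted distances are exact.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    positions = [("ref", i + 1) for i in range(n_positions)]
    donor_majors = rng.integers(0, 4, n_positions)
    profiles = {
        "DONOR_d0": _profile_from_majors(donor_majors, positions, depth, "ref")
    }
    meta_rows = [{"sample_id": "DONOR_d0", "subject": "DONOR", "day": 0}]
    lam = config.convergence_rate
    for rec in config.recipients:
        perm = rng.permutation(n_positions)
        flips = (donor_majors + rng.integers(1, 4, n_positions)) % 4
        for day in config.timepoints:
            q = q0 if day <= 0 else q0 * np.exp(-lam * day)
            m = int(np.floor(q * n_positions))
            majors = donor_majors.copy()
            majors[perm[:m]] = flips[perm[:m]]
            name = f"{rec}_d{day}"
            profiles[name] = _profile_from_majors(
                majors, positions, depth, "ref"
            )
            meta_rows.append({"sample_id": name, "subject": rec, "day": day})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return profiles, meta


# ---------------------------------------------------------------------------
# planted single-family succession (balance-dendrogram recovery)


def simulate_family_shift(
    n_parts: int = 8,
    n_samples: int = 24,
    shift: float = 3.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, Composition], dict[str, int], str]:
    """Compositions where a single part's clr coordinate drifts over time.

    Returns (compositions by sample, sample -> day group, shifted part).
    The SBP node separating the shifted part should absorb the largest
    variance share.
    """
    rng = np.random.default_rng(seed)
    parts = [f"F{i + 1:02d}" for i in range(n_parts)]
    target = parts[int(rng.integers(0, n_parts))]
    base = rng.normal(0.0, 1.0, n_parts)
    comps: dict[str, Composition] = {}
    groups: dict[str, int] = {}
    for i in range(n_samples):
        u = i / (n_samples - 1)
        vec = base + rng.normal(0.0, noise_sd, n_parts)
        vec[parts.index(target)] += shift * u
        name = f"S{i + 1:03d}"
        comps[name] = clr_inverse(vec, parts)
        groups[name] = i
    return comps, groups, target


# ---------------------------------------------------------------------------
# full cohort (genomes + coverage time course)


@dataclass
class CohortData:
    """Everything the engraftment caller consumes, plus planted truth."""

    config: SimulationConfig
    donor_mags: list[MagRecord]
    recipient_mags: dict[str, list[MagRecord]]
    detections: pd.DataFrame  # donor_mag, recipient, day, detection
    mag_subjects: dict[str, str]
    truth: SyntheticTruth

    @property
    def all_mags(self) -> list[MagRecord]:
        out = list(self.donor_mags)
        for rec in sorted(self.recipient_mags):
            out.extend(self.recipient_mags[rec])
        return out


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Genomes plus a coverage time course for every donor MAG in every
    recipient: engrafted strains appear (Poisson coverage at the configured
    depth) only after the transplant; distinct strains never produce
    donor-MAG coverage because recipient reads are mapped at 100% identity.
    """
    donor_mags, recipient_mags, truth = simulate_genomes(config)
    seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rows = []
    for mag in donor_mags:
        for rec in config.recipients:
            engrafted = truth.engrafted_labels[mag.id][rec]
            for day in config.timepoints:
                present = engrafted and day > 0
                profile = simulate_coverage(
                    mag,
                    present,
                    config.coverage_depth,
                    seed=int(seed_rng.integers(0, 2**31 - 1)),
                    sample_id=f"{rec}_d{day}",
                )
                rows.append(
                    {
                        "donor_mag": mag.id,
                        "recipient": rec,
                        "day": day,
                        "detection": detection(profile),
                    }
                )
    detections = pd.DataFrame(rows)
    mag_subjects = {m.id: "DONOR" for m in donor_mags}
    for rec, mags in recipient_mags.items():
        for m in mags:
            mag_subjects[m.id] = rec
    return CohortData(
        config=config,
        donor_mags=donor_mags,
        recipient_mags=recipient_mags,
        detections=detections,
        mag_subjects=mag_subjects,
        truth=truth,
    )
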