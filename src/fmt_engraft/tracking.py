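"""Donor-strain tracking: coverage detection, engraftment calls, SNV distance.

"Detection" is the fraction of a genome's nucleotides covered by at least
one mapped read — a breadth-of-coverage presence proxy that, unlike mean
depth, is insensitive to a few high-coverage repeats.  Engraftment of a
donor strain in a recipient is called from three lines of evidence: marker-
protein identity (same species-level cluster), ANI at strain resolution, and
detection across the pre/post-transplant time course.  Major-allele distance
compares SNV profiles of two samples at shared well-covered positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AniResult, is_same_strain

__all__ = [
    "CoverageProfile",
    "SnvProfile",
    "EngraftmentCall",
    "IncomparableProfilesError",
    "detection",
    "call_engraftment",
    "major_allele_distance",
    "donor_similarity_trend",
]

ALLELES = ("A", "C", "G", "T")

STATUSES = (
    "engrafted",
    "excluded_low_ani",
    "excluded_pre_fmt_presence",
    "no_marker_match",
    "no_coverage_support",
)


class IncomparableProfilesError(ValueError):
    """Raised when two profiles share no qualifying positions/markers."""


@dataclass
class CoverageProfile:
    """Read coverage of one MAG in one sample.

    Each contig carries either an explicit per-position depth array or a
    ``(covered_bases, total_bases)`` summary; both support the detection
    metric.
    """

    mag_id: str
    sample_id: str
    depths: dict[str, np.ndarray] = field(default_factory=dict)
    summaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def contig_summary(self) -> dict[str, tuple[int, int]]:
        out = dict(self.summaries)
        for contig, depth in self.depths.items():
            depth = np.asarray(depth)
            out[contig] = (int((depth >= 1).sum()), int(depth.size))
        return out


@dataclass
class SnvProfile:
    """Per-position allele counts of one sample against one reference.

    positions: list of (contig, 1-based position); counts: (n, 4) array in
    A, C, G, T order.
    """

    ref_id: str
    positions: list[tuple[str, int]]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.positions), 4):
            raise ValueError("counts must be (n_positions, 4)")
        if (self.counts < 0).any():
            raise ValueError("allele counts must be non-negative")


@dataclass
class EngraftmentCall:
    """Decision for one (donor MAG, recipient) pair with its evidence."""

    donor_mag: str
    recipient: str
    status: str
    marker_identity: float | None = None
    matched_mag: str | None = None
    ani: float | None = None
    detection_pre_max: float | None = None
    detection_post_max: float | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def detection(
    profile: CoverageProfile, mag_lengths: dict[str, int] | None = None
) -> float:
    """Fraction of nucleotides covered at >= 1x, aggregated over contigs
    weighted by contig length.

    ``mag_lengths`` (contig -> length) cross-checks the profile against the
    MAG record when supplied.
    """
    summary = profile.contig_summary()
    if not summary:
        raise ValueError(f"empty coverage profile for {profile.mag_id}")
    if mag_lengths is not None:
        for contig, (_, total) in summary.items():
            if contig not in mag_lengths:
                raise ValueError(f"unknown contig {contig!r}")
            if total != mag_lengths[contig]:
                raise ValueError(
                    f"contig {contig!r}: profile length {total} != "
                    f"MAG length {mag_lengths[contig]}"
                )
    covered = sum(c for c, _ in summary.values())
    total = sum(t for _, t in summary.values())
    if total <= 0:
        raise ValueError("total_bases must be positive")
    return covered / total


def call_engraftment(
    clusters: list[set[str]],
    ani_results: dict[frozenset, AniResult],
    detections: pd.DataFrame,
    mag_subjects: dict[str, str],
    pre_days: list[int],
    post_days: list[int],
    presence_threshold: float = 0.25,
    ani_threshold: float = 99.90,
    exclude_on_pre_fmt: bool = True,
) -> list[EngraftmentCall]:
    """Call engraftment for every (donor MAG, recipient) pair.

    Decision chain, first match wins:

    1. ``no_marker_match`` — no recipient MAG co-clusters with the donor MAG
       at 100% aggregate marker-protein identity;
    2. ``excluded_low_ani`` — the best co-clustered recipient MAG fails the
       strain-level ANI threshold;
    3. ``excluded_pre_fmt_presence`` — the donor MAG is already detected in
       the recipient before the transplant, so its donor origin is uncertain
       (set ``exclude_on_pre_fmt=False`` to test presence on post days
       instead, flipping the convention);
    4. ``engrafted`` — detection reaches ``presence_threshold`` in at least
       one post-transplant sample;
    5. ``no_coverage_support`` otherwise.

    ``clusters`` come from marker-identity clustering at threshold 1.0;
    ``detections`` is a tidy frame (donor_mag, recipient, day, detection);
    ``mag_subjects`` maps MAG id -> subject (donors map to the donor
    subject).  Every donor MAG must have a detection value for every
    declared day of every recipient.
    """
    if not pre_days:
        raise ValueError("pre_days must be nonempty")
    donor_mags = sorted(set(detections["donor_mag"]))
    recipients = sorted(set(detections["recipient"]))
    det = {
        (r.donor_mag, r.recipient, int(r.day)): float(r.detection)
        for r in detections.itertuples()
    }
    for mag in donor_mags:
        for rec in recipients:
            for day in list(pre_days) + list(post_days):
                if (mag, rec, day) not in det:
                    raise ValueError(
                        f"missing detection for {mag} in {rec} day {day}"
                    )

    cluster_of: dict[str, set[str]] = {}
    for cl in clusters:
        for m in cl:
            cluster_of[m] = cl

    calls = []
    for mag in donor_mags:
        for rec in recipients:
            pre_max = max(det[(mag, rec, d)] for d in pre_days)
            post_max = max(det[(mag, rec, d)] for d in post_days)
            mates = sorted(
                m
                for m in cluster_of.get(mag, set())
                if m != mag and mag_subjects.get(m) == rec
            )
            if not mates:
                calls.append(
                    EngraftmentCall(
                        mag, rec, "no_marker_match",
                        detection_pre_max=pre_max,
                        detection_post_max=post_max,
                        reason="no recipient MAG at 100% marker identity",
                    )
                )
                continue
            # best-matching recipient MAG = highest ANI among cluster mates
            best_mate, best_ani = None, None
            for m in mates:
                res = ani_results.get(frozenset((mag, m)))
                if res is None:
                    continue
                val = res.ani if res.has_signal else -1.0
                if best_ani is None or val > best_ani:
                    best_mate, best_ani = m, val
            res = (
                ani_results.get(frozenset((mag, best_mate)))
                if best_mate is not None
                else None
            )
            common = dict(
                marker_identity=1.0,
                matched_mag=best_mate,
                ani=(res.ani if res is not None and res.has_signal else None),
                detection_pre_max=pre_max,
                detection_post_max=post_max,
            )
            if res is None or not is_same_strain(res, ani_threshold):
                calls.append(
                    EngraftmentCall(
                        mag, rec, "excluded_low_ani",
                        reason=(
                            "no ANI signal" if res is None or not res.has_signal
                            else f"ANI {res.ani:.3f} < {ani_threshold}"
                        ),
                        **common,
                    )
                )
                continue
            presence_max = pre_max if exclude_on_pre_fmt else post_max
            if presence_max >= presence_threshold:
                calls.append(
                    EngraftmentCall(
                        mag, rec, "excluded_pre_fmt_presence",
                        reason="detected in recipient before transplant",
                        **common,
                    )
                )
                continue
            if post_max >= presence_threshold:
                calls.append(EngraftmentCall(mag, rec, "engrafted", **common))
            else:
                calls.append(
                    EngraftmentCall(
                        mag, rec, "no_coverage_support",
                        reason="never detected after transplant",
                        **common,
                    )
                )
    return calls


def calls_to_frame(calls: list[EngraftmentCall]) -> pd.DataFrame:
    rows = [
        {
            "donor_mag": c.donor_mag,
            "recipient": c.recipient,
            "status": c.status,
            "marker_identity": c.marker_identity,
            "matched_mag": c.matched_mag,
            "ani": c.ani,
            "detection_pre_max": c.detection_pre_max,
            "detection_post_max": c.detection_post_max,
            "reason": c.reason,
        }
        for c in calls
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["donor_mag", "recipient"], kind="stable")
        .reset_index(drop=True)
    )


def major_allele_distance(
    a: SnvProfile, b: SnvProfile, min_depth: int = 5
) -> float:
    """Fraction of shared well-covered positions where the most frequent
    allele differs.

    Positions with depth below ``min_depth`` in either sample are excluded
    from numerator and denominator; ties on allele counts resolve to the
    first allele in A < C < G < T order.
    """
    if a.ref_id != b.ref_id:
        raise ValueError("profiles are against different references")
    pos_a = {p: i for i, p in enumerate(a.positions)}
    shared = [(p, pos_a[p], j) for j, p in enumerate(b.positions) if p in pos_a]
    if not shared:
        raise IncomparableProfilesError("no shared positions")
    ia = np.array([i for _, i, _ in shared])
    ib = np.array([j for _, _, j in shared])
    depth_ok = (a.counts[ia].sum(axis=1) >= min_depth) & (
        b.counts[ib].sum(axis=1) >= min_depth
    )
    if not depth_ok.any():
        raise IncomparableProfilesError(
            f"no shared positions with depth >= {min_depth} in both samples"
        )
    maj_a = a.counts[ia[depth_ok]].argmax(axis=1)
    maj_b = b.counts[ib[depth_ok]].argmax(axis=1)
    return float((maj_a != maj_b).mean())


def donor_similarity_trend(
    profiles: dict[str, SnvProfile],
    donor_sample: str,
    sample_meta: pd.DataFrame,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Major-allele distance of every sample to a donor reference sample.

    ``sample_meta`` is indexed by sample id with columns subject and day.
    Returns (sample_id, subject, day, distance) ordered by (subject, day);
    samples incomparable with the donor are omitted.
    """
    if donor_sample not in profiles:
        raise ValueError(f"unknown donor sample {donor_sample!r}")
    ref = profiles[donor_sample]
    rows = []
    for sample, prof in profiles.items():
        try:
            dist = major_allele_distance(prof, ref, min_depth)
        except IncomparableProfilesError:
            continue
        meta = sample_meta.loc[sample]
        rows.append(
            {
                "sample_id": sample,
                "subject": meta["subject"],
                "day": int(meta["day"]),
                "distance": dist,
            }
        )
    out = pd.DataFrame(rows).sort_values(["subject", "day"], kind="stable")
    return out.reset_index(drop=True)
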