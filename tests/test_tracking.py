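"""Detection metric, engraftment decision chain and SNV distances."""

import numpy as np
import pandas as pd
import pytest

from fmt_engraft.genome import AniResult
from fmt_engraft.tracking import (
    CoverageProfile,
    EngraftmentCall,
    IncomparableProfilesError,
    SnvProfile,
    call_engraftment,
    calls_to_frame,
    detection,
    donor_similarity_trend,
    major_allele_distance,
)


def profile(depths=None, summaries=None):
    return CoverageProfile(
        mag_id="m", sample_id="s", depths=depths or {},
        summaries=summaries or {},
    )


class TestDetection:
    def test_all_zero_depth(self):
        assert detection(profile({"c1": np.zeros(100)})) == 0.0

    def test_everything_covered(self):
        assert detection(profile({"c1": np.ones(100)})) == 1.0

    def test_two_contigs_weighted_by_length(self):
        p = profile({"c1": np.ones(1000), "c2": np.zeros(1000)})
        assert detection(p) == 0.5

    def test_summary_and_depth_forms_agree(self):
        d = np.array([0, 1, 2, 0, 3])
        assert detection(profile({"c": d})) == detection(
            profile(summaries={"c": (3, 5)})
        )

    def test_length_mismatch_with_mag_rejected(self):
        p = profile({"c1": np.ones(100)})
        with pytest.raises(ValueError, match="c1"):
            detection(p, mag_lengths={"c1": 200})

    def test_monotone_in_planted_depth(self):
        rng_values = []
        for depth in (0.0, 0.1, 0.5, 1.0, 5.0):
            rng = np.random.default_rng(42)
            d = rng.poisson(depth, 50_000)
            rng_values.append(detection(profile({"c": d})))
        assert rng_values == sorted(rng_values)


def synthetic_inputs(
    *,
    marker_match=True,
    ani_value=99.95,
    pre_detection=0.0,
    post_detection=0.9,
):
    clusters = [{"D1", "V1_M1"}] if marker_match else [{"D1"}, {"V1_M1"}]
    ani_results = {
        frozenset(("D1", "V1_M1")): AniResult(
            "D1", "V1_M1", ani_value, 10, 1.0, ani_value is not None
        )
    }
    rows = [
        {"donor_mag": "D1", "recipient": "V1", "day": -7,
         "detection": pre_detection},
        {"donor_mag": "D1", "recipient": "V1", "day": 30,
         "detection": post_detection},
    ]
    detections = pd.DataFrame(rows)
    subjects = {"D1": "DONOR", "V1_M1": "V1"}
    return clusters, ani_results, detections, subjects


class TestCallEngraftment:
    def call_one(self, **kwargs):
        clusters, ani_results, detections, subjects = synthetic_inputs(
            **kwargs
        )
        calls = call_engraftment(
            clusters, ani_results, detections, subjects, [-7], [30]
        )
        assert len(calls) == 1
        return calls[0]

    def test_clean_case_is_engrafted(self):
        call = self.call_one()
        assert call.status == "engrafted"
        assert call.ani == 99.95
        assert call.matched_mag == "V1_M1"

    def test_no_marker_match(self):
        assert self.call_one(marker_match=False).status == "no_marker_match"

    def test_low_ani_excluded(self):
        call = self.call_one(ani_value=99.5)
        assert call.status == "excluded_low_ani"
        assert "99.5" in call.reason

    def test_boundary_ani_is_same_strain(self):
        assert self.call_one(ani_value=99.90).status == "engrafted"

    def test_pre_fmt_presence_excluded(self):
        call = self.call_one(pre_detection=0.8)
        assert call.status == "excluded_pre_fmt_presence"

    def test_no_post_coverage(self):
        call = self.call_one(post_detection=0.0)
        assert call.status == "no_coverage_support"

    def test_presence_convention_can_flip(self):
        # flipping the exclusion convention tests presence on post days,
        # which in the clean case excludes the otherwise-engrafted strain
        clusters, ani_results, detections, subjects = synthetic_inputs()
        calls = call_engraftment(
            clusters, ani_results, detections, subjects, [-7], [30],
            exclude_on_pre_fmt=False,
        )
        assert calls[0].status == "excluded_pre_fmt_presence"

    def test_missing_detection_day_rejected(self):
        clusters, ani_results, detections, subjects = synthetic_inputs()
        with pytest.raises(ValueError, match="day 60"):
            call_engraftment(
                clusters, ani_results, detections, subjects, [-7], [30, 60]
            )

    def test_empty_pre_days_rejected(self):
        clusters, ani_results, detections, subjects = synthetic_inputs()
        with pytest.raises(ValueError, match="pre_days"):
            call_engraftment(
                clusters, ani_results, detections, subjects, [], [30]
            )

    def test_status_counts_invariant_to_input_order(self):
        clusters, ani_results, detections, subjects = synthetic_inputs()
        shuffled = detections.iloc[::-1].reset_index(drop=True)
        c1 = call_engraftment(
            clusters, ani_results, detections, subjects, [-7], [30]
        )
        c2 = call_engraftment(
            list(reversed(clusters)), ani_results, shuffled, subjects,
            [-7], [30],
        )
        f1, f2 = calls_to_frame(c1), calls_to_frame(c2)
        assert f1["status"].value_counts().to_dict() == (
            f2["status"].value_counts().to_dict()
        )

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            EngraftmentCall("d", "r", "maybe")


def snv(positions, majors, depth=10):
    counts = np.zeros((len(positions), 4))
    counts[np.arange(len(positions)), majors] = depth
    return SnvProfile("ref", positions, counts)


class TestMajorAlleleDistance:
    def test_identical_profiles(self):
        pos = [("c", i + 1) for i in range(10)]
        a = snv(pos, np.zeros(10, dtype=int))
        assert major_allele_distance(a, a) == 0.0

    def test_counts_disagreeing_positions(self):
        pos = [("c", i + 1) for i in range(10)]
        a = snv(pos, np.zeros(10, dtype=int))
        b = snv(pos, np.array([1] * 3 + [0] * 7))
        assert major_allele_distance(a, b) == pytest.approx(0.3)

    def test_symmetry_and_bounds(self, rng):
        pos = [("c", i + 1) for i in range(50)]
        a = snv(pos, rng.integers(0, 4, 50))
        b = snv(pos, rng.integers(0, 4, 50))
        d1 = major_allele_distance(a, b)
        assert d1 == major_allele_distance(b, a)
        assert 0.0 <= d1 <= 1.0

    def test_low_depth_positions_excluded(self):
        pos = [("c", 1), ("c", 2)]
        a = snv(pos, np.array([0, 0]), depth=10)
        b_counts = np.array([[0, 10, 0, 0], [2, 0, 0, 0]], dtype=float)
        b = SnvProfile("ref", pos, b_counts)
        # position 2 fails min_depth=5 in b -> only position 1 counted
        assert major_allele_distance(a, b, min_depth=5) == 1.0

    def test_tie_breaks_by_allele_order(self):
        pos = [("c", 1)]
        tied = SnvProfile("ref", pos, np.array([[5.0, 5.0, 0.0, 0.0]]))
        a_major = SnvProfile("ref", pos, np.array([[9.0, 1.0, 0.0, 0.0]]))
        # tie A/C resolves to A -> no disagreement
        assert major_allele_distance(tied, a_major) == 0.0

    def test_no_qualifying_positions_is_incomparable(self):
        pos = [("c", 1)]
        a = snv(pos, np.array([0]), depth=2)
        b = snv(pos, np.array([0]), depth=2)
        with pytest.raises(IncomparableProfilesError):
            major_allele_distance(a, b, min_depth=5)

    def test_disjoint_positions_incomparable(self):
        a = snv([("c", 1)], np.array([0]))
        b = snv([("c", 2)], np.array([0]))
        with pytest.raises(IncomparableProfilesError):
            major_allele_distance(a, b)


class TestDonorSimilarityTrend:
    def make_profiles(self):
        pos = [("c", i + 1) for i in range(20)]
        donor = snv(pos, np.zeros(20, dtype=int))
        near = snv(pos, np.array([1] + [0] * 19))
        far = snv(pos, np.array([1] * 10 + [0] * 10))
        profiles = {"DONOR_d0": donor, "V1_d-7": far, "V1_d30": near}
        meta = pd.DataFrame(
            {"subject": ["DONOR", "V1", "V1"], "day": [0, -7, 30]},
            index=["DONOR_d0", "V1_d-7", "V1_d30"],
        )
        return profiles, meta

    def test_donor_to_itself_zero_and_ordering(self):
        profiles, meta = self.make_profiles()
        trend = donor_similarity_trend(profiles, "DONOR_d0", meta)
        assert trend.query("sample_id == 'DONOR_d0'")["distance"].iloc[0] == 0
        v1 = trend[trend.subject == "V1"]
        assert list(v1.day) == [-7, 30]
        assert v1.distance.iloc[0] > v1.distance.iloc[1]

    def test_rows_independent_of_other_samples(self):
        profiles, meta = self.make_profiles()
        full = donor_similarity_trend(profiles, "DONOR_d0", meta)
        del profiles["V1_d-7"]
        partial = donor_similarity_trend(
            profiles, "DONOR_d0", meta.drop("V1_d-7")
        )
        merged = full.merge(partial, on="sample_id", suffixes=("", "_p"))
        assert (merged["distance"] == merged["distance_p"]).all()

    def test_unknown_donor_sample_rejected(self):
        profiles, meta = self.make_profiles()
        with pytest.raises(ValueError):
            donor_similarity_trend(profiles, "nope", meta)
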