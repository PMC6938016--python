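"""Synthetic-cohort generator: planted structure and determinism."""

import numpy as np
import pytest
from scipy import stats

from fmt_engraft.coda import aitchison_distance, replace_zeros
from fmt_engraft.genome import marker_identity
from fmt_engraft.synthetic import (
    SimulationConfig,
    simulate_cohort,
    simulate_coverage,
    simulate_genomes,
    simulate_snv_profiles,
    simulate_snv_timeseries,
    simulate_timeseries,
)
from fmt_engraft.tracking import detection, major_allele_distance

SMALL_GENOMES = dict(
    genome_length=16_000,
    marker_count=10,
    marker_length=40,
    shared_strain_count=2,
    distinct_strain_count=2,
    n_recipients=2,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(convergence_rate=-0.1),
            dict(shared_ani=99.90),
            dict(shared_ani=100.5),
            dict(distinct_ani=99.8),
            dict(n_taxa=0),
            dict(dispersion=-5),
            dict(timepoints=(5, 30)),
            dict(timepoints=(-7, -1)),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)

    def test_marker_region_must_fit_genome(self):
        cfg = SimulationConfig(
            genome_length=5_000, marker_count=43, marker_length=100,
            shared_strain_count=1, distinct_strain_count=1,
        )
        with pytest.raises(ValueError, match="marker regions"):
            simulate_genomes(cfg)


class TestTimeseries:
    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(seed=5)
        t1, _ = simulate_timeseries(cfg)
        t2, _ = simulate_timeseries(cfg)
        assert t1.counts.equals(t2.counts)
        assert t1.metadata.equals(t2.metadata)

    def test_counts_sum_to_depth(self):
        cfg = SimulationConfig(seed=3, dispersion=5000)
        table, _ = simulate_timeseries(cfg)
        assert (table.counts.sum(axis=0) == 5000).all()

    def test_rate_zero_means_no_convergence(self):
        # lambda = 0: the post-FMT expectation stays at baseline, so the
        # day-300 distance to the donor matches the baseline distance in
        # distribution; check means over replicates
        pre, post = [], []
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, convergence_rate=0.0, n_taxa=30,
                timepoints=(-7, 300), n_recipients=1,
            )
            table, _ = simulate_timeseries(cfg)
            comps = replace_zeros(table)
            donor = comps["DONOR_d0"]
            pre.append(aitchison_distance(comps["V1_d-7"], donor))
            post.append(aitchison_distance(comps["V1_d300"], donor))
        assert abs(np.mean(pre) - np.mean(post)) < 0.1 * np.mean(pre)

    def test_infinite_rate_collapses_onto_donor(self):
        cfg = SimulationConfig(
            seed=11, convergence_rate=1e6, clr_noise_sd=0.0,
            dispersion=10**6, n_taxa=20, n_recipients=1,
            timepoints=(-7, 10),
        )
        table, truth = simulate_timeseries(cfg)
        comps = replace_zeros(table)
        d_post = aitchison_distance(comps["V1_d10"], comps["DONOR_d0"])
        d_pre = aitchison_distance(comps["V1_d-7"], comps["DONOR_d0"])
        assert d_post < 0.05  # multinomial noise only
        assert d_pre > 1.0

    def test_distance_ordering_over_replicates(self):
        # mean distance to donor: day 60 < day 5 < day -1
        d = {day: [] for day in (-1, 5, 60)}
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, convergence_rate=0.05, dispersion=10**5,
                n_taxa=50, n_recipients=1, timepoints=(-1, 5, 60),
            )
            table, _ = simulate_timeseries(cfg)
            comps = replace_zeros(table)
            donor = comps["DONOR_d0"]
            for day in d:
                d[day].append(
                    aitchison_distance(comps[f"V1_d{day}"], donor)
                )
        assert np.mean(d[60]) < np.mean(d[5]) < np.mean(d[-1])


class TestGenomes:
    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(seed=9, **SMALL_GENOMES)
        d1, r1, _ = simulate_genomes(cfg)
        d2, r2, _ = simulate_genomes(cfg)
        assert [m.contigs for m in d1] == [m.contigs for m in d2]
        assert r1["V1"][0].markers == r2["V1"][0].markers

    def test_shared_ani_100_gives_identical_genomes(self):
        cfg = SimulationConfig(seed=2, shared_ani=100.0, **SMALL_GENOMES)
        donors, recips, _ = simulate_genomes(cfg)
        shared_donor = donors[0]
        shared_rec = recips["V1"][0]
        assert "".join(
            shared_donor.contigs[c] for c in sorted(shared_donor.contigs)
        ) == "".join(shared_rec.contigs[c] for c in sorted(shared_rec.contigs))

    def test_planted_substitution_fraction(self):
        cfg = SimulationConfig(seed=4, shared_ani=99.95, **SMALL_GENOMES)
        donors, recips, truth = simulate_genomes(cfg)
        rate = 0.0005
        n = cfg.genome_length
        for donor, rec_mag in zip(donors[:2], recips["V1"][:2]):
            a = "".join(donor.contigs[c] for c in sorted(donor.contigs))
            b = "".join(rec_mag.contigs[c] for c in sorted(rec_mag.contigs))
            mism = sum(x != y for x, y in zip(a, b))
            # 99.7% binomial interval around the planted rate
            lo, hi = stats.binom.interval(0.997, n, rate)
            assert lo <= mism <= hi
            assert truth.true_ani[frozenset((donor.id, rec_mag.id))] == (
                pytest.approx(100 * (1 - mism / n))
            )

    def test_shared_strains_keep_marker_proteins_identical(self):
        cfg = SimulationConfig(seed=6, **SMALL_GENOMES)
        donors, recips, truth = simulate_genomes(cfg)
        for rec in cfg.recipients:
            for donor, mag in zip(donors, recips[rec]):
                ident = marker_identity(donor, mag)
                if truth.engrafted_labels[donor.id][rec]:
                    assert ident.aggregate == 1.0
                else:
                    assert ident.aggregate < 1.0

    def test_truth_covers_every_strain_recipient_pair(self):
        cfg = SimulationConfig(seed=8, **SMALL_GENOMES)
        donors, recips, truth = simulate_genomes(cfg)
        assert set(truth.engrafted_labels) == {m.id for m in donors}
        for by_rec in truth.engrafted_labels.values():
            assert set(by_rec) == set(cfg.recipients)


class TestCoverage:
    def test_absent_gives_zero_detection(self):
        cfg = SimulationConfig(seed=1, **SMALL_GENOMES)
        donors, _, _ = simulate_genomes(cfg)
        profile = simulate_coverage(donors[0], present=False, depth=10,
                                    seed=0)
        assert detection(profile) == 0.0

    @pytest.mark.parametrize("depth", [0.25, 10.0])
    def test_detection_matches_poisson_zero_class(self, depth):
        cfg = SimulationConfig(seed=1, **SMALL_GENOMES)
        donors, _, _ = simulate_genomes(cfg)
        profile = simulate_coverage(donors[0], present=True, depth=depth,
                                    seed=123)
        expected = 1 - np.exp(-depth)
        n = donors[0].total_length
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(detection(profile) - expected) < 3 * sigma + 1e-9

    def test_negative_depth_rejected(self):
        cfg = SimulationConfig(seed=1, **SMALL_GENOMES)
        donors, _, _ = simulate_genomes(cfg)
        with pytest.raises(ValueError):
            simulate_coverage(donors[0], present=True, depth=-1, seed=0)


class TestSnvProfiles:
    @pytest.mark.parametrize("q,expected", [(0.0, 0.0), (1.0, 1.0),
                                            (0.3, 0.3)])
    def test_planted_disagreement_recovered_exactly(self, q, expected):
        a, b = simulate_snv_profiles(1000, q, depth=20, seed=5)
        assert major_allele_distance(a, b, min_depth=5) == expected

    def test_timeseries_distances_decay(self):
        cfg = SimulationConfig(seed=3, convergence_rate=0.05)
        profiles, meta = simulate_snv_timeseries(cfg, n_positions=500,
                                                 q0=0.5)
        d_pre = major_allele_distance(profiles["V1_d-7"],
                                      profiles["DONOR_d0"])
        d_post = major_allele_distance(profiles["V1_d300"],
                                       profiles["DONOR_d0"])
        assert d_pre == pytest.approx(0.5, abs=0.002)
        assert d_post < 0.01


class TestCohort:
    def test_cohort_detections_cover_all_cells(self):
        cfg = SimulationConfig(seed=2, **SMALL_GENOMES)
        cohort = simulate_cohort(cfg)
        expected = (
            (cfg.shared_strain_count + cfg.distinct_strain_count)
            * cfg.n_recipients
            * len(cfg.timepoints)
        )
        assert len(cohort.detections) == expected
        pre = cohort.detections.query("day < 0")
        assert (pre["detection"] == 0).all()

    def test_engrafted_strains_detected_post_fmt(self):
        cfg = SimulationConfig(seed=2, **SMALL_GENOMES)
        cohort = simulate_cohort(cfg)
        truth = cohort.truth.engrafted_labels
        post = cohort.detections.query("day > 0")
        for row in post.itertuples():
            if truth[row.donor_mag][row.recipient]:
                assert row.detection > 0.99
            else:
                assert row.detection == 0.0
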