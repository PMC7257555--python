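import numpy as np
import pytest

from msical.catalog import ScanParams, scan_reference
from msical.scoring import MSI_H, MSS
from msical.simulate import (
    StutterModel,
    dilute,
    effective_purity,
    make_cohort,
    make_reference,
    sample_profile,
    simulate_sample,
    truth_from_catalog,
    LocusTruth,
    SimTruth,
)
from msical.stats import mann_whitney_u
from msical.training import build_score_matrix, group_mean_scores, EmptyClassError


class TestMakeReference:
    @pytest.mark.parametrize("n_loci", [9, 50])
    def test_scanner_round_trip_recovers_truth(self, n_loci):
        reference, catalog = make_reference(n_loci, 12, seed=5)
        found = scan_reference(reference, ScanParams())
        assert {(l.start, l.end, l.unit) for l in found} == {
            (l.start, l.end, l.unit) for l in catalog
        }
        assert len(catalog) == n_loci

    def test_seed_changes_flanks_not_geometry(self):
        ref_a, cat_a = make_reference(9, 12, seed=1)
        ref_b, cat_b = make_reference(9, 12, seed=2, units=["A"] * 9)
        ref_a2, cat_a2 = make_reference(9, 12, seed=1)
        assert ref_a == ref_a2 and cat_a == cat_a2  # determinism
        assert [(l.start, l.end) for l in cat_a] == [(l.start, l.end) for l in cat_b]

    def test_spacing_must_exceed_read_length(self):
        with pytest.raises(ValueError):
            make_reference(3, 12, spacing=80, read_length=100)

    def test_variable_tract_lengths(self):
        _, catalog = make_reference(6, [10, 14, 18], seed=4)
        assert [l.end - l.start for l in catalog] == [10, 14, 18, 10, 14, 18]


class TestStutterModel:
    def test_deviation_probs_sum_to_one(self):
        model = StutterModel()
        for tract_len in (10, 13, 24):
            _, probs = model.deviation_probs(tract_len)
            assert probs.sum() == pytest.approx(1.0)
            assert (probs >= 0).all()

    def test_longer_tracts_stutter_more(self):
        model = StutterModel()
        assert model.locus_stutter_prob(24) > model.locus_stutter_prob(10)

    def test_empirical_frequencies_within_three_sd(self, rng):
        model = StutterModel()
        devs, probs = model.deviation_probs(14)
        n = 10_000
        draws = rng.choice(devs, size=n, p=probs)
        for d, p in zip(devs, probs):
            if p == 0:
                continue
            observed = int((draws == d).sum())
            sd = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sd + 1

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            StutterModel(stutter_prob=1.5)


class TestSimulateSample:
    def test_deterministic_for_fixed_seed(self, toy_reference):
        reference, catalog = toy_reference
        truth = truth_from_catalog(catalog, 0.4, [catalog[0].key], -3, seed=13)
        a = simulate_sample(truth, reference)
        b = simulate_sample(truth, reference)
        assert a == b

    def test_noise_free_full_purity_shows_pure_shift(self, toy_reference):
        reference, catalog = toy_reference
        truth = truth_from_catalog(
            catalog, 1.0, [l.key for l in catalog], -3, coverage=30, seed=3
        )
        quiet = StutterModel(stutter_prob=0.0, length_slope=0.0)
        reads = simulate_sample(truth, reference, quiet)
        for read in reads:
            assert read.observed_count == 12 - 3

    def test_zero_purity_draws_no_somatic_reads(self, toy_reference):
        reference, catalog = toy_reference
        truth = truth_from_catalog(catalog, 0.0, [catalog[0].key], -3, seed=4)
        reads = simulate_sample(truth, reference)
        assert not any(r.is_somatic for r in reads)

    def test_somatic_read_fraction_tracks_purity(self, toy_reference):
        reference, catalog = toy_reference
        purity = 0.32
        somatic = total = 0
        for rep in range(20):
            truth = truth_from_catalog(
                catalog, purity, [l.key for l in catalog], -3,
                coverage=50, seed=400 + rep,
            )
            reads = simulate_sample(truth, reference)
            somatic += sum(r.is_somatic for r in reads)
            total += len(reads)
        sd = np.sqrt(total * purity * (1 - purity))
        assert abs(somatic - total * purity) <= 3 * sd

    def test_invalid_purity_rejected(self, toy_reference):
        _, catalog = toy_reference
        with pytest.raises(ValueError):
            truth_from_catalog(catalog, 1.2)


class TestDilute:
    def test_effective_purity_arithmetic(self):
        assert effective_purity(0.50, 0.32) == pytest.approx(0.16)
        assert effective_purity(0.33, 0.32) == pytest.approx(0.1056)
        with pytest.raises(ValueError):
            effective_purity(1.5, 0.32)

    def test_fraction_one_is_identity_in_law(self, paired_reads):
        tumor, normal, _ = paired_reads
        mixed, meta = dilute(tumor, normal, 1.0, seed=5, tumor_purity=0.5)
        assert sorted(r.name for r in mixed) == sorted(r.name for r in tumor)
        assert meta["effective_purity"] == pytest.approx(0.5)

    def test_fraction_zero_is_all_normal(self, paired_reads):
        tumor, normal, _ = paired_reads
        mixed, _ = dilute(tumor, normal, 0.0, seed=5)
        names = {r.name for r in mixed}
        assert names <= {r.name for r in normal}

    def test_invalid_fraction_rejected(self, paired_reads):
        tumor, normal, _ = paired_reads
        with pytest.raises(ValueError):
            dilute(tumor, normal, 1.2)

    def test_mixture_fraction_within_binomial_noise(self, paired_reads):
        tumor, normal, _ = paired_reads
        frac, n_draws, tumor_names = 0.5, 0, {r.name for r in tumor}
        n_tumor = 0
        for rep in range(10):
            mixed, _ = dilute(tumor, normal, frac, seed=rep)
            n_tumor += sum(r.name in tumor_names for r in mixed)
            n_draws += len(mixed)
        sd = np.sqrt(n_draws * frac * (1 - frac))
        assert abs(n_tumor - n_draws * frac) <= 3 * sd


class TestDistributionSampling:
    def test_zero_purity_indistinguishable_from_normal(self, toy_reference):
        _, catalog = toy_reference
        model = StutterModel()
        low_p = 0
        for rep in range(20):
            rng = np.random.default_rng(9000 + rep)
            pooled_t, pooled_n = [], []
            for locus in catalog:
                lt = LocusTruth(locus, locus.ref_repeat_count, -3)
                t = sample_profile(rng, lt, 0.0, 100, model)
                n = sample_profile(rng, lt, 0.0, 100, model)
                pooled_t += [k for k, v in t.counts.items() for _ in range(v)]
                pooled_n += [k for k, v in n.counts.items() for _ in range(v)]
            if mann_whitney_u(pooled_t, pooled_n) <= 0.01:
                low_p += 1
        assert low_p <= 2

    def test_read_level_and_distribution_level_agree_in_law(self, toy_reference):
        """Mean counts from read simulation match the direct histogram draw."""
        reference, catalog = toy_reference
        locus = catalog[0]
        model = StutterModel()
        truth = truth_from_catalog([locus], 0.0, (), coverage=400, seed=6)
        reads = simulate_sample(truth, reference)
        read_mean = np.mean([r.observed_count for r in reads])
        rng = np.random.default_rng(6)
        prof = sample_profile(
            rng, LocusTruth(locus, locus.ref_repeat_count, 0), 0.0, 400, model
        )
        dist_mean = np.mean([k for k, v in prof.counts.items() for _ in range(v)])
        assert read_mean == pytest.approx(dist_mean, abs=0.3)


class TestMakeCohort:
    def test_default_composition_and_labels(self):
        cohort = make_cohort(n_loci=40, n_informative=4, seed=2)
        assert len(cohort.samples) == 28
        assert sum(s.label == MSI_H for s in cohort.samples) == 7
        assert sum(s.label == MSS for s in cohort.samples) == 21
        assert len(cohort.informative_keys) == 4
        assert len(cohort.catalog) == 40

    def test_mss_samples_carry_no_shift_signal(self):
        cohort = make_cohort(n_msih=2, n_mss=3, n_loci=20, n_informative=3, seed=8)
        for s in cohort.samples:
            if s.label == MSS:
                assert s.purity == 0.0

    def test_determinism(self):
        a = make_cohort(n_msih=2, n_mss=2, n_loci=12, n_informative=2, seed=31)
        b = make_cohort(n_msih=2, n_mss=2, n_loci=12, n_informative=2, seed=31)
        for sa, sb in zip(a.samples, b.samples):
            assert sa.sample_id == sb.sample_id and sa.purity == sb.purity
            for key in (l.key for l in a.catalog):
                assert sa.tumor_profiles[key].counts == sb.tumor_profiles[key].counts

    def test_sample_seed_varies_draws_not_geometry(self):
        a = make_cohort(n_msih=2, n_mss=2, n_loci=12, n_informative=2, seed=31)
        b = make_cohort(n_msih=2, n_mss=2, n_loci=12, n_informative=2, seed=31,
                        sample_seed=99)
        assert [l.key for l in a.catalog] == [l.key for l in b.catalog]
        assert a.informative_keys == b.informative_keys
        diff = any(
            a.samples[i].tumor_profiles[k].counts
            != b.samples[i].tumor_profiles[k].counts
            for i in range(4)
            for k in (l.key for l in a.catalog)
        )
        assert diff

    def test_empty_msih_class_breaks_group_means(self):
        cohort = make_cohort(n_msih=0, n_mss=4, n_loci=12, n_informative=2, seed=3)
        matrix = build_score_matrix(cohort.profiles, cohort.labels, cohort.catalog)
        with pytest.raises(EmptyClassError):
            group_mean_scores(matrix)

    def test_read_level_mode_round_trips_through_profiler(self):
        cohort = make_cohort(
            n_msih=1, n_mss=1, n_loci=6, n_informative=2, seed=17,
            coverage=40, read_level=True,
        )
        for s in cohort.samples:
            for key, dist in s.tumor_profiles.items():
                assert dist.coverage == 40
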