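import numpy as np
import pandas as pd
import pytest

from msical.catalog import MicrosatelliteLocus
from msical.scoring import MSI_H, MSS
from msical.simulate import make_cohort
from msical.training import (
    CohortScoreMatrix,
    EmptyClassError,
    NotEnoughRankableLociError,
    SampleSetMismatchError,
    build_score_matrix,
    evaluate,
    group_mean_scores,
    select_markers,
    train_model,
)


def loci_at(n, prefix="L"):
    return [
        MicrosatelliteLocus("c", 100 * i, 100 * i + 12, "A", name=f"{prefix}{i}")
        for i in range(n)
    ]


def matrix_from(scores: dict, labels: dict, loci):
    df = pd.DataFrame(scores, index=[l.key for l in loci], dtype=float)
    return CohortScoreMatrix(df, labels, loci)


class TestGroupMeanScores:
    def test_class_means(self):
        loci = loci_at(1)
        m = matrix_from(
            {"h1": [0.8], "h2": [0.6], "s1": [0.1]},
            {"h1": MSI_H, "h2": MSI_H, "s1": MSS},
            loci,
        )
        means = group_mean_scores(m)
        assert means["mean_msih"].iloc[0] == pytest.approx(0.7)
        assert means["mean_mss"].iloc[0] == pytest.approx(0.1)

    def test_locus_missing_in_whole_class_not_rankable(self):
        loci = loci_at(1)
        m = matrix_from(
            {"h1": [0.8], "s1": [np.nan], "s2": [np.nan]},
            {"h1": MSI_H, "s1": MSS, "s2": MSS},
            loci,
        )
        assert not group_mean_scores(m)["rankable"].iloc[0]

    def test_empty_class_raises(self):
        loci = loci_at(1)
        m = matrix_from({"s1": [0.1]}, {"s1": MSS}, loci)
        with pytest.raises(EmptyClassError):
            group_mean_scores(m)

    def test_random_matrix_matches_recomputation(self, rng):
        loci = loci_at(20)
        samples = {f"h{i}": MSI_H for i in range(4)} | {f"s{i}": MSS for i in range(6)}
        values = {s: rng.uniform(0, 2, size=20) for s in samples}
        m = matrix_from(values, samples, loci)
        means = group_mean_scores(m)
        expect_h = np.mean([values[s] for s in samples if samples[s] == MSI_H], axis=0)
        expect_s = np.mean([values[s] for s in samples if samples[s] == MSS], axis=0)
        np.testing.assert_allclose(means["mean_msih"], expect_h)
        np.testing.assert_allclose(means["mean_mss"], expect_s)


class TestSelectMarkers:
    def make_means(self, msih, mss, loci):
        return pd.DataFrame(
            {
                "mean_msih": msih,
                "mean_mss": mss,
                "rankable": [True] * len(msih),
            },
            index=[l.key for l in loci],
        )

    def test_forced_overlap_example(self):
        loci = loci_at(5)  # A..E in coordinate order
        means = self.make_means(
            [0.9, 0.8, 0.7, 0.2, 0.1], [0.05, 0.06, 0.5, 0.04, 0.03], loci
        )
        markers = select_markers(means, loci, k=3)
        assert [l.name for l in markers] == ["L0"]  # top-3 {A,B,C} & bottom-3 {E,D,A}

    def test_all_tied_means_resolve_by_coordinate(self):
        loci = loci_at(6)
        means = self.make_means([0.5] * 6, [0.5] * 6, loci)
        markers = select_markers(means, loci, k=3)
        assert [l.name for l in markers] == ["L0", "L1", "L2"]

    def test_invariant_to_locus_input_order(self, rng):
        loci = loci_at(30)
        means = self.make_means(
            list(rng.uniform(0, 1, 30)), list(rng.uniform(0, 1, 30)), loci
        )
        a = select_markers(means, loci, k=10)
        perm = list(rng.permutation(30))
        b = select_markers(means.iloc[perm], [loci[i] for i in perm], k=10)
        assert a == b

    def test_too_few_rankable_raises(self):
        loci = loci_at(3)
        means = self.make_means([0.1] * 3, [0.1] * 3, loci)
        means.loc[means.index[0], "rankable"] = False
        with pytest.raises(NotEnoughRankableLociError):
            select_markers(means, loci, k=3)

    def test_recovers_implanted_loci_on_synthetic_cohort(self):
        cohort = make_cohort(seed=42)
        matrix = build_score_matrix(cohort.profiles, cohort.labels, cohort.catalog)
        means = group_mean_scores(matrix)
        markers = select_markers(means, cohort.catalog, k=50)
        assert set(cohort.informative_keys) <= {l.key for l in markers}


class TestEvaluate:
    def test_perfect_agreement(self):
        labels = {f"s{i}": (MSI_H if i < 14 else MSS) for i in range(64)}
        metrics = evaluate(labels, labels)
        assert metrics == {"sensitivity": 1.0, "specificity": 1.0, "opa": 1.0}

    def test_all_mss_predictions(self):
        labels = {f"s{i}": (MSI_H if i < 7 else MSS) for i in range(28)}
        predictions = {s: MSS for s in labels}
        metrics = evaluate(predictions, labels)
        assert metrics["sensitivity"] == 0.0
        assert metrics["specificity"] == 1.0
        assert metrics["opa"] == pytest.approx(21 / 28)

    def test_matches_confusion_matrix_oracle(self, rng):
        labels = {f"s{i}": (MSI_H if rng.random() < 0.3 else MSS) for i in range(50)}
        predictions = {
            s: (labels[s] if rng.random() < 0.8 else
                (MSS if labels[s] == MSI_H else MSI_H))
            for s in labels
        }
        tp = sum(predictions[s] == MSI_H and labels[s] == MSI_H for s in labels)
        fn = sum(predictions[s] == MSS and labels[s] == MSI_H for s in labels)
        tn = sum(predictions[s] == MSS and labels[s] == MSS for s in labels)
        fp = sum(predictions[s] == MSI_H and labels[s] == MSS for s in labels)
        metrics = evaluate(predictions, labels)
        assert metrics["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert metrics["specificity"] == pytest.approx(tn / (tn + fp))
        assert metrics["opa"] == pytest.approx((tp + tn) / 50)

    def test_sample_id_mismatch_raises(self):
        with pytest.raises(SampleSetMismatchError):
            evaluate({"a": MSS}, {"b": MSS})


def test_train_model_records_provenance():
    cohort = make_cohort(n_msih=3, n_mss=6, n_loci=80, n_informative=5, seed=9)
    matrix = build_score_matrix(cohort.profiles, cohort.labels, cohort.catalog)
    model = train_model(matrix, k=20, seed=9)
    assert model.marker_loci
    assert model.provenance["n_msih"] == 3
    assert model.provenance["n_mss"] == 6
    assert model.provenance["seed"] == 9
    assert "cohort_fingerprint" in model.provenance
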