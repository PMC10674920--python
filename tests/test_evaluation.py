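"""Metrics and the repeated-measurement planner against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import finspec as fs
from finspec.dispute import ConfusionMatrix, confusion_from_predictions
from finspec.evaluation import (
    cohens_kappa,
    cross_validate,
    mean_species_accuracy,
    min_measurements_for_target,
    repeated_measurement_probability,
)


def majority_vote_enumeration(p: float, n: int) -> float:
    """Brute-force oracle: sum over all 2^n outcome sequences."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) > n / 2:
            k = sum(outcome)
            total += p**k * (1 - p) ** (n - k)
    return total


class TestRepeatedMeasurement:
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.68, 0.78, 0.8, 0.96])
    @pytest.mark.parametrize("n", [1, 3, 5, 7, 9, 11])
    def test_matches_exhaustive_enumeration(self, p, n):
        assert abs(repeated_measurement_probability(p, n)
                   - majority_vote_enumeration(p, n)) < 1e-12

    def test_limits(self):
        assert repeated_measurement_probability(1.0, 5) == 1.0
        assert repeated_measurement_probability(0.3, 1) == pytest.approx(0.3)
        for n in (1, 3, 7, 11):
            assert repeated_measurement_probability(0.5, n) == pytest.approx(0.5)

    def test_strictly_increasing_in_n_above_half(self):
        vals = [repeated_measurement_probability(0.78, n) for n in range(1, 22, 2)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_even_n_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            repeated_measurement_probability(0.8, 4)


class TestPlanner:
    def test_threshold_accuracy_needs_seven_measurements(self):
        # 0.78 single-point accuracy: five votes are not enough, seven are
        assert repeated_measurement_probability(0.78, 5) == pytest.approx(0.9256, abs=1e-4)
        assert repeated_measurement_probability(0.78, 7) == pytest.approx(0.9539, abs=1e-4)
        assert min_measurements_for_target(0.78, 0.95) == 7

    def test_already_above_target(self):
        assert min_measurements_for_target(0.96, 0.95) == 1

    def test_monotone_in_p(self):
        grid = np.linspace(0.62, 0.99, 20)
        ns = [min_measurements_for_target(p, 0.95) for p in grid]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_hopeless_p_rejected(self):
        with pytest.raises(ValueError):
            min_measurements_for_target(0.4, 0.95)


class TestMeanSpeciesAccuracy:
    def test_identity_is_one(self):
        cm = ConfusionMatrix(["a", "b"], np.eye(2, dtype=int) * 5)
        assert mean_species_accuracy(cm) == 1.0

    def test_unweighted_mean(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[10, 0], [5, 5]]))
        assert mean_species_accuracy(cm) == pytest.approx(0.75)

    def test_matches_brute_force_tally(self, rng):
        classes = list("abcdefgh")
        truth = rng.choice(classes, size=400)
        pred = rng.choice(classes, size=400)
        cm = confusion_from_predictions(truth, pred, classes)
        recalls = []
        for c in classes:
            rows = truth == c
            if rows.any():
                recalls.append((pred[rows] == c).mean())
        assert mean_species_accuracy(cm) == pytest.approx(np.mean(recalls))

    def test_empty_class_excluded_with_warning(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[8, 2], [0, 0]]))
        with pytest.warns(UserWarning, match="no test rows"):
            assert mean_species_accuracy(cm) == pytest.approx(0.8)


class TestCohensKappa:
    def test_perfect_agreement(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[7, 0], [0, 3]]))
        assert cohens_kappa(cm) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[40, 10], [5, 45]]))
        # p_o = 85/100, p_e = 0.5*0.45 + 0.5*0.55 = 0.5 -> kappa = 0.7
        assert cohens_kappa(cm) == pytest.approx(0.7)

    def test_independent_marginals_near_zero(self):
        # counts proportional to the product of marginals -> chance level
        rows = np.array([0.6, 0.4])
        cols = np.array([0.3, 0.7])
        counts = np.round(1000 * np.outer(rows, cols)).astype(int)
        cm = ConfusionMatrix(["a", "b"], counts)
        assert abs(cohens_kappa(cm)) < 1e-9

    def test_agrees_with_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import cohen_kappa_score

        classes = list("pqrs")
        truth = rng.choice(classes, size=300)
        pred = rng.choice(classes, size=300)
        cm = confusion_from_predictions(truth, pred, classes)
        assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(truth, pred))

    @settings(deadline=None, derandomize=True)
    @given(st.permutations(range(4)),
           st.lists(st.integers(0, 20), min_size=16, max_size=16))
    def test_invariant_under_class_relabeling(self, perm, flat):
        counts = np.array(flat).reshape(4, 4)
        if counts.sum() == 0 or counts.trace() == counts.sum():
            return
        classes = list("abcd")
        cm = ConfusionMatrix(classes, counts)
        permuted = ConfusionMatrix([classes[i] for i in perm],
                                   counts[np.ix_(perm, perm)])
        k1, k2 = cohens_kappa(cm), cohens_kappa(permuted)
        if math.isnan(k1):
            assert math.isnan(k2)
        else:
            assert k1 == pytest.approx(k2)


@pytest.fixture(scope="module")
def noiseless_report(fluor_mode):
    cfg = fs.GeneratorConfig(
        n_species=4, cluster_sizes=(2, 2), fillets_per_species=4, voxels_per_fillet=6,
        within_cluster_sep=1.0, between_cluster_sep=1.4,
        fillet_effect_sd=0.0, noise_sd=0.0, seed=3,
    )
    ds = fs.generate_point_spectra(fs.generate_species_library(cfg, {"Fluor": fluor_mode}), cfg)
    return cross_validate(
        ds, k=4, seed=0,
        global_spec=fs.GlobalModelSpec(epochs=30, patience=8, seed=0),
        dispute_spec=fs.DisputeModelSpec(epochs=10, patience=5, seed=0),
    )


class TestCrossValidate:
    def test_noiseless_separable_all_recalls_one_no_disputes(self, noiseless_report):
        rep = noiseless_report
        assert (rep.confusions[("Fluor", "global")].recalls == 1.0).all()
        assert len(rep.dispute_records) == 0
        assert rep.mode_table().iloc[0]["global_pct"] == 100.0

    def test_report_recalls_match_prediction_dump(self, noiseless_report):
        rep = noiseless_report
        sub = rep.predictions[rep.predictions["mode"] == "Fluor"]
        for family in ("global", "hybrid"):
            for c in rep.classes:
                rows = sub[sub["truth"] == c]
                recomputed = (rows[family] == c).mean()
                assert rep.confusions[("Fluor", family)].recalls[c] == pytest.approx(recomputed)

    def test_pooled_counts_equal_sum_of_fold_counts(self, noiseless_report):
        rep = noiseless_report
        sub = rep.predictions[rep.predictions["mode"] == "Fluor"]
        total = np.zeros((len(rep.classes), len(rep.classes)), dtype=int)
        for f in sorted(sub["fold"].unique()):
            fold_rows = sub[sub["fold"] == f]
            cm = confusion_from_predictions(fold_rows["truth"], fold_rows["global"], rep.classes)
            total += cm.counts
        np.testing.assert_array_equal(total, rep.confusions[("Fluor", "global")].counts)

    def test_report_save_writes_artifacts(self, noiseless_report, tmp_path):
        noiseless_report.save(tmp_path / "out")
        for name in ("mode_summary.csv", "species_Fluor.csv", "predictions.csv", "report.json",
                     "fold_plan.json"):
            assert (tmp_path / "out" / name).exists()
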