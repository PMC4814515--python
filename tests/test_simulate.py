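"""Generator and experiment engine: construction identities, calibration."""

import numpy as np
import pandas as pd
import pytest

from mleffect import (
    GroupScores,
    SimulationConfig,
    compute_effect_size,
    generate_sample,
    recover_overlap,
    run_experiment,
    sampling_sd,
    train_linear,
    weight_overlap,
)


class TestConfig:
    def test_overlap_realized_exactly_by_feature_counts(self):
        cfg = SimulationConfig(n_subgroups=2, f_target=0.5, seed=0)
        v0, v1 = cfg.shift_vector(0), cfg.shift_vector(1)
        assert weight_overlap(v0, v1)[0] == pytest.approx(0.5, abs=1e-12)

    def test_fractional_overlap_target_met_via_partial_feature(self):
        cfg = SimulationConfig(n_subgroups=2, f_target=0.37, seed=0)
        v0, v1 = cfg.shift_vector(0), cfg.shift_vector(1)
        assert weight_overlap(v0, v1)[0] == pytest.approx(0.37, abs=1e-9)

    def test_delta_derived_from_effect_size_target(self):
        cfg = SimulationConfig(d0_target=2.0, seed=0)
        assert cfg.analytic_d0 == pytest.approx(2.0, abs=1e-12)

    def test_feature_budget_enforced(self):
        with pytest.raises(ValueError, match="feature budget exceeded"):
            SimulationConfig(p=30, n_subgroups=4, f_target=0.0, k_total=20, seed=0)

    def test_seed_required(self):
        cfg = SimulationConfig(seed=None)
        with pytest.raises(ValueError, match="seed mandatory"):
            generate_sample(cfg, "train")


class TestGenerateSample:
    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(p=30, n_per_group=40, n_subgroups=2, f_target=0.5, seed=5)
        a = generate_sample(cfg, "train")
        b = generate_sample(cfg, "train")
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.subgroup, b.subgroup)

    def test_patients_split_evenly_across_subgroups(self):
        cfg = SimulationConfig(p=80, n_per_group=101, n_subgroups=3, f_target=0.0, seed=1)
        sample = generate_sample(cfg, "train")
        counts = np.bincount(sample.subgroup)[1:]
        assert counts.sum() == 101 and counts.max() - counts.min() <= 1

    def test_null_model_has_exchangeable_groups(self):
        cfg = SimulationConfig(p=20, n_per_group=2000, d0_target=0.0, seed=2)
        sample = generate_sample(cfg, "train")
        gap = np.abs(
            sample.features[sample.labels == 1].mean(0)
            - sample.features[sample.labels == 0].mean(0)
        )
        assert gap.max() < 4 * 1.0 / np.sqrt(2000 / 2)

    def test_homogeneous_sample_reaches_analytic_effect_size(self):
        cfg = SimulationConfig(
            p=20, n_per_group=1000, n_subgroups=1, f_target=1.0, d0_target=2.0,
            n_test_per_group=1000, cv_folds=0, reps=1, seed=3,
        )
        train = generate_sample(cfg, "train")
        model = train_linear(train, cfg)
        test = generate_sample(cfg, "test")
        d = compute_effect_size(
            GroupScores(test.labels, model.decision_values(test.features))
        ).d_ml
        assert d == pytest.approx(cfg.analytic_d0, abs=0.15)


class TestTrainLinear:
    def test_weight_vector_aligns_with_class_mean_difference(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal([-3.0, 0.0], 0.3, size=(100, 2))
        x1 = rng.normal([3.0, 0.0], 0.3, size=(100, 2))
        model = train_linear(
            (np.vstack([x0, x1]), np.r_[np.zeros(100, int), np.ones(100, int)])
        )
        angle = weight_overlap(model.weights, [1.0, 0.0])[1]
        assert angle < 5.0

    def test_duplicated_sample_leaves_model_direction_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 10))
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        x[y == 1] += 0.5
        w1 = train_linear((x, y)).weights
        w2 = train_linear((np.vstack([x, x]), np.r_[y, y])).weights
        assert weight_overlap(w1, w2)[1] < 0.5  # degrees

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            train_linear((np.zeros((4, 3)), np.zeros(4, int)))

    def test_hinge_classifier_reports_support_vectors(self):
        cfg = SimulationConfig(
            p=40, n_per_group=60, classifier="hinge-linear", cv_folds=0, reps=1, seed=4
        )
        sample = generate_sample(cfg, "train")
        model = train_linear(sample, cfg)
        assert model.n_sv is not None and 2 <= model.n_sv <= 120


class TestRunExperiment:
    def test_bit_identical_given_config_and_seed(self):
        cfg = dict(p=40, n_per_group=50, n_subgroups=2, f_target=0.5,
                   cv_folds=3, reps=3, n_eval_per_group=50, seed=11)
        a = run_experiment(SimulationConfig(**cfg))
        b = run_experiment(SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)
        assert np.array_equal(a.w_bar, b.w_bar)
        assert a.d_ml_ensemble == b.d_ml_ensemble

    def test_null_effect_keeps_cv_accuracy_at_chance(self):
        cfg = SimulationConfig(
            p=20, n_per_group=100, d0_target=0.0, cv_folds=5, reps=20, seed=12,
            n_eval_per_group=100,
        )
        result = run_experiment(cfg)
        assert abs(result.acc_cv_mean - 50.0) <= 2 * sampling_sd(50.0, 200)

    def test_fully_shuffled_training_labels_destroy_the_model(self):
        cfg = SimulationConfig(
            p=20, n_per_group=100, d0_target=2.0, label_flip_train=0.5,
            cv_folds=0, reps=10, n_test_per_group=200, n_eval_per_group=100, seed=13,
        )
        result = run_experiment(cfg)
        assert result.acc_test_clean_mean == pytest.approx(50.0, abs=4.0)

    def test_disjoint_test_population_reduces_to_chance(self):
        # test petals share nothing with training (T = 0, no core)
        cfg = SimulationConfig(
            p=100, n_per_group=200, n_subgroups=2, f_target=0.0,
            h_prime=2, t_shared=0, cv_folds=0, reps=10, n_eval_per_group=100, seed=14,
        )
        result = run_experiment(cfg)
        assert result.analytic["test_attenuation"] == pytest.approx(0.0, abs=1e-12)
        assert abs(result.acc_test_mean - 50.0) <= 3 * sampling_sd(50.0, 400) / np.sqrt(10)

    def test_across_rep_spread_matches_binomial_oracle(self):
        cfg = SimulationConfig(
            p=50, n_per_group=500, d0_target=2.0, cv_folds=0, reps=50,
            n_test_per_group=50, n_eval_per_group=100, seed=15,
        )
        result = run_experiment(cfg)
        oracle = sampling_sd(result.acc_test_clean_mean, 100)
        assert 0.7 <= result.acc_test_sd / oracle <= 1.3

    def test_cv_accuracy_degrades_monotonically_with_heterogeneity(self):
        means = []
        for h in (1, 2, 4):
            cfg = SimulationConfig(
                p=100, n_per_group=200, n_subgroups=h, f_target=0.0, d0_target=2.0,
                cv_folds=5, reps=10, n_eval_per_group=100, seed=16,
            )
            means.append(run_experiment(cfg).acc_cv_mean)
        assert means[0] >= means[1] - 2.0 >= means[2] - 4.0
        assert means[0] > means[2]

    def test_heterogeneous_cv_accuracy_matches_attenuated_prediction(self):
        """H = 2 disjoint subgroups: CV accuracy tracks the sqrt((1+f)/2)
        attenuation of a d0 = 2 homogeneous effect within 3 points."""
        cfg = SimulationConfig(
            p=50, n_per_group=500, n_subgroups=2, f_target=0.0, d0_target=2.0,
            cv_folds=10, reps=20, n_eval_per_group=100, seed=17,
        )
        result = run_experiment(cfg)
        assert result.acc_cv_mean == pytest.approx(result.analytic["acc_cv"], abs=3.0)

    def test_tidy_csv_roundtrip(self, tmp_path):
        cfg = SimulationConfig(p=25, n_per_group=30, cv_folds=3, reps=2,
                               n_eval_per_group=30, seed=18)
        result = run_experiment(cfg)
        out = tmp_path / "tidy.csv"
        result.to_tidy_csv(out)
        tidy = pd.read_csv(out)
        assert set(tidy.columns) == {"rep", "metric", "value"}
        assert len(tidy) == 2 * 5


class TestRecoverOverlap:
    def test_requires_two_subgroups(self):
        with pytest.raises(ValueError, match="two-subgroup"):
            recover_overlap(SimulationConfig(n_subgroups=3, f_target=0.0, seed=20))

    @pytest.mark.parametrize("f", [0.0, 0.5, 1.0])
    def test_small_scale_recovery(self, f):
        cfg = SimulationConfig(
            p=50, n_per_group=300, n_subgroups=2, f_target=f, reps=10, seed=21
        )
        recovery = recover_overlap(cfg)
        assert recovery.f_hat == pytest.approx(f, abs=0.1)
        # single-fit estimates are attenuated toward zero, never inflated
        assert abs(recovery.f_hat_single_mean) <= abs(recovery.f_hat) + 0.05
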