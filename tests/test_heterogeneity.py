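"""Petal-model arithmetic: attenuation, log rules, overlap estimation."""

import numpy as np
import pytest

from mleffect import (
    HeterogeneitySpec,
    LinearModel,
    NoiseModel,
    TrainTestOverlap,
    accuracy_curve,
    accuracy_drop_between,
    accuracy_drop_within,
    accuracy_from_effect_size,
    between_sample_effect_size,
    compose_noise,
    effect_size_from_accuracy,
    estimate_overlap,
    predict_accuracy_curve,
    train_test_effect_size,
    train_test_overlap_attenuation,
    weight_overlap,
    within_sample_attenuation,
)


class TestWithinSampleAttenuation:
    @pytest.mark.parametrize(
        "f, h, expected",
        [(1.0, 5, 1.0), (0.0, 2, np.sqrt(0.5)), (0.5, 2, np.sqrt(0.75)), (0.0, 1, 1.0)],
    )
    def test_closed_form(self, f, h, expected):
        assert within_sample_attenuation(f, h) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_h_and_f(self):
        hs = np.linspace(1, 20, 40)
        vals = [within_sample_attenuation(0.4, h) for h in hs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        fs = np.linspace(-0.2, 1.0, 30)
        vals = [within_sample_attenuation(f, 3) for f in fs]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_undefined_region_raises(self):
        with pytest.raises(ValueError, match="petal model undefined"):
            within_sample_attenuation(-0.8, 5)


class TestBetweenSample:
    def test_scaling(self):
        assert between_sample_effect_size(2.0, 0.5) == 1.0
        assert between_sample_effect_size(1.68, 1.0) == 1.68

    def test_compose_with_accuracy(self):
        d_train = float(effect_size_from_accuracy(80))
        f = estimate_overlap(80, 65.54, method="exact")
        acc_test = float(accuracy_from_effect_size(between_sample_effect_size(d_train, f)))
        assert acc_test == pytest.approx(65.54, abs=0.01)

    @pytest.mark.parametrize("f, drop", [(0.5, 16.0), (1.0, 0.0), (0.8, 5.1)])
    def test_53_point_rule(self, f, drop):
        assert round(accuracy_drop_between(f), 1) == pytest.approx(drop, abs=0.05)

    @pytest.mark.parametrize("f, drop", [(1.0, 0.0), (0.0, 7.8), (0.5, 3.2)])
    def test_26_point_rule(self, f, drop):
        assert accuracy_drop_within(f) == pytest.approx(drop, abs=0.05)

    def test_rules_reject_undefined_f(self):
        with pytest.raises(ValueError, match="undefined"):
            accuracy_drop_between(0.0)
        with pytest.raises(ValueError, match="undefined"):
            accuracy_drop_within(-1.0)

    def test_warning_outside_validity_band(self):
        with pytest.warns(UserWarning, match="70-90"):
            accuracy_drop_between(0.5, train_accuracy=95.0)

    def test_log_rule_tracks_exact_drop_when_both_accuracies_in_band(self):
        """The 53-point rule is the tangent of the Phi model near 80%; it
        stays within 2 accuracy points of the exact drop as long as train
        AND test accuracies remain in the 70-90% band."""
        for f in np.linspace(0.55, 1.0, 19):
            for acc in np.linspace(70, 90, 21):
                d = float(effect_size_from_accuracy(acc))
                acc_test = float(accuracy_from_effect_size(f * d))
                if not 70.0 <= acc_test <= 90.0:
                    continue
                exact = acc - acc_test
                assert abs(exact - accuracy_drop_between(f)) <= 2.0


class TestEstimateOverlap:
    def test_equal_accuracies_give_unity(self):
        assert estimate_overlap(77.0, 77.0, method="exact") == pytest.approx(1.0)

    def test_exact_ratio(self):
        # 88% -> d = 2.35; 72% -> d = 1.17; ratio ~ 0.50
        assert estimate_overlap(88, 72, method="exact") == pytest.approx(0.496, abs=0.005)

    def test_log_approx_inverts_the_rule(self):
        assert estimate_overlap(80, 64, method="log-approx") == pytest.approx(
            10 ** (-16 / 53), abs=1e-12
        )

    def test_exact_roundtrip_with_attenuation(self):
        d = float(effect_size_from_accuracy(83.0))
        for f in (0.3, 0.476, 0.9):
            acc_test = float(accuracy_from_effect_size(f * d))
            assert estimate_overlap(83.0, acc_test, method="exact") == pytest.approx(
                f, abs=1e-9
            )

    def test_chance_train_accuracy_rejected(self):
        with pytest.raises(ValueError, match="f undefined"):
            estimate_overlap(50.0, 60.0, method="exact")


class TestNoise:
    @pytest.mark.parametrize("parts, total", [((3, 4), 5.0), ((2, 0), 2.0), ((1, 1), np.sqrt(2))])
    def test_compose(self, parts, total):
        assert compose_noise(*parts) == pytest.approx(total, abs=1e-12)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="invalid SD"):
            compose_noise(-1, 2)

    def test_train_test_effect_size(self):
        same = NoiseModel(sigma_y=1.0, sigma_yt=1.0)
        assert train_test_effect_size(1.5, 1.0, same) == pytest.approx(1.5)
        # doubled test spread halves the effect size -- like a 50% overlap
        doubled = NoiseModel(sigma_y=1.0, sigma_yt=2.0)
        assert train_test_effect_size(1.5, 1.0, doubled) == pytest.approx(0.75)
        narrow = NoiseModel(sigma_y=1.0, sigma_yt=1 / np.sqrt(2))
        assert train_test_effect_size(1.0, 0.9, narrow) == pytest.approx(0.9 * np.sqrt(2))

    def test_degenerate_test_variance(self):
        with pytest.raises(ValueError, match="degenerate test variance"):
            train_test_effect_size(1.0, 1.0, NoiseModel(sigma_y=1.0, sigma_yt=0.0))


class TestWeightOverlap:
    def test_identical_and_orthogonal(self):
        w = np.array([1.0, 2.0, 3.0])
        f, theta = weight_overlap(w, w)
        assert f == pytest.approx(1.0) and theta == pytest.approx(0.0)
        f, theta = weight_overlap([1, 0], [0, 1])
        assert f == pytest.approx(0.0) and theta == pytest.approx(90.0)

    def test_hand_computed_angle(self):
        f, theta = weight_overlap([1, 1, 0], [1, 0, 1])
        assert f == pytest.approx(0.5) and theta == pytest.approx(60.0)

    def test_accepts_linear_models_and_rejects_mismatch(self):
        m1 = LinearModel(weights=[1, 0, 0])
        m2 = LinearModel(weights=[0, 1, 0])
        assert weight_overlap(m1, m2)[0] == pytest.approx(0.0)
        with pytest.raises(ValueError, match="equal dimension"):
            weight_overlap([1, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="zero weight"):
            weight_overlap([0, 0], [1, 0])


class TestAccuracyCurve:
    def test_reference_parameters(self):
        spec = HeterogeneitySpec(d0=2.0, f=0.0, n0=50.0)
        assert float(predict_accuracy_curve(spec, 50)) == pytest.approx(84.13, abs=0.01)
        assert float(predict_accuracy_curve(spec, 150)) == pytest.approx(71.81, abs=0.01)

    def test_plateau_below_n0(self):
        spec = HeterogeneitySpec(d0=2.0, f=0.0, n0=50.0)
        assert float(predict_accuracy_curve(spec, 10)) == float(predict_accuracy_curve(spec, 50))

    def test_homogeneous_population_is_flat(self):
        spec = HeterogeneitySpec(d0=1.5, f=1.0, n0=50.0)
        accs = predict_accuracy_curve(spec, [10, 100, 1000])
        assert np.allclose(accs, float(accuracy_from_effect_size(1.5)))

    def test_kappa_ceiling_lowers_curve(self):
        spec = HeterogeneitySpec(d0=2.0, f=0.0, n0=50.0)
        plain = float(predict_accuracy_curve(spec, 50))
        capped = float(predict_accuracy_curve(spec, 50, ceiling_kappa=0.8))
        assert capped == pytest.approx(0.8 * plain + 10.0, abs=1e-9)

    def test_curve_records(self):
        spec = HeterogeneitySpec(d0=2.0, f=0.0, n0=50.0)
        points = accuracy_curve(spec, [50, 150])
        assert points[0]["H_eff"] == 1.0 and points[1]["H_eff"] == 3.0
        assert points[1]["d_ml"] == pytest.approx(2 / np.sqrt(3))


class TestTrainTestOverlapAttenuation:
    def test_identical_homogeneous_samples(self):
        assert train_test_overlap_attenuation(
            TrainTestOverlap(h=1, h_prime=1, t=1, f=0.3)
        ) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "h, hp, t, f, expected",
        [(2, 1, 1, 0.0, np.sqrt(0.5)), (2, 1, 0, 0.0, 0.0)],
    )
    def test_closed_form(self, h, hp, t, f, expected):
        assert train_test_overlap_attenuation(
            TrainTestOverlap(h=h, h_prime=hp, t=t, f=f)
        ) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("h", [1, 2, 3, 5])
    @pytest.mark.parametrize("f", [0.0, 0.3, 0.8])
    def test_self_test_reduces_to_within_sample_attenuation(self, h, f):
        overlap = TrainTestOverlap(h=h, h_prime=h, t=h, f=f)
        assert train_test_overlap_attenuation(overlap) == pytest.approx(
            within_sample_attenuation(f, h), abs=1e-12
        )

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="T must satisfy"):
            TrainTestOverlap(h=2, h_prime=1, t=2, f=0.0)
        with pytest.raises(ValueError, match=">= 1"):
            TrainTestOverlap(h=0, h_prime=1, t=0, f=0.0)
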