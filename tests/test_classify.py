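"""Reference bank moments, KS feature extraction against brute-force
ECDF comparison, classifier training and the transformation contract."""

import numpy as np
import pytest
from scipy import stats

from vqtlkit.classify import (CLASS_LABELS, TransformSpec,
                              apply_transformation, build_training_set,
                              classify_and_recommend, default_bank,
                              ks_d_plus, ks_feature_vector, train_classifier)
from vqtlkit.exceptions import InvalidArgumentError


class TestReferenceBank:
    def test_bank_has_79_densities(self):
        bank = default_bank()
        assert bank.size == 79
        assert len(set(bank.names)) == 79

    @pytest.mark.parametrize("name", ["gaussian", "lognorm_s1.0",
                                      "mix_l0.4_d3", "gamma_k0.5"])
    def test_moment_matching(self, name):
        bank = default_bank()
        i = bank.names.index(name)
        rng = np.random.default_rng(0)
        s = bank.sample_matched(i, mean=3.0, var=4.0, size=400_000, rng=rng)
        assert abs(s.mean() - 3.0) < 0.05
        assert abs(s.var() - 4.0) < 0.1

    def test_analytic_moments_match_samplers(self):
        """Declared mean/variance agree with large-sample moments for a
        spread of families (the matching transform relies on them)."""
        bank = default_bank()
        rng = np.random.default_rng(1)
        for name in ("t_df5", "beta_2_5", "weibull_c1.5", "pareto_b4",
                     "mix_l0.2_d5"):
            d = bank.densities[bank.names.index(name)]
            m, v = d.stats()
            s = np.asarray(d.rvs(size=500_000, random_state=rng))
            assert abs(s.mean() - m) < 6 * np.sqrt(s.var() / s.size) + 1e-3
            assert abs(s.var() - v) / v < 0.05


class TestKsFeatures:
    def test_d_plus_matches_brute_force(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.5, 2.5, 3.5, 4.5, 5.5])
        # brute force: evaluate both ECDFs at every point
        pts = np.concatenate([a, b])
        fa = np.array([(a <= t).mean() for t in pts])
        fb = np.array([(b <= t).mean() for t in pts])
        assert abs(ks_d_plus(a, b) - np.max(fa - fb)) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1])
    def test_d_plus_matches_scipy_one_sided(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 300)
        b = rng.normal(0.3, 1.2, 200)
        ref = stats.ks_2samp(a, b, alternative="greater").statistic
        assert abs(ks_d_plus(a, b) - ref) < 1e-12

    def test_feature_vector_dimension_and_determinism(self):
        bank = default_bank()
        y = np.random.default_rng(2).normal(size=50)
        f1 = ks_feature_vector(y, bank, ref_size=50, seed=3)
        f2 = ks_feature_vector(y, bank, ref_size=50, seed=3)
        assert f1.shape == (79,)
        np.testing.assert_array_equal(f1, f2)

    def test_gaussian_sample_close_to_gaussian_reference(self):
        bank = default_bank()
        y = np.random.default_rng(4).normal(2.0, 1.5, 1000)
        f = ks_feature_vector(y, bank, ref_size=1000, seed=5)
        assert f[bank.names.index("gaussian")] < 0.1

    def test_zero_variance_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ks_feature_vector(np.ones(30), default_bank(), seed=0)

    def test_tiny_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ks_feature_vector(np.arange(10.0), default_bank(), seed=0)


class TestTrainingSet:
    def test_single_sample_per_cell_counts(self):
        X, labels = build_training_set(samples_per_cell=1, n=60, ref_size=30,
                                       seed=1)
        assert X.shape == (28, 79)
        assert set(labels) == set(CLASS_LABELS)

    def test_determinism(self):
        a, la = build_training_set(samples_per_cell=1, n=60, ref_size=30,
                                   seed=2)
        b, lb = build_training_set(samples_per_cell=1, n=60, ref_size=30,
                                   seed=2)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(la, lb)


class TestClassifier:
    def test_beats_chance_and_probabilities_normalized(self, small_classifier):
        bank, model = small_classifier
        assert model.cv_report["macro_accuracy"] > 1 / 7
        y = np.random.default_rng(6).lognormal(1.0, 1.0, 200)
        x = np.random.default_rng(6).integers(0, 3, 200).astype(float)
        probs, _ = classify_and_recommend(y, x, model, bank, seed=7)
        assert abs(sum(probs.values()) - 1.0) < 1e-9

    def test_shuffled_labels_fall_to_chance(self):
        X, labels = build_training_set(samples_per_cell=4, n=80, ref_size=40,
                                       seed=3)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        model = train_classifier(X, shuffled, folds=3, seed=0)
        acc = model.cv_report["macro_accuracy"]
        n = len(labels)
        se = np.sqrt((1 / 7) * (6 / 7) / n)
        assert acc < 1 / 7 + 3 * se

    def test_missing_class_rejected(self):
        X = np.random.default_rng(1).normal(size=(20, 79))
        labels = np.array(["bth_ideal", "gamma"] * 10)
        with pytest.raises(InvalidArgumentError):
            train_classifier(X, labels, folds=2)

    def test_model_round_trip(self, small_classifier, tmp_path):
        from vqtlkit.classify import ClassifierModel

        bank, model = small_classifier
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = ClassifierModel.load(path)
        assert loaded.bank_names == model.bank_names
        assert loaded.cv_report == model.cv_report


class TestTransforms:
    def test_label_to_transform_mapping(self, small_classifier):
        from vqtlkit.classify import TRANSFORM_FOR_LABEL

        assert TRANSFORM_FOR_LABEL["log_gaussian"] == "log"
        assert TRANSFORM_FOR_LABEL["gamma"] == "mean_centered_sqrt"
        assert "bth_ideal" not in TRANSFORM_FOR_LABEL

    def test_log_gaussian_trait_recommended_log(self, small_classifier):
        bank, model = small_classifier
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, 200).astype(float)
        y = np.exp(1.0 + 0.5 * x + rng.normal(0, 1, 200))
        probs, spec = classify_and_recommend(y, x, model, bank, seed=9)
        top = max(probs, key=probs.get)
        if top == "log_gaussian":
            assert spec.kind == "log"

    def test_log_recovers_gaussian(self):
        z = np.random.default_rng(10).normal(1, 0.5, 100)
        out = apply_transformation(np.exp(z), TransformSpec(kind="log"))
        np.testing.assert_allclose(out, z, atol=1e-12)

    def test_mean_centered_sqrt_centers(self):
        y = np.random.default_rng(11).gamma(5, 1, 200)
        spec = TransformSpec(kind="mean_centered_sqrt")
        out = apply_transformation(y, spec)
        assert abs(out.mean()) < 1e-12
        assert spec.offset == pytest.approx(np.sqrt(y).mean())

    def test_log_domain_error(self):
        with pytest.raises(InvalidArgumentError):
            apply_transformation(np.array([1.0, 0.0, 2.0]),
                                 TransformSpec(kind="log"))

    def test_sqrt_domain_error(self):
        with pytest.raises(InvalidArgumentError):
            apply_transformation(np.array([1.0, -0.5]),
                                 TransformSpec(kind="mean_centered_sqrt"))
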