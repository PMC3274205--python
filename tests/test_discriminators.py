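import numpy as np
import pytest
from scipy import stats

from ramanforensiq.chemometrics import CvScheme, pca_project
from ramanforensiq.discriminators import (
    classification_metrics,
    classify_unknowns,
    consensus_vote,
    gaussian_family_predict,
    lda_discriminants,
    lda_loo,
    lda_predict,
    lda_train,
    plsda_evaluate,
    plsda_predict,
    plsda_train,
    simca_classify,
    simca_train,
    _fit_compressor,
)
from ramanforensiq.pipeline import ExperimentConfig, preprocess
from ramanforensiq.spectral_core import SpectralDataset
from ramanforensiq.synthetic import SimulationConfig, simulate_dataset


class TestClassMetrics:
    def test_hand_computed_confusion(self):
        # 10 actual positives (9 found), 20 actual negatives (all rejected)
        y_true = ["blood"] * 10 + ["saliva"] * 20
        y_pred = ["blood"] * 9 + ["saliva"] + ["saliva"] * 20
        m = classification_metrics(y_true, y_pred, ["blood", "saliva"])
        assert m.sensitivity["blood"] == pytest.approx(0.9)
        assert m.specificity["blood"] == pytest.approx(1.0)
        assert m.class_error["blood"] == pytest.approx(0.05)

    def test_identities_on_random_confusions(self):
        rng = np.random.default_rng(0)
        classes = ["blood", "saliva", "semen"]
        for _ in range(10):
            y_true = [classes[i] for i in rng.integers(0, 3, 60)]
            y_pred = [classes[i] for i in rng.integers(0, 3, 60)]
            m = classification_metrics(y_true, y_pred, classes)
            assert m.confusion.sum(axis=1).tolist() == [
                y_true.count(c) for c in classes
            ]
            for i, c in enumerate(classes):
                tp = m.confusion[i, i]
                n_in = m.confusion[i].sum()
                n_out = m.confusion.sum() - n_in
                tn = n_out - (m.confusion[:, i].sum() - tp)
                assert m.sensitivity[c] * n_in == pytest.approx(tp)
                assert m.specificity[c] * n_out == pytest.approx(tn)

    def test_all_one_class_predictor(self):
        y_true = ["blood"] * 5 + ["saliva"] * 5 + ["semen"] * 5
        y_pred = ["blood"] * 15
        m = classification_metrics(y_true, y_pred, ["blood", "saliva", "semen"])
        assert m.sensitivity["blood"] == 1.0
        assert m.specificity["blood"] == 0.0
        assert m.sensitivity["saliva"] == 0.0
        assert m.sensitivity["semen"] == 0.0

    def test_indicator_rmse(self):
        y_true = ["blood", "saliva"]
        y_pred = ["blood", "saliva"]
        pred = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = classification_metrics(y_true, y_pred, ["blood", "saliva"], pred)
        assert m.rmse["blood"] == pytest.approx(
            np.sqrt(((0.9 - 1) ** 2 + (0.2 - 0) ** 2) / 2)
        )


class TestSimca:
    def test_t2_limit_formula(self, small_dataset):
        m = simca_train(small_dataset, a_per_class=2, alpha=0.95)
        sub = m.submodels["blood"]
        n = int(np.sum(small_dataset.labels == "blood"))
        expected = 2 * (n - 1) / (n - 2) * stats.f.ppf(0.95, 2, n - 2)
        assert sub.t2_limit == pytest.approx(expected, rel=1e-10)

    def test_q_coverage_on_low_rank_class(self):
        # 500 points in an exact 2-D subspace plus tiny isotropic noise:
        # the alpha=0.95 Q limit should hold for ~95 % of training points
        rng = np.random.default_rng(12)
        basis = rng.normal(size=(2, 40))
        X = rng.normal(size=(500, 2)) @ basis + 1e-3 * rng.normal(size=(500, 40))
        d = SpectralDataset(
            np.arange(40.0), np.abs(X), ["blood"] * 500,
            [f"d{i}" for i in range(500)],
        )
        m = simca_train(d, a_per_class=2, alpha=0.95)
        sub = m.submodels["blood"]
        _, _, q = pca_project(sub.pca, d.matrix)
        assert np.mean(q <= sub.q_limit) >= 0.93

    def test_three_submodels(self, small_dataset):
        m = simca_train(small_dataset, a_per_class=3)
        assert m.classes == ("blood", "saliva", "semen")
        assert set(m.submodels) == {"blood", "saliva", "semen"}

    def test_class_mean_is_nearest_with_tiny_distance(self, small_dataset):
        m = simca_train(small_dataset, a_per_class=3)
        mean_blood = small_dataset.matrix[small_dataset.labels == "blood"].mean(0)
        probe = SpectralDataset(
            small_dataset.wavenumbers, mean_blood[None, :], ["unknown"], ["x"]
        )
        assignments, _ = simca_classify(m, probe)
        assert assignments[0].nearest_class == "blood"
        assert assignments[0].distances["blood"] < 0.1

    def test_spot_level_accuracy(self, small_dataset):
        m = simca_train(small_dataset, a_per_class=3)
        _, metrics = simca_classify(m, small_dataset)
        for c in metrics.classes:
            assert metrics.sensitivity[c] >= 0.8

    def test_training_self_consistency(self, small_dataset):
        # well-specified classes: most training spectra inside own limits
        m = simca_train(small_dataset, a_per_class=3, alpha=0.95)
        assignments, _ = simca_classify(m, small_dataset)
        inside = [
            a.in_class[t]
            for a, t in zip(assignments, small_dataset.labels)
        ]
        assert np.mean(inside) >= 0.90

    def test_too_few_spectra_names_class(self):
        rng = np.random.default_rng(1)
        d = SpectralDataset(
            np.arange(20.0),
            np.abs(rng.normal(size=(5, 20))),
            ["blood", "blood", "blood", "blood", "saliva"],
            list("abcde"),
        )
        with pytest.raises(ValueError, match="saliva"):
            simca_train(d, a_per_class=3)


class TestLda:
    def _spherical_two_class(self, rng, n=40, d=4, sep=8.0):
        X = np.vstack(
            [rng.normal(0, 1, size=(n, d)), rng.normal(0, 1, size=(n, d))]
        )
        X[n:, 0] += sep
        y = np.array(["blood"] * n + ["saliva"] * n, dtype=object)
        return X, y

    def test_boundary_is_perpendicular_bisector(self):
        rng = np.random.default_rng(2)
        X, y = self._spherical_two_class(rng, n=500, sep=6.0)
        m = lda_train(X, y, ["blood", "saliva"])
        mid = (m.means[0] + m.means[1]) / 2
        direction = m.means[1] - m.means[0]
        rng2 = np.random.default_rng(3)
        for _ in range(10):
            probe = mid + rng2.normal(0, 1, size=4)
            side = (probe - mid) @ direction
            pred = lda_predict(m, probe)[0]
            # probes clearly on one side classify with that side's class
            if abs(side) > 0.5:
                assert pred == ("saliva" if side > 0 else "blood")

    def test_discriminant_matches_formula(self):
        rng = np.random.default_rng(4)
        X, y = self._spherical_two_class(rng)
        m = lda_train(X, y, ["blood", "saliva"])
        probe = rng.normal(size=(5, 4))
        delta = lda_discriminants(m, probe)
        for i in range(5):
            for c in range(2):
                mu = m.means[c]
                expected = (
                    probe[i] @ m.pooled_inv @ mu
                    - 0.5 * mu @ m.pooled_inv @ mu
                    + np.log(m.priors[c])
                )
                assert delta[i, c] == pytest.approx(expected, abs=1e-10)

    def test_identical_means_tie_broken_by_class_order(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = np.array((["blood", "saliva", "semen"] * 10), dtype=object)
        m = lda_train(X, y, ["blood", "saliva", "semen"])
        delta = lda_discriminants(m, np.zeros((1, 3)))
        assert np.ptp(delta) < 1.0  # near-degenerate discriminants
        # exact ties in argmax go to the first (canonical) class
        tied = np.zeros((1, 3))
        preds = [
            ("blood", "saliva", "semen")[i]
            for i in np.argmax(np.zeros((1, 3)), axis=1)
        ]
        assert preds[0] == "blood"

    def test_loo_contract_small_n(self):
        rng = np.random.default_rng(6)
        cfg = SimulationConfig(n_samples_per_fluid=2, spots_per_sample=1, seed=1)
        d = preprocess(simulate_dataset(cfg), ExperimentConfig())
        assert d.n_spectra == 6
        preds, metrics = lda_loo(d, "pca", a=2)
        assert len(preds) == 6

    def test_loo_perfect_on_separated_classes(self, small_dataset):
        _, metrics = lda_loo(small_dataset, "pca")
        assert metrics.accuracy == 1.0

    def test_loo_heavy_noise_band(self):
        cfg = SimulationConfig(n_samples_per_fluid=6, spots_per_sample=3,
                               peak_snr=1.0, seed=5)
        d = preprocess(simulate_dataset(cfg), ExperimentConfig())
        _, metrics = lda_loo(d, "pca")
        assert 1 / 3 <= metrics.accuracy < 1.0

    def test_pls_compression_also_perfect(self, small_dataset):
        _, metrics = lda_loo(small_dataset, "pls", a=5)
        assert metrics.accuracy == 1.0


class TestGaussianFamily:
    def test_spherical_classes_agree_with_lda(self):
        rng = np.random.default_rng(7)
        n = 25
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(0, 1, (n, 3))])
        X[n:] += 8.0
        y = ["blood"] * n + ["saliva"] * n
        d = SpectralDataset(np.arange(3.0), X - X.min() + 0.1, y,
                            [f"d{i}" for i in range(2 * n)])
        lda_preds, _ = lda_loo(d, "pca", a=2)
        for variant in ("naive_bayes", "stratified_covariance", "mahalanobis"):
            preds, _ = gaussian_family_predict(d, variant, "pca", a=2)
            agreement = np.mean([p == q for p, q in zip(preds, lda_preds)])
            assert agreement == 1.0, variant

    def test_consistent_with_lda_on_fluids(self, small_dataset):
        _, lda_m = lda_loo(small_dataset, "pca")
        for variant in ("naive_bayes", "stratified_covariance", "mahalanobis"):
            _, m = gaussian_family_predict(small_dataset, variant, "pca")
            assert abs(m.accuracy - lda_m.accuracy) <= 0.05, variant

    def test_mahalanobis_identity_cov_is_nearest_mean(self):
        rng = np.random.default_rng(8)
        from ramanforensiq.discriminators import _gaussian_rule

        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(5, 1, (50, 2))])
        y = np.array(["blood"] * 50 + ["saliva"] * 50, dtype=object)
        rule = _gaussian_rule("mahalanobis", X, y, ("blood", "saliva"))
        means = np.vstack([X[:50].mean(0), X[50:].mean(0)])
        probes = rng.normal(2.5, 3.0, size=(40, 2))
        preds = rule(probes)
        # pooled covariance is ~spherical here, so Mahalanobis ~ Euclidean
        for p, probe in zip(preds, probes):
            d0 = np.linalg.norm(probe - means[0])
            d1 = np.linalg.norm(probe - means[1])
            if abs(d0 - d1) > 0.5:
                assert p == ("blood" if d0 < d1 else "saliva")


class TestPlsda:
    def test_two_separable_one_peak_classes(self):
        axis = np.arange(0.0, 50.0, 1.0)
        rng = np.random.default_rng(9)
        rows, labels = [], []
        for i in range(10):
            y = np.exp(-0.5 * ((axis - 15) / 2) ** 2) + rng.normal(0, 0.01, 50)
            rows.append(y)
            labels.append("blood")
        for i in range(10):
            y = np.exp(-0.5 * ((axis - 35) / 2) ** 2) + rng.normal(0, 0.01, 50)
            rows.append(y)
            labels.append("saliva")
        d = SpectralDataset(axis, np.abs(rows), labels,
                            [f"d{i}" for i in range(20)])
        m = plsda_train(d, a=1)
        preds, indicator = plsda_predict(m, d.matrix)
        assert preds == labels
        # indicator values are not probabilities (they can leave [0, 1]);
        # the decision rule is pure argmax
        assert indicator.min() < 0.0 or indicator.max() > 1.0

    def test_latent_scores_cluster_by_fluid(self, default_dataset):
        # the three fluids separate into clusters in the space of the
        # leading latent variables
        metrics_mod = pytest.importorskip("sklearn.metrics")
        m = plsda_train(default_dataset, a=5)
        scores = (default_dataset.matrix - m.pls.x_mean) @ m.pls.weights
        sel = scores[:, [0, 1, 2]]
        sil = metrics_mod.silhouette_score(sel, default_dataset.labels)
        assert sil > 0.5

    def test_evaluate_perfect_predictor(self, small_dataset):
        m = plsda_train(small_dataset, a=5)
        cal, cv = plsda_evaluate(m, small_dataset, CvScheme("venetian_blind", 6))
        for c in cal.classes:
            assert cal.sensitivity[c] == 1.0
            assert cal.specificity[c] == 1.0
            assert cal.class_error[c] == 0.0
        assert cal.rmse is not None and all(v >= 0 for v in cal.rmse.values())

    def test_single_class_rejected(self):
        rng = np.random.default_rng(10)
        d = SpectralDataset(
            np.arange(10.0), np.abs(rng.normal(size=(5, 10))),
            ["blood"] * 5, list("abcde"),
        )
        with pytest.raises(ValueError):
            plsda_train(d, a=2)


class TestConsensus:
    def test_unanimous(self):
        assert consensus_vote({"a": "blood", "b": "blood", "c": "blood"}) == (
            "blood", True,
        )

    def test_majority_flags_disagreement(self):
        label, unanimous = consensus_vote(
            {"a": "blood", "b": "blood", "c": "semen"}
        )
        assert label == "blood" and not unanimous

    def test_full_disagreement_is_ambiguous(self):
        label, unanimous = consensus_vote(
            {"a": "blood", "b": "saliva", "c": "semen"}
        )
        assert label == "ambiguous" and not unanimous

    def test_training_copy_classified_unanimously(self, small_dataset):
        d = small_dataset
        simca = simca_train(d, 3)
        transform = _fit_compressor(
            d.matrix, d.labels, tuple(d.classes), "pca", None
        )
        lda = lda_train(transform(d.matrix), d.labels, tuple(d.classes))
        plsda = plsda_train(d, a=5)
        i = int(np.flatnonzero(d.labels == "blood")[0])
        probe = d.subset([i])
        records = classify_unknowns(
            {"simca": simca, "lda": (lda, transform), "plsda": plsda}, probe
        )
        assert records[0]["consensus"] == "blood"
        assert records[0]["unanimous"]
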