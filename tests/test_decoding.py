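"""Feature extraction, shrinkage-LDA, AUC and cross-validation mechanics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import cogdepth as cd
from cogdepth.decoding import (
    EmptyFeatureError,
    FeatureScaler,
    _fold_features,
    _stratified_folds,
)
from cogdepth.univariate import IntervalSet


def _epochs(data, labels, fs=100.0):
    return cd.EpochSet(
        data=data,
        labels=np.asarray(labels),
        times=np.arange(-20, data.shape[2] - 20) * 1000.0 / fs,
        fs=fs,
        channel_labels=[f"C{i}" for i in range(data.shape[1])],
    )


class TestERPFeatures:
    def test_constant_epochs_give_constant_features(self):
        ep = _epochs(np.full((4, 3, 220), 2.5), ["NT"] * 4)
        ivs = IntervalSet(intervals=[(100.0, 300.0), (400.0, 600.0)])
        table = cd.erp_features(ep, ivs)
        assert table.matrix.shape == (4, 6)
        assert np.allclose(table.matrix, 2.5)

    def test_ramp_feature_is_midpoint_value(self):
        data = np.tile(np.linspace(0.0, 219.0, 220), (2, 1, 1))[:, None, :] \
            if False else np.broadcast_to(
                np.linspace(0.0, 219.0, 220), (2, 1, 220)
            ).copy()
        ep = _epochs(data, ["NT", "DT"])
        # interval [0, 1000) ms = samples 20..119; midpoint value (69.5)
        table = cd.erp_features(ep, IntervalSet(intervals=[(0.0, 1000.0)]))
        assert np.allclose(table.matrix, (20 + 119) / 2)

    def test_feature_count_is_channels_times_intervals(self):
        ep = _epochs(np.zeros((3, 31, 220)), ["NT"] * 3)
        ivs = IntervalSet(
            intervals=[(i * 100.0, i * 100.0 + 50.0) for i in range(5)]
        )
        table = cd.erp_features(ep, ivs)
        assert table.n_features == 155
        assert len(table.provenance) == 155

    def test_empty_interval_set_raises(self):
        ep = _epochs(np.zeros((3, 2, 220)), ["NT"] * 3)
        with pytest.raises(EmptyFeatureError):
            cd.erp_features(ep, IntervalSet(intervals=[]))


class TestLogvarFeatures:
    def test_unit_variance_noise_maps_to_zero(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.standard_normal((50, 2, 220)), ["NT"] * 50)
        table = cd.logvar_features(ep, window=(0.0, 1990.0))
        assert abs(table.matrix.mean()) < 0.05

    def test_sinusoid_matches_analytic_variance(self):
        """Oracle: a sinusoid of amplitude a has variance a²/2."""
        t = np.arange(220) / 100.0
        a = 3.0
        data = (a * np.sin(2 * np.pi * 7.0 * t))[None, None, :].repeat(2, axis=0)
        ep = _epochs(data, ["NT", "DT"])
        table = cd.logvar_features(ep, window=(350.0, 1990.0), band_name="alpha")
        assert np.allclose(table.matrix, np.log(a**2 / 2), atol=0.02)
        assert all(p["modality"] == "csp-alpha" for p in table.provenance)


class TestFusion:
    def _table(self, rng, n=10, k=3, labels=None):
        return cd.FeatureTable(
            matrix=rng.standard_normal((n, k)),
            provenance=[{"modality": "erp", "channel": f"C{i}"} for i in range(k)],
            labels=np.asarray(labels if labels is not None else ["NT"] * n),
        )

    def test_single_table_identity(self):
        rng = np.random.default_rng(1)
        t = self._table(rng)
        fused = cd.fuse_features([t], zscore=False)
        assert np.array_equal(fused.matrix, t.matrix)

    def test_zscore_standardizes_columns(self):
        rng = np.random.default_rng(2)
        fused = cd.fuse_features([self._table(rng), self._table(rng)], zscore=True)
        assert np.allclose(fused.matrix.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(fused.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_provenance_preserved_in_order(self):
        rng = np.random.default_rng(3)
        a, b = self._table(rng, k=2), self._table(rng, k=3)
        fused = cd.fuse_features([a, b])
        assert fused.provenance == a.provenance + b.provenance

    def test_trial_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(cd.InvalidConfigurationError):
            cd.fuse_features([self._table(rng, n=10), self._table(rng, n=12)])

    def test_scaler_applies_training_statistics_to_test(self):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((100, 4)) * 3 + 7
        scaler = FeatureScaler.fit(train)
        test = rng.standard_normal((20, 4)) * 3 + 7
        out = scaler.transform(test)
        assert abs(out.mean()) < 0.5  # centered by train stats, not its own


class TestShrinkageLDA:
    def _features(self, rng, n=200, delta=(2.0, 0.0), cov=None):
        cov = np.eye(2) if cov is None else np.asarray(cov)
        chol = np.linalg.cholesky(cov)
        xa = rng.standard_normal((n, 2)) @ chol.T
        xb = rng.standard_normal((n, 2)) @ chol.T + np.asarray(delta)
        return cd.FeatureTable(
            matrix=np.vstack([xa, xb]),
            provenance=[{"modality": "erp", "channel": c} for c in ("a", "b")],
            labels=np.array(["NT"] * n + ["DT"] * n),
        )

    def test_full_shrinkage_reduces_to_mean_difference(self):
        rng = np.random.default_rng(6)
        feats = self._features(rng, cov=[[2.0, 0.9], [0.9, 1.0]])
        model = cd.lda_train(feats, ("NT", "DT"), shrinkage=1.0)
        mu_diff = model.means["DT"] - model.means["NT"]
        cos = model.weights @ mu_diff / (
            np.linalg.norm(model.weights) * np.linalg.norm(mu_diff)
        )
        assert cos > 0.9999

    def test_recovers_bayes_discriminant_direction(self):
        """Oracle: the closed-form discriminant Σ⁻¹Δμ of the generating
        Gaussians; the learned weights agree within 5°."""
        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        feats = self._features(rng, n=1000, delta=(1.5, -0.5), cov=cov)
        model = cd.lda_train(feats, ("NT", "DT"))
        w_true = np.linalg.solve(cov, np.array([1.5, -0.5]))
        cos = abs(model.weights @ w_true) / (
            np.linalg.norm(model.weights) * np.linalg.norm(w_true)
        )
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_agrees_with_reference_shrinkage_lda(self):
        """Cross-check against an independent shrinkage-LDA implementation
        (least-squares solver with analytic shrinkage)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(8)
        feats = self._features(rng, n=150, cov=[[2.0, 0.8], [0.8, 1.0]])
        model = cd.lda_train(feats, ("NT", "DT"))
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        ref.fit(feats.matrix, (feats.labels == "DT").astype(int))
        cos = abs(model.weights @ ref.coef_[0]) / (
            np.linalg.norm(model.weights) * np.linalg.norm(ref.coef_[0])
        )
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_identical_means_score_at_chance(self):
        rng = np.random.default_rng(9)
        feats = self._features(rng, delta=(0.0, 0.0))
        model = cd.lda_train(feats, ("NT", "DT"))
        scores = model.decision_values(feats.matrix)
        assert abs(cd.auc(scores, feats.labels == "DT") - 0.5) < 0.1

    def test_single_class_raises(self):
        rng = np.random.default_rng(10)
        feats = self._features(rng)
        feats.labels[:] = "NT"
        with pytest.raises(cd.MissingClassError):
            cd.lda_train(feats, ("NT", "DT"))


class TestAUC:
    def test_perfect_separation(self):
        assert cd.auc(np.array([1, 2, 3, 10, 11]), np.array([0, 0, 0, 1, 1], bool)) == 1.0

    def test_all_ties_give_half(self):
        assert cd.auc(np.zeros(6), np.array([0, 0, 0, 1, 1, 1], bool)) == 0.5

    def test_worked_example(self):
        # positives {0.35, 0.8} vs negatives {0.1, 0.4}: 3 of 4 pairs won
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1], bool)
        assert cd.auc(scores, labels) == 0.75

    def test_matches_roc_integration_on_random_sets(self):
        """Oracle equivalence: normalized U statistic equals trapezoidal ROC
        integration on 1000 random score/label sets (ties included)."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = np.zeros(n, bool)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert cd.auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(cd.MissingClassError):
            cd.auc(np.arange(4.0), np.ones(4, bool))


class TestPermutationTest:
    def test_detects_real_separation_and_accepts_null(self):
        rng = np.random.default_rng(12)
        labels = np.repeat([False, True], 50)
        strong = np.where(labels, 2.0, 0.0) + 0.3 * rng.standard_normal(100)
        null = rng.standard_normal(100)
        assert cd.auc_permutation_pvalue(strong, labels, 200, seed=1) < 0.01
        assert cd.auc_permutation_pvalue(null, labels, 200, seed=1) > 0.05


class TestCrossValidation:
    def test_stratified_folds_partition_every_trial_once(self):
        rng = np.random.default_rng(13)
        labels = np.array(["NT"] * 90 + ["DT"] * 15)
        folds = _stratified_folds(labels, 10, rng)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 105
        assert len(np.unique(all_idx)) == 105
        for f in folds:
            assert (labels[f] == "DT").sum() >= 1  # stratification

    def test_too_few_trials_for_stratification(self):
        rng = np.random.default_rng(14)
        labels = np.array(["NT"] * 50 + ["DT"] * 5)
        with pytest.raises(cd.InvalidConfigurationError):
            _stratified_folds(labels, 10, rng)

    def test_no_leakage_from_test_labels(self, clean_epochs):
        """Corrupting the held-out trials' labels leaves the trained model
        bit-identical (training never sees them)."""
        cfg = cd.DecodingConfig(n_folds=5, n_repetitions=1, seed=0)
        pair = ("NT", "DT")
        sub = clean_epochs.select_classes(pair)
        rng = np.random.default_rng(0)
        folds = _stratified_folds(sub.labels, 5, rng)
        test_idx = folds[0]
        train_idx = np.setdiff1d(np.arange(sub.n_trials), test_idx)
        from cogdepth.decoding import _band_filtered_cache, _subset

        def fit(epochs):
            cache = _band_filtered_cache(epochs, cfg)
            train = _subset(epochs, train_idx)
            test = _subset(epochs, test_idx)
            ftr, _ = _fold_features(
                train, test, cache, train_idx, test_idx, pair, cfg, None, {}
            )
            return cd.lda_train(ftr, pair).weights

        w_clean = fit(sub)
        corrupted = sub.copy()
        corrupted.labels[test_idx] = np.where(
            corrupted.labels[test_idx] == "NT", "DT", "NT"
        )
        w_corrupt = fit(corrupted)
        assert np.array_equal(w_clean, w_corrupt)

    def test_report_bookkeeping(self, clean_epochs):
        cfg = cd.DecodingConfig(n_folds=5, n_repetitions=2, seed=3)
        rep = cd.crossvalidate(clean_epochs, ("NT", "DT"), cfg)
        assert rep.aucs.shape == (2, 5)
        assert 0.0 <= rep.mean_auc <= 1.0
        assert rep.seed == 3
        assert rep.config_fingerprint == cfg.fingerprint()

    def test_same_seed_reproduces_report(self, clean_epochs):
        cfg = cd.DecodingConfig(n_folds=5, n_repetitions=2, seed=4)
        a = cd.crossvalidate(clean_epochs, ("NT", "DT"), cfg)
        b = cd.crossvalidate(clean_epochs, ("NT", "DT"), cfg)
        assert np.array_equal(a.aucs, b.aucs)

    def test_decoding_improves_with_effect_size(self):
        """3-point monotonicity: larger injected ERP/ERD effects give larger
        cross-validated AUC."""
        timing = cd.TimingConfig(sampling_rate_hz=200.0)
        seq = cd.generate_stimulus_sequence(n_runs=1, n_total=200, seed=30)
        cfg = cd.DecodingConfig(n_folds=5, n_repetitions=2, seed=0)
        aucs = []
        for gain in (0.0, 2.0, 6.0):
            fx = cd.EffectSpec(
                erp_peak1_amp={"NT": 0.0, "ST": 0.0, "DT": 0.0},
                erp_peak2_amp={"NT": 0.0, "ST": 0.0, "DT": gain},
                erd={
                    "alpha": {
                        "NT": cd.ErdSpec(0.0, 0.0),
                        "ST": cd.ErdSpec(0.0, 0.0),
                        "DT": cd.ErdSpec(min(0.2 * gain, 0.9), 600.0),
                    },
                    "beta": {c: cd.ErdSpec(0.0, 0.0) for c in ("NT", "ST", "DT")},
                },
            )
            rec = cd.generate_continuous_eeg(seq, timing, fx, n_channels=16, seed=31)
            ep = cd.preprocess(rec, target_fs=100.0)
            aucs.append(cd.crossvalidate(ep, ("NT", "DT"), cfg).mean_auc)
        assert aucs[0] < aucs[1] < aucs[2]
        assert abs(aucs[0] - 0.5) < 0.12  # zero effect ⇒ chance


class TestEOGControl:
    def test_mode_marked_and_runs(self, clean_epochs):
        cfg = cd.DecodingConfig(
            modalities=("erp",), n_folds=5, n_repetitions=1, seed=0
        )
        rep = cd.channel_subset_control(clean_epochs, ("NT", "DT"), cfg)
        assert rep.mode == "EOG-control"
        assert rep.aucs.shape == (1, 5)

    def test_missing_channels_rejected(self, noise_epochs):
        with pytest.raises(cd.InvalidConfigurationError):
            cd.channel_subset_control(noise_epochs, ("NT", "DT"))
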