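"""CCA filter bank, canonical-correlation features, LDA, cross-validation."""

import numpy as np
import pytest
from scipy import linalg

from ssvepnav import (
    CLASSES,
    SsvepDecoder,
    build_reference,
    crossval_accuracy,
    extract_features,
    fit_cca,
    train_decoder,
    train_filter_bank,
    train_lda,
)


def cca_eigen_oracle(X, Y):
    """Independent CCA route: the generalized eigenproblem
    Cxy Cyy^-1 Cyx a = rho^2 Cxx a formed from explicit covariance blocks."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    T = X.shape[1]
    Cxx = Xc @ Xc.T / (T - 1)
    Cyy = Yc @ Yc.T / (T - 1)
    Cxy = Xc @ Yc.T / (T - 1)
    M = Cxy @ np.linalg.solve(Cyy, Cxy.T)
    w = linalg.eigh(M, Cxx, eigvals_only=True)
    rho2 = np.sort(w)[::-1][: min(X.shape[0], Y.shape[0])]
    return np.sqrt(np.clip(rho2, 0.0, 1.0))


class TestReferenceSignal:
    def test_first_column_is_sin0_cos0_pattern(self):
        ref = build_reference(15.0, 512.0, 100, t0=0.0)
        np.testing.assert_allclose(ref.Y[:, 0], [0, 1, 0, 1, 0, 1], atol=1e-12)

    def test_fundamental_period(self):
        ref = build_reference(15.0, 512.0, 2048, t0=0.0)
        k = np.arange(2048)
        np.testing.assert_allclose(ref.Y[0], np.sin(2 * np.pi * 15 * k / 512), atol=1e-12)

    def test_rows_orthogonal_over_integer_cycles(self):
        ref = build_reference(16.0, 512.0, 512, t0=0.0)  # 16 full cycles
        G = ref.Y @ ref.Y.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-9

    def test_onset_offset_shifts_phase(self):
        a = build_reference(15.0, 512.0, 512, t0=0.0)
        b = build_reference(15.0, 512.0, 512, t0=0.5)
        assert not np.allclose(a.Y[0], b.Y[0])
        np.testing.assert_allclose(b.Y[0, 0], np.sin(2 * np.pi * 15 * 0.5), atol=1e-12)

    def test_aliasing_harmonic_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_reference(15.0, 80.0, 100, n_harmonics=3)


class TestFitCca:
    def test_identity_case_all_correlations_one(self):
        ref = build_reference(15.0, 512.0, 1024)
        _, _, rho = fit_cca(ref.Y.copy(), ref.Y.copy())
        np.testing.assert_allclose(rho, 1.0, atol=1e-8)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_generalized_eigen_oracle(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.standard_normal((8, 500))
        Y = rng.standard_normal((6, 500))
        _, _, rho = fit_cca(X, Y)
        np.testing.assert_allclose(rho, cca_eigen_oracle(X, Y), atol=1e-8)
        assert np.all(np.diff(rho) <= 1e-12)  # sorted descending
        assert np.all((rho >= 0) & (rho <= 1))

    def test_matches_sklearn_cca_first_component(self):
        from sklearn.cross_decomposition import CCA

        rng = np.random.default_rng(0)
        Z = rng.standard_normal((1, 400))
        X = rng.standard_normal((5, 400)) + 2 * Z
        Y = rng.standard_normal((4, 400)) + 2 * Z
        _, _, rho = fit_cca(X, Y)
        cca = CCA(n_components=1, tol=1e-12, max_iter=5000).fit(X.T, Y.T)
        u, v = cca.transform(X.T, Y.T)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert rho[0] == pytest.approx(r_sk, abs=1e-6)

    def test_correlations_invariant_under_channel_mixing(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 600))
        Y = rng.standard_normal((6, 600))
        M = rng.standard_normal((8, 8)) + 8 * np.eye(8)  # invertible mixing
        _, _, rho1 = fit_cca(X, Y)
        _, _, rho2 = fit_cca(M @ X, Y)
        np.testing.assert_allclose(rho1, rho2, atol=1e-8)

    def test_sign_convention_largest_eeg_weight_positive(self):
        rng = np.random.default_rng(4)
        A, _, _ = fit_cca(rng.standard_normal((8, 500)), rng.standard_normal((6, 500)))
        for row in A:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_deficient_covariance_warns_and_solves(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 300))
        X = np.vstack([X, X[0]])  # duplicated channel -> singular Cxx
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            _, _, rho = fit_cca(X, rng.standard_normal((3, 300)))
        assert np.all(np.isfinite(rho))

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            fit_cca(rng.standard_normal((8, 10)), rng.standard_normal((6, 10)))


class TestFilterBank:
    def test_own_class_filters_correlate_best(self, small_clean):
        """For each class c, c's trials filtered by c's own (A_c, B_c) attain a
        higher top canonical correlation than under any other class's filters."""
        bank = train_filter_bank(small_clean)
        ref = bank.reference()

        def top_corr(ci, trials):
            X = np.concatenate(list(trials), axis=1)
            Y = np.tile(ref.Y, (1, trials.shape[0]))
            u = bank.A[ci, 0] @ X
            v = bank.B[ci, 0] @ Y
            return abs(np.corrcoef(u, v)[0, 1])

        for ci, c in enumerate(CLASSES):
            trials = small_clean.class_trials(c)
            own = top_corr(ci, trials)
            for cj in range(4):
                if cj != ci:
                    assert own > top_corr(cj, trials)

    def test_trial_order_irrelevant(self, small_clean):
        bank1 = train_filter_bank(small_clean)
        perm = np.random.default_rng(0).permutation(small_clean.n_trials)
        bank2 = train_filter_bank(small_clean.select(perm))
        np.testing.assert_allclose(bank1.A, bank2.A, atol=1e-8)
        np.testing.assert_allclose(bank1.rho, bank2.rho, atol=1e-10)

    def test_single_class_input_rejected(self, small_clean):
        only_n = small_clean.select(np.flatnonzero(small_clean.labels == "N"))
        with pytest.raises(ValueError, match="trials"):
            train_filter_bank(only_n)


class TestFeatures:
    def test_own_class_block_dominates_for_noiseless_trial(self, small_clean):
        """A trial built as topography x reference mixture scores highest in
        its own class's feature block."""
        bank = train_filter_bank(small_clean)
        ref = bank.reference()
        for ci in range(4):
            trial = bank.A[ci, 0][:, None] * (bank.B[ci, 0] @ ref.Y)[None, :]
            feats = extract_features(trial, bank)
            blocks = feats.reshape(4, -1)
            assert blocks[ci, 0] == pytest.approx(1.0, abs=1e-6)
            assert np.argmax(blocks[:, 0]) == ci

    def test_all_zero_trial_maps_to_zero_features(self, small_clean):
        bank = train_filter_bank(small_clean)
        feats = extract_features(np.zeros((small_clean.n_channels, bank.n_samples)), bank)
        assert np.all(feats == 0.0)

    def test_amplitude_scale_invariance(self, small_clean):
        bank = train_filter_bank(small_clean)
        trial = small_clean.data[0]
        f1 = extract_features(trial, bank)
        f2 = extract_features(1e3 * trial, bank)
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_features_bounded_unit_interval(self, small_clean):
        bank = train_filter_bank(small_clean)
        for trial in small_clean.data[:8]:
            f = extract_features(trial, bank)
            assert np.all((f >= 0) & (f <= 1))
            assert f.size == 4 * bank.A.shape[1]

    def test_first_component_mode_gives_4_features(self, small_clean):
        bank = train_filter_bank(small_clean, feature_mode="first")
        assert extract_features(small_clean.data[0], bank).size == 4

    def test_sample_count_mismatch_rejected(self, small_clean):
        bank = train_filter_bank(small_clean)
        with pytest.raises(ValueError, match="samples"):
            extract_features(np.zeros((small_clean.n_channels, 10)), bank)


class TestLda:
    def test_separated_gaussians_training_accuracy_100(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 3)), rng.normal(5, 0.1, (50, 3))])
        y = np.array(["N"] * 50 + ["E"] * 50, dtype=object)
        model = train_lda(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_identical_features_fall_back_to_prior_argmax(self):
        X = np.ones((40, 3))
        y = np.array(list(CLASSES) * 10, dtype=object)
        equal = train_lda(X, y)
        assert equal.predict(np.ones((1, 3)))[0] == "N"  # tie -> lowest index
        skewed = train_lda(X, y, priors=np.array([0.1, 0.7, 0.1, 0.1]))
        assert skewed.predict(np.ones((1, 3)))[0] == "E"

    def test_gamma_one_equals_nearest_class_mean(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 4))
        y = np.array(list(CLASSES) * 20, dtype=object)
        model = train_lda(X, y, gamma=1.0, priors=np.full(4, 0.25))
        Q = rng.standard_normal((30, 4))
        dists = np.stack([np.linalg.norm(Q - m, axis=1) for m in model.means])
        nearest = np.array([model.classes[i] for i in np.argmin(dists, axis=0)])
        assert np.array_equal(model.predict(Q), nearest)

    def test_matches_sklearn_lda_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(2)
        centers = rng.normal(0, 2, (4, 6))
        X = np.vstack([rng.normal(c, 1.0, (40, 6)) for c in centers])
        y = np.repeat(list(CLASSES), 40).astype(object)
        mine = train_lda(X, y, gamma=0.0, priors=np.full(4, 0.25))
        sk = LinearDiscriminantAnalysis(solver="lsqr", priors=np.full(4, 0.25)).fit(
            X, y.astype(str)
        )
        Q = rng.standard_normal((100, 6))
        assert np.mean(mine.predict(Q).astype(str) == sk.predict(Q)) > 0.99

    def test_absent_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["N"] * 10, dtype=object)
        with pytest.raises(ValueError):
            train_lda(X, y, classes=CLASSES)

    def test_covariance_positive_definite_after_shrinkage(self, small_clean):
        dec = train_decoder(small_clean)
        w = np.linalg.eigvalsh(dec.lda.covariance)
        assert np.all(w > 0)
        assert dec.lda.priors.sum() == pytest.approx(1.0)


class TestDecoder:
    def test_high_snr_trials_decoded_correctly(self, small_clean, small_sim, small_params):
        from ssvepnav import preprocess_online

        dec = train_decoder(small_clean)
        rng = np.random.default_rng(99)
        test = small_sim.generate_session(30, seed=555)  # 120 fresh trials
        test = preprocess_online(test, small_params)
        assert dec.accuracy(test) > 0.95

    def test_prediction_deterministic(self, small_clean):
        dec = train_decoder(small_clean)
        trial = small_clean.data[0]
        assert dec.predict(trial) == dec.predict(trial)

    def test_serialization_roundtrip_bit_exact(self, small_clean, tmp_path):
        dec = train_decoder(small_clean)
        path = dec.save(tmp_path / "model")
        loaded = SsvepDecoder.load(path)
        p1 = dec.predict_set(small_clean)
        p2 = loaded.predict_set(small_clean)
        assert np.array_equal(p1, p2)
        np.testing.assert_array_equal(dec.lda.coef_, loaded.lda.coef_)


class TestCrossValidation:
    def test_signal_free_data_at_chance_level(self, noise_only_session, small_params):
        from ssvepnav import preprocess_training

        clean, _ = preprocess_training(noise_only_session, small_params)
        acc = crossval_accuracy(clean, k_folds=5, seed=0)
        # 95% binomial band around 0.25 for 40 trials
        half = 1.96 * np.sqrt(0.25 * 0.75 / clean.n_trials)
        assert 0.25 - half <= acc <= 0.25 + half
        assert 0.0 <= acc <= 1.0

    def test_label_shuffle_kills_accuracy(self, small_clean):
        """No-leakage control: shuffling labels drops cross-validated accuracy
        to the chance band even though the signals are perfectly decodable."""
        shuffled = small_clean.select(np.arange(small_clean.n_trials))
        rng = np.random.default_rng(8)
        shuffled.labels = rng.permutation(shuffled.labels)
        acc = crossval_accuracy(shuffled, k_folds=5, seed=0)
        half = 1.96 * np.sqrt(0.25 * 0.75 / shuffled.n_trials)
        assert acc <= 0.25 + half

    def test_high_snr_crossval_accuracy(self, small_clean):
        assert crossval_accuracy(small_clean, k_folds=5, seed=0) >= 0.95


def test_accuracy_monotone_in_snr():
    """Seed-averaged decoder accuracy is non-decreasing in simulator SNR."""
    from ssvepnav import PreprocessParams, SimConfig, Simulator, preprocess_training

    snrs = [-20.0, -10.0, 0.0, 10.0]
    acc = np.zeros((6, len(snrs)))
    params = PreprocessParams(fs_out=128.0)
    for si, seed in enumerate(range(6)):
        for gi, snr in enumerate(snrs):
            sim = Simulator(SimConfig(fs=256.0, epoch_dur=4.0, snr_db=snr, seed=seed))
            clean, _ = preprocess_training(sim.generate_session(15, seed=seed + 100), params)
            acc[si, gi] = crossval_accuracy(clean, k_folds=4, seed=0)
    means = acc.mean(axis=0)
    assert np.all(np.diff(means) >= 0), f"accuracy not monotone in SNR: {means}"
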