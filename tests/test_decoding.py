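"""SVR decoding: recovery on linear generators, null behavior, shuffle
controls, band restriction, generic and cross-subject decoding."""

import numpy as np
import pandas as pd
import pytest

from stnmes.decoding import (
    aligned_xy,
    apply_generic,
    band_mes_correlations,
    band_restricted_decoding,
    broadband_vs_band,
    build_generic_model,
    cross_decode,
    shuffle_control,
    train_svr_decoder,
)
from stnmes.mes import MESeries
from stnmes.spectral import SpectralFeatures, build_band_scheme


def _features(values: np.ndarray, epoch_len=7.0) -> SpectralFeatures:
    scheme = build_band_scheme()
    n = len(values)
    starts = epoch_len * np.arange(n)
    return SpectralFeatures(
        times=np.column_stack([starts, starts + epoch_len]),
        values=pd.DataFrame(values, columns=list(scheme.feature_names)),
        scheme=scheme,
        epoch_len=epoch_len,
    )


def _linear_instance(rng, n=200, noise=0.1, w=None):
    x = rng.normal(0, 1, (n, 42))
    if w is None:
        w = rng.normal(0, 1, 42)
    y = x @ w
    y = y / y.std()
    y = y + noise * rng.normal(size=n)
    return x, y, w


def _ols_cv_r(x, y, n_folds, seed):
    """Ordinary-least-squares oracle on the same Monte Carlo splits."""
    from stnmes.decoding import _fold_splits, _pearson

    rs = []
    for tr, te in _fold_splits(len(y), n_folds, (2, 1), seed):
        xm, xs = x[tr].mean(0), x[tr].std(0)
        xs = np.where(xs < 1e-12, 1.0, xs)
        z_tr = (x[tr] - xm) / xs
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(tr)), z_tr]), y[tr], rcond=None
        )
        pred = np.column_stack([np.ones(len(te)), (x[te] - xm) / xs]) @ coef
        rs.append(_pearson(pred, y[te]))
    return float(np.nanmean(rs))


class TestTrainDecoder:
    def test_linear_generator_recovered_and_matches_ols_oracle(self):
        rng = np.random.default_rng(0)
        x, y, _ = _linear_instance(rng, noise=0.1)
        res = train_svr_decoder(x, y, n_folds=50, seed=1)
        assert res.mean_r >= 0.9
        assert abs(res.mean_r - _ols_cv_r(x, y, 50, 1)) <= 0.05

    def test_independent_features_decode_at_chance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (120, 42))
        y = rng.normal(0, 1, 120)
        res = train_svr_decoder(x, y, n_folds=100, seed=2)
        assert -0.1 <= res.mean_r <= 0.1

    def test_coefficient_signs_follow_generating_weights(self):
        rng = np.random.default_rng(2)
        w = np.zeros(42)
        w[:7] = 1.0
        w[35:] = -1.0
        x, y, _ = _linear_instance(rng, n=300, noise=0.3, w=w)
        res = train_svr_decoder(x, y, n_folds=30, seed=3)
        mc = res.mean_coef()
        assert (mc[:7] > 0).all() and (mc[35:] < 0).all()

    def test_duplicated_feature_leaves_rbf_accuracy_unchanged(self):
        rng = np.random.default_rng(3)
        x, y, _ = _linear_instance(rng, n=150, noise=0.3)
        r1 = train_svr_decoder(x, y, kernel="rbf", n_folds=40, seed=4).mean_r
        x_dup = np.column_stack([x, x[:, 0]])
        r2 = train_svr_decoder(x_dup, y, kernel="rbf", n_folds=40, seed=4).mean_r
        assert abs(r1 - r2) < 0.05

    def test_same_seed_reproduces_mean_r_exactly(self):
        rng = np.random.default_rng(4)
        x, y, _ = _linear_instance(rng, n=100)
        a = train_svr_decoder(x, y, n_folds=20, seed=7)
        b = train_svr_decoder(x, y, n_folds=20, seed=7)
        assert a.mean_r == b.mean_r
        assert np.array_equal(a.coefs, b.coefs)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            train_svr_decoder(np.zeros((10, 42)), np.zeros(10))

    def test_rbf_coefs_absent(self):
        rng = np.random.default_rng(5)
        x, y, _ = _linear_instance(rng, n=60)
        res = train_svr_decoder(x, y, kernel="rbf", n_folds=5, seed=0)
        assert res.coefs is None
        with pytest.raises(ValueError, match="linear"):
            res.mean_coef()


class TestBandCorrelations:
    def test_rank_identities(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (60, 42))
        feats = _features(vals)
        theta_mean = vals[:, :7].mean(axis=1)
        mes = MESeries(times=feats.times, mes=theta_mean, epoch_len=7.0)
        df = band_mes_correlations(feats, mes).set_index("band")
        assert df.loc["theta_alpha", "rho"] == pytest.approx(1.0)
        vhf_mean = vals[:, 35:].mean(axis=1)
        mes2 = MESeries(times=feats.times, mes=-vhf_mean, epoch_len=7.0)
        df2 = band_mes_correlations(feats, mes2).set_index("band")
        assert df2.loc["vhf", "rho"] == pytest.approx(-1.0)

    def test_null_significant_fraction_small(self):
        rng = np.random.default_rng(7)
        sig = 0
        total = 0
        for k in range(40):
            feats = _features(rng.normal(0, 1, (40, 42)))
            mes = MESeries(times=feats.times, mes=rng.normal(0, 1, 40), epoch_len=7.0)
            df = band_mes_correlations(feats, mes)
            sig += df["significant"].sum()
            total += len(df)
        assert sig / total < 0.1

    def test_too_few_epochs_rejected(self):
        feats = _features(np.zeros((10, 42)))
        mes = MESeries(times=feats.times, mes=np.zeros(10), epoch_len=7.0)
        with pytest.raises(ValueError, match="epochs"):
            band_mes_correlations(feats, mes)


class TestShuffleControl:
    def test_strong_generator_beats_every_shuffle(self):
        rng = np.random.default_rng(8)
        x, y, _ = _linear_instance(rng, n=100, noise=0.1)
        res = shuffle_control(x, y, n_shuffles=30, seed=9, n_folds=20)
        assert (res.observed.mean_r > res.null_mean_r).all()
        assert res.p_mannwhitney < 0.001
        assert res.p_empirical == pytest.approx(1.0 / 31.0)

    def test_null_distribution_centered(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (90, 42))
        y = rng.normal(0, 1, 90)
        res = shuffle_control(x, y, n_shuffles=50, seed=10, n_folds=20)
        assert abs(res.null_mean_r.mean()) <= 0.05

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError, match="n_shuffles"):
            shuffle_control(np.zeros((40, 42)), np.zeros(40), n_shuffles=0)


class TestBandRestriction:
    def test_unknown_band_rejected(self):
        rng = np.random.default_rng(10)
        feats = _features(rng.normal(0, 1, (40, 42)))
        mes = MESeries(times=feats.times, mes=rng.normal(0, 1, 40), epoch_len=7.0)
        with pytest.raises(ValueError, match="unknown"):
            band_restricted_decoding(feats, mes, "delta")

    def test_single_band_generator_isolates_its_band(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1, (150, 42))
        y = vals[:, 7:14].mean(axis=1) + 0.2 * rng.normal(size=150)  # beta only
        feats = _features(vals)
        mes = MESeries(times=feats.times, mes=y, epoch_len=7.0)
        beta = band_restricted_decoding(feats, mes, "beta", seed=12, n_folds=30)
        vhf = band_restricted_decoding(feats, mes, "vhf", seed=12, n_folds=30)
        broadband = train_svr_decoder(feats, mes, seed=12, n_folds=30)
        assert beta.mean_r > 0.85
        assert abs(vhf.mean_r) < 0.15
        assert abs(beta.mean_r - broadband.mean_r) < 0.1

    def test_self_comparison_has_zero_differences(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, (60, 42))
        y = vals @ rng.normal(0, 1, 42)
        feats = _features(vals)
        mes = MESeries(times=feats.times, mes=y, epoch_len=7.0)
        a = train_svr_decoder(feats, mes, seed=13, n_folds=10)
        b = train_svr_decoder(feats, mes, seed=13, n_folds=10)
        assert np.allclose(a.fold_r - b.fold_r, 0.0)


class TestGenericAndCross:
    @staticmethod
    def _subject(rng, w, n=120, noise=0.4):
        x = rng.normal(0, 1, (n, 42))
        y = x @ w
        y = y / y.std() + noise * rng.normal(size=n)
        feats = _features(x)
        mes = MESeries(times=feats.times, mes=y, epoch_len=7.0)
        return feats, mes

    def test_single_contributor_generic_equals_its_vector(self):
        rng = np.random.default_rng(13)
        feats, mes = self._subject(rng, rng.normal(0, 1, 42))
        res = train_svr_decoder(feats, mes, n_folds=20, seed=14, subject_id="A")
        gm = build_generic_model([res])
        from stnmes.weight_stats import max_normalize

        assert np.allclose(gm.coef, max_normalize(res.mean_coef()))
        assert gm.intercept == 0.0

    def test_homogeneous_population_generic_matches_autologous(self):
        rng = np.random.default_rng(14)
        w = rng.normal(0, 1, 42)
        subjects = [self._subject(rng, w) for _ in range(4)]
        results = [
            train_svr_decoder(f, m, n_folds=20, seed=15, subject_id=f"S{i}")
            for i, (f, m) in enumerate(subjects)
        ]
        gm = build_generic_model(results)
        for (f, m), res in zip(subjects, results):
            assert apply_generic(gm, f, m) >= res.mean_r - 0.1

    def test_signbalanced_heterogeneous_population_defeats_generic(self):
        # opposite-coupling pairs: the population-mean coefficient vector
        # vanishes, so the generic decoder carries no usable signal while
        # each autologous decoder stays strong
        rng = np.random.default_rng(15)
        w = rng.normal(0, 1, 42)
        subjects = [self._subject(rng, sign * w, noise=0.2) for sign in (1, -1, 1, -1)]
        results = [
            train_svr_decoder(f, m, n_folds=20, seed=16, subject_id=f"S{i}")
            for i, (f, m) in enumerate(subjects)
        ]
        gm = build_generic_model(results)
        generic_rs = [abs(apply_generic(gm, f, m)) for f, m in subjects]
        auto_rs = [res.mean_r for res in results]
        assert max(generic_rs) < 0.5
        assert min(auto_rs) > 0.8

    def test_no_linear_results_rejected(self):
        rng = np.random.default_rng(16)
        feats, mes = self._subject(rng, rng.normal(0, 1, 42))
        res = train_svr_decoder(feats, mes, kernel="rbf", n_folds=5, seed=17)
        with pytest.raises(ValueError, match="linear"):
            build_generic_model([res])

    def test_cross_decode_single_subject(self):
        rng = np.random.default_rng(17)
        feats, mes = self._subject(rng, rng.normal(0, 1, 42))
        mat = cross_decode({"A": [(feats, mes)]}, n_folds=10, seed=18)
        assert mat.r.shape == (1, 1)
        assert mat.r[0, 0] > 0.7

    def test_identical_generators_transfer_across_subjects(self):
        rng = np.random.default_rng(18)
        w = rng.normal(0, 1, 42)
        a = self._subject(rng, w, noise=0.2)
        b = self._subject(rng, w, noise=0.2)
        mat = cross_decode({"A": [a], "B": [b]}, n_folds=15, seed=19)
        off = mat.off_diagonal
        assert np.min(off) > np.min(mat.diagonal) - 0.1

    def test_mismatched_feature_count_rejected(self):
        rng = np.random.default_rng(19)
        feats, mes = self._subject(rng, rng.normal(0, 1, 42))
        gm = build_generic_model(
            [train_svr_decoder(feats, mes, n_folds=5, seed=20, subject_id="A")]
        )
        with pytest.raises(ValueError, match="dimensionality"):
            apply_generic(gm, np.zeros((40, 10)), np.zeros(40))


class TestTimescaleSweep:
    def test_longer_epochs_average_out_fast_noise(
        self, pd_session, control_session
    ):
        from stnmes.decoding import timescale_sweep
        from stnmes.spectral import preprocess_lfp

        clean = preprocess_lfp(pd_session.lfp)
        sweep = timescale_sweep(
            pd_session.cursor,
            pd_session.target,
            control_session.cursor,
            control_session.target,
            clean,
            epoch_lens=[1.0, 3.0, 7.0],
            preprocessed=True,
            n_folds=30,
            mes_folds=20,
            seed=1,
        )
        assert set(sweep["epoch_len"]) == {1.0, 3.0, 7.0}
        r = sweep.set_index("epoch_len")["mean_r"]
        # the generator's latent has a 7 s correlation time: accuracy at
        # the matched timescale beats the 1 s timescale
        assert r[7.0] > r[1.0]

    def test_short_lengths_skipped_when_too_few_epochs(
        self, pd_session, control_session
    ):
        from stnmes.decoding import timescale_sweep
        from stnmes.spectral import preprocess_lfp

        clean = preprocess_lfp(pd_session.lfp)
        sweep = timescale_sweep(
            pd_session.cursor,
            pd_session.target,
            control_session.cursor,
            control_session.target,
            clean,
            epoch_lens=[7.0, 20.0],  # 300 s / 20 s = 15 epochs < 30
            preprocessed=True,
            n_folds=10,
            mes_folds=10,
            seed=1,
        )
        assert sweep["epoch_len"].tolist() == [7.0]


class TestAlignment:
    def test_row_alignment_drops_missing(self):
        rng = np.random.default_rng(20)
        x = rng.normal(0, 1, (50, 42))
        y = rng.normal(0, 1, 50)
        y[3] = np.nan
        x[7, 0] = np.nan
        xa, ya, _ = aligned_xy(x, y)
        assert len(ya) == 48

    def test_gross_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            aligned_xy(np.zeros((50, 42)), np.zeros(40))
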