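"""nCREANN: contrast signals, training data, order selection, the MLP
trainer, connectivity extraction and surrogate significance."""

import numpy as np
import pytest

from oddconn.ncreann import (
    ContrastSet,
    NetConfig,
    SubjectExcluded,
    build_training_data,
    contrast_trials,
    estimate_connectivity,
    extract_connectivity,
    select_model_order,
    surrogate_test,
    train_network,
)
from oddconn.synth import NmvarSpec, NonlinearTerm, simulate_nmvar

from conftest import make_epochs


def _contrast_from_series(x, fs=1.0):
    labels = tuple(f"ch{i}" for i in range(x.shape[0]))
    return ContrastSet(
        data=x[None],
        times=np.arange(x.shape[1], dtype=float),
        fs=fs,
        channel_labels=labels,
    )


FAST = NetConfig(max_epochs=40, patience=6, n_reps=2)
FAST1 = NetConfig(max_epochs=20, patience=4, n_reps=1)


class TestContrast:
    def test_deviants_equal_to_standard_mean_vanish(self):
        data = np.tile(np.sin(np.linspace(0, 5, 100)), (8, 2, 1))
        cond = np.array(["deviant" if i < 3 else "standard" for i in range(8)])
        cs = contrast_trials(make_epochs(data, condition=cond))
        assert np.allclose(cs.data, 0.0)
        assert cs.data.shape[0] == 3

    def test_contrast_mean_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((10, 3, 60))
        cond = np.array(["deviant" if i % 2 else "standard" for i in range(10)])
        ep = make_epochs(data, condition=cond)
        cs = contrast_trials(ep)
        dev_mean = data[cond == "deviant"].mean(axis=0)
        std_mean = data[cond == "standard"].mean(axis=0)
        assert np.allclose(cs.data.mean(axis=0), dev_mean - std_mean)

    def test_single_deviant_zero_standards_passthrough(self):
        data = np.zeros((3, 2, 50))
        data[1] = 7.0  # the deviant
        cond = np.array(["standard", "deviant", "standard"])
        cs = contrast_trials(make_epochs(data, condition=cond))
        assert np.allclose(cs.data[0], 7.0)

    def test_no_deviants_raises(self):
        ep = make_epochs(np.zeros((4, 2, 50)),
                         condition=np.array(["standard"] * 4))
        with pytest.raises(ValueError, match="deviant"):
            contrast_trials(ep)


class TestTrainingData:
    def test_row_count_two_trials(self):
        rng = np.random.default_rng(0)
        cs = ContrastSet(
            data=rng.standard_normal((2, 3, 100)),
            times=np.arange(100.0), fs=1.0, channel_labels=("a", "b", "c"),
        )
        td = build_training_data(cs, p=8, seed=0)
        assert td.X.shape == (184, 24)  # (100 - 8) * 2 rows
        assert td.Y.shape == (184, 3)

    def test_standardization(self):
        rng = np.random.default_rng(1)
        cs = ContrastSet(
            data=5 + 3 * rng.standard_normal((4, 2, 200)),
            times=np.arange(200.0), fs=1.0, channel_labels=("a", "b"),
        )
        td = build_training_data(cs, p=2, seed=0)
        flat = np.concatenate([td.Y, td.X[:, :2]])
        assert abs(flat.mean()) < 0.05
        assert abs(flat.std() - 1.0) < 0.05

    def test_rows_never_span_trial_boundaries(self):
        # two constant trials with distinct values: any row mixing them
        # would pair inputs from one trial with targets from the other
        data = np.stack([np.full((2, 20), -1.0), np.full((2, 20), 1.0)])
        cs = ContrastSet(data=data, times=np.arange(20.0), fs=1.0,
                         channel_labels=("a", "b"))
        td = build_training_data(cs, p=3, seed=0)
        signs = np.sign(td.X.sum(axis=1)) == np.sign(td.Y.sum(axis=1))
        assert signs.all()
        assert np.array_equal(np.bincount(td.seg_ids), [17, 17])

    def test_fold_assignment_reproducible_and_partitioned(self):
        rng = np.random.default_rng(2)
        cs = _contrast_from_series(rng.standard_normal((2, 500)))
        a = build_training_data(cs, p=4, seed=7)
        b = build_training_data(cs, p=4, seed=7)
        assert np.array_equal(a.folds, b.folds)
        n = a.X.shape[0]
        for r in range(a.folds.shape[0]):
            counts = np.bincount(a.folds[r], minlength=3)
            assert counts[0] == round(0.8 * n)
            assert counts[1] == round(0.1 * n)

    def test_order_exceeding_trial_length_raises(self):
        cs = ContrastSet(data=np.zeros((1, 2, 10)), times=np.arange(10.0),
                         fs=1.0, channel_labels=("a", "b"))
        with pytest.raises(ValueError, match="p"):
            build_training_data(cs, p=10, seed=0)


class TestOrderSelection:
    def test_var3_order_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = rng.normal(0, 0.25, (4, 4, 3))
            spec = NmvarSpec(M=4, p=3, A=A)
            rho = spec.spectral_radius()
            if rho >= 0.95:
                A = A * (0.85 / rho)
                spec = NmvarSpec(M=4, p=3, A=A)
            x = simulate_nmvar(spec, 8000, seed=seed + 50)
            sel = select_model_order(_contrast_from_series(x), p_max=6)
            hits += sel.chosen == 3
        assert hits >= 4

    def test_white_noise_prefers_order_one(self):
        x = np.random.default_rng(0).standard_normal((3, 8000))
        sel = select_model_order(_contrast_from_series(x), p_max=5)
        assert sel.chosen == 1 or np.all(np.diff(sel.bic) >= 0)

    def test_scores_finite(self):
        x = np.random.default_rng(1).standard_normal((2, 1000))
        sel = select_model_order(_contrast_from_series(x), p_max=4)
        assert np.all(np.isfinite(sel.aic))
        assert np.all(np.isfinite(sel.bic))


class TestTrainNetwork:
    def test_realizable_function_recovered(self):
        # targets generated exactly by a network of the same architecture
        rng = np.random.default_rng(0)
        from oddconn.ncreann import TrainingData

        n, n_in, hid, M = 4000, 4, 10, 2
        W1, b1 = rng.normal(0, 0.8, (hid, n_in)), rng.normal(0, 0.3, hid)
        W2, b2 = rng.normal(0, 0.8, (M, hid)), rng.normal(0, 0.1, M)
        X = rng.standard_normal((n, n_in))
        Y = np.tanh(X @ W1.T + b1) @ W2.T + b2
        folds = np.zeros((1, n), dtype=np.int8)
        perm = rng.permutation(n)
        folds[0, perm[int(0.8 * n):int(0.9 * n)]] = 1
        folds[0, perm[int(0.9 * n):]] = 2
        td = TrainingData(X=X, Y=Y, seg_ids=np.zeros(n, int), folds=folds,
                          mean=np.zeros(M), sd=np.ones(M), M=M, p=2)
        net = train_network(
            td, NetConfig(max_epochs=300, patience=20, n_reps=1), seed=0
        )
        assert net.best.mse_test < 0.01 * Y.var()

    def test_linear_var_matches_least_squares_r2(self):
        A = np.zeros((2, 2, 1))
        A[1, 0, 0], A[0, 0, 0], A[1, 1, 0] = 0.5, 0.4, -0.3
        x = simulate_nmvar(NmvarSpec(M=2, p=1, A=A), 6000, seed=1)
        td = build_training_data(_contrast_from_series(x), p=1, seed=0, n_reps=2)
        net = train_network(td, NetConfig(max_epochs=200, patience=10, n_reps=2),
                            seed=0)
        for r in range(2):
            tr, te = td.folds[r] == 0, td.folds[r] == 2
            coef, *_ = np.linalg.lstsq(td.X[tr], td.Y[tr], rcond=None)
            resid = td.Y[te] - td.X[te] @ coef
            sst = ((td.Y[te] - td.Y[te].mean(0)) ** 2).sum()
            r2_ls = 1.0 - (resid**2).sum() / sst
            assert net.reps[r].r2_test == pytest.approx(r2_ls, abs=0.05)

    def test_test_error_within_range_of_training_error(self):
        # the nMVAR validity criterion, checked on well-specified data
        A = np.zeros((3, 3, 2))
        A[1, 0, 0], A[2, 1, 1] = 0.4, 0.3
        x = simulate_nmvar(NmvarSpec(M=3, p=2, A=A), 6000, seed=2)
        td = build_training_data(_contrast_from_series(x), p=2, seed=0, n_reps=3)
        net = train_network(td, NetConfig(max_epochs=60, n_reps=3), seed=0)
        for rep in net.reps:
            ratio = rep.mse_test / rep.mse_train
            assert 1.0 / 1.5 <= ratio <= 1.5

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 1500))
        td = build_training_data(_contrast_from_series(x), p=2, seed=0, n_reps=1)
        n1 = train_network(td, FAST1, seed=5)
        n2 = train_network(td, FAST1, seed=5)
        assert np.array_equal(n1.best.W1, n2.best.W1)
        assert n1.best.mse_test == n2.best.mse_test


class TestExtractConnectivity:
    def test_zero_input_weights_give_zero_connectivity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 800))
        td = build_training_data(_contrast_from_series(x), p=2, seed=0, n_reps=1)
        net = train_network(td, FAST1, seed=0)
        for rep in net.reps:
            rep.W1[:] = 0.0
        res = extract_connectivity(net, td)
        assert np.allclose(res.lc, 0.0)
        assert np.allclose(res.nc, 0.0)

    def test_linear_var_direction_recovered(self):
        A = np.zeros((2, 2, 1))
        A[1, 0, 0] = 0.5
        x = simulate_nmvar(NmvarSpec(M=2, p=1, A=A), 6000, seed=4)
        td = build_training_data(_contrast_from_series(x), p=1, seed=0, n_reps=2)
        net = train_network(td, FAST, seed=0)
        res = extract_connectivity(net, td)
        assert res.lc[0, 1] > res.lc[1, 0]

    def test_lc_ranking_matches_coefficient_magnitudes(self):
        # off-diagonal lC ranking vs the coupling-magnitude ranking of the
        # generating VAR(2); the estimator z-scores channels, so the truth
        # is taken on the same (standardized) scale
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(3):
            rng = np.random.default_rng(seed + 10)
            A = rng.normal(0, 0.22, (4, 4, 2))
            spec = NmvarSpec(M=4, p=2, A=A)
            rho_s = spec.spectral_radius()
            if rho_s >= 0.95:
                A = A * (0.85 / rho_s)
                spec = NmvarSpec(M=4, p=2, A=A)
            x = simulate_nmvar(spec, 12_000, seed=seed)
            td = build_training_data(_contrast_from_series(x), p=2, seed=0,
                                     n_reps=2)
            net = train_network(
                td, NetConfig(max_epochs=150, patience=10, n_reps=2), seed=seed
            )
            res = extract_connectivity(net, td)
            A_std = A * (td.sd[None, :, None] / td.sd[:, None, None])
            truth = np.abs(A_std).sum(axis=2).T  # [i, j] = influence i -> j
            mask = ~np.eye(4, dtype=bool)
            rhos.append(spearmanr(truth[mask], res.lc[mask]).statistic)
        assert np.mean(rhos) > 0.8


class TestSurrogates:
    def test_circular_shift_preserves_spectrum(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        shifted = np.roll(x, 137)
        assert np.allclose(
            np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(shifted))
        )

    def test_planted_nonlinear_coupling_detected_directionally(self):
        spec = NmvarSpec(
            M=2, p=1, A=np.diag([0.3, 0.0])[:, :, None],
            nonlinear_terms=[NonlinearTerm(0, 1, 1, 0.8, "square")],
        )
        x = simulate_nmvar(spec, 4000, seed=3)
        res = surrogate_test(
            _contrast_from_series(x), p=1, config=FAST, n_surrogates=20,
            seed=0, surrogate_config=FAST1, surrogate_n_reps=1,
        )
        assert res.sig_nc[0, 1]
        assert not res.sig_nc[1, 0]
        assert res.nc[0, 1] > res.surrogate["nc_q95"][0, 1]

    def test_p_values_never_zero_and_bounded(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2000))
        res = surrogate_test(
            _contrast_from_series(x), p=1, config=FAST1, n_surrogates=20,
            seed=0, surrogate_config=FAST1, surrogate_n_reps=1,
        )
        for p in (res.p_lc, res.p_nc):
            assert np.all(p > 0.0)
            assert np.all(p <= 1.0)
            assert p.min() >= 1.0 / 21.0

    def test_too_few_surrogates_rejected(self):
        x = np.zeros((2, 100))
        with pytest.raises(ValueError, match="20"):
            surrogate_test(_contrast_from_series(x), p=1, n_surrogates=5, seed=0)


class TestEstimateConnectivity:
    def _epochs(self, n_ch=9, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((12, n_ch, 120))
        # planted lag-1 dependency FC -> MC
        data[:, 3, 1:] += 0.9 * data[:, 0, :-1]
        cond = np.array(["deviant" if i % 3 == 0 else "standard"
                         for i in range(12)])
        return make_epochs(data, condition=cond)

    def test_planted_dependency_top_ranked(self):
        ep = self._epochs()
        res = estimate_connectivity(
            ep, p=2, config=FAST, n_surrogates=20, seed=0,
            surrogate_config=FAST1, surrogate_n_reps=1,
        )
        mask = ~np.eye(9, dtype=bool)
        assert res.lc[0, 3] == res.lc[mask].max()

    def test_insufficient_channels_excluded(self):
        ep = self._epochs()
        ep = ep.copy_with(bad_channels=ep.channel_labels[7:] + ep.channel_labels[5:6])
        with pytest.raises(SubjectExcluded, match="insufficient"):
            estimate_connectivity(ep, p=2, config=FAST1, n_surrogates=20, seed=0)

    def test_missing_ninth_channel_interpolated_and_deterministic(self):
        ep = self._epochs().copy_with(bad_channels=("PR",))
        kw = dict(p=2, config=FAST1, n_surrogates=20, seed=1,
                  surrogate_config=FAST1, surrogate_n_reps=1)
        a = estimate_connectivity(ep, **kw)
        b = estimate_connectivity(ep, **kw)
        assert np.array_equal(a.lc, b.lc)
        assert np.array_equal(a.p_nc, b.p_nc)
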