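"""Generator contracts: determinism, marginals, batch-effect algebra, thresholding."""

import numpy as np
import pytest

from fedsim import (
    BatchEffectSpec,
    Dataset,
    LinearArch,
    LossSpec,
    accuracy,
    binarize_activation,
    client_moments,
    federated_pca,
    init_params,
    inject_batch_effect,
    local_step,
    local_znorm,
    make_blobs,
    make_expression,
    make_fingerprints,
    project,
)
from fedsim.partitioner import train_test_split


def _fit_linear(X, y, lr, rounds=50, seed=0):
    arch = LinearArch(X.shape[1], int(y.max()) + 1)
    params = init_params(arch, seed)
    loss = LossSpec("logistic", "sum")
    for _ in range(rounds):
        params = local_step(params, X, y, lr, loss)
    return params


class TestMakeBlobs:
    def test_separable_blobs_fit_by_logistic_regression(self):
        ds = make_blobs(n=200, d=2, C=2, separation=5.0, seed=1)
        params = _fit_linear(ds.X, ds.y, lr=0.01)
        assert accuracy(params, ds.X, ds.y) > 0.95

    def test_zero_separation_is_symmetric_chance(self):
        ds = make_blobs(n=4, d=1, C=2, separation=0.0, seed=7)
        big = make_blobs(n=2000, d=1, C=2, separation=0.0, seed=7)
        params = _fit_linear(ds.X, ds.y, lr=0.1, rounds=20)
        # any linear model is a coin flip when both class means coincide
        assert abs(accuracy(params, big.X, big.y) - 0.5) < 0.05

    def test_seeding_contract_bitwise(self):
        a = make_blobs(200, 3, 2, 2.0, seed=3)
        b = make_blobs(200, 3, 2, 2.0, seed=3)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)
        c = make_blobs(200, 3, 2, 2.0, seed=4)
        assert not np.array_equal(a.X, c.X)

    def test_class_counts_balanced_and_mean_distance(self):
        ds = make_blobs(n=303, d=6, C=3, separation=4.0, seed=0)
        counts = np.bincount(ds.y)
        assert counts.max() - counts.min() <= 1
        mus = np.array([ds.X[ds.y == c].mean(axis=0) for c in range(3)])
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(mus[i] - mus[j]) == pytest.approx(4.0, abs=0.6)

    @pytest.mark.parametrize("bad", [dict(n=0, d=2, C=2), dict(n=10, d=0, C=2),
                                     dict(n=1, d=2, C=2), dict(n=10, d=2, C=1)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            make_blobs(separation=1.0, seed=0, **bad)


class TestMakeExpression:
    def test_pca_pipeline_beats_raw_features(self):
        # oracle: run both centralized pipelines and compare test accuracy
        ds = make_expression(n=300, d=2000, k_informative=5, noise_sd=1.0, seed=1)
        train, test = train_test_split(ds, 0.8, seed=0)
        best_raw = max(
            accuracy(_fit_linear(train.X, train.y, lr, rounds=30), test.X, test.y)
            for lr in (1e-4, 1e-3, 1e-2)
        )
        Ztr, Zte = local_znorm(train.X), local_znorm(test.X)
        proj = federated_pca([client_moments(Ztr)], 100)
        Ptr, Pte = project(Ztr, proj), project(Zte, proj)
        best_pca = max(
            accuracy(_fit_linear(Ptr, train.y, lr, rounds=30), Pte, test.y)
            for lr in (1e-3, 1e-2)
        )
        assert best_pca - best_raw > 0.1

    def test_noiseless_full_rank_is_separable(self):
        ds = make_expression(n=50, d=50, k_informative=50, noise_sd=0.0, seed=2)
        params = _fit_linear(ds.X, ds.y, lr=1e-4, rounds=400)
        assert accuracy(params, ds.X, ds.y) == 1.0

    def test_seeding_contract(self):
        a = make_expression(60, 100, 5, 1.0, seed=5)
        b = make_expression(60, 100, 5, 1.0, seed=5)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_k_exceeding_d_rejected(self):
        with pytest.raises(ValueError):
            make_expression(50, 10, 11, 1.0, seed=0)


class TestMakeFingerprints:
    def test_density_and_label_marginals(self):
        ds = make_fingerprints(n=1000, d=64, density=0.1, class_imbalance=0.3, seed=1)
        assert ds.feature_kind == "sparse-binary"
        assert abs(ds.X.mean() - 0.1) < 0.02
        assert abs(ds.y.mean() - 0.3) < 0.05

    def test_density_boundary_all_zero(self):
        ds = make_fingerprints(n=20, d=16, density=1e-9, class_imbalance=0.5, seed=3)
        assert ds.X.sum() == 0

    def test_seeding_contract(self):
        a = make_fingerprints(100, 32, 0.2, 0.4, seed=9)
        b = make_fingerprints(100, 32, 0.2, 0.4, seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    @pytest.mark.parametrize("density,imbalance", [(0.0, 0.5), (1.0, 0.5),
                                                   (0.5, 0.0), (0.5, 1.0)])
    def test_open_interval_preconditions(self, density, imbalance):
        with pytest.raises(ValueError):
            make_fingerprints(100, 16, density, imbalance, seed=0)


class TestBinarizeActivation:
    def test_strictly_above_cutoff_is_active(self):
        assert binarize_activation([6.4]).tolist() == [1]

    def test_exactly_at_cutoff_is_inactive(self):
        assert binarize_activation([6.3]).tolist() == [0]

    def test_empty_and_nan(self):
        assert binarize_activation([]).size == 0
        with pytest.raises(ValueError):
            binarize_activation([6.0, np.nan])


class TestBatchEffect:
    def test_identity_effect_leaves_data_unchanged(self, binary_blobs):
        d = binary_blobs.n_features
        spec = BatchEffectSpec(shift=np.zeros((2, d)), scale=np.ones((2, d)),
                               groups=np.arange(binary_blobs.n_samples) % 2)
        out = inject_batch_effect(binary_blobs, spec)
        assert np.array_equal(out.X, binary_blobs.X)
        assert np.array_equal(out.y, binary_blobs.y)

    def test_additive_shift_moves_group_means_exactly(self, binary_blobs):
        d = binary_blobs.n_features
        groups = np.arange(binary_blobs.n_samples) % 2
        spec = BatchEffectSpec(
            shift=np.vstack([np.zeros(d), 10.0 * np.ones(d)]),
            scale=np.ones((2, d)), groups=groups,
        )
        out = inject_batch_effect(binary_blobs, spec)
        gap = out.X[groups == 1].mean(axis=0) - out.X[groups == 0].mean(axis=0)
        expected = (binary_blobs.X[groups == 1].mean(axis=0)
                    - binary_blobs.X[groups == 0].mean(axis=0) + 10.0)
        np.testing.assert_allclose(gap, expected, atol=1e-12)

    def test_per_group_znorm_restores_unit_moments(self, rng, binary_blobs):
        d = binary_blobs.n_features
        groups = np.arange(binary_blobs.n_samples) % 3
        spec = BatchEffectSpec(
            shift=rng.normal(scale=5, size=(3, d)),
            scale=np.exp(rng.normal(scale=0.5, size=(3, d))),
            groups=groups,
        )
        out = inject_batch_effect(binary_blobs, spec)
        for g in range(3):
            Z = local_znorm(out.X[groups == g])
            np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
            np.testing.assert_allclose(Z.var(axis=0), 1.0, atol=1e-9)

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            BatchEffectSpec(shift=np.zeros((1, 2)), scale=np.zeros((1, 2)),
                            groups=np.zeros(4, dtype=int))

    def test_dimension_mismatch_rejected(self, binary_blobs):
        spec = BatchEffectSpec(shift=np.zeros((1, 3)), scale=np.ones((1, 3)),
                               groups=np.zeros(binary_blobs.n_samples, dtype=int))
        with pytest.raises(ValueError):
            inject_batch_effect(binary_blobs, spec)


class TestDatasetIO:
    def test_csv_roundtrip_with_label_column(self, tmp_path, binary_blobs):
        path = tmp_path / "ds.csv"
        binary_blobs.to_csv(path)
        back = Dataset.from_csv(path)
        np.testing.assert_allclose(back.X, binary_blobs.X)
        assert np.array_equal(back.y, binary_blobs.y)
        assert back.meta["generator"] == "make_blobs"

    def test_sparse_binary_invariant_enforced(self):
        with pytest.raises(ValueError):
            Dataset(np.array([[0.5, 1.0]]), np.array([0]), "sparse-binary")
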