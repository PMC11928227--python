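"""Round-loop semantics: aggregation algebra, SCAFFOLD equations, degeneracies."""

import numpy as np
import pytest

from fedsim import (
    LinearArch,
    LossSpec,
    ModelParams,
    TrainConfig,
    fedavg_global_step,
    gradient,
    init_params,
    make_blobs,
    make_clients,
    run_centralized,
    run_federated,
    scaffold_global_step,
    scaffold_local_step,
)
from fedsim.harness import pooled_train_test
from fedsim.partitioner import PartitionSpec

ARCH1 = LinearArch(n_features=1, n_classes=1)  # scalar params for algebra tests
LOSS = LossSpec("logistic", "sum")


def _params(vals, arch=None):
    vals = np.atleast_1d(np.asarray(vals, dtype=float))
    if arch is None:
        arch = LinearArch(n_features=vals.size - 1, n_classes=1) \
            if vals.size > 1 else ARCH1
    return ModelParams(vals, arch)


@pytest.fixture
def ten_clients():
    ds = make_blobs(600, 6, 2, 3.0, seed=0)
    return make_clients(ds, PartitionSpec(kind="iid", N=10, seed=0))


class TestFedavgGlobalStep:
    def test_identical_models_unchanged(self):
        arch = LinearArch(2, 2)
        m = init_params(arch, 0)
        out = fedavg_global_step([m.copy(), m.copy(), m.copy()], [5, 2, 9])
        np.testing.assert_allclose(out.theta, m.theta)

    def test_weighted_two_client_example(self):
        out = fedavg_global_step([_params([1.0, 0.0]), _params([4.0, 0.0])], [2, 1])
        assert out.theta[0] == pytest.approx(2.0)

    def test_permutation_invariance_and_sum_oracle(self, rng):
        arch = LinearArch(3, 2)
        models = [ModelParams(rng.normal(size=arch.n_params), arch) for _ in range(5)]
        sizes = [3, 1, 4, 1, 5]
        out = fedavg_global_step(models, sizes)
        # brute-force weighted sum oracle
        expect = np.zeros(arch.n_params)
        for m, s in zip(models, sizes):
            expect += s * m.theta
        expect /= sum(sizes)
        np.testing.assert_allclose(out.theta, expect, rtol=1e-12)
        perm = [2, 0, 4, 1, 3]
        out2 = fedavg_global_step([models[i] for i in perm], [sizes[i] for i in perm])
        np.testing.assert_allclose(out2.theta, out.theta, rtol=1e-12)

    def test_convex_combination_bounds(self, rng):
        arch = LinearArch(4, 3)
        models = [ModelParams(rng.normal(size=arch.n_params), arch) for _ in range(4)]
        out = fedavg_global_step(models, [1, 2, 3, 4])
        stack = np.stack([m.theta for m in models])
        assert np.all(out.theta >= stack.min(axis=0) - 1e-12)
        assert np.all(out.theta <= stack.max(axis=0) + 1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fedavg_global_step([_params([1.0, 0.0])], [1, 2])


class TestScaffoldLocalStep:
    def test_zero_variates_reduce_to_fedavg_step(self, rng, binary_blobs):
        arch = LinearArch(binary_blobs.n_features, 2)
        W_g = init_params(arch, 0)
        zeros = np.zeros(arch.n_params)
        X, y = binary_blobs.X, binary_blobs.y
        W_new, c_new = scaffold_local_step(W_g, zeros, zeros, X, y, 0.01, LOSS)
        g = gradient(W_g, X, y, LOSS)
        np.testing.assert_allclose(W_new.theta, W_g.theta - 0.01 * g, rtol=1e-12)
        # new control variate equals the realized gradient
        np.testing.assert_allclose(c_new, g, rtol=1e-12)

    def test_fixed_point_when_gradient_zero_and_variates_equal(self):
        # large-margin hinge: zero gradient, equal variates cancel in the W
        # update; the variate update c' = c_i - c_g + (W_g - W_new)/eta is
        # self-consistent only at c = 0, the converged state
        X = np.array([[-3.0], [3.0]])
        y = np.array([0, 1])
        arch = LinearArch(1, 2)
        W_g = ModelParams(np.array([-1.0, 1.0, 0.0, 0.0]), arch)
        equal = np.full(4, 0.7)
        W_new, _ = scaffold_local_step(W_g, equal, equal, X, y, 0.5,
                                       LossSpec("hinge", "sum"))
        np.testing.assert_array_equal(W_new.theta, W_g.theta)
        zero = np.zeros(4)
        W_new, c_new = scaffold_local_step(W_g, zero, zero, X, y, 0.5,
                                           LossSpec("hinge", "sum"))
        np.testing.assert_array_equal(W_new.theta, W_g.theta)
        np.testing.assert_array_equal(c_new, zero)

    @pytest.mark.parametrize("variant", ["additive", "scaled"])
    def test_matches_formula_transcription_oracle(self, rng, variant, binary_blobs):
        # independent re-implementation of the two printed update equations
        arch = LinearArch(binary_blobs.n_features, 2)
        W_g = init_params(arch, 4)
        c_g = rng.normal(size=arch.n_params)
        c_i = rng.normal(size=arch.n_params)
        X, y = binary_blobs.X[:40], binary_blobs.y[:40]
        eta = 0.05
        W_new, c_new = scaffold_local_step(W_g, c_g, c_i, X, y, eta, LOSS,
                                           variant=variant)
        g = gradient(W_g, X, y, LOSS)
        if variant == "additive":
            expect_W = W_g.theta - eta * g + c_g - c_i
        else:
            expect_W = W_g.theta - eta * (g + c_g - c_i)
        expect_c = c_i - c_g + (W_g.theta - expect_W) / eta
        np.testing.assert_allclose(W_new.theta, expect_W, rtol=1e-10)
        np.testing.assert_allclose(c_new, expect_c, rtol=1e-10)


class TestScaffoldGlobalStep:
    def test_zero_deltas_leave_state_unchanged(self, rng):
        arch = LinearArch(2, 2)
        W_g = init_params(arch, 0)
        c_g = rng.normal(size=arch.n_params)
        cs = [rng.normal(size=arch.n_params) for _ in range(3)]
        W_new, c_new = scaffold_global_step(
            W_g, [W_g.copy()] * 3, W_g, c_g, cs, [c.copy() for c in cs], eta_g=1.0
        )
        np.testing.assert_allclose(W_new.theta, W_g.theta)
        np.testing.assert_allclose(c_new, c_g)

    def test_single_client_eta_one_telescopes(self, rng):
        arch = LinearArch(2, 2)
        W_g = init_params(arch, 0)
        W_i = ModelParams(rng.normal(size=arch.n_params), arch)
        zeros = np.zeros(arch.n_params)
        W_new, _ = scaffold_global_step(W_g, [W_i], W_g, zeros, [zeros], [zeros], 1.0)
        np.testing.assert_allclose(W_new.theta, W_i.theta, rtol=1e-12)

    def test_global_variate_is_client_mean_every_round(self):
        # induction over simulated rounds from zero initialization
        ds = make_blobs(200, 4, 2, 3.0, seed=1)
        clients = make_clients(ds, PartitionSpec(kind="ci", N=4, seed=0,
                                                 fraction_range=(0.1, 0.9)))
        arch = LinearArch(4, 2)
        W_g = init_params(arch, 0)
        c_g = np.zeros(arch.n_params)
        c_list = [np.zeros(arch.n_params) for _ in clients]
        for r in range(5):
            new_models, new_cs = [], []
            for c, ci in zip(clients, c_list):
                W_i, ci_new = scaffold_local_step(
                    W_g, c_g, ci, c.train.X, c.train.y, 0.01, LOSS)
                new_models.append(W_i)
                new_cs.append(ci_new)
            W_g, c_g = scaffold_global_step(W_g, new_models, W_g, c_g,
                                            c_list, new_cs, 1.0)
            c_list = new_cs
            # exact identity in real arithmetic; the 1/eta in the variate
            # update amplifies round-off, so compare relative to the
            # magnitude of the variates themselves
            scale = max(1.0, max(np.max(np.abs(c)) for c in new_cs))
            assert np.max(np.abs(c_g - np.mean(new_cs, axis=0))) <= 1e-9 * scale


class TestRunLoops:
    def test_single_client_fedavg_equals_centralized(self, binary_blobs):
        clients = make_clients(binary_blobs, PartitionSpec(kind="iid", N=1, seed=0))
        arch = LinearArch(binary_blobs.n_features, 2)
        cfg = TrainConfig(eta_l=0.02, rounds=15, seed=3)
        fed = run_federated(cfg, clients, arch, LOSS)
        train, test = pooled_train_test(clients)
        cen = run_centralized(cfg, train, test, arch, LOSS)
        np.testing.assert_array_equal(fed.global_accuracy, cen.global_accuracy)
        for a, b in zip(fed.global_params, cen.global_params):
            np.testing.assert_array_equal(a.theta, b.theta)

    def test_replicated_clients_match_solo_training(self, binary_blobs):
        # every client holds an identical copy: averaging is a no-op
        from fedsim.partitioner import ClientData, train_test_split

        tr, te = train_test_split(binary_blobs, 0.8, seed=0)
        solo = [ClientData(train=tr, test=te)]
        copies = [ClientData(train=tr, test=te) for _ in range(4)]
        arch = LinearArch(binary_blobs.n_features, 2)
        cfg = TrainConfig(eta_l=0.02, rounds=10, seed=1)
        a = run_federated(cfg, solo, arch, LOSS)
        b = run_federated(cfg, copies, arch, LOSS)
        for pa, pb in zip(a.global_params, b.global_params):
            np.testing.assert_allclose(pa.theta, pb.theta, atol=1e-12)

    def test_zero_rounds_reports_initial_model_only(self, ten_clients):
        arch = LinearArch(6, 2)
        cfg = TrainConfig(eta_l=0.1, rounds=0, seed=0)
        res = run_federated(cfg, ten_clients, arch, LOSS)
        assert len(res.global_accuracy) == 1
        assert res.client_accuracy == []

    def test_zero_learning_rate_flat_curve(self, ten_clients):
        arch = LinearArch(6, 2)
        cfg = TrainConfig(eta_l=0.0, rounds=5, seed=0)
        train, test = pooled_train_test(ten_clients)
        res = run_centralized(cfg, train, test, arch, LOSS)
        assert len(set(res.global_accuracy)) == 1

    def test_factor_n_learning_rate_equivalence(self, ten_clients):
        # full-batch sum-loss linear: federated at eta over N equal clients
        # equals centralized at eta/N, round for round
        arch = LinearArch(6, 2)
        fed = run_federated(TrainConfig(eta_l=0.5, rounds=8, seed=2),
                            ten_clients, arch, LOSS)
        train, test = pooled_train_test(ten_clients)
        cen = run_centralized(TrainConfig(eta_l=0.05, rounds=8, seed=2),
                              train, test, arch, LOSS)
        for a, b in zip(fed.global_params, cen.global_params):
            assert np.max(np.abs(a.theta - b.theta)) <= 1e-9

    def test_split_client_invariance(self, binary_blobs):
        # splitting one client into two equal halves leaves fedAVG unchanged
        from fedsim.partitioner import ClientData, train_test_split

        tr, te = train_test_split(binary_blobs, 0.8, seed=0)
        half = tr.n_samples // 2
        rows = np.arange(tr.n_samples)
        one = [ClientData(train=tr, test=te)]
        two = [ClientData(train=tr.subset(rows[:half]), test=te),
               ClientData(train=tr.subset(rows[half:]), test=te)]
        arch = LinearArch(binary_blobs.n_features, 2)
        cfg = TrainConfig(eta_l=0.01, rounds=6, seed=0)
        a = run_federated(cfg, one, arch, LOSS)
        cfg2 = TrainConfig(eta_l=0.02, rounds=6, seed=0)  # eta scales with N
        b = run_federated(cfg2, two, arch, LOSS)
        for pa, pb in zip(a.global_params, b.global_params):
            np.testing.assert_allclose(pa.theta, pb.theta, atol=1e-10)

    def test_scaffold_single_client_matches_fedavg(self, binary_blobs):
        clients = make_clients(binary_blobs, PartitionSpec(kind="iid", N=1, seed=0))
        arch = LinearArch(binary_blobs.n_features, 2)
        fed = run_federated(TrainConfig(eta_l=0.02, rounds=12, seed=5,
                                        aggregator="fedavg"), clients, arch, LOSS)
        sca = run_federated(TrainConfig(eta_l=0.02, rounds=12, seed=5,
                                        aggregator="scaffold", eta_g=1.0),
                            clients, arch, LOSS)
        for a, b in zip(fed.global_params, sca.global_params):
            np.testing.assert_allclose(a.theta, b.theta, atol=1e-10)

    def test_divergence_flagged_not_raised(self, ten_clients):
        arch = LinearArch(6, 2)
        cfg = TrainConfig(eta_l=1e12, rounds=40, seed=0)
        res = run_federated(cfg, ten_clients, arch, LOSS)
        # either the run diverges (flagged) or it survives; it must not raise
        assert isinstance(res.diverged, bool)

    def test_end_to_end_determinism(self, ten_clients):
        arch = LinearArch(6, 2)
        cfg = TrainConfig(eta_l=0.05, rounds=6, seed=9, n_batches=4)
        a = run_federated(cfg, ten_clients, arch, LOSS)
        b = run_federated(cfg, ten_clients, arch, LOSS)
        assert a.global_accuracy == b.global_accuracy
        for pa, pb in zip(a.global_params, b.global_params):
            np.testing.assert_array_equal(pa.theta, pb.theta)
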