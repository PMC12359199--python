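import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plddtkit.autodiff import Tensor
from plddtkit.egnn import (
    BinDistribution, BinWeights, HeadConfig, SQDIST_NORM,
    bins_to_plddt, compute_bin_weights, egcl_step, init_params, lddt_bin,
    load_params, predict, predict_plddt, save_params, train_head,
    weighted_bin_loss,
)
from plddtkit.features import ProteinGraph
from plddtkit.lddt import LDDTProfile
from plddtkit.synthetic import SyntheticSpec, make_dataset, training_pairs

from conftest import random_rigid_motion


def small_graph(seed=0, L=12):
    recs = make_dataset(1, (L, L), SyntheticSpec(), seed=seed)
    return recs[0].graph(), recs[0]


class TestBins:
    def test_plddt_readout(self):
        uniform = BinDistribution(np.full((1, 50), 1 / 50))
        assert bins_to_plddt(uniform)[0] == pytest.approx(50.0)
        hot49 = np.zeros((1, 50)); hot49[0, 49] = 1
        assert bins_to_plddt(BinDistribution(hot49))[0] == pytest.approx(99.0)
        hot0 = np.zeros((1, 50)); hot0[0, 0] = 1
        assert bins_to_plddt(BinDistribution(hot0))[0] == pytest.approx(1.0)

    def test_bin_closure(self):
        assert lddt_bin([0.0, 1.9, 2.0, 99.9, 100.0]).tolist() == [0, 0, 1, 49, 49]

    def test_weights_single_bin(self):
        w = compute_bin_weights([99.0] * 10).w
        assert w[49] == 0.0
        assert (np.delete(w, 49) == 1.0).all()

    def test_weights_two_bin_split(self):
        w = compute_bin_weights([10.0] * 5 + [90.0] * 5).w
        assert w[5] == 0.5 and w[45] == 0.5
        assert (np.delete(w, [5, 45]) == 1.0).all()

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_weight_sum_is_49(self, values):
        assert compute_bin_weights(values).w.sum() == pytest.approx(49.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_bin_weights([])


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        true = np.array([10.0, 55.0, 95.0])
        probs = np.full((3, 50), 1e-12)
        for i, b in enumerate(lddt_bin(true)):
            probs[i, b] = 1.0
        probs /= probs.sum(1, keepdims=True)
        w = BinWeights(np.ones(50) * 0.5)
        assert weighted_bin_loss(BinDistribution(probs), true, w) == pytest.approx(0, abs=1e-4)

    def test_uniform_probs_give_log50(self):
        true = np.array([3.0, 42.0, 88.0])
        dist = BinDistribution(np.full((3, 50), 1 / 50))
        rng = np.random.default_rng(0)
        w = BinWeights(rng.uniform(0.1, 1.0, size=50))
        assert weighted_bin_loss(dist, true, w) == pytest.approx(np.log(50))

    def test_zero_weight_excludes_residue(self):
        true = np.array([1.0, 99.0])
        probs = np.full((2, 50), 1 / 50)
        probs[0] = 0; probs[0, 0] = 1.0
        w = np.ones(50); w[49] = 0.0
        loss = weighted_bin_loss(BinDistribution(probs), true, BinWeights(w))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_uniform_weights_equal_plain_cross_entropy(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(6, 50))
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        true = rng.uniform(0, 100, size=6)
        w = BinWeights(np.full(50, 0.7))
        loss = weighted_bin_loss(BinDistribution(probs), true, w)
        ce = -np.mean(np.log(probs[np.arange(6), lddt_bin(true)]))
        assert loss == pytest.approx(ce)

    def test_all_masked_rejected(self):
        dist = BinDistribution(np.full((2, 50), 1 / 50))
        with pytest.raises(ValueError, match="masked"):
            weighted_bin_loss(dist, np.array([5.0, 6.0]), BinWeights(np.ones(50)),
                              mask=np.array([False, False]))


class TestEgcl:
    def test_two_node_hand_computation(self):
        """Messages and updates match an independent numpy replication."""
        H = 3
        rng = np.random.default_rng(2)
        P = {}
        dims = {"phi_e.0": (2 * H + 1, H), "phi_e.1": (H, H),
                "phi_x.0": (H, H), "phi_x.1": (H, 1),
                "phi_h.0": (2 * H, H), "phi_h.1": (H, H)}
        for nm, (di, do) in dims.items():
            P[f"l.{nm}.W"] = Tensor(rng.normal(size=(di, do)) * 0.3, requires_grad=True)
            P[f"l.{nm}.b"] = Tensor(rng.normal(size=do) * 0.1, requires_grad=True)
        h = np.array([[0.5, -0.2, 0.1], [0.3, 0.4, -0.6]])
        x = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        edges = np.array([[0, 1], [1, 0]])
        h_out, x_out = egcl_step(Tensor(h), Tensor(x), edges, None, P, "l")

        def silu(v):
            return v / (1 + np.exp(-v))

        def mlp(v, a, b_):
            return silu(v @ P[f"l.{a}.W"].data + P[f"l.{a}.b"].data) \
                if b_ else v @ P[f"l.{a}.W"].data + P[f"l.{a}.b"].data

        expect_h, expect_x = [], []
        for i, j in [(0, 1), (1, 0)]:
            sq = np.sum((x[i] - x[j]) ** 2) / SQDIST_NORM
            m_in = np.concatenate([h[i], h[j], [sq]])
            m = silu(mlp(silu(mlp(m_in, "phi_e.0", False)), "phi_e.1", False))
            xw = mlp(silu(mlp(m, "phi_x.0", False)), "phi_x.1", False)
            expect_x.append(x[i] + (x[i] - x[j]) * xw)  # degree 1
            h_in = np.concatenate([h[i], m])
            expect_h.append(mlp(silu(mlp(h_in, "phi_h.0", False)), "phi_h.1", False))
        np.testing.assert_allclose(h_out.data, np.array(expect_h), atol=1e-12)
        np.testing.assert_allclose(x_out.data, np.array(expect_x), atol=1e-12)

    def test_zero_parameters_degenerate(self):
        H = 4
        P = {}
        for nm, (di, do) in {"phi_e.0": (2 * H + 1, H), "phi_e.1": (H, H),
                             "phi_x.0": (H, H), "phi_x.1": (H, 1),
                             "phi_h.0": (2 * H, H), "phi_h.1": (H, H)}.items():
            P[f"l.{nm}.W"] = Tensor(np.zeros((di, do)), requires_grad=True)
            P[f"l.{nm}.b"] = Tensor(np.zeros(do), requires_grad=True)
        h = np.ones((3, H))
        x = np.arange(9, dtype=float).reshape(3, 3)
        edges = np.array([[0, 1], [1, 0], [1, 2], [2, 1]])
        h_out, x_out = egcl_step(Tensor(h), Tensor(x), edges, None, P, "l")
        np.testing.assert_array_equal(x_out.data, x)  # phi_x == 0
        assert h_out.shape == h.shape
        np.testing.assert_array_equal(h_out.data, np.zeros_like(h))  # bias path

    def test_equivariance(self):
        rng = np.random.default_rng(3)
        H = 5
        P = {}
        for nm, (di, do) in {"phi_e.0": (2 * H + 1, H), "phi_e.1": (H, H),
                             "phi_x.0": (H, H), "phi_x.1": (H, 1),
                             "phi_h.0": (2 * H, H), "phi_h.1": (H, H)}.items():
            P[f"l.{nm}.W"] = Tensor(rng.normal(size=(di, do)) * 0.3, requires_grad=True)
            P[f"l.{nm}.b"] = Tensor(np.zeros(do), requires_grad=True)
        h = rng.normal(size=(6, H))
        x = rng.uniform(0, 10, size=(6, 3))
        edges = np.array([(i, j) for i in range(6) for j in range(6) if i != j])
        h1, x1 = egcl_step(Tensor(h), Tensor(x), edges, None, P, "l")
        R, t = random_rigid_motion(rng)
        h2, x2 = egcl_step(Tensor(h), Tensor(x @ R.T + t), edges, None, P, "l")
        np.testing.assert_allclose(h2.data, h1.data, atol=1e-9)
        np.testing.assert_allclose(x2.data, x1.data @ R.T + t, atol=1e-9)


class TestPredict:
    def test_rows_sum_to_one(self):
        g, _ = small_graph()
        params = init_params(g.node_input.shape[1], g.edge_input.shape[1])
        dist = predict(g, params)
        np.testing.assert_allclose(dist.probs.sum(1), 1.0, atol=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        g, _ = small_graph()
        params = init_params(g.node_input.shape[1], g.edge_input.shape[1])
        base = predict_plddt(g, params)
        for _ in range(3):
            R, t = random_rigid_motion(rng)
            g2 = ProteinGraph(g.coords @ R.T + t, g.node_input, g.edges,
                              g.edge_input, g.residue_indices)
            np.testing.assert_allclose(predict_plddt(g2, params), base, atol=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        g, _ = small_graph()
        params = init_params(g.node_input.shape[1], g.edge_input.shape[1])
        base = predict(g, params).probs
        perm = rng.permutation(g.L)
        inv = np.argsort(perm)
        # node k of the permuted graph is node perm[k] of the original
        g2 = ProteinGraph(
            g.coords[perm], g.node_input[perm],
            np.stack([inv[g.edges[:, 0]], inv[g.edges[:, 1]]], axis=1),
            g.edge_input,
            tuple(np.array(g.residue_indices)[perm]),
        )
        out = predict(g2, params).probs
        np.testing.assert_allclose(out, base[perm], atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        g, _ = small_graph()
        params = init_params(g.node_input.shape[1] + 1, g.edge_input.shape[1])
        with pytest.raises(ValueError, match="node dim"):
            predict(g, params)


@pytest.fixture(scope="module")
def tiny_dataset():
    return training_pairs(make_dataset(3, (25, 30), SyntheticSpec(), seed=21))


class TestTraining:
    def test_loss_decreases(self, tiny_dataset):
        cfg = HeadConfig(epochs=5, seed=0)
        _, trace = train_head(tiny_dataset, cfg)
        assert trace[-1] < trace[0]

    def test_deterministic_given_seed(self, tiny_dataset):
        cfg = HeadConfig(epochs=2, seed=7)
        _, t1 = train_head(tiny_dataset, cfg)
        _, t2 = train_head(tiny_dataset, cfg)
        assert t1 == t2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_head([], HeadConfig(epochs=1))

    def test_params_round_trip(self, tiny_dataset, tmp_path):
        cfg = HeadConfig(epochs=1, seed=0)
        params, _ = train_head(tiny_dataset, cfg)
        p = tmp_path / "params.npz"
        save_params(params, cfg, p)
        back, cfg2 = load_params(p)
        assert cfg2 == cfg
        g = tiny_dataset[0][0]
        np.testing.assert_allclose(
            predict_plddt(g, back, cfg2), predict_plddt(g, params, cfg), atol=1e-12
        )


def test_config_validation():
    with pytest.raises(ValueError):
        HeadConfig(n_bins=10, bin_width=2.0)
    with pytest.raises(ValueError):
        HeadConfig(aggregation="mean")
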