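"""GVP layer algebra, message passing, inference and training contracts."""

import numpy as np
import pytest

from conftest import random_rotation
from pocketseer.autodiff import Tensor, stack_loss
from pocketseer.featurize import GraphFeatures, build_graph
from pocketseer.gvp_model import (
    GVP,
    GVPModel,
    ModelConfig,
    TrainConfig,
    load_weights,
    predict,
    save_weights,
    train,
)
from pocketseer.synthetic import make_training_set


def _np_gvp(gvp, s, V):
    """Straight-line numpy re-implementation of one GVP forward pass."""
    p = {k: v.data for k, v in gvp.params.items()}
    if gvp.vi:
        Vh = np.einsum("...vc,vw->...wc", V, p["Wh"])
        sh = np.sqrt(np.sum(Vh**2, axis=-1) + 1e-16)
        s_in = np.concatenate([s, sh], axis=-1)
    else:
        Vh = None
        s_in = s
    sm = s_in @ p["Ws"] + p["bs"]
    s_out = np.maximum(sm, 0.0) if gvp.activation else sm
    V_out = None
    if gvp.vo:
        Vu = np.einsum("...vc,vw->...wc", Vh, p["Wv"])
        gate = 1.0 / (1.0 + np.exp(-(s_out @ p["Wg"] + p["bg"])))
        V_out = Vu * gate[..., None]
    return s_out, V_out


class TestGVPLayer:
    def test_zero_vectors_give_zero_vector_output(self):
        gvp = GVP((4, 2), (3, 2), rng=np.random.default_rng(1))
        s = np.random.default_rng(2).normal(size=(5, 4))
        s1, V1 = gvp(Tensor(s), Tensor(np.zeros((5, 2, 3))))
        np.testing.assert_allclose(V1.data, 0.0, atol=1e-12)
        # scalars depend on vectors only through (zero) norms
        gvp_ref = GVP((4, 2), (3, 2), rng=np.random.default_rng(1))
        big = np.zeros((5, 2, 3))
        s2, _ = gvp_ref(Tensor(s), Tensor(big))
        np.testing.assert_allclose(s1.data, s2.data)

    def test_rotation_equivariance(self):
        gvp = GVP((5, 3), (4, 2), rng=np.random.default_rng(0))
        rng = np.random.default_rng(3)
        s = rng.normal(size=(7, 5))
        V = rng.normal(size=(7, 3, 3))
        for seed in range(5):
            R = random_rotation(seed)
            s1, V1 = gvp(Tensor(s), Tensor(V))
            s2, V2 = gvp(Tensor(s), Tensor(V @ R.T))
            np.testing.assert_allclose(s2.data, s1.data, atol=1e-5)
            np.testing.assert_allclose(V2.data, V1.data @ R.T, atol=1e-5)

    def test_identity_maps_pass_scalars_through(self):
        gvp = GVP((3, 1), (3, 1), activation=False, rng=np.random.default_rng(0))
        # Ws picks the scalar block only; zero bias
        W = np.zeros((3 + gvp.h, 3))
        W[:3, :3] = np.eye(3)
        gvp.params["Ws"].data = W
        gvp.params["bs"].data = np.zeros(3)
        s = np.random.default_rng(1).normal(size=(4, 3))
        s1, _ = gvp(Tensor(s), Tensor(np.random.default_rng(2).normal(size=(4, 1, 3))))
        np.testing.assert_allclose(s1.data, s, atol=1e-12)

    def test_gradients_match_finite_differences(self):
        gvp = GVP((2, 1), (2, 1), rng=np.random.default_rng(3))
        rng = np.random.default_rng(0)
        s0 = rng.normal(size=(3, 2))
        V0 = rng.normal(size=(3, 1, 3))

        def f(sv, vv):
            so, Vo = gvp(Tensor(sv), Tensor(vv))
            return float((so.sum() + Vo.norm().sum()).data)

        st = Tensor(s0, requires_grad=True)
        Vt = Tensor(V0, requires_grad=True)
        so, Vo = gvp(st, Vt)
        (so.sum() + Vo.norm().sum()).backward()
        eps = 1e-6
        for arr, tensor in ((s0, st), (V0, Vt)):
            num = np.zeros_like(arr)
            for i in np.ndindex(arr.shape):
                up = arr.copy(); up[i] += eps
                dn = arr.copy(); dn[i] -= eps
                if arr is s0:
                    num[i] = (f(up, V0) - f(dn, V0)) / (2 * eps)
                else:
                    num[i] = (f(s0, up) - f(s0, dn)) / (2 * eps)
            np.testing.assert_allclose(tensor.grad, num, atol=1e-4)
        for name, p in gvp.named_params().items():
            analytic = p.grad.copy()
            num = np.zeros_like(p.data)
            for i in np.ndindex(p.data.shape):
                orig = p.data[i]
                p.data[i] = orig + eps
                up = f(s0, V0)
                p.data[i] = orig - eps
                dn = f(s0, V0)
                p.data[i] = orig
                num[i] = (up - dn) / (2 * eps)
            np.testing.assert_allclose(analytic, num, atol=1e-4, err_msg=name)

    def test_dimension_mismatch_rejected(self):
        gvp = GVP((4, 2), (3, 1), rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            gvp(Tensor(np.zeros((2, 5))), Tensor(np.zeros((2, 2, 3))))


def _tiny_graph(n_nodes, edges, rng):
    es = rng.normal(size=(len(edges), 32))
    eV = rng.normal(size=(len(edges), 1, 3))
    edge_index = np.array(edges, dtype=int).T.reshape(2, -1)
    return GraphFeatures(
        node_scalars=np.zeros((n_nodes, 26)),
        node_vectors=np.zeros((n_nodes, 3, 3)),
        edge_index=edge_index,
        edge_scalars=es,
        edge_vectors=eV,
        node_mask=np.ones(n_nodes, dtype=bool),
        residue_indices=np.arange(1, n_nodes + 1),
    )


class TestMessagePassing:
    def _model(self):
        return GVPModel(ModelConfig(node_embed_dims=(2, 1), hidden_dims=(2, 1),
                                    num_layers=1, k_neighbors=2, dropout=0.0, seed=4))

    def test_two_node_step_matches_hand_unrolled_oracle(self):
        model = self._model()
        layer = model.layers[0]
        rng = np.random.default_rng(8)
        graph = _tiny_graph(2, [(0, 1), (1, 0)], rng)
        s = rng.normal(size=(2, 2))
        V = rng.normal(size=(2, 1, 3))
        got_s, got_V = model.message_passing_step(layer, Tensor(s), Tensor(V), graph)

        # independent straight-line recomputation
        src, dst = graph.edge_index
        msgs_s, msgs_V = [], []
        for e in range(2):
            in_s = np.concatenate([s[src[e]], graph.edge_scalars[e]])
            in_V = np.concatenate([V[src[e]], graph.edge_vectors[e]], axis=0)
            m1s, m1V = _np_gvp(layer["msg1"], in_s[None], in_V[None])
            m2s, m2V = _np_gvp(layer["msg2"], m1s, m1V)
            msgs_s.append((dst[e], m2s[0]))
            msgs_V.append((dst[e], m2V[0]))
        s_mid = s.copy()
        V_mid = V.copy()
        for i in range(2):
            s_mid[i] = s[i] + np.mean([m for d, m in msgs_s if d == i], axis=0)
            V_mid[i] = V[i] + np.mean([m for d, m in msgs_V if d == i], axis=0)
        f1s, f1V = _np_gvp(layer["ff1"], s_mid, V_mid)
        f2s, f2V = _np_gvp(layer["ff2"], f1s, f1V)
        np.testing.assert_allclose(got_s.data, s_mid + f2s, atol=1e-10)
        np.testing.assert_allclose(got_V.data, V_mid + f2V, atol=1e-10)

    def test_symmetric_graph_keeps_nodes_identical(self):
        model = self._model()
        rng = np.random.default_rng(1)
        edge_feat_s = rng.normal(size=32)
        edge_feat_V = rng.normal(size=(1, 3))
        edges = [(0, 1), (1, 0), (1, 2), (2, 1), (2, 0), (0, 2)]
        graph = _tiny_graph(3, edges, rng)
        graph.edge_scalars = np.tile(edge_feat_s, (6, 1))
        graph.edge_vectors = np.tile(edge_feat_V, (6, 1, 1))
        s = np.tile(rng.normal(size=2), (3, 1))
        V = np.tile(rng.normal(size=(1, 3)), (3, 1, 1))
        out_s, out_V = model.message_passing_step(
            model.layers[0], Tensor(s), Tensor(V), graph
        )
        np.testing.assert_allclose(out_s.data[0], out_s.data[1], atol=1e-12)
        np.testing.assert_allclose(out_s.data[1], out_s.data[2], atol=1e-12)
        np.testing.assert_allclose(out_V.data[0], out_V.data[2], atol=1e-12)

    def test_isolated_node_update_is_self_plus_feedforward(self):
        model = self._model()
        rng = np.random.default_rng(2)
        graph = _tiny_graph(1, [], rng)
        s = rng.normal(size=(1, 2))
        V = rng.normal(size=(1, 1, 3))
        out_s, out_V = model.message_passing_step(
            model.layers[0], Tensor(s), Tensor(V), graph
        )
        f1s, f1V = _np_gvp(model.layers[0]["ff1"], s, V)
        f2s, f2V = _np_gvp(model.layers[0]["ff2"], f1s, f1V)
        np.testing.assert_allclose(out_s.data, s + f2s, atol=1e-10)
        np.testing.assert_allclose(out_V.data, V + f2V, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_model():
    return GVPModel(ModelConfig(node_embed_dims=(16, 4), hidden_dims=(16, 4),
                                num_layers=2, k_neighbors=15, dropout=0.1, seed=0))


class TestPredict:
    def test_probabilities_in_unit_interval(self, helix20, tiny_model):
        pred = predict(helix20, tiny_model)
        p = pred.probs[pred.mask]
        assert np.all((p > 0) & (p < 1))
        assert pred.mask.all()

    def test_rigid_transform_invariance(self, helix20, tiny_model):
        p0 = predict(helix20, tiny_model).probs
        for seed in range(10):
            R = random_rotation(seed + 40)
            t = np.random.default_rng(seed).normal(size=3) * 8
            p1 = predict(helix20.transformed(R, t), tiny_model).probs
            np.testing.assert_allclose(p1, p0, atol=1e-5)

    def test_checkpoint_roundtrip(self, helix20, tiny_model, tmp_path):
        path = tmp_path / "weights.npz"
        save_weights(tiny_model, path)
        back = load_weights(path)
        assert back.fingerprint() == tiny_model.fingerprint()
        np.testing.assert_allclose(
            predict(helix20, back).probs, predict(helix20, tiny_model).probs
        )


@pytest.fixture(scope="module")
def small_dataset():
    data = make_training_set(8, seed=21, n_residues=20)
    return [(build_graph(st, k=10), lab) for st, lab in data]


class TestTraining:
    def test_uniform_half_labels_give_ln2_loss(self):
        pred = Tensor(np.full(10, 0.5))
        loss = stack_loss(pred, np.full(10, 0.5))
        assert float(loss.data) == pytest.approx(np.log(2.0), abs=1e-6)

    def test_identical_seeds_reproduce_loss_curves_bitwise(self, small_dataset):
        mc = ModelConfig(node_embed_dims=(8, 2), hidden_dims=(8, 2),
                         num_layers=1, k_neighbors=10, dropout=0.1, seed=0)
        tc = TrainConfig(epochs=3, batch_mode="residues_32", learning_rate=1e-3, seed=9)
        _, log1 = train(small_dataset, tc, mc)
        _, log2 = train(small_dataset, tc, mc)
        assert log1["epoch_loss"] == log2["epoch_loss"]

    def test_oversampling_balances_class_ratio(self, small_dataset):
        mc = ModelConfig(node_embed_dims=(8, 2), hidden_dims=(8, 2),
                         num_layers=1, k_neighbors=10, dropout=0.0, seed=0)
        tc = TrainConfig(epochs=2, batch_mode="residues_32",
                         balancing="oversample_positive", learning_rate=1e-3, seed=1)
        _, log = train(small_dataset, tc, mc)
        for frac in log["epoch_pos_fraction"]:
            assert abs(frac - 0.5) < 0.05

    def test_balanced_draws_balance_class_ratio(self, small_dataset):
        mc = ModelConfig(node_embed_dims=(8, 2), hidden_dims=(8, 2),
                         num_layers=1, k_neighbors=10, dropout=0.0, seed=0)
        tc = TrainConfig(epochs=1, batch_mode="balanced_draw_160",
                         learning_rate=1e-3, seed=1)
        _, log = train(small_dataset, tc, mc)
        assert abs(log["epoch_pos_fraction"][0] - 0.5) < 0.05

    def test_all_masked_dataset_rejected(self, small_dataset):
        graphs = []
        for g, lab in small_dataset:
            lab2 = type(lab)(
                labels=lab.labels, mask=np.zeros_like(lab.mask),
                residue_indices=lab.residue_indices,
            )
            graphs.append((g, lab2))
        with pytest.raises(ValueError, match="masked"):
            train(graphs, TrainConfig(epochs=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TrainConfig(epochs=1))
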