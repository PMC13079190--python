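"""Network architecture contracts: GCN oracle equivalence, TCN causality,
receptive field, attention normalization, shapes and determinism."""

import numpy as np
import pytest

import strokesym as ss
from strokesym.nn.autodiff import Tensor
from strokesym.nn.layers import GCNLayer, MLP, TCN
from strokesym.nn.model import measure_receptive_field
from strokesym.training import prepare_batch


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        h = rng.normal(size=(17, 8))
        out = ss.gcn_layer_forward(h, np.eye(17), np.eye(8))
        assert np.allclose(out, h)

    def test_two_node_hand_computation(self):
        a = np.full((2, 2), 0.5)
        h = np.array([[1.0], [3.0]])
        out = ss.gcn_layer_forward(h, a, np.array([[1.0]]))
        assert np.allclose(out, [[2.0], [2.0]])

    def test_three_stacked_layers_match_dense_oracle(self, rng):
        a = ss.normalized_adjacency(ss.build_skeleton_graph("right"))
        h = rng.normal(size=(17, 8))
        ws = [rng.normal(size=(8, 8)) for _ in range(3)]
        expected = h
        for w in ws:
            expected = np.maximum(a @ expected @ w, 0.0)
        out = h
        for w in ws:
            out = ss.gcn_layer_forward(out, a, w, activation=lambda x: np.maximum(x, 0))
        assert np.allclose(out, expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            ss.gcn_layer_forward(rng.normal(size=(17, 8)), np.eye(16), np.eye(8))

    def test_joint_permutation_equivariance(self, rng):
        a = ss.normalized_adjacency(ss.build_skeleton_graph("right"))
        h = rng.normal(size=(17, 6))
        w = rng.normal(size=(6, 6))
        perm = rng.permutation(17)
        out = ss.gcn_layer_forward(h, a, w)
        out_p = ss.gcn_layer_forward(h[perm], a[np.ix_(perm, perm)], w)
        assert np.allclose(out_p, out[perm])


class TestReceptiveField:
    @pytest.mark.parametrize(
        "layers,kernel,expected",
        [(4, 5, 61), (1, 3, 3), (2, 3, 7)],
    )
    def test_formula(self, layers, kernel, expected):
        cfg = ss.ModelConfig(tcn_layers=layers, tcn_kernel=kernel)
        assert ss.receptive_field(cfg) == expected
        assert cfg.tcn_dilations == tuple(2**i for i in range(layers))

    @pytest.mark.parametrize("layers", [1, 2, 3])
    @pytest.mark.parametrize("kernel", [2, 3, 5])
    def test_formula_matches_perturbation_probe(self, layers, kernel):
        cfg = ss.ModelConfig(tcn_layers=layers, tcn_kernel=kernel, tcn_channels=8)
        assert measure_receptive_field(cfg, seed=0) == ss.receptive_field(cfg)

    def test_design_config_probe_is_61(self):
        cfg = ss.ModelConfig(tcn_channels=8)
        assert measure_receptive_field(cfg, seed=1) == 61


class TestTcnForward:
    def test_causality_future_frames_do_not_leak(self, rng):
        cfg = ss.ModelConfig(tcn_channels=6, tcn_layers=2, tcn_kernel=3)
        x = rng.normal(size=(20, 6))
        base = ss.tcn_forward(x, cfg, seed=3)
        for t in range(19):
            probe = x.copy()
            probe[t + 1] += 1.0
            out = ss.tcn_forward(probe, cfg, seed=3)
            assert np.allclose(out[: t + 1], base[: t + 1])

    def test_zero_input_zero_bias_zero_output(self, rng):
        tcn = TCN(4, 2, 3, rng)
        out = tcn(Tensor(np.zeros((1, 12, 4)))).data
        assert np.allclose(out, 0.0)

    def test_impulse_reaches_receptive_field_positions(self, rng):
        cfg = ss.ModelConfig(tcn_channels=4, tcn_layers=2, tcn_kernel=3)
        rf = ss.receptive_field(cfg)  # 7
        t = 16
        base = np.zeros((t, 4))
        out0 = ss.tcn_forward(base, cfg, seed=5)
        impulse = base.copy()
        impulse[4] = 1.0
        out1 = ss.tcn_forward(impulse, cfg, seed=5)
        changed = np.flatnonzero(np.any(~np.isclose(out0, out1), axis=1))
        assert changed.min() >= 4
        assert changed.max() <= 4 + rf - 1

    def test_channel_mismatch_rejected(self, rng):
        cfg = ss.ModelConfig(tcn_channels=6)
        with pytest.raises(ValueError, match="channel"):
            ss.tcn_forward(rng.normal(size=(10, 5)), cfg)

    def test_length_preserved(self, rng):
        cfg = ss.ModelConfig(tcn_channels=3, tcn_layers=3)
        for t in (1, 5, 40):
            assert ss.tcn_forward(rng.normal(size=(t, 3)), cfg).shape == (t, 3)


class TestCrossModalAttention:
    def test_identical_modalities_uniform_attention(self, rng):
        f = rng.normal(size=(4, 16))
        fused, weights = ss.cross_modal_attention([f, f, f])
        assert np.allclose(weights, 1.0 / 3.0)
        assert fused.shape == (4, 512)

    def test_rows_sum_to_one(self, rng):
        feats = [rng.normal(size=(5, 16)) * 3 for _ in range(3)]
        _, weights = ss.cross_modal_attention(feats)
        assert np.allclose(weights.sum(axis=-1), 1.0)

    def test_dominant_key_attracts_all_rows(self):
        # identity projections make the key logits explicit: one modality
        # with a huge key score takes column weight -> 1 in every row
        from strokesym.nn.layers import CrossModalAttention
        att = CrossModalAttention(8, 8, 16, np.random.default_rng(0))
        att.wq.weight.data = np.eye(8)
        att.wk.weight.data = np.eye(8)
        att.wq.bias.data[:] = 0
        att.wk.bias.data[:] = 0
        f = [Tensor(np.ones((1, 8))), Tensor(np.ones((1, 8))),
             Tensor(np.ones((1, 8)) * 60.0)]
        weights = att.attention_weights(f).data
        assert np.all(weights[0, :, 2] > 0.999)

    def test_fewer_than_three_modalities_rejected(self, rng):
        with pytest.raises(ValueError, match="3 modal"):
            ss.cross_modal_attention([rng.normal(size=(2, 8))] * 2)


class TestKinematicEncoder:
    def test_output_dim_128_and_statelessness(self, rng):
        x = rng.normal(size=(26, 12))
        a = ss.kinematic_encoder(x, seed=4)
        b = ss.kinematic_encoder(x, seed=4)
        assert a.shape == (26, 128)
        assert np.array_equal(a, b)

    def test_wrong_input_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.kinematic_encoder(rng.normal(size=(26, 11)))

    def test_linear_composition_matches_matrix_oracle(self, rng):
        mlp = MLP((12, 64, 128, 128), rng)
        for layer in mlp.layers:  # disable nonlinearity by positivity
            layer.weight.data = np.abs(layer.weight.data) * 0.05
            layer.bias.data += 1.0  # keep activations positive -> ReLU identity
        x = np.abs(rng.normal(size=(5, 12)))
        out = mlp(Tensor(x)).data
        expected = x
        for layer in mlp.layers:
            expected = expected @ layer.weight.data + layer.bias.data
        assert np.allclose(out, expected)


@pytest.fixture(scope="module")
def batch():
    samples, _ = ss.generate_cohort(ss.CohortConfig(n_samples=8, seed=3))
    return prepare_batch(samples)


class TestModelForward:
    def _small_cfg(self, **kw):
        params = dict(
            gcn_hidden=12, node_embed_dim=8, fused_node_dim=8, tcn_channels=12,
            d_model=16, d_k=8, fusion_dim=32, head_dims=(16, 12, 8),
        )
        params.update(kw)
        return ss.ModelConfig(**params)

    def test_logits_finite_and_softmax_normalized(self, batch):
        net = ss.MultimodalStrokeNet(self._small_cfg())
        pa, pr = net.predict_proba(batch["coords"], batch["kin"], batch["rgb"],
                                   batch["a_norm"])
        assert pa.shape == (8, 4) and pr.shape == (8, 3)
        assert np.all(np.isfinite(pa)) and np.all(np.isfinite(pr))
        assert np.allclose(pa.sum(1), 1.0) and np.allclose(pr.sum(1), 1.0)

    def test_missing_modality_rejected_outside_ablation(self, batch):
        net = ss.MultimodalStrokeNet(self._small_cfg())
        with pytest.raises(ValueError, match="requir"):
            net.forward(batch["coords"], None, batch["rgb"], batch["a_norm"])

    def test_skeleton_only_ablation_still_produces_both_heads(self, batch):
        net = ss.MultimodalStrokeNet(self._small_cfg(modalities=("skeleton",)))
        la, lr = net.forward(batch["coords"], None, None, batch["a_norm"])
        assert la.shape == (8, 4) and lr.shape == (8, 3)

    def test_deterministic_with_dropout_zero(self, batch):
        cfg = self._small_cfg(dropout=0.0)
        a = ss.MultimodalStrokeNet(cfg).predict_logits(
            batch["coords"], batch["kin"], batch["rgb"], batch["a_norm"])
        b = ss.MultimodalStrokeNet(cfg).predict_logits(
            batch["coords"], batch["kin"], batch["rgb"], batch["a_norm"])
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_parameter_count_is_config_function(self):
        cfg = self._small_cfg()
        n1 = ss.MultimodalStrokeNet(cfg).n_parameters()
        n2 = ss.MultimodalStrokeNet(cfg).n_parameters()
        assert n1 == n2 > 0
        bigger = ss.MultimodalStrokeNet(self._small_cfg(gcn_hidden=24))
        assert bigger.n_parameters() > n1

    def test_wrong_coords_shape_rejected(self, batch):
        net = ss.MultimodalStrokeNet(self._small_cfg())
        with pytest.raises(ValueError, match="17"):
            net.forward(batch["coords"][:, :, :16], batch["kin"], batch["rgb"],
                        batch["a_norm"])
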