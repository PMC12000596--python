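"""Network structure, layer equations, training contracts and serialization."""

import numpy as np
import pytest

from conftest import tiny_network_config
from maizeyield import network, oracle
from maizeyield.autodiff import Tensor
from maizeyield.config import NetworkConfig
from maizeyield.network import (ShapeError, attention_pool, count_parameters,
                                forward_batch, gru_cell_step, init_params,
                                load_model, panel_to_inputs, predict,
                                save_model, train)
from maizeyield.panel import FeaturePanel
from maizeyield.synthetic import SyntheticConfig, generate_panel


def zero_gru_params(d_in=1, hidden=1):
    zeros = lambda *s: np.zeros(s)
    return {"Wz": zeros(d_in, hidden), "Uz": zeros(hidden, hidden), "bz": zeros(hidden),
            "Wr": zeros(d_in, hidden), "Ur": zeros(hidden, hidden), "br": zeros(hidden),
            "Wh": zeros(d_in, hidden), "Uh": zeros(hidden, hidden), "bh": zeros(hidden)}


# -- convolution ---------------------------------------------------------------


def test_valid_convolution_hand_example():
    # input [1,2,3], kernel [1,1], bias 0 -> [3,5]
    x = Tensor(np.array([1.0, 2.0, 3.0]).reshape(1, 3, 1))
    W = Tensor(np.ones((2, 1, 1)))
    b = Tensor(np.zeros(1))
    out = network._conv1d(x, W, b, same_pad=False)
    np.testing.assert_allclose(out.data.ravel(), [3.0, 5.0])


def test_zero_kernels_give_zero_output_and_relu_clamps():
    cfg = tiny_network_config()
    params = init_params(cfg)
    for name, p in params.items():
        if name.startswith("conv"):
            p.data[:] = 0.0
    x = Tensor(np.random.default_rng(0).normal(size=(2, 5, 2)))
    h = network._conv1d(x, params["conv0_W"], params["conv0_b"], same_pad=True).relu()
    np.testing.assert_array_equal(h.data, 0.0)
    # negative pre-activations are exactly zero after ReLU
    y = Tensor(np.array([[-3.0, 2.0]])).relu()
    np.testing.assert_array_equal(y.data, [[0.0, 2.0]])


def test_sequence_too_short_reports_minimum():
    cfg = tiny_network_config(conv_same_pad_first=False, sequence_length=2)
    params = init_params(cfg)
    with pytest.raises(ShapeError, match=">= 3"):
        network.forward_graph(params, cfg, np.zeros((1, 2, 2)))


def test_conv_stack_shrinks_length_by_valid_layers():
    cfg = tiny_network_config()
    assert network.conv_output_length(cfg) == 4  # 5 ->(same) 5 ->(valid) 4
    cfg2 = tiny_network_config(conv_same_pad_first=False)
    assert network.conv_output_length(cfg2) == 3


# -- GRU cell ------------------------------------------------------------------


def test_gru_zero_params_halves_previous_state():
    """With all parameters zero both gates sit at 0.5 and the candidate is 0,
    so h_t = 0.5 * h_prev exactly."""
    p = zero_gru_params()
    h = gru_cell_step(np.zeros((1, 1)), np.ones((1, 1)), p)
    np.testing.assert_allclose(h, 0.5, atol=0)


def test_gru_zero_state_zero_input_is_fixed_point():
    p = zero_gru_params(d_in=3, hidden=4)
    h = gru_cell_step(np.zeros((1, 3)), np.zeros((1, 4)), p)
    np.testing.assert_array_equal(h, 0.0)


def test_gru_saturated_update_gate_passes_candidate():
    p = zero_gru_params(d_in=2, hidden=2)
    p["bz"] = np.full(2, 50.0)
    rng = np.random.default_rng(1)
    p["Wh"] = rng.normal(size=(2, 2))
    x = rng.normal(size=(1, 2))
    h_prev = rng.normal(size=(1, 2))
    h = gru_cell_step(x, h_prev, p)
    candidate = np.tanh(x @ p["Wh"] + 0.5 * (h_prev @ p["Uh"]))
    np.testing.assert_allclose(h, candidate, atol=1e-9)


def test_gru_gates_bounded_and_hidden_below_one():
    """From a zero initial state every hidden coordinate is a convex
    combination of tanh outputs, hence strictly inside (-1, 1)."""
    rng = np.random.default_rng(2)
    p = {k: rng.normal(scale=2.0, size=v.shape)
         for k, v in zero_gru_params(d_in=3, hidden=5).items()}
    h = np.zeros((4, 5))
    for _ in range(7):
        h = gru_cell_step(rng.normal(size=(4, 3)), h, p)
        assert np.abs(h).max() < 1.0


# -- BiGRU ----------------------------------------------------------------------


def test_bigru_palindrome_with_shared_parameters_is_symmetric():
    cfg = tiny_network_config(no_cnn=True, gru_layers=2)
    params = init_params(cfg)
    for gate in ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh"):
        params[f"gru0_bw_{gate}"].data[:] = params[f"gru0_fw_{gate}"].data
    rng = np.random.default_rng(3)
    half = rng.normal(size=(1, 2, 2))
    X = np.concatenate([half, half[:, ::-1, :]], axis=1)  # palindrome, T=4
    fw = network._gru_direction(Tensor(X), params, "gru0_fw", reverse=False)
    bw = network._gru_direction(Tensor(X), params, "gru0_bw", reverse=True)
    np.testing.assert_allclose(fw.data, bw.data[:, ::-1, :], atol=1e-12)


def test_bigru_alpha_one_beta_zero_reduces_to_forward_gru():
    cfg = tiny_network_config(no_cnn=True, gru_layers=2)
    params = init_params(cfg)
    params["gru0_alpha"].data[:] = 1.0
    params["gru0_beta"].data[:] = 0.0
    params["gru0_bcomb"].data[:] = 0.0
    X = np.random.default_rng(4).normal(size=(2, 5, 2))
    combined = network._bigru_layer(Tensor(X), params, 0, cfg)
    fw = network._gru_direction(Tensor(X), params, "gru0_fw", reverse=False)
    np.testing.assert_allclose(combined.data, fw.data, atol=1e-12)


def test_bigru_single_step_matches_cell_oracle():
    cfg = tiny_network_config(no_cnn=True)
    params = init_params(cfg)
    x = np.random.default_rng(5).normal(size=(1, 1, 2))
    combined = network._bigru_layer(Tensor(x), params, 0, cfg)
    gates = ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh")
    p_fw = {g: params[f"gru0_fw_{g}"].data for g in gates}
    p_bw = {g: params[f"gru0_bw_{g}"].data for g in gates}
    h_fw = gru_cell_step(x[:, 0, :], np.zeros((1, 3)), p_fw)
    h_bw = gru_cell_step(x[:, 0, :], np.zeros((1, 3)), p_bw)
    want = (params["gru0_alpha"].data * h_fw + params["gru0_beta"].data * h_bw
            + params["gru0_bcomb"].data)
    np.testing.assert_allclose(combined.data[:, 0, :], want, atol=1e-12)


# -- attention ------------------------------------------------------------------


def test_attention_single_step_gets_full_weight():
    rng = np.random.default_rng(6)
    h = rng.normal(size=(1, 4))
    ctx, w = attention_pool(h, rng.normal(size=(4, 4)), rng.normal(size=4),
                            rng.normal(size=(4, 1)))
    np.testing.assert_allclose(w, [1.0], atol=0)
    np.testing.assert_allclose(ctx, h[0], atol=0)


def test_attention_identical_states_uniform_weights():
    rng = np.random.default_rng(7)
    state = rng.normal(size=4)
    h = np.tile(state, (4, 1))
    _, w = attention_pool(h, rng.normal(size=(4, 4)), rng.normal(size=4),
                          rng.normal(size=(4, 1)))
    np.testing.assert_allclose(w, 0.25, atol=1e-12)


def test_attention_two_step_matches_hand_softmax():
    h = np.array([[1.0, 0.0], [0.0, 1.0]])
    Wd = np.array([[0.5, -0.2], [0.1, 0.3]])
    b = np.array([0.05, -0.1])
    u = np.array([[0.7], [-0.4]])
    mu = np.tanh(h @ Wd + b)
    scores = mu @ u.ravel()
    e = np.exp(scores - scores.max())
    want_w = e / e.sum()
    want_ctx = want_w @ h
    ctx, w = attention_pool(h, Wd, b, u)
    np.testing.assert_allclose(w, want_w, atol=1e-10)
    np.testing.assert_allclose(ctx, want_ctx, atol=1e-10)


def test_attention_weights_nonnegative_sum_one_shift_invariant():
    rng = np.random.default_rng(8)
    h = rng.normal(size=(6, 5))
    Wd, b, u = rng.normal(size=(5, 5)), rng.normal(size=5), rng.normal(size=(5, 1))
    _, w = attention_pool(h, Wd, b, u)
    assert (w >= 0).all()
    assert w.sum() == pytest.approx(1.0, abs=1e-6)


# -- full forward ----------------------------------------------------------------


def test_all_zero_weights_predict_head_bias():
    cfg = tiny_network_config()
    params = init_params(cfg)
    for p in params.values():
        p.data[:] = 0.0
    params["head_b"].data[:] = 3.25
    X = np.random.default_rng(9).normal(size=(4, 5, 2))
    np.testing.assert_allclose(forward_batch(params, cfg, X), 3.25, atol=1e-12)


@pytest.mark.parametrize("flags", [
    {}, {"no_cnn": True}, {"drop_one_gru_layer": True}, {"no_attention": True},
    {"bigru_combine": "concat"}, {"conv_same_pad_first": False},
])
def test_forward_matches_loop_oracle_for_all_variants(flags):
    cfg = tiny_network_config(seed=13, **flags)
    params = init_params(cfg)
    rng = np.random.default_rng(13)
    X = rng.normal(size=(5, 5, 2))
    got = forward_batch(params, cfg, X)
    want = np.array([oracle.forward_single(params, cfg, x) for x in X])
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_no_attention_changes_output_on_fixed_seed():
    cfg_full = tiny_network_config(seed=21)
    cfg_abl = tiny_network_config(seed=21, no_attention=True)
    X = np.random.default_rng(21).normal(size=(3, 5, 2))
    full = forward_batch(init_params(cfg_full), cfg_full, X)
    ablated = forward_batch(init_params(cfg_abl), cfg_abl, X)
    assert not np.allclose(full, ablated)


# -- parameter accounting --------------------------------------------------------


def analytic_count(cfg: NetworkConfig) -> int:
    total = 0
    c_in = cfg.input_channels
    if not cfg.no_cnn:
        for f in cfg.conv_filters:
            total += cfg.kernel_size * c_in * f + f
            c_in = f
        total += c_in * cfg.bottleneck_units + cfg.bottleneck_units
        c_in = cfg.bottleneck_units
    H = cfg.gru_hidden
    layers = cfg.gru_layers - 1 if cfg.drop_one_gru_layer else cfg.gru_layers
    d = c_in
    for _ in range(layers):
        total += 2 * (3 * (d * H + H * H + H))  # two directions, three gates
        if cfg.bigru_combine == "weighted":
            total += 3 * H
        d = 2 * H if cfg.bigru_combine == "concat" else H
    if not cfg.no_attention:
        total += d * d + d + d  # projection, bias, context vector
    total += d + 1  # head
    return total


def test_default_parameter_count_matches_analytic_formula():
    cfg = NetworkConfig()
    assert count_parameters(init_params(cfg)) == analytic_count(cfg)


def test_ablations_shrink_parameter_count():
    full = count_parameters(init_params(NetworkConfig()))
    for flag in ("no_cnn", "drop_one_gru_layer", "no_attention"):
        cfg = NetworkConfig(**{flag: True})
        assert count_parameters(init_params(cfg)) < full
        assert count_parameters(init_params(cfg)) == analytic_count(cfg)


def test_no_attention_removes_attention_parameters():
    params = init_params(NetworkConfig(no_attention=True))
    assert not any(k.startswith("attn") for k in params)


# -- training -------------------------------------------------------------------


def small_training_panel(n=40, seed=0):
    panel, _ = generate_panel(
        SyntheticConfig(n_counties=max(2, n // 4), year_start=2001,
                        year_end=2004, seed=seed)
    )
    from maizeyield.panel import normalize_panel
    normed, _ = normalize_panel(panel)
    return normed


def test_zero_learning_rate_leaves_parameters_unchanged():
    panel = small_training_panel()
    cfg = NetworkConfig(seed=3, epochs=2, learning_rate=0.0, gru_hidden=4,
                        conv_filters=(4, 3), bottleneck_units=3)
    params, history = train(panel, panel, cfg)
    fresh = init_params(cfg, rng=np.random.default_rng(3))
    for k in params:
        np.testing.assert_array_equal(params[k].data, fresh[k].data)
    # full-batch validation loss is flat when nothing updates
    assert history["val_loss"][0] == history["val_loss"][-1]


def test_training_is_bit_deterministic_for_fixed_seed():
    panel = small_training_panel()
    cfg = NetworkConfig(seed=5, epochs=2, gru_hidden=4, conv_filters=(4, 3),
                        bottleneck_units=3)
    p1, h1 = train(panel, panel, cfg)
    p2, h2 = train(panel, panel, cfg)
    assert h1 == h2
    for k in p1:
        np.testing.assert_array_equal(p1[k].data, p2[k].data)
    np.testing.assert_array_equal(predict(p1, cfg, panel), predict(p2, cfg, panel))


def test_constant_target_is_learned_within_budget():
    """A constant-yield panel is trivially learnable: train MAE falls below
    5% of the target value within the default epoch budget."""
    panel = small_training_panel(seed=1)
    panel = FeaturePanel(panel.county_ids, panel.years, panel.dynamic,
                         panel.periodic, np.full(len(panel), 6.0))
    cfg = NetworkConfig(seed=2, epochs=95, gru_hidden=4, conv_filters=(4, 3),
                        bottleneck_units=3)
    _, history = train(panel, None, cfg)
    assert history["train_loss"][-1] < 0.05 * 6.0


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train(None, None, NetworkConfig())


def test_predictions_are_order_equivariant_and_batch_consistent():
    panel = small_training_panel(seed=2)
    cfg = tiny_network_config(input_channels=24)
    params = init_params(cfg)
    preds = predict(params, cfg, panel)
    perm = np.random.default_rng(0).permutation(len(panel))
    np.testing.assert_allclose(predict(params, cfg, panel.subset(perm)),
                               preds[perm], atol=1e-12)
    one_by_one = np.array([
        predict(params, cfg, panel.subset(np.array([i])))[0]
        for i in range(0, len(panel), 7)
    ])
    np.testing.assert_allclose(one_by_one, preds[::7], atol=1e-9)


def test_model_archive_round_trip(tmp_path):
    cfg = tiny_network_config(seed=17)
    params = init_params(cfg)
    path = tmp_path / "model.npz"
    save_model(path, params, cfg)
    params2, cfg2 = load_model(path)
    assert cfg2 == cfg
    X = np.random.default_rng(17).normal(size=(3, 5, 2))
    np.testing.assert_array_equal(forward_batch(params, cfg, X),
                                  forward_batch(params2, cfg2, X))


def test_panel_to_inputs_layout(small_panel):
    panel, _ = small_panel
    X = panel_to_inputs(panel)
    assert X.shape == (len(panel), 5, 24)
    np.testing.assert_array_equal(X[:, :, :15], panel.dynamic)
    for t in range(5):
        np.testing.assert_array_equal(X[:, t, 15:], panel.periodic)
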