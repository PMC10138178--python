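import numpy as np
import pytest

from paddygrade import autodiff as ad
from paddygrade.data import MonitoringDataset, split_dataset, fit_normalizer
from paddygrade.decomposition import moving_average
from paddygrade.forecaster import (FrequencyForecaster, ModelConfig,
                                   PersistenceForecaster, baseline_forecasters,
                                   decoder_init, make_windows, train)
from paddygrade.frequency import feb as feb_ref, fea as fea_ref
from paddygrade.synthetic import simulate_dataset

TOY = ModelConfig(seq_len=16, label_len=8, pred_len=8, model_width=8, n_heads=1,
                  encoder_layers=1, decoder_layers=1, n_modes=3,
                  kernel_sizes=(3, 5), mode_policy="lowest", epochs=2, seed=0)

SMALL = ModelConfig(seq_len=14, label_len=7, pred_len=7, model_width=8, n_heads=2,
                    encoder_layers=1, decoder_layers=1, n_modes=3,
                    kernel_sizes=(3, 5), epochs=3, seed=1)


@pytest.fixture(scope="module")
def toy_model(small_dataset):
    nz = fit_normalizer(small_dataset)
    return FrequencyForecaster(TOY, nz)


# ---------------------------------------------------------- layer-level oracles
def test_feb_layer_matches_reference_composition(toy_model):
    """The differentiable FEB equals the scripted dft→select→multiply→pad→idft."""
    m = toy_model
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, TOY.seq_len, TOY.model_width))
    out = m.feb_layer(ad.constant(x), "enc0.feb", "enc").data
    w = m.params["enc0.feb.w.W"].data
    b = m.params["enc0.feb.w.b"].data
    r = m.params["enc0.feb.Rre"].data + 1j * m.params["enc0.feb.Rim"].data
    expected = feb_ref(x[0] @ w + b, r, m._const["enc"]["select"])
    assert np.allclose(out[0], expected, atol=1e-9)


def test_decomp_layer_matches_weighted_moving_averages(toy_model):
    m = toy_model
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, TOY.seq_len, TOY.model_width))
    seasonal, trend = m.decomp_layer(ad.constant(x), "enc0.dc1", "enc")
    logits = x @ m.params["enc0.dc1.logit.W"].data + m.params["enc0.dc1.logit.b"].data
    w = np.exp(logits - logits.max(-1, keepdims=True))
    w /= w.sum(-1, keepdims=True)
    expected = sum(w[..., j:j + 1] * moving_average(x[0], k)
                   for j, k in enumerate(TOY.kernel_sizes))
    assert np.allclose(trend.data[0], expected, atol=1e-9)
    assert np.allclose(seasonal.data + trend.data, x, atol=1e-12)
    assert np.allclose(w.sum(-1), 1.0)


def test_fea_layer_matches_reference_cross_attention(toy_model):
    m = toy_model
    rng = np.random.default_rng(2)
    q = rng.normal(size=(1, m._len_dec, TOY.model_width))
    kv = rng.normal(size=(1, m._len_enc, TOY.model_width))
    out = m.fea_layer(ad.constant(q), ad.constant(kv), "dec0.fea").data
    p = {k: m.params[f"dec0.fea.{k}.W"].data for k in ("Wq", "Wk", "Wv", "Wo")}
    pb = {k: m.params[f"dec0.fea.{k}.b"].data for k in ("Wq", "Wk", "Wv", "Wo")}
    ref = fea_ref(q[0] @ p["Wq"] + pb["Wq"], kv[0] @ p["Wk"] + pb["Wk"],
                  kv[0] @ p["Wv"] + pb["Wv"],
                  m._const["dec"]["select"], m._const["enc"]["select"])
    assert np.allclose(out[0], ref @ p["Wo"] + pb["Wo"], atol=1e-9)


def test_zero_input_propagates_to_zero_through_both_layers(toy_model):
    m = toy_model
    zq = ad.constant(np.zeros((2, m._len_dec, TOY.model_width)))
    zk = ad.constant(np.zeros((2, m._len_enc, TOY.model_width)))
    assert np.allclose(m.encoder_layer(zk, 0).data, 0.0, atol=1e-12)
    seasonal, trend = m.decoder_layer(zq, zk, 0)
    assert np.allclose(seasonal.data, 0.0, atol=1e-12)
    assert np.allclose(trend.data, 0.0, atol=1e-12)


def test_encoder_layer_preserves_shape(toy_model):
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, TOY.seq_len, TOY.model_width))
    assert toy_model.encoder_layer(ad.constant(x), 0).data.shape == x.shape


def test_embedding_is_linear_and_permutation_equivariant(toy_model):
    m = toy_model
    w = m.params["embed_enc.W"].data
    rng = np.random.default_rng(4)
    x = rng.normal(size=(TOY.seq_len, w.shape[0]))
    assert (x @ w).shape == (TOY.seq_len, TOY.model_width)
    perm = rng.permutation(w.shape[0])
    assert np.allclose(x[:, perm] @ w[perm], x @ w, atol=1e-12)
    assert np.allclose(np.zeros_like(x) @ w, 0.0)


# ----------------------------------------------------------------- decoder init
def test_decoder_init_constant_window():
    c = 4.2
    s_init, t_init = decoder_init(np.full((12, 2), c), label_len=6, pred_len=4)
    assert s_init.shape == (10, 2) and t_init.shape == (10, 2)
    assert np.allclose(s_init, 0.0, atol=1e-12)
    assert np.allclose(t_init, c)


def test_decoder_init_ramp_extends_window_mean():
    window = np.arange(1.0, 13.0)[:, None]
    s_init, t_init = decoder_init(window, label_len=6, pred_len=4)
    assert np.allclose(t_init[-4:], window.mean())
    assert np.allclose(s_init[-4:], 0.0)
    with pytest.raises(ValueError):
        decoder_init(window, label_len=20, pred_len=2)


# -------------------------------------------------------------------- training
def test_training_is_seed_deterministic(small_dataset):
    tr, _, va = split_dataset(small_dataset)
    _, h1 = train(SMALL, tr, va, context=small_dataset)
    _, h2 = train(SMALL, tr, va, context=small_dataset)
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_loss"] == h2["val_loss"]


def test_zero_learning_rate_freezes_parameters(small_dataset):
    tr, _, _ = split_dataset(small_dataset)
    cfg = ModelConfig(**{**SMALL.__dict__, "learning_rate": 0.0})
    model, hist = train(cfg, tr)
    fresh = FrequencyForecaster(cfg, model.normalizer)
    for k in model.params:
        assert np.array_equal(model.params[k].data, fresh.params[k].data)
    assert len(set(np.round(hist["train_loss"], 15))) == 1


def test_loss_decreases_on_noiseless_data():
    from paddygrade.synthetic import GrowthParams
    afb1 = GrowthParams("AFB1", 0.5, 20.0, 0.25, noise_sd=0.0)
    don = GrowthParams("DON", 60.0, 2500.0, 0.25, noise_sd=0.0)
    ds = simulate_dataset(n_bins=2, n_points=1, n_days=30, seed=3,
                          afb1=afb1, don=don)
    cfg = ModelConfig(**{**SMALL.__dict__, "epochs": 2, "learning_rate": 1e-3})
    _, hist = train(cfg, ds)
    assert hist["train_loss"][1] <= hist["train_loss"][0]


def test_forecast_contract_and_errors(small_dataset):
    tr, _, _ = split_dataset(small_dataset)
    model, _ = train(SMALL, tr)
    s = small_dataset.series[0]
    fc = model.forecast(s)
    assert fc.predicted.shape == (SMALL.pred_len, 2)
    assert np.allclose(fc.predicted, fc.seasonal_part + fc.trend_part, atol=1e-9)
    assert np.array_equal(fc.days, np.arange(31, 38))
    with pytest.raises(ValueError):
        model.forecast(s.slice_days(0, SMALL.seq_len - 1))
    with pytest.raises(ValueError):
        model.forecast(s, horizon=SMALL.pred_len + 1)


def test_save_load_roundtrip(small_dataset, tmp_path):
    tr, _, _ = split_dataset(small_dataset)
    model, _ = train(SMALL, tr)
    path = tmp_path / "model.json"
    model.save(path)
    from paddygrade.forecaster import _TrainableForecaster
    back = _TrainableForecaster.load(path)
    s = small_dataset.series[0]
    assert np.allclose(model.forecast(s).predicted, back.forecast(s).predicted,
                       atol=1e-12)


def test_window_extraction_requires_long_enough_series(small_dataset):
    nz = fit_normalizer(small_dataset)
    short = MonitoringDataset([small_dataset.series[0].slice_days(0, 10)])
    with pytest.raises(ValueError, match="windows"):
        make_windows(short, SMALL, nz)


# ------------------------------------------------------------------- baselines
def test_persistence_repeats_last_value(small_dataset):
    nz = fit_normalizer(small_dataset)
    model = PersistenceForecaster(SMALL, nz)
    s = small_dataset.series[0]
    fc = model.forecast(s)
    assert np.allclose(fc.predicted, s.values[-1], atol=1e-12)


def test_persistence_on_constant_series_has_zero_error():
    from conftest import constant_series
    ds = MonitoringDataset([constant_series()])
    model, _ = train(SMALL, ds, kind="persistence")
    fc = model.forecast(ds.series[0])
    assert np.allclose(fc.predicted, 5.0, atol=1e-12)


@pytest.mark.parametrize("kind", ["RNN", "GRU", "LSTM", "Transformer"])
def test_baseline_kinds_share_the_contract(kind, small_dataset):
    tr, _, _ = split_dataset(small_dataset)
    model, hist = train(SMALL, tr, kind=kind)
    assert len(hist["train_loss"]) == SMALL.epochs
    fc = model.forecast(small_dataset.series[0])
    assert fc.predicted.shape == (SMALL.pred_len, 2)


def test_unknown_kind_rejected(small_dataset):
    nz = fit_normalizer(small_dataset)
    with pytest.raises(ValueError):
        baseline_forecasters("prophet", SMALL, nz)


def test_config_invariants():
    with pytest.raises(ValueError):
        ModelConfig(label_len=20, seq_len=14)
    with pytest.raises(ValueError):
        ModelConfig(model_width=10, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(pred_len=0)
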