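"""The frequency-enhanced decomposition forecaster and baseline comparators.

The main model is an encoder–decoder: the encoder alternates Frequency
Enhanced Blocks and mixture-of-experts decompositions, keeping only the
seasonal stream; the decoder additionally runs Frequency Enhanced Attention
against the encoder's seasonal output and accumulates the trend components it
extracts, which are added back to the seasonal forecast at the end.  All
layers are built on :mod:`paddygrade.autodiff`; spectral weights are stored
as paired real/imaginary arrays.

Baselines (RNN, GRU, LSTM, a vanilla-attention Transformer, and persistence)
share the same train/forecast contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import autodiff as ad
from .autodiff import Tensor
from .data import MonitoringDataset, Normalizer, ToxinSeries, fit_normalizer
from .decomposition import moving_average_matrix
from .frequency import ModeSelection, dft_matrices, idft_matrices

__all__ = ["ModelConfig", "ForecastResult", "FrequencyForecaster",
           "PersistenceForecaster", "RecurrentForecaster", "TransformerForecaster",
           "baseline_forecasters", "train", "decoder_init", "make_windows"]

#: day-grid scale used by the time features (length of the default campaign)
DAY_SCALE = 30.0


@dataclass
class ModelConfig:
    """Hyperparameters of the forecaster.

    Defaults follow the best-scoring hyperparameter combination (learning
    rate 1e-4, 2 encoder layers, 1 decoder layer); window lengths are sized
    to 30-day monitoring series.
    """

    seq_len: int = 14
    label_len: int = 7
    pred_len: int = 7
    model_width: int = 64
    n_heads: int = 2
    encoder_layers: int = 2
    decoder_layers: int = 1
    n_modes: int = 8
    kernel_sizes: tuple[int, ...] = (5, 9, 13)
    activation: str = "tanh"            # FEA score activation: tanh | softmax
    mode_policy: str = "random-fixed"   # or "lowest"
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 0                 # 0 = full batch
    seed: int = 0

    def __post_init__(self):
        for name in ("seq_len", "label_len", "pred_len", "model_width", "n_heads",
                     "encoder_layers", "decoder_layers", "n_modes", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.label_len > self.seq_len:
            raise ValueError("label_len must not exceed seq_len")
        if self.model_width % self.n_heads:
            raise ValueError("model_width must be divisible by n_heads")


@dataclass
class ForecastResult:
    """Denormalized forecast with its additive seasonal/trend split."""

    days: np.ndarray                # future day indices, length = horizon
    predicted: np.ndarray           # (horizon, n_channels), µg/kg
    seasonal_part: np.ndarray
    trend_part: np.ndarray
    channels: tuple[str, ...]


# --------------------------------------------------------------------- features
def _time_features(days: np.ndarray) -> np.ndarray:
    d = np.asarray(days, dtype=float)
    return np.stack([d / DAY_SCALE,
                     np.sin(2 * np.pi * d / DAY_SCALE),
                     np.cos(2 * np.pi * d / DAY_SCALE)], axis=-1)


def _covariates(series: ToxinSeries, days: np.ndarray) -> np.ndarray:
    t = (series.condition.temperature - 20.0) / 10.0
    a = (series.condition.water_activity - 0.95) / 0.03
    cov = np.column_stack([np.full(len(days), t), np.full(len(days), a)])
    return np.concatenate([cov, _time_features(days)], axis=1)


N_COVARIATES = 5  # temperature, water activity, 3 time features


def make_windows(dataset: MonitoringDataset, config: ModelConfig,
                 normalizer: Normalizer, eval_days: set[int] | None = None):
    """Sliding forecast windows from every series.

    Each window has ``seq_len`` encoder days followed by ``pred_len`` target
    days.  With ``eval_days`` set, only windows whose target days intersect
    the set are kept and the returned mask marks the in-set target days, so
    partition blocks shorter than ``pred_len`` can still be evaluated without
    mixing their records into other partitions' scores.

    Returns a dict of arrays: enc_x (B, seq, C), enc_cov (B, seq, 5),
    dec_cov (B, label+pred, 5), target (B, pred, C), mask (B, pred, 1),
    target_days (B, pred), series_ref (list).
    """
    enc_x, enc_cov, dec_cov, target, mask, tdays, refs = [], [], [], [], [], [], []
    for s in dataset:
        n = s.n_days
        for t0 in range(0, n - config.seq_len - config.pred_len + 1):
            t_enc = slice(t0, t0 + config.seq_len)
            t_tgt = slice(t0 + config.seq_len, t0 + config.seq_len + config.pred_len)
            tgt_days = s.days[t_tgt]
            if eval_days is not None:
                m = np.isin(tgt_days, list(eval_days)).astype(float)
                if m.sum() == 0:
                    continue
            else:
                m = np.ones(config.pred_len)
            dec_days = np.concatenate([
                s.days[t0 + config.seq_len - config.label_len: t0 + config.seq_len],
                tgt_days])
            enc_x.append(normalizer.apply(s.values[t_enc]))
            enc_cov.append(_covariates(s, s.days[t_enc]))
            dec_cov.append(_covariates(s, dec_days))
            target.append(normalizer.apply(s.values[t_tgt]))
            mask.append(m[:, None])
            tdays.append(tgt_days)
            refs.append((s.sample_id, t0))
    if not enc_x:
        raise ValueError("no valid windows: series shorter than seq_len + pred_len")
    return {"enc_x": np.stack(enc_x), "enc_cov": np.stack(enc_cov),
            "dec_cov": np.stack(dec_cov), "target": np.stack(target),
            "mask": np.stack(mask), "target_days": np.stack(tdays), "refs": refs}


def decoder_init(window: np.ndarray, label_len: int, pred_len: int,
                 kernel_sizes: Sequence[int] = (5, 9, 13)):
    """Warm-start pair (seasonal_init, trend_init) for the decoder.

    Decomposes the last ``label_len`` days of the encoder window with the
    equal-weight filter mixture; the seasonal part is extended with
    ``pred_len`` zeros and the trend part with ``pred_len`` copies of the
    window mean.  ``window`` is (T, C) or (B, T, C).
    """
    w = np.asarray(window, dtype=float)
    squeeze = w.ndim == 2
    if squeeze:
        w = w[None]
    if label_len > w.shape[1]:
        raise ValueError("label_len exceeds the encoder window length")
    tail = w[:, -label_len:, :]
    trend = np.mean([uniform_filter1d(tail, size=k, axis=1, mode="nearest")
                     for k in kernel_sizes], axis=0)
    seasonal = tail - trend
    zeros = np.zeros((w.shape[0], pred_len, w.shape[2]))
    mean_ext = np.repeat(w.mean(axis=1, keepdims=True), pred_len, axis=1)
    s_init = np.concatenate([seasonal, zeros], axis=1)
    t_init = np.concatenate([trend, mean_ext], axis=1)
    if squeeze:
        return s_init[0], t_init[0]
    return s_init, t_init


# ----------------------------------------------------------------- base trainer
class _TrainableForecaster:
    """Shared window extraction, Adam training loop, and forecast plumbing."""

    kind = "base"

    def __init__(self, config: ModelConfig, normalizer: Normalizer):
        self.config = config
        self.normalizer = normalizer
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # subclasses implement _build and _predict
    def _build(self) -> None:
        raise NotImplementedError

    def _predict(self, batch: dict) -> Tensor:
        """Normalized predictions (B, pred_len, C)."""
        raise NotImplementedError

    def _param(self, name: str, shape, scale: float = 0.02) -> Tensor:
        self.params[name] = ad.parameter(scale * self._rng.standard_normal(shape))
        return self.params[name]

    def _zeros(self, name: str, shape) -> Tensor:
        self.params[name] = ad.parameter(np.zeros(shape))
        return self.params[name]

    def _ones(self, name: str, shape) -> Tensor:
        self.params[name] = ad.parameter(np.ones(shape))
        return self.params[name]

    def _linear(self, x: Tensor, prefix: str) -> Tensor:
        return x @ self.params[f"{prefix}.W"] + self.params[f"{prefix}.b"]

    def _loss(self, batch: dict) -> Tensor:
        pred = self._predict(batch)
        err = pred - ad.constant(batch["target"])
        masked = err * err * ad.constant(batch["mask"])
        return masked.sum() * (1.0 / (batch["mask"].sum() * batch["target"].shape[2]))

    def fit(self, train: MonitoringDataset, validation: MonitoringDataset | None = None,
            context: MonitoringDataset | None = None) -> dict:
        """Minimize masked MSE on normalized forecasts with Adam.

        Validation windows come from ``validation`` itself when its series are
        long enough, otherwise from ``context`` (full-history series) with the
        loss masked to validation days.  The parameters with the best
        validation loss (train loss if no validation windows exist) are kept.
        """
        cfg = self.config
        train_batch = make_windows(train, cfg, self.normalizer)
        val_batch = None
        if validation is not None and len(validation):
            try:
                val_batch = make_windows(validation, cfg, self.normalizer)
            except ValueError:
                if context is not None:
                    days = {int(d) for s in validation for d in s.days}
                    val_batch = make_windows(context, cfg, self.normalizer,
                                             eval_days=days)
        opt = ad.Adam(self.params.values(), lr=cfg.learning_rate)
        history = {"train_loss": [], "val_loss": []}
        best = (np.inf, None)
        for _ in range(cfg.epochs):
            opt.zero_grad()
            loss = self._loss(train_batch)
            loss.backward()
            opt.step()
            tl = float(loss.data)
            history["train_loss"].append(tl)
            vl = float(self._loss(val_batch).data) if val_batch is not None else tl
            history["val_loss"].append(vl)
            if vl < best[0]:
                best = (vl, {k: p.data.copy() for k, p in self.params.items()})
        if best[1] is not None:
            for k, p in self.params.items():
                p.data = best[1][k]
        return history

    def _forecast_batch(self, batch: dict) -> np.ndarray:
        return self._predict(batch).data

    def forecast(self, series: ToxinSeries, horizon: int | None = None) -> ForecastResult:
        cfg = self.config
        horizon = cfg.pred_len if horizon is None else horizon
        if horizon < 1 or horizon > cfg.pred_len:
            raise ValueError(f"horizon must be in 1..pred_len ({cfg.pred_len})")
        if series.n_days < cfg.seq_len:
            raise ValueError(f"series provides {series.n_days} days; "
                             f"seq_len {cfg.seq_len} history required")
        last = series.days[-1]
        future = np.arange(last + 1, last + cfg.pred_len + 1)
        enc_days = series.days[-cfg.seq_len:]
        dec_days = np.concatenate([enc_days[-cfg.label_len:], future])
        batch = {
            "enc_x": self.normalizer.apply(series.values[-cfg.seq_len:])[None],
            "enc_cov": _covariates(series, enc_days)[None],
            "dec_cov": _covariates(series, dec_days)[None],
        }
        pred_n, seas_n, trend_n = self._predict_parts(batch)
        sd, mean = self.normalizer.sd, self.normalizer.mean
        return ForecastResult(
            days=future[:horizon],
            predicted=(pred_n[0] * sd + mean)[:horizon],
            seasonal_part=(seas_n[0] * sd)[:horizon],
            trend_part=(trend_n[0] * sd + mean)[:horizon],
            channels=self.normalizer.channels)

    def _predict_parts(self, batch: dict):
        """(predicted, seasonal, trend) in normalized units; default: all-trend."""
        pred = self._predict(batch).data
        return pred, np.zeros_like(pred), pred

    # ------------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        payload = {"kind": self.kind, "config": asdict(self.config),
                   "normalizer": {"channels": list(self.normalizer.channels),
                                  "mean": self.normalizer.mean.tolist(),
                                  "sd": self.normalizer.sd.tolist()},
                   "params": {k: p.data.tolist() for k, p in self.params.items()}}
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path) -> "_TrainableForecaster":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
        config = ModelConfig(**cfg)
        nz = payload["normalizer"]
        normalizer = Normalizer(channels=tuple(nz["channels"]),
                                mean=np.array(nz["mean"]), sd=np.array(nz["sd"]))
        model = baseline_forecasters(payload["kind"], config, normalizer)
        for k, v in payload["params"].items():
            model.params[k].data = np.asarray(v, dtype=float)
        return model


# ------------------------------------------------------------------ main model
class FrequencyForecaster(_TrainableForecaster):
    """Encoder–decoder forecaster with frequency-enhanced sublayers."""

    kind = "FEDformer"

    N_CHANNELS = 2

    def _build(self) -> None:
        cfg = self.config
        w, c = cfg.model_width, self.N_CHANNELS
        d_in = c + N_COVARIATES
        self._len_enc = cfg.seq_len
        self._len_dec = cfg.label_len + cfg.pred_len
        # fixed spectral/selection/averaging operators per stream length
        self._const: dict = {}
        for tag, length in (("enc", self._len_enc), ("dec", self._len_dec)):
            n_freq = length // 2 + 1
            sel = ModeSelection.build(length, cfg.n_modes, cfg.mode_policy,
                                      seed=cfg.seed + (0 if tag == "enc" else 1))
            p = np.zeros((sel.n_modes, n_freq))
            p[np.arange(sel.n_modes), list(sel.mode_indices)] = 1.0
            cmat, smat = dft_matrices(length)
            cr, ci = idft_matrices(length)
            self._const[tag] = {
                "select": sel, "P": ad.constant(p),
                "C": ad.constant(cmat), "S": ad.constant(smat),
                "Cr": ad.constant(cr), "Ci": ad.constant(ci),
                "A": [ad.constant(moving_average_matrix(length, k))
                      for k in cfg.kernel_sizes]}
        # embeddings
        self._param("embed_enc.W", (d_in, w));  self._zeros("embed_enc.b", (w,))
        self._param("embed_dec.W", (d_in, w));  self._zeros("embed_dec.b", (w,))
        n_k = len(cfg.kernel_sizes)
        m_enc = self._const["enc"]["select"].n_modes
        m_dec = self._const["dec"]["select"].n_modes

        def feb_params(prefix, m):
            self._param(f"{prefix}.w.W", (w, w)); self._zeros(f"{prefix}.w.b", (w,))
            self._param(f"{prefix}.Rre", (m, w, w), scale=0.02)
            self._param(f"{prefix}.Rim", (m, w, w), scale=0.02)

        def decomp_params(prefix):
            self._param(f"{prefix}.logit.W", (w, n_k))
            self._zeros(f"{prefix}.logit.b", (n_k,))

        def ff_params(prefix):
            self._param(f"{prefix}.1.W", (w, 2 * w)); self._zeros(f"{prefix}.1.b", (2 * w,))
            self._param(f"{prefix}.2.W", (2 * w, w)); self._zeros(f"{prefix}.2.b", (w,))

        for i in range(cfg.encoder_layers):
            feb_params(f"enc{i}.feb", m_enc)
            decomp_params(f"enc{i}.dc1")
            ff_params(f"enc{i}.ff")
            decomp_params(f"enc{i}.dc2")
        for i in range(cfg.decoder_layers):
            feb_params(f"dec{i}.feb", m_dec)
            for j in (1, 2, 3):
                decomp_params(f"dec{i}.dc{j}")
            ff_params(f"dec{i}.ff")
            for name in ("Wq", "Wk", "Wv", "Wo"):
                self._param(f"dec{i}.fea.{name}.W", (w, w))
                self._zeros(f"dec{i}.fea.{name}.b", (w,))
            self._ones(f"dec{i}.ln.g", (w,)); self._zeros(f"dec{i}.ln.b", (w,))
            for j in (1, 2, 3):
                self._param(f"dec{i}.trend{j}.W", (w, c))
                self._zeros(f"dec{i}.trend{j}.b", (c,))
        self._param("out.W", (w, c)); self._zeros("out.b", (c,))

    # ------------------------------------------------------------- sublayers
    def _dft(self, x: Tensor, tag: str) -> tuple[Tensor, Tensor]:
        k = self._const[tag]
        return (ad.einsum("fl,bld->bfd", k["C"], x),
                ad.einsum("fl,bld->bfd", k["S"], x))

    def _idft(self, re: Tensor, im: Tensor, tag: str) -> Tensor:
        k = self._const[tag]
        return (ad.einsum("lf,bfd->bld", k["Cr"], re)
                + ad.einsum("lf,bfd->bld", k["Ci"], im))

    def _select(self, re: Tensor, im: Tensor, tag: str) -> tuple[Tensor, Tensor]:
        p = self._const[tag]["P"]
        return (ad.einsum("mf,bfd->bmd", p, re), ad.einsum("mf,bfd->bmd", p, im))

    def _pad(self, re: Tensor, im: Tensor, tag: str) -> tuple[Tensor, Tensor]:
        p = self._const[tag]["P"]
        return (ad.einsum("mf,bmd->bfd", p, re), ad.einsum("mf,bmd->bfd", p, im))

    def feb_layer(self, x: Tensor, prefix: str, tag: str) -> Tensor:
        """idft(pad(select(dft(w·x)) ⊙ R)) with complex R as re/im pairs."""
        xp = self._linear(x, f"{prefix}.w")
        re, im = self._select(*self._dft(xp, tag), tag)
        rre, rim = self.params[f"{prefix}.Rre"], self.params[f"{prefix}.Rim"]
        ore = ad.einsum("bmd,mde->bme", re, rre) - ad.einsum("bmd,mde->bme", im, rim)
        oim = ad.einsum("bmd,mde->bme", re, rim) + ad.einsum("bmd,mde->bme", im, rre)
        return self._idft(*self._pad(ore, oim, tag), tag)

    def decomp_layer(self, x: Tensor, prefix: str, tag: str) -> tuple[Tensor, Tensor]:
        """Seasonal/trend split with learnable per-time-step mixing weights."""
        weights = ad.softmax(self._linear(x, f"{prefix}.logit"), axis=-1)
        trend = None
        for j, a in enumerate(self._const[tag]["A"]):
            term = weights[:, :, j:j + 1] * ad.einsum("lm,bmd->bld", a, x)
            trend = term if trend is None else trend + term
        return x - trend, trend

    def ff_layer(self, x: Tensor, prefix: str) -> Tensor:
        return self._linear(ad.relu(self._linear(x, f"{prefix}.1")), f"{prefix}.2")

    def fea_layer(self, q: Tensor, kv: Tensor, prefix: str) -> Tensor:
        """Cross-attention between truncated decoder/encoder spectra."""
        cfg = self.config
        h = cfg.n_heads
        dh = cfg.model_width // h
        qp = self._linear(q, f"{prefix}.Wq").reshape(-1, self._len_dec, cfg.model_width)
        kp = self._linear(kv, f"{prefix}.Wk")
        vp = self._linear(kv, f"{prefix}.Wv")
        qre, qim = self._select(*self._dft(qp, "dec"), "dec")
        kre, kim = self._select(*self._dft(kp, "enc"), "enc")
        vre, vim = self._select(*self._dft(vp, "enc"), "enc")
        mq = qre.shape[1]
        mk = kre.shape[1]
        qre = qre.reshape(-1, mq, h, dh); qim = qim.reshape(-1, mq, h, dh)
        kre = kre.reshape(-1, mk, h, dh); kim = kim.reshape(-1, mk, h, dh)
        vre = vre.reshape(-1, mk, h, dh); vim = vim.reshape(-1, mk, h, dh)
        # score = Q' · conj(K')ᵀ per head
        sre = (ad.einsum("bmhd,bnhd->bhmn", qre, kre)
               + ad.einsum("bmhd,bnhd->bhmn", qim, kim))
        sim = (ad.einsum("bmhd,bnhd->bhmn", qim, kre)
               - ad.einsum("bmhd,bnhd->bhmn", qre, kim))
        if cfg.activation == "tanh":
            sre, sim = ad.tanh(sre), ad.tanh(sim)
        elif cfg.activation == "softmax":
            mag = ad.sqrt(sre * sre + sim * sim + ad.constant(1e-12))
            sre = ad.softmax(mag, axis=-1)
            sim = sre * 0.0
        elif cfg.activation != "identity":
            raise ValueError(f"unknown FEA activation {cfg.activation!r}")
        ore = (ad.einsum("bhmn,bnhd->bmhd", sre, vre)
               - ad.einsum("bhmn,bnhd->bmhd", sim, vim))
        oim = (ad.einsum("bhmn,bnhd->bmhd", sre, vim)
               + ad.einsum("bhmn,bnhd->bmhd", sim, vre))
        ore = ore.reshape(-1, mq, cfg.model_width)
        oim = oim.reshape(-1, mq, cfg.model_width)
        out = self._idft(*self._pad(ore, oim, "dec"), "dec")
        return self._linear(out, f"{prefix}.Wo")

    def encoder_layer(self, x: Tensor, i: int) -> Tensor:
        """FEB + residual, decompose (keep seasonal); feed-forward + residual,
        decompose again (keep seasonal).  Trends are discarded."""
        s1, _ = self.decomp_layer(self.feb_layer(x, f"enc{i}.feb", "enc") + x,
                                  f"enc{i}.dc1", "enc")
        s2, _ = self.decomp_layer(self.ff_layer(s1, f"enc{i}.ff") + s1,
                                  f"enc{i}.dc2", "enc")
        return s2

    def decoder_layer(self, x: Tensor, s_en: Tensor, i: int) -> tuple[Tensor, Tensor]:
        """Returns (final seasonal stream, summed projected trends)."""
        s1, t1 = self.decomp_layer(self.feb_layer(x, f"dec{i}.feb", "dec") + x,
                                   f"dec{i}.dc1", "dec")
        cross = ad.layer_norm(s_en, self.params[f"dec{i}.ln.g"],
                              self.params[f"dec{i}.ln.b"])
        s2, t2 = self.decomp_layer(self.fea_layer(s1, cross, f"dec{i}.fea") + s1,
                                   f"dec{i}.dc2", "dec")
        s3, t3 = self.decomp_layer(self.ff_layer(s2, f"dec{i}.ff") + s2,
                                   f"dec{i}.dc3", "dec")
        trend = (self._linear(t1, f"dec{i}.trend1")
                 + self._linear(t2, f"dec{i}.trend2")
                 + self._linear(t3, f"dec{i}.trend3"))
        return s3, trend

    # --------------------------------------------------------------- forward
    def _forward(self, batch: dict) -> tuple[Tensor, Tensor, Tensor]:
        cfg = self.config
        s_init, t_init = decoder_init(batch["enc_x"], cfg.label_len, cfg.pred_len,
                                      cfg.kernel_sizes)
        enc_in = ad.constant(np.concatenate([batch["enc_x"], batch["enc_cov"]], axis=2))
        dec_in = ad.constant(np.concatenate([s_init, batch["dec_cov"]], axis=2))
        x = self._linear(enc_in, "embed_enc")
        for i in range(cfg.encoder_layers):
            x = self.encoder_layer(x, i)
        s_en = x
        y = self._linear(dec_in, "embed_dec")
        trend_acc = ad.constant(t_init)
        for i in range(cfg.decoder_layers):
            y, tr = self.decoder_layer(y, s_en, i)
            trend_acc = trend_acc + tr
        seasonal_out = self._linear(y, "out")
        pred = seasonal_out + trend_acc
        sl = slice(self._len_dec - cfg.pred_len, self._len_dec)
        return (pred[:, sl, :], seasonal_out[:, sl, :], trend_acc[:, sl, :])

    def _predict(self, batch: dict) -> Tensor:
        return self._forward(batch)[0]

    def _predict_parts(self, batch: dict):
        pred, seas, trend = self._forward(batch)
        return pred.data, seas.data, trend.data


# ------------------------------------------------------------------- baselines
class PersistenceForecaster(_TrainableForecaster):
    """Repeats the last observed value; the no-skill reference."""

    kind = "persistence"

    def _build(self) -> None:
        pass

    def fit(self, train, validation=None, context=None) -> dict:
        return {"train_loss": [], "val_loss": []}

    def _predict(self, batch: dict) -> Tensor:
        last = batch["enc_x"][:, -1:, :]
        return ad.constant(np.repeat(last, self.config.pred_len, axis=1))


class RecurrentForecaster(_TrainableForecaster):
    """RNN/GRU/LSTM encoder with a direct multi-step linear head."""

    HIDDEN = 32

    def __init__(self, config, normalizer, cell: str = "RNN"):
        self.cell = cell
        self.kind = cell
        super().__init__(config, normalizer)

    def _build(self) -> None:
        d_in = 2 + N_COVARIATES
        h = self.HIDDEN
        gates = {"RNN": 1, "GRU": 3, "LSTM": 4}[self.cell]
        self._param("in.W", (d_in, h * gates)); self._zeros("in.b", (h * gates,))
        self._param("rec.W", (h, h * gates))
        self._param("head.W", (h, self.config.pred_len * 2))
        self._zeros("head.b", (self.config.pred_len * 2,))

    def _predict(self, batch: dict) -> Tensor:
        cfg = self.config
        x = np.concatenate([batch["enc_x"], batch["enc_cov"]], axis=2)
        b = x.shape[0]
        hsz = self.HIDDEN
        hid = ad.constant(np.zeros((b, hsz)))
        cell_state = ad.constant(np.zeros((b, hsz)))
        xin = ad.constant(x) @ self.params["in.W"] + self.params["in.b"]
        for t in range(cfg.seq_len):
            pre = xin[:, t, :]
            rec = hid @ self.params["rec.W"]
            if self.cell == "RNN":
                hid = ad.tanh(pre + rec)
            elif self.cell == "GRU":
                z = ad.sigmoid(pre[:, :hsz] + rec[:, :hsz])
                r = ad.sigmoid(pre[:, hsz:2 * hsz] + rec[:, hsz:2 * hsz])
                cand = ad.tanh(pre[:, 2 * hsz:] + r * rec[:, 2 * hsz:])
                hid = (ad.constant(1.0) - z) * hid + z * cand
            else:  # LSTM
                i = ad.sigmoid(pre[:, :hsz] + rec[:, :hsz])
                f = ad.sigmoid(pre[:, hsz:2 * hsz] + rec[:, hsz:2 * hsz])
                o = ad.sigmoid(pre[:, 2 * hsz:3 * hsz] + rec[:, 2 * hsz:3 * hsz])
                g = ad.tanh(pre[:, 3 * hsz:] + rec[:, 3 * hsz:])
                cell_state = f * cell_state + i * g
                hid = o * ad.tanh(cell_state)
        out = hid @ self.params["head.W"] + self.params["head.b"]
        return out.reshape(-1, cfg.pred_len, 2)


class TransformerForecaster(_TrainableForecaster):
    """One time-domain self-attention layer with a direct multi-step head."""

    kind = "Transformer"

    def _build(self) -> None:
        cfg = self.config
        d_in = 2 + N_COVARIATES
        w = cfg.model_width
        self._param("embed.W", (d_in, w)); self._zeros("embed.b", (w,))
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self._param(f"attn.{name}.W", (w, w)); self._zeros(f"attn.{name}.b", (w,))
        self._param("ff.1.W", (w, 2 * w)); self._zeros("ff.1.b", (2 * w,))
        self._param("ff.2.W", (2 * w, w)); self._zeros("ff.2.b", (w,))
        self._ones("ln1.g", (w,)); self._zeros("ln1.b", (w,))
        self._ones("ln2.g", (w,)); self._zeros("ln2.b", (w,))
        self._param("head.W", (w, cfg.pred_len * 2))
        self._zeros("head.b", (cfg.pred_len * 2,))

    def _predict(self, batch: dict) -> Tensor:
        cfg = self.config
        w = cfg.model_width
        x = ad.constant(np.concatenate([batch["enc_x"], batch["enc_cov"]], axis=2))
        e = self._linear(x, "embed")
        q = self._linear(e, "attn.Wq")
        k = self._linear(e, "attn.Wk")
        v = self._linear(e, "attn.Wv")
        score = ad.softmax(ad.einsum("bld,bmd->blm", q, k) * (1.0 / np.sqrt(w)), axis=-1)
        att = self._linear(ad.einsum("blm,bmd->bld", score, v), "attn.Wo")
        y = ad.layer_norm(e + att, self.params["ln1.g"], self.params["ln1.b"])
        z = self._linear(ad.relu(self._linear(y, "ff.1")), "ff.2")
        z = ad.layer_norm(y + z, self.params["ln2.g"], self.params["ln2.b"])
        out = z.mean(axis=1) @ self.params["head.W"] + self.params["head.b"]
        return out.reshape(-1, cfg.pred_len, 2)


def baseline_forecasters(kind: str, config: ModelConfig,
                         normalizer: Normalizer) -> _TrainableForecaster:
    """Model factory sharing the train/forecast contract across kinds."""
    if kind == "FEDformer":
        return FrequencyForecaster(config, normalizer)
    if kind == "persistence":
        return PersistenceForecaster(config, normalizer)
    if kind in ("RNN", "GRU", "LSTM"):
        return RecurrentForecaster(config, normalizer, cell=kind)
    if kind == "Transformer":
        return TransformerForecaster(config, normalizer)
    raise ValueError(f"unknown forecaster kind {kind!r}")


def train(config: ModelConfig, train_set: MonitoringDataset,
          validation: MonitoringDataset | None = None,
          context: MonitoringDataset | None = None,
          kind: str = "FEDformer") -> tuple[_TrainableForecaster, dict]:
    """Train a forecaster; returns (model with best validation loss, history)."""
    if len(train_set) == 0:
        raise ValueError("training dataset is empty")
    normalizer = fit_normalizer(train_set, strict=False)
    model = baseline_forecasters(kind, config, normalizer)
    history = model.fit(train_set, validation, context)
    return model, history
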