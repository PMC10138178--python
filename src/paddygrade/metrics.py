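"""Forecast-error metrics and the silhouette coefficient.

All percentage metrics are returned on the 0–100 scale (a value of 12.5 means
12.5%).  ``silhouette`` is the mean per-point coefficient (b−a)/max(a,b) with
``a`` the mean intra-cluster distance and ``b`` the smallest mean distance to
another cluster; points in singleton clusters score 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["mape", "mse", "rmse", "mae", "smape", "mspe", "silhouette",
           "all_forecast_metrics"]


def _paired(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yp.shape:
        raise ValueError("true and predicted series must have equal length")
    if y.size < 1:
        raise ValueError("series must be nonempty")
    return y, yp


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, 100/n · Σ|y'−y|/|y| (percent)."""
    y, yp = _paired(y_true, y_pred)
    if np.any(y == 0):
        raise ValueError("MAPE undefined: true value equal to zero")
    return float(100.0 * np.mean(np.abs((yp - y) / y)))


def mse(y_true, y_pred) -> float:
    y, yp = _paired(y_true, y_pred)
    return float(np.mean((yp - y) ** 2))


def rmse(y_true, y_pred) -> float:
    return float(np.sqrt(mse(y_true, y_pred)))


def mae(y_true, y_pred) -> float:
    y, yp = _paired(y_true, y_pred)
    return float(np.mean(np.abs(yp - y)))


def smape(y_true, y_pred) -> float:
    """Symmetric MAPE, 100/n · Σ|y'−y| / ((|y'|+|y|)/2) (percent)."""
    y, yp = _paired(y_true, y_pred)
    denom = (np.abs(yp) + np.abs(y)) / 2.0
    if np.any(denom == 0):
        raise ValueError("SMAPE undefined: true and predicted both zero")
    return float(100.0 * np.mean(np.abs(yp - y) / denom))


def mspe(y_true, y_pred) -> float:
    """Mean squared percentage error, 100²/n · Σ((y'−y)/y)² (percent²)."""
    y, yp = _paired(y_true, y_pred)
    if np.any(y == 0):
        raise ValueError("MSPE undefined: true value equal to zero")
    return float(100.0 ** 2 * np.mean(((yp - y) / y) ** 2))


def all_forecast_metrics(y_true, y_pred) -> dict[str, float]:
    return {"MAE": mae(y_true, y_pred), "MSE": mse(y_true, y_pred),
            "RMSE": rmse(y_true, y_pred), "MAPE": mape(y_true, y_pred),
            "MSPE": mspe(y_true, y_pred), "SMAPE": smape(y_true, y_pred)}


def silhouette(points, labels) -> float:
    """Mean silhouette coefficient with Euclidean distances.

    Degenerate per-point cases (singleton cluster, or a=b=0 when several
    points coincide) score 0.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    lab = np.asarray(labels)
    if x.shape[0] != lab.shape[0]:
        raise ValueError("points and labels must have equal length")
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = cdist(x, x)
    n = x.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = lab == lab[i]
        if own.sum() == 1:
            continue  # singleton: s = 0
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, lab == c].mean() for c in uniq if c != lab[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())
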