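"""Frequency-domain operators: spectra, mode selection, FEB and FEA.

The Frequency Enhanced Block (FEB) transforms a sequence to the frequency
domain, keeps a fixed subset of modes, multiplies them by learnable complex
weights, zero-pads the rest of the spectrum and inverse-transforms.  The
Frequency Enhanced Attention (FEA) computes cross-attention between the
truncated spectra of a decoder query stream and encoder key/value streams.

This module holds the NumPy reference forms used directly and as the contract
for the differentiable layers in :mod:`paddygrade.forecaster`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ModeSelection", "dft", "idft", "select_modes", "feb", "fea",
           "dft_matrices", "idft_matrices"]


@dataclass(frozen=True)
class ModeSelection:
    """Which rfft frequency indices a block retains; fixed at construction."""

    mode_indices: tuple[int, ...]
    seq_len: int

    def __post_init__(self):
        n_freq = self.seq_len // 2 + 1
        if len(set(self.mode_indices)) != len(self.mode_indices):
            raise ValueError("mode indices must be unique")
        for m in self.mode_indices:
            if not 0 <= m < n_freq:
                raise ValueError(f"mode index {m} out of range for length {self.seq_len}")

    @classmethod
    def build(cls, seq_len: int, n_modes: int, policy: str = "random-fixed",
              seed: int = 0) -> "ModeSelection":
        """Draw the retained modes once: ``lowest`` keeps indices 0..M-1,
        ``random-fixed`` samples M distinct indices with a seeded generator."""
        n_freq = seq_len // 2 + 1
        m = min(n_modes, n_freq)
        if policy == "lowest":
            idx = tuple(range(m))
        elif policy == "random-fixed":
            rng = np.random.default_rng(seed)
            idx = tuple(sorted(rng.choice(n_freq, size=m, replace=False).tolist()))
        else:
            raise ValueError(f"unknown mode-selection policy {policy!r}")
        return cls(mode_indices=idx, seq_len=seq_len)

    @property
    def n_modes(self) -> int:
        return len(self.mode_indices)


def dft(x: np.ndarray) -> np.ndarray:
    """Real-input discrete Fourier transform along axis 0 (length L//2+1)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 1:
        raise ValueError("input must have length >= 1")
    return np.fft.rfft(x, axis=0)


def idft(spectrum: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`dft`; ``length`` must match the original sequence."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape[0] != length // 2 + 1:
        raise ValueError(
            f"spectrum has {spectrum.shape[0]} bins; length {length} needs {length // 2 + 1}")
    return np.fft.irfft(spectrum, n=length, axis=0)


def select_modes(spectrum: np.ndarray, selection: ModeSelection) -> np.ndarray:
    """Keep exactly the selected frequency indices, in index order."""
    spectrum = np.asarray(spectrum)
    n_freq = selection.seq_len // 2 + 1
    if spectrum.shape[0] != n_freq:
        raise ValueError("spectrum length does not match the selection's sequence length")
    return spectrum[list(selection.mode_indices)]


def _pad_modes(reduced: np.ndarray, selection: ModeSelection) -> np.ndarray:
    full_shape = (selection.seq_len // 2 + 1,) + reduced.shape[1:]
    full = np.zeros(full_shape, dtype=complex)
    full[list(selection.mode_indices)] = reduced
    return full


def feb(x: np.ndarray, weights: np.ndarray, selection: ModeSelection) -> np.ndarray:
    """Frequency Enhanced Block, reference form.

    ``x`` is (L,) or (L, D); ``weights`` R is complex with shape (M,) / (M, D)
    (per-mode diagonal) or (M, D, D) (per-mode channel mixing).  Output is the
    real sequence idft(pad(select(dft(x)) ⊙ R)) of x's length.
    """
    weights = np.asarray(weights)
    if not np.all(np.isfinite(weights.real)) or not np.all(np.isfinite(weights.imag)):
        raise ValueError("spectral weights must be finite")
    x = np.asarray(x, dtype=float)
    q = select_modes(dft(x), selection)
    if weights.ndim == 3:
        if q.ndim != 2:
            raise ValueError("channel-mixing weights require a (L, D) input")
        prod = np.einsum("md,mde->me", q, weights)
    else:
        prod = q * weights
    return idft(_pad_modes(prod, selection), x.shape[0])


def fea(q: np.ndarray, k: np.ndarray, v: np.ndarray,
        q_selection: ModeSelection, kv_selection: ModeSelection,
        activation: Callable[[np.ndarray], np.ndarray] | None = None) -> np.ndarray:
    """Frequency Enhanced Attention, reference form.

    q is (Lq, D) from the decoder stream, k and v are (Lkv, D) from the
    encoder stream.  Each is transformed, truncated to its selected modes,
    the score Q'·K'ᵀ is passed through ``activation`` (default: tanh applied
    independently to real and imaginary parts), multiplied with V', zero-padded
    back to q's spectrum and inverse-transformed to a real sequence of q's
    length.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float).T).T
    k = np.atleast_2d(np.asarray(k, dtype=float).T).T
    v = np.atleast_2d(np.asarray(v, dtype=float).T).T
    if q.shape[1] != k.shape[1] or k.shape != v.shape:
        raise ValueError("q, k, v widths are incompatible")
    if activation is None:
        activation = lambda z: np.tanh(z.real) + 1j * np.tanh(z.imag)
    qf = select_modes(dft(q), q_selection)          # (Mq, D)
    kf = select_modes(dft(k), kv_selection)         # (Mk, D)
    vf = select_modes(dft(v), kv_selection)         # (Mk, D)
    score = activation(qf @ kf.conj().T)            # (Mq, Mk)
    out = score @ vf                                # (Mq, D)
    return idft(_pad_modes(out, q_selection), q.shape[0])


# ---------------------------------------------------------------- matrix forms
def dft_matrices(length: int) -> tuple[np.ndarray, np.ndarray]:
    """Real matrices (C, S) with rfft(x) = C @ x + i · S @ x, shape (F, L)."""
    f = np.arange(length // 2 + 1)[:, None]
    t = np.arange(length)[None, :]
    ang = 2.0 * np.pi * f * t / length
    return np.cos(ang), -np.sin(ang)


def idft_matrices(length: int) -> tuple[np.ndarray, np.ndarray]:
    """Real matrices (Cr, Ci) with irfft(X) = Cr @ Re X + Ci @ Im X, shape (L, F)."""
    n_freq = length // 2 + 1
    f = np.arange(n_freq)[None, :]
    t = np.arange(length)[:, None]
    ang = 2.0 * np.pi * f * t / length
    w = np.full(n_freq, 2.0)
    w[0] = 1.0
    if length % 2 == 0:
        w[-1] = 1.0
    cr = np.cos(ang) * w / length
    ci = -np.sin(ang) * w / length
    return cr, ci
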