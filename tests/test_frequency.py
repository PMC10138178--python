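import numpy as np
import pytest

from paddygrade.frequency import (ModeSelection, dft, dft_matrices, fea, feb,
                                  idft, idft_matrices, select_modes)


def naive_full_dft(x: np.ndarray) -> np.ndarray:
    """O(L²) full complex DFT used as an independent oracle."""
    L = len(x)
    n = np.arange(L)
    return np.array([np.sum(x * np.exp(-2j * np.pi * f * n / L)) for f in range(L)])


def test_pure_cosine_concentrates_on_its_mode():
    L = 32
    t = np.arange(L)
    x = np.cos(2 * np.pi * 3 * t / L)
    spec = dft(x)
    mags = np.abs(spec)
    assert mags[3] == pytest.approx(L / 2)
    others = np.delete(mags, 3)
    assert np.all(others < 1e-9)


@pytest.mark.parametrize("length", [1, 2, 7, 16, 33])
def test_roundtrip_and_parseval_vs_naive_oracle(length):
    rng = np.random.default_rng(length)
    x = rng.normal(size=length)
    assert np.allclose(idft(dft(x), length), x, rtol=1e-9, atol=1e-12)
    full = naive_full_dft(x)
    assert np.sum(x ** 2) == pytest.approx(np.sum(np.abs(full) ** 2) / length)
    # the real-input spectrum agrees with the naive oracle's first half
    assert np.allclose(dft(x), full[:length // 2 + 1], atol=1e-9)


def test_idft_length_mismatch_rejected():
    with pytest.raises(ValueError):
        idft(dft(np.ones(8)), 12)


def test_select_modes_identity_dc_and_lowest():
    rng = np.random.default_rng(4)
    x = rng.normal(size=16)
    spec = dft(x)
    all_sel = ModeSelection(tuple(range(9)), 16)
    assert np.array_equal(select_modes(spec, all_sel), spec)
    dc = select_modes(spec, ModeSelection((0,), 16))
    assert dc.shape == (1,) and dc[0] == spec[0]
    lowest = ModeSelection.build(16, 4, policy="lowest")
    assert lowest.mode_indices == (0, 1, 2, 3)


def test_mode_selection_validation():
    with pytest.raises(ValueError):
        ModeSelection((0, 0), 16)
    with pytest.raises(ValueError):
        ModeSelection((9,), 16)
    sel = ModeSelection.build(16, 100, policy="lowest")
    assert sel.n_modes == 9  # capped at the number of available modes


def test_random_fixed_policy_is_seed_stable():
    a = ModeSelection.build(64, 8, policy="random-fixed", seed=5)
    b = ModeSelection.build(64, 8, policy="random-fixed", seed=5)
    assert a.mode_indices == b.mode_indices
    assert len(a.mode_indices) == 8


def test_feb_identity_under_all_modes_unit_weights():
    rng = np.random.default_rng(6)
    x = rng.normal(size=20)
    sel = ModeSelection(tuple(range(11)), 20)
    out = feb(x, np.ones(11, dtype=complex), sel)
    assert np.allclose(out, x, atol=1e-9)


def test_feb_band_limited_exact_and_empty_selection_zero():
    L = 32
    t = np.arange(L)
    x = 0.7 * np.cos(2 * np.pi * 2 * t / L) + 0.3 * np.sin(2 * np.pi * 5 * t / L)
    sel = ModeSelection((2, 5), L)
    assert np.allclose(feb(x, np.ones(2, dtype=complex), sel), x, atol=1e-9)
    none = ModeSelection((), L)
    assert np.allclose(feb(x, np.ones(0, dtype=complex), none), 0.0)


def test_feb_rejects_nonfinite_weights():
    sel = ModeSelection((0, 1), 8)
    with pytest.raises(ValueError):
        feb(np.ones(8), np.array([1.0, np.inf], dtype=complex), sel)


def test_feb_linear_in_input():
    rng = np.random.default_rng(8)
    sel = ModeSelection.build(24, 5, policy="lowest")
    w = rng.normal(size=5) + 1j * rng.normal(size=5)
    x, y = rng.normal(size=24), rng.normal(size=24)
    lhs = feb(2.0 * x - 3.0 * y, w, sel)
    rhs = 2.0 * feb(x, w, sel) - 3.0 * feb(y, w, sel)
    assert np.allclose(lhs, rhs, atol=1e-9)


def naive_fea(q, k, v, q_sel, kv_sel):
    """Dense scripted oracle: explicit DFT, truncation, product, padding, inverse."""
    Lq, Lk = len(q), len(k)
    qf = np.array([naive_full_dft(q[:, d])[:Lq // 2 + 1] for d in range(q.shape[1])]).T
    kf = np.array([naive_full_dft(k[:, d])[:Lk // 2 + 1] for d in range(k.shape[1])]).T
    vf = np.array([naive_full_dft(v[:, d])[:Lk // 2 + 1] for d in range(v.shape[1])]).T
    qs = qf[list(q_sel.mode_indices)]
    ks = kf[list(kv_sel.mode_indices)]
    vs = vf[list(kv_sel.mode_indices)]
    score = qs @ ks.conj().T
    score = np.tanh(score.real) + 1j * np.tanh(score.imag)
    out = score @ vs
    full = np.zeros((Lq // 2 + 1, q.shape[1]), dtype=complex)
    full[list(q_sel.mode_indices)] = out
    return idft(full, Lq)


def test_fea_matches_dense_oracle_on_length_8_toys():
    rng = np.random.default_rng(9)
    q = rng.normal(size=(8, 2))
    k = rng.normal(size=(8, 2))
    v = rng.normal(size=(8, 2))
    q_sel = ModeSelection((0, 2, 3), 8)
    kv_sel = ModeSelection((1, 2), 8)
    out = fea(q, k, v, q_sel, kv_sel)
    assert np.allclose(out, naive_fea(q, k, v, q_sel, kv_sel), atol=1e-9)
    assert np.all(np.isreal(out)) and out.shape == q.shape


def test_fea_zero_values_give_zero_output():
    rng = np.random.default_rng(10)
    q = rng.normal(size=(8, 2))
    sel = ModeSelection.build(8, 3, policy="lowest")
    out = fea(q, q, np.zeros_like(q), sel, sel)
    assert np.allclose(out, 0.0)


def test_fea_rejects_incompatible_widths():
    sel = ModeSelection.build(8, 2, policy="lowest")
    with pytest.raises(ValueError):
        fea(np.ones((8, 2)), np.ones((8, 3)), np.ones((8, 3)), sel, sel)


@pytest.mark.parametrize("length", [8, 15, 16])
def test_matrix_transforms_agree_with_fft(length):
    """The real matrix pair used by the autodiff layers equals rfft/irfft."""
    rng = np.random.default_rng(length)
    x = rng.normal(size=(length, 3))
    c, s = dft_matrices(length)
    spec = np.fft.rfft(x, axis=0)
    assert np.allclose(c @ x, spec.real, atol=1e-9)
    assert np.allclose(s @ x, spec.imag, atol=1e-9)
    cr, ci = idft_matrices(length)
    assert np.allclose(cr @ spec.real + ci @ spec.imag, x, atol=1e-9)
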