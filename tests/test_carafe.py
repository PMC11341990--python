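"""Content-aware reassembly upsampling against naive-loop references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from piyolo.carafe import (
    CARAFE, CarafeConfig, CarafeParams, carafe_upsample, predict_kernels,
    reassemble,
)
from piyolo.nn import Tensor


def random_params(rng, c, cfg):
    s2k2 = cfg.sigma**2 * cfg.kup**2
    return CarafeParams(
        w_comp=rng.standard_normal((cfg.Cm, c, 1, 1)) * 0.5,
        b_comp=rng.standard_normal(cfg.Cm) * 0.1,
        w_enc=rng.standard_normal((s2k2, cfg.Cm, cfg.kenc, cfg.kenc)) * 0.5,
        b_enc=rng.standard_normal(s2k2) * 0.1,
    )


def naive_carafe(X, cfg, params):
    """Fully explicit loops: conv, channel-to-space, softmax, reassembly."""
    h, w, c = X.shape
    s, kup, kenc = cfg.sigma, cfg.kup, cfg.kenc

    def conv(inp, wgt, b):
        co = wgt.shape[0]
        hh, ww, ci = inp.shape
        pad = wgt.shape[-1] // 2
        out = np.zeros((hh, ww, co))
        for i in range(hh):
            for j in range(ww):
                for o in range(co):
                    acc = b[o]
                    for di in range(-pad, pad + 1):
                        for dj in range(-pad, pad + 1):
                            if 0 <= i + di < hh and 0 <= j + dj < ww:
                                acc += inp[i + di, j + dj] @ \
                                    wgt[o, :, di + pad, dj + pad]
                    out[i, j, o] = acc
        return out

    enc = conv(conv(X, params.w_comp, params.b_comp), params.w_enc, params.b_enc)
    out = np.zeros((s * h, s * w, c))
    for i2 in range(s * h):
        for j2 in range(s * w):
            i, di = divmod(i2, s)
            j, dj = divmod(j2, s)
            logits = enc[i, j, (di * s + dj) * kup * kup:(di * s + dj + 1) * kup * kup]
            e = np.exp(logits - logits.max())
            kern = e / e.sum()
            acc = np.zeros(c)
            pad = kup // 2
            for a in range(kup):
                for b_ in range(kup):
                    si, sj = i + a - pad, j + b_ - pad
                    if 0 <= si < h and 0 <= sj < w:
                        acc += X[si, sj] * kern[a * kup + b_]
            out[i2, j2] = acc
    return out


def test_kernel_field_shape_and_normalisation(rng):
    cfg = CarafeConfig(Cm=4, sigma=2, kup=5)
    X = rng.standard_normal((3, 4, 6))
    kern = predict_kernels(X, cfg, random_params(rng, 6, cfg))
    assert kern.shape == (6, 8, 25)
    assert np.allclose(kern.sum(axis=-1), 1.0, atol=1e-6)
    assert (kern > 0).all() and (kern < 1).all()


def test_cm_larger_than_channels_rejected(rng):
    cfg = CarafeConfig(Cm=8, sigma=2)
    with pytest.raises(ValueError):
        predict_kernels(rng.standard_normal((3, 3, 4)), cfg,
                        random_params(rng, 4, cfg))


def test_even_kernel_rejected():
    with pytest.raises(ValueError):
        CarafeConfig(kup=4).validate()


def test_constant_input_preserved(rng):
    """Unit-sum kernels reproduce a constant field wherever the window stays
    in bounds (zero padding dilutes the two border rows/columns)."""
    cfg = CarafeConfig(Cm=3, sigma=2, kup=3)
    const = np.array([2.0, -1.0, 0.5, 3.3])
    X = np.tile(const, (4, 4, 1))
    out = carafe_upsample(X, cfg, random_params(rng, 4, cfg))
    assert np.allclose(out[2:-2, 2:-2], np.tile(const, (4, 4, 1)), atol=1e-6)
    # kup=1 has no window overhang: preserved everywhere including borders
    cfg1 = CarafeConfig(Cm=3, sigma=2, kup=1)
    out1 = carafe_upsample(X, cfg1, random_params(rng, 4, cfg1))
    assert np.allclose(out1, np.tile(const, (8, 8, 1)), atol=1e-6)


def test_kup1_reduces_to_nearest_neighbor(rng):
    cfg = CarafeConfig(Cm=2, sigma=2, kup=1)
    X = rng.standard_normal((2, 2, 3))
    out = carafe_upsample(X, cfg, random_params(rng, 3, cfg))
    want = X.repeat(2, axis=0).repeat(2, axis=1)
    assert np.allclose(out, want, atol=1e-12)


def test_delta_kernel_copies_source_pixel(rng):
    cfg = CarafeConfig(Cm=2, sigma=2, kup=3)
    X = rng.standard_normal((3, 3, 2))
    kern = np.zeros((6, 6, 9))
    kern[:, :, 4] = 1.0                      # one-hot at the window centre
    out = reassemble(X, kern, cfg)
    assert np.allclose(out, X.repeat(2, axis=0).repeat(2, axis=1))


def test_kernel_shape_mismatch_rejected(rng):
    cfg = CarafeConfig(Cm=2, sigma=2, kup=3)
    with pytest.raises(ValueError):
        reassemble(rng.standard_normal((3, 3, 2)), np.ones((4, 4, 9)), cfg)


def test_channel_permutation_equivariance(rng):
    cfg = CarafeConfig(Cm=4, sigma=2, kup=3)
    X = rng.standard_normal((3, 3, 4))
    params = random_params(rng, 4, cfg)
    perm = np.array([2, 0, 3, 1])
    out = carafe_upsample(X, cfg, params)
    params_p = CarafeParams(params.w_comp[:, perm], params.b_comp,
                            params.w_enc, params.b_enc)
    out_p = carafe_upsample(X[:, :, perm], cfg, params_p)
    assert np.allclose(out_p, out[:, :, perm], atol=1e-9)


@pytest.mark.parametrize("h,w,sigma,kup", [
    (3, 3, 2, 5), (2, 2, 2, 1), (4, 3, 2, 3), (4, 4, 1, 3), (2, 4, 1, 5),
])
def test_pipeline_matches_naive_loops(h, w, sigma, kup):
    for seed in range(4):
        rng = np.random.default_rng(seed + 31 * (h + w + sigma + kup))
        cfg = CarafeConfig(Cm=2, sigma=sigma, kup=kup)
        X = rng.standard_normal((h, w, 2))
        params = random_params(rng, 2, cfg)
        got = carafe_upsample(X, cfg, params)
        assert np.abs(got - naive_carafe(X, cfg, params)).max() < 1e-6


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), kup=st.sampled_from([1, 3, 5]))
def test_kernels_normalised_and_output_convex(seed, kup):
    """Every output value is a convex combination of its source window."""
    rng = np.random.default_rng(seed)
    cfg = CarafeConfig(Cm=3, sigma=2, kup=kup)
    X = rng.standard_normal((4, 4, 3))
    params = random_params(rng, 3, cfg)
    kern = predict_kernels(X, cfg, params)
    assert np.allclose(kern.sum(axis=-1), 1.0, atol=1e-6)
    out = reassemble(X, kern, cfg)
    pad = kup // 2
    Xp = np.pad(X, ((pad, pad), (pad, pad), (0, 0)))
    for i2 in range(8):
        for j2 in range(8):
            win = Xp[i2 // 2:i2 // 2 + kup, j2 // 2:j2 // 2 + kup]
            lo = np.minimum(win.min(axis=(0, 1)), 0)   # zero padding counts
            hi = np.maximum(win.max(axis=(0, 1)), 0)
            assert (out[i2, j2] >= lo - 1e-9).all()
            assert (out[i2, j2] <= hi + 1e-9).all()


def test_module_matches_functional_path(rng):
    cfg = CarafeConfig(Cm=3, sigma=2, kup=5, kenc=3)
    mod = CARAFE(5, cfg)
    params = CarafeParams(
        w_comp=mod.comp.weight.data.astype(float),
        b_comp=mod.comp.bias.data.astype(float),
        w_enc=mod.enc.weight.data.astype(float),
        b_enc=mod.enc.bias.data.astype(float),
    )
    X = rng.standard_normal((4, 4, 5)).astype(np.float32)
    got = mod(Tensor(X.transpose(2, 0, 1)[None])).data[0].transpose(1, 2, 0)
    want = carafe_upsample(X.astype(float), cfg, params)
    assert np.abs(got - want).max() < 1e-4
    assert got.shape == (8, 8, 5)
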