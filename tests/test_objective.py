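"""Loss functions and evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gliomaseg.nn import Tensor
from gliomaseg.objective import (
    EPSILON,
    WEIGHT_EPSILON,
    categorical_cross_entropy,
    dsc,
    generalized_dice_loss,
    hd95,
    overall_loss,
)


# ------------------------------------------------------------ loss oracles
def gd_loss_bruteforce(s, y, eps=EPSILON, w_eps=WEIGHT_EPSILON):
    """Voxel-by-voxel evaluation of the generalized dice loss."""
    s = s.reshape(-1, s.shape[-1])
    y = y.reshape(-1, y.shape[-1])
    n, c = s.shape
    num = 0.0
    den = 0.0
    for ci in range(c):
        ysum = sum(y[i, ci] for i in range(n))
        ssum = sum(s[i, ci] for i in range(n))
        inter = sum(y[i, ci] * s[i, ci] for i in range(n))
        w = 1.0 / (ysum + w_eps) ** 2 if ysum > 0 else 0.0  # absent class: no weight
        num += w * inter
        den += w * (ysum + ssum)
    return 1.0 - (2.0 * num + eps) / (den + eps)


def ce_loss_bruteforce(s, y, floor=1e-7):
    s = s.reshape(-1, s.shape[-1])
    y = y.reshape(-1, y.shape[-1])
    total = 0.0
    for i in range(s.shape[0]):
        for ci in range(s.shape[1]):
            total -= y[i, ci] * np.log(max(s[i, ci], floor))
    return total / s.shape[0]


def random_softmax_targets(rng, shape=(8, 8), c=4):
    logits = rng.normal(size=shape + (c,))
    e = np.exp(logits - logits.max(-1, keepdims=True))
    s = e / e.sum(-1, keepdims=True)
    idx = rng.integers(0, c, size=shape)
    y = np.zeros(shape + (c,))
    np.put_along_axis(y, idx[..., None], 1.0, axis=-1)
    return s, y


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_losses_match_bruteforce_oracles(seed):
    rng = np.random.default_rng(seed)
    s, y = random_softmax_targets(rng)
    gd, _ = generalized_dice_loss(s, y)
    ce = categorical_cross_entropy(s, y)
    assert abs(float(gd.data) - gd_loss_bruteforce(s, y)) < 1e-7
    assert abs(float(ce.data) - ce_loss_bruteforce(s, y)) < 1e-7
    terms = overall_loss(s, y)
    assert terms.overall == pytest.approx(terms.gd + terms.ce, abs=1e-12)


def test_perfect_prediction_near_zero_loss():
    rng = np.random.default_rng(0)
    _, y = random_softmax_targets(rng)
    terms = overall_loss(y.copy(), y)
    assert terms.gd <= 1e-6
    assert terms.overall < 1e-5


def test_uniform_prediction_ce_is_ln4():
    rng = np.random.default_rng(1)
    _, y = random_softmax_targets(rng, shape=(6, 6))
    s = np.full_like(y, 0.25)
    ce = float(categorical_cross_entropy(s, y).data)
    assert ce == pytest.approx(np.log(4.0), abs=1e-7)


def test_two_class_hand_example():
    """y = [A, A, B, B], s = hard [A, B, B, B]: brute-force Eq check."""
    y = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    s = np.array([[1, 0], [0, 1], [0, 1], [0, 1]], dtype=float)
    gd, _ = generalized_dice_loss(s, y)
    assert float(gd.data) == pytest.approx(gd_loss_bruteforce(s, y), abs=1e-9)
    # uniform prediction on balanced classes, C=2, n=4: closed form
    su = np.full_like(y, 0.5)
    w = 1.0 / (2 + WEIGHT_EPSILON) ** 2
    num = 2 * (w * 1.0 + w * 1.0) + EPSILON   # per-class intersection = 2*0.5
    den = (w * (2 + 2) + w * (2 + 2)) + EPSILON
    gd_u, _ = generalized_dice_loss(su, y)
    assert float(gd_u.data) == pytest.approx(1 - num / den, abs=1e-9)


def test_gd_monotone_toward_target():
    rng = np.random.default_rng(2)
    _, y = random_softmax_targets(rng, shape=(4, 4))
    uniform = np.full_like(y, 0.25)
    losses = []
    for t in np.linspace(0, 1, 11):
        s = (1 - t) * uniform + t * y
        gd, _ = generalized_dice_loss(s, y)
        losses.append(float(gd.data))
    assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))


def test_loss_voxel_permutation_invariance():
    rng = np.random.default_rng(3)
    s, y = random_softmax_targets(rng, shape=(5, 5))
    sf, yf = s.reshape(-1, 4), y.reshape(-1, 4)
    perm = rng.permutation(sf.shape[0])
    gd1, _ = generalized_dice_loss(sf, yf)
    gd2, _ = generalized_dice_loss(sf[perm], yf[perm])
    assert float(gd1.data) == pytest.approx(float(gd2.data), abs=1e-9)
    ce1 = float(categorical_cross_entropy(sf, yf).data)
    ce2 = float(categorical_cross_entropy(sf[perm], yf[perm]).data)
    assert ce1 == pytest.approx(ce2, abs=1e-9)


def test_loss_gradient_finite(rng):
    s, y = random_softmax_targets(np.random.default_rng(4))
    st = Tensor(s, requires_grad=True)
    terms = overall_loss(st, y)
    terms.tensor.backward()
    assert np.isfinite(st.grad).all()


def test_loss_shape_mismatch_fatal():
    with pytest.raises(ValueError, match="mismatch"):
        generalized_dice_loss(np.zeros((2, 4)), np.zeros((3, 4)))


# ---------------------------------------------------------------- metrics
def test_dsc_examples_and_symmetry():
    a = np.zeros((4, 4), dtype=bool)
    a[:2] = True
    assert dsc(a, a) == 1.0
    assert dsc(a, ~a) == 0.0
    p = np.zeros(16, dtype=bool)
    t = np.zeros(16, dtype=bool)
    p[:4] = True
    t[1:7] = True  # |P|=4, |T|=6, |P∩T|=3
    assert dsc(p, t) == pytest.approx(0.6)
    assert dsc(p, t) == dsc(t, p)
    assert dsc(np.zeros(4, dtype=bool), np.zeros(4, dtype=bool)) == 1.0


def surface_bruteforce(mask):
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        for ax in range(mask.ndim):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if not (0 <= nb[ax] < mask.shape[ax]) or not mask[tuple(nb)]:
                    out[tuple(idx)] = True
                    break
            if out[tuple(idx)]:
                break
    return out


def hd95_bruteforce(p, t, spacing):
    sp = np.argwhere(surface_bruteforce(p)) * spacing
    st = np.argwhere(surface_bruteforce(t)) * spacing
    d = cdist(sp, st)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hd95_matches_allpairs_oracle(seed):
    rng = np.random.default_rng(seed)
    spacing = np.array([1.0, 1.5, 2.0])
    p = rng.random((12, 12, 12)) > 0.8
    t = rng.random((12, 12, 12)) > 0.8
    got = hd95(p, t, spacing=spacing)
    want = hd95_bruteforce(p, t, spacing)
    assert got == pytest.approx(want, abs=1e-9)
    assert hd95(t, p, spacing=spacing) == pytest.approx(got, abs=1e-9)  # pooled symmetry


def test_hd95_simple_cases():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros((8, 8, 8), dtype=bool)
    a[2, 2, 2] = True
    b[2, 2, 5] = True
    assert hd95(a, a) == 0.0
    assert hd95(a, b) == pytest.approx(3.0)
    # empty-mask sentinels
    e = np.zeros((8, 8, 8), dtype=bool)
    assert hd95(e, e) == 0.0
    assert hd95(a, e) == pytest.approx(np.linalg.norm([8, 8, 8]))
    assert hd95(a, e, empty_sentinel=99.0) == 99.0


def test_hd95_max_directed_mode():
    rng = np.random.default_rng(5)
    p = rng.random((10, 10)) > 0.7
    t = rng.random((10, 10)) > 0.7
    sp = np.argwhere(surface_bruteforce(p)).astype(float)
    st = np.argwhere(surface_bruteforce(t)).astype(float)
    d = cdist(sp, st)
    want = max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))
    assert hd95(p, t, mode="max_directed") == pytest.approx(want, abs=1e-9)
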