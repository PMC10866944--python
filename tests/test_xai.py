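"""Grad-CAM correctness on toy networks with hand-checkable structure."""

import hashlib
import types

import numpy as np
import pytest

from gliomaseg.brats_io import MODALITIES
from gliomaseg.net import LAYER_TAGS, ModelConfig, build_model
from gliomaseg.nn import Conv2d, Module, Tensor, conv2d
from gliomaseg.xai import ClassScoreSpec, SaliencyMap, _normalize, grad_cam, layer_sweep, modality_ablation

TINY = dict(base_filters=4, input_size=(32, 32),
            transformer={"num_blocks": 1, "num_heads": 2, "embed_dim": 16, "mlp_dim": 32, "patch_size": 1})


class ToyNet(Module):
    """input --conv3x3--> A (tag CAM) --relu--conv1x1--> 2-class logits."""

    def __init__(self, seed=0, neg_head=False):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(2, 3, 3, rng=rng)
        self.head = Conv2d(3, 2, 1, rng=rng)
        for p in self.parameters():
            p.data = rng.normal(size=p.data.shape)  # float64 for tight oracles
        if neg_head:
            self.head.weight.data = -np.abs(self.head.weight.data)
            self.head.bias.data[...] = 0.0
        self.cfg = types.SimpleNamespace(in_channels=2)

    def forward_features(self, x):
        a = self.conv1(x)
        logits = self.head(a.relu())
        return logits, {"CAM": a, "POST": a.relu(), "OUT": logits}


def test_gradcam_matches_finite_difference_oracle():
    """alpha and the heatmap match central finite differences of y^c wrt A."""
    net = ToyNet(seed=1)
    rng = np.random.default_rng(0)
    img = rng.normal(size=(4, 4, 2))
    spec = ClassScoreSpec(target_class=1, aggregation="all-pixels")
    sm = grad_cam(net, img, "CAM", spec, normalize=False)

    # independent path: numpy forward to get A, then FD of y(A) per element
    x = Tensor(img.astype(np.float64).transpose(2, 0, 1)[None])
    a0 = net.conv1(x).data.copy()
    w = net.head.weight.data[:, :, 0, 0]  # (2, 3)
    b = net.head.bias.data

    def y_of_a(a):
        ar = np.maximum(a, 0.0)
        logits = np.einsum("oc,nchw->nohw", w, ar) + b[None, :, None, None]
        return float(logits[:, 1].sum())

    eps = 1e-6
    grads = np.zeros_like(a0)
    it = np.nditer(a0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = a0[i]
        a0[i] = old + eps
        yp = y_of_a(a0)
        a0[i] = old - eps
        ym = y_of_a(a0)
        a0[i] = old
        grads[i] = (yp - ym) / (2 * eps)
    alpha = grads.mean(axis=(2, 3))  # Eq: spatial mean of dy/dA
    heat_ref = np.maximum((alpha[0][:, None, None] * a0[0]).sum(axis=0), 0.0)
    assert np.abs(sm.heatmap - heat_ref).max() < 1e-4


def test_gradcam_matches_symbolic_toy():
    """Five-parameter toy: A = w*x + b, y = sum(v*A); alpha = v exactly and
    the map is ReLU(v * (w*x + b)), matching the symbolic derivation to 1e-8."""

    class Scalar1x1(Module):
        def __init__(self, w, b, v):
            super().__init__()
            self.conv1 = Conv2d(1, 1, 1, rng=np.random.default_rng(0))
            self.head = Conv2d(1, 2, 1, rng=np.random.default_rng(0))
            self.conv1.weight.data = np.array([[[[w]]]], dtype=np.float64)
            self.conv1.bias.data = np.array([b], dtype=np.float64)
            self.head.weight.data = np.array([[[[0.0]]], [[[v]]]], dtype=np.float64)
            self.head.bias.data = np.array([0.0, 0.0], dtype=np.float64)
            self.cfg = types.SimpleNamespace(in_channels=1)

        def forward_features(self, x):
            a = self.conv1(x)
            return self.head(a), {"CAM": a}

    w, b, v = 1.7, -0.3, 2.5
    net = Scalar1x1(w, b, v)
    x = np.arange(4, dtype=np.float64).reshape(2, 2, 1)
    sm = grad_cam(net, x, "CAM", ClassScoreSpec(target_class=1, aggregation="all-pixels"),
                  normalize=False)
    expected = np.maximum(v * (w * x[..., 0] + b), 0.0)
    assert np.abs(sm.heatmap - expected).max() < 1e-8


def test_relu_annihilation_with_negative_alpha():
    """Nonnegative activations and all-negative gradients give an all-zero,
    flagged map."""
    net = ToyNet(seed=2, neg_head=True)
    img = np.abs(np.random.default_rng(1).normal(size=(4, 4, 2)))
    sm = grad_cam(net, img, "POST", ClassScoreSpec(target_class=1, aggregation="all-pixels"))
    assert sm.all_zero
    assert np.all(sm.heatmap == 0.0)


def test_map_linear_in_activations_for_frozen_gradients():
    """Doubling A with unchanged head gradients doubles the pre-ReLU map."""
    net = ToyNet(seed=3)
    # force positive head so ReLU(A) = A on positive input and grads are constant
    net.head.weight.data = np.abs(net.head.weight.data)
    img = np.abs(np.random.default_rng(2).normal(size=(4, 4, 2))) + 0.5
    spec = ClassScoreSpec(target_class=0, aggregation="all-pixels")
    m1 = grad_cam(net, img, "POST", spec, normalize=False).heatmap
    net.conv1.weight.data *= 2.0
    net.conv1.bias.data *= 2.0
    m2 = grad_cam(net, img, "POST", spec, normalize=False).heatmap
    assert np.abs(m2 - 2.0 * m1).max() < 1e-8


def test_normalization_idempotent():
    h = np.random.default_rng(3).random((5, 5)) * 4.0
    once, _ = _normalize(h)
    twice, _ = _normalize(once)
    assert np.abs(once - twice).max() < 1e-12
    assert once.min() == 0.0 and once.max() == 1.0


def test_unknown_layer_tag_lists_available():
    net = ToyNet()
    with pytest.raises(ValueError, match="CAM"):
        grad_cam(net, np.zeros((4, 4, 2)), "NOPE", ClassScoreSpec(target_class=0))


def test_spec_validation():
    with pytest.raises(ValueError):
        ClassScoreSpec(target_class=7)
    with pytest.raises(ValueError):
        ClassScoreSpec(target_class=1, aggregation="roi-mask")


def _weights_hash(model):
    h = hashlib.sha256()
    for name, arr in sorted(model.state_dict().items()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def test_explanations_never_mutate_weights(rng):
    model = build_model(ModelConfig(**TINY), seed=0).eval()
    img = rng.normal(size=(32, 32, 4)).astype(np.float32)
    before = _weights_hash(model)
    layer_sweep(model, img, ClassScoreSpec(target_class=3))
    assert _weights_hash(model) == before


def test_layer_sweep_contract(rng):
    model = build_model(ModelConfig(**TINY), seed=4).eval()
    img = rng.normal(size=(32, 32, 4)).astype(np.float32)
    maps = layer_sweep(model, img, ClassScoreSpec(target_class=2))
    assert tuple(maps) == LAYER_TAGS  # 10 maps: EB1..EB4, BOT, DB1..DB4, OUT
    for sm in maps.values():
        assert isinstance(sm, SaliencyMap)
        assert sm.heatmap.shape == (32, 32)
        assert sm.heatmap.min() >= 0.0
        assert sm.all_zero or sm.heatmap.max() == pytest.approx(1.0)


def test_ablation_report_contract_and_zero_channel_noop(single_phantom):
    _, vol, lab = single_phantom
    # plant an identically-zero T1 channel
    channels = {m: (np.zeros_like(vol.channels[m]) if m == "T1" else vol.channels[m])
                for m in MODALITIES}
    vol0 = vol.replace_channels(channels)
    model = build_model(ModelConfig(base_filters=4, input_size=(96, 96),
                                    transformer={"num_blocks": 1, "num_heads": 2,
                                                 "embed_dim": 16, "mlp_dim": 32,
                                                 "patch_size": 1}), seed=5).eval()
    rows, _ = modality_ablation(model, vol0, lab, crop_size=(96, 96))
    assert len(rows) == 8  # 4 keep-only + 4 leave-one-out
    modes = {(r["mode"], r["modality"]) for r in rows}
    assert len(modes) == 8
    # leaving out the all-zero channel changes nothing vs. full inference
    from gliomaseg.preprocess import preprocess_case
    from gliomaseg.xai import _predict_with_channel_mask
    from gliomaseg.objective import region_report

    pvol, plab, _ = preprocess_case(vol0, lab, crop_size=(96, 96))
    full = region_report(_predict_with_channel_mask(model, pvol, np.ones(4, dtype=bool)),
                         plab.labels)
    loo_t1 = next(r for r in rows if r["mode"] == "leave_one_out" and r["modality"] == "T1")
    for region in ("ET", "TC", "WT"):
        assert loo_t1[f"{region}_dsc"] == full[region]["dsc"]
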