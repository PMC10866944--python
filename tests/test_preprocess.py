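"""Preprocessing: brain masking, z-score convention, crop/pad inversion, slicing."""

import numpy as np
import pytest

from gliomaseg.brats_io import MODALITIES, LabelVolume, MultimodalVolume
from gliomaseg.preprocess import (
    center_crop,
    extract_axial_slices,
    filter_slices,
    invert_crop,
    preprocess_case,
    reassemble_slices,
    zero_nonbrain,
    zscore,
)


def make_vol(arrays_or_shape, fill=None):
    if isinstance(arrays_or_shape, tuple):
        base = np.zeros(arrays_or_shape, dtype=np.float32) if fill is None else fill
        arrays = {m: base.copy() for m in MODALITIES}
    else:
        arrays = arrays_or_shape
    return MultimodalVolume(arrays, np.eye(4), (1.0, 1.0, 1.0))


def flood_fill_components(mask):
    """Exhaustive 6-connected flood fill; independent of scipy labelling."""
    mask = mask.copy()
    comps = []
    while mask.any():
        seed = tuple(np.argwhere(mask)[0])
        comp = set()
        stack = [seed]
        while stack:
            v = stack.pop()
            if v in comp or not mask[v]:
                continue
            comp.add(v)
            for ax in range(3):
                for d in (-1, 1):
                    nb = list(v)
                    nb[ax] += d
                    if 0 <= nb[ax] < mask.shape[ax]:
                        nb = tuple(nb)
                        if mask[nb] and nb not in comp:
                            stack.append(nb)
        for v in comp:
            mask[v] = False
        comps.append(comp)
    return comps


def test_zero_nonbrain_removes_speckles_flood_fill_oracle():
    shape = (24, 24, 8)
    arr = np.zeros(shape, dtype=np.float32)
    arr[6:18, 6:18, 2:6] = 1.0  # main blob
    speckles = [(0, 0, 0), (23, 23, 7), (0, 23, 0), (23, 0, 7), (0, 12, 7)]
    for s in speckles:
        arr[s] = 5.0
    vol = make_vol({m: arr.copy() for m in MODALITIES})
    out = zero_nonbrain(vol)
    comps = flood_fill_components(arr != 0)
    main = max(comps, key=len)
    for m in MODALITIES:
        for s in speckles:
            assert out.channels[m][s] == 0.0
        for v in list(main)[:50]:
            assert out.channels[m][v] == arr[v]


def test_zero_nonbrain_idempotent(single_phantom):
    _, vol, _ = single_phantom
    once = zero_nonbrain(vol)
    twice = zero_nonbrain(once)
    for m in MODALITIES:
        assert np.array_equal(once.channels[m], twice.channels[m])


def test_zero_nonbrain_empty_volume_fatal():
    with pytest.raises(ValueError, match="zero"):
        zero_nonbrain(make_vol((4, 4, 4)))


def test_zscore_hand_computed_population_convention():
    arr = np.zeros((3, 1, 1), dtype=np.float32)
    arr[:, 0, 0] = [1.0, 2.0, 3.0]
    vol = make_vol({m: arr.copy() for m in MODALITIES})
    out, rec = zscore(vol, mask=np.ones_like(arr, dtype=bool))
    expected = np.array([-1.22474487, 0.0, 1.22474487])
    for m in MODALITIES:
        assert np.allclose(out.channels[m][:, 0, 0], expected, atol=1e-6)
        assert not rec.normalization[m].zero_std_fallback


def test_zscore_brain_stats_and_background_zero(single_phantom):
    _, vol, _ = single_phantom
    vol = zero_nonbrain(vol)
    out, rec = zscore(vol)
    from gliomaseg.preprocess import brain_mask

    mask = brain_mask(vol)
    for m in MODALITIES:
        vals = out.channels[m][mask]
        assert abs(vals.mean()) < 1e-5
        assert abs(vals.std() - 1.0) < 1e-5
        assert np.all(out.channels[m][~mask] == 0.0)


def test_zscore_constant_channel_fallback():
    arr = np.zeros((4, 4, 2), dtype=np.float32)
    arr[1:3, 1:3, :] = 2.5  # constant within brain
    vol = make_vol({m: arr.copy() for m in MODALITIES})
    out, rec = zscore(vol)
    for m in MODALITIES:
        assert rec.normalization[m].zero_std_fallback
        assert np.all(out.channels[m] == 0.0)


def test_zscore_affine_rescale_invariance(single_phantom):
    _, vol, _ = single_phantom
    vol = zero_nonbrain(vol)
    out1, _ = zscore(vol)
    from gliomaseg.preprocess import brain_mask

    mask = brain_mask(vol)
    scaled = {}
    for m in MODALITIES:
        ch = vol.channels[m] * 3.0
        ch = np.where(mask, ch + 7.0, 0.0).astype(np.float32)
        scaled[m] = ch
    out2, _ = zscore(vol.replace_channels(scaled), mask=mask)
    for m in MODALITIES:
        assert np.allclose(out1.channels[m], out2.channels[m], atol=1e-4)


@pytest.mark.parametrize("in_plane,expected_offsets", [
    ((240, 240), (24, 24)),
    ((192, 192), (0, 0)),
    ((160, 160), (-16, -16)),
])
def test_center_crop_offsets(in_plane, expected_offsets):
    shape = in_plane + (5,)
    rng = np.random.default_rng(0)
    arrays = {m: rng.normal(size=shape).astype(np.float32) for m in MODALITIES}
    vol = make_vol(arrays)
    lab = LabelVolume(np.zeros(shape, dtype=np.int16), np.eye(4), (1, 1, 1))
    cvol, clab, rec = center_crop(vol, lab, size=(192, 192))
    assert rec.crop_offsets == expected_offsets
    assert cvol.shape == (192, 192, 5) and clab.shape == (192, 192, 5)
    if in_plane == (192, 192):
        for m in MODALITIES:
            assert np.array_equal(cvol.channels[m], arrays[m])


@pytest.mark.parametrize("in_plane", [(240, 240), (160, 160), (97, 203)])
def test_invert_crop_restores_placement(in_plane):
    shape = in_plane + (3,)
    rng = np.random.default_rng(1)
    labels = rng.choice([0, 1, 2, 4], size=shape).astype(np.int16)
    lab = LabelVolume(labels, np.eye(4), (1, 1, 1))
    vol = make_vol({m: (labels > 0).astype(np.float32) for m in MODALITIES})
    _, clab, rec = center_crop(vol, lab, size=(192, 192))
    restored = invert_crop(clab.labels, rec)
    assert restored.shape == shape
    # inside the crop window content is identical; outside it is background
    h0 = max(0, (in_plane[0] - 192) // 2)
    w0 = max(0, (in_plane[1] - 192) // 2)
    h1, w1 = min(in_plane[0], h0 + 192), min(in_plane[1], w0 + 192)
    assert np.array_equal(restored[h0:h1, w0:w1], labels[h0:h1, w0:w1])
    outside = restored.copy()
    outside[h0:h1, w0:w1] = 0
    assert np.all(outside == 0)


def test_extract_slices_contract(single_phantom):
    _, vol, lab = single_phantom
    slices = extract_axial_slices(vol, lab)
    assert len(slices) == vol.shape[2]
    assert slices[0].image.shape == vol.shape[:2] + (4,)
    # channel order is positional (T1, T1Gd, T2, FLAIR), independent of dict order
    permuted = MultimodalVolume(
        {m: vol.channels[m] for m in reversed(MODALITIES)}, vol.affine, vol.spacing)
    slices_p = extract_axial_slices(permuted, lab)
    assert np.array_equal(slices[5].image, slices_p[5].image)
    # reassembly inverts extraction
    re_lab = reassemble_slices(slices, "label")
    assert np.array_equal(re_lab, lab.labels)
    re_img = reassemble_slices(slices, "image")
    assert np.array_equal(re_img, vol.stacked())


def test_filter_slices_drops_empty():
    img = np.zeros((8, 8, 4), dtype=np.float32)
    from gliomaseg.preprocess import SlicePair

    empty = SlicePair(img, None, 0)
    full = SlicePair(img + 1.0, None, 1)
    kept = filter_slices([empty, full], min_brain_fraction=0.01)
    assert [s.index for s in kept] == [1]


def test_full_pipeline_label_invertibility(single_phantom):
    """volume -> preprocess -> slices -> reassemble -> un-crop preserves labels."""
    _, vol, lab = single_phantom
    pvol, plab, rec = preprocess_case(vol, lab, crop_size=(128, 128))
    slices = extract_axial_slices(pvol, plab)
    re = reassemble_slices(slices, "label")
    restored = invert_crop(re, rec)
    assert restored.shape == lab.labels.shape
    assert np.array_equal(restored, lab.labels)  # 96 -> pad to 128 -> back
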