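"""Level-2 helpers: ROI cuboid, local tissues, skull/background split."""

from __future__ import annotations

import numpy as np
import pytest

from malfseg.core_io import LabelMap, Volume
from malfseg.structseg import (
    build_local_tissue_labels,
    cuboid_roi,
    make_skull_background_labels,
    segment_structures,
)


def test_cuboid_roi_single_voxel():
    m = np.zeros((20, 20, 20), bool)
    m[10, 10, 10] = True
    roi = cuboid_roi([m], margin=0)
    assert roi == (slice(10, 11), slice(10, 11), slice(10, 11))


def test_cuboid_roi_two_voxels_with_margin():
    m1 = np.zeros((20, 20, 20), bool)
    m2 = np.zeros((20, 20, 20), bool)
    m1[0, 0, 0] = True
    m2[5, 5, 5] = True
    roi = cuboid_roi([m1, m2], margin=2)
    assert roi == (slice(0, 8), slice(0, 8), slice(0, 8))


def test_cuboid_roi_margin_clamps_to_grid():
    m = np.zeros((10, 10, 10), bool)
    m[5, 5, 5] = True
    roi = cuboid_roi([m], margin=100)
    assert roi == (slice(0, 10), slice(0, 10), slice(0, 10))


def test_cuboid_roi_empty_raises():
    with pytest.raises(ValueError):
        cuboid_roi([])
    with pytest.raises(ValueError):
        cuboid_roi([np.zeros((4, 4, 4), bool)])


def test_build_local_tissue_labels_three_class_recovery(rng):
    """Three well separated intensity classes are recovered with means
    within 0.02 and ordered CSF < GM < WM."""
    shape = (24, 24, 24)
    data = np.zeros(shape)
    truth = rng.integers(0, 3, size=shape)
    means = np.array([0.2, 0.5, 0.8])
    data = means[truth] + rng.normal(0, 0.02, shape)
    data = np.clip(data, 0.01, None)
    struct = LabelMap(np.zeros(shape, np.int32), {})
    roi = (slice(0, 24),) * 3
    out = build_local_tissue_labels(Volume(data), struct, roi,
                                    mode_filter=False)
    by_name = {v: k for k, v in out.scheme.items()}
    for cls, name in zip(range(3), ("local CSF", "local GM", "local WM")):
        sel = out.data == by_name[name]
        assert sel.any()
        assert data[sel].mean() == pytest.approx(means[cls], abs=0.02)


def test_build_local_tissue_labels_structure_precedence(rng):
    shape = (12, 12, 12)
    data = rng.random(shape) + 0.1
    struct_data = np.zeros(shape, np.int32)
    struct_data[4:8, 4:8, 4:8] = 1
    struct = LabelMap(struct_data, {1: "s"})
    out = build_local_tissue_labels(Volume(data), struct, (slice(0, 12),) * 3)
    assert (out.data[4:8, 4:8, 4:8] == 1).all()


def test_build_local_tissue_labels_full_cover_noop():
    shape = (8, 8, 8)
    struct = LabelMap(np.ones(shape, np.int32), {1: "s"})
    out = build_local_tissue_labels(Volume(np.random.default_rng(0).random(shape)),
                                    struct, (slice(0, 8),) * 3)
    assert (out.data == struct.data).all()
    assert out.scheme == struct.scheme


def test_make_skull_background_two_level_oracle():
    """Non-brain shell of value 0.9 on 0.05 background: Otsu threshold
    makes the shell exactly the skull."""
    shape = (24, 24, 24)
    data = np.full(shape, 0.05)
    brain = np.zeros(shape, bool)
    brain[8:16, 8:16, 8:16] = True
    shell = np.zeros(shape, bool)
    shell[6:18, 6:18, 6:18] = True
    shell &= ~brain
    data[shell] = 0.9
    data[brain] = 0.5
    skull, background = make_skull_background_labels(Volume(data), brain)
    assert (skull == shell).all()
    assert (skull | background | brain).all()
    assert not (skull & background).any()
    assert not (skull & brain).any()


def test_make_skull_background_all_zero_nonbrain():
    shape = (8, 8, 8)
    data = np.zeros(shape)
    brain = np.zeros(shape, bool)
    brain[2:6, 2:6, 2:6] = True
    data[brain] = 0.5
    skull, background = make_skull_background_labels(Volume(data), brain)
    assert not skull.any()
    assert (background == ~brain).all()


def test_segment_structures_scheme_mismatch_raises(base_phantom):
    from malfseg.core_io import Atlas

    other = Atlas(image=base_phantom.image,
                  labels_level2=LabelMap(
                      base_phantom.labels_level2.data,
                      {**base_phantom.labels_level2.scheme, 99: "extra"}),
                  id="bad")
    with pytest.raises(ValueError):
        segment_structures(base_phantom.image, [base_phantom, other])


def test_segment_structures_unlabeled_outside_roi(base_phantom):
    from malfseg.evaluation import _strip_with_truth
    from malfseg.core_io import Atlas

    stripped = _strip_with_truth(base_phantom)
    atlas = Atlas(image=stripped, labels_level1=base_phantom.labels_level1,
                  labels_level2=base_phantom.labels_level2, id="a")
    seg, state = segment_structures(stripped, [atlas])
    # nothing labeled far away from the deformed atlas ROI
    truth_roi = base_phantom.labels_level2.data > 0
    from scipy import ndimage

    allowed = ndimage.binary_dilation(truth_roi, iterations=3)
    assert (seg.data[~allowed] == 0).all()
    assert state.roi_bbox is not None
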