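"""Volume/LabelMap containers, NIfTI round trips, grids and resampling."""

from __future__ import annotations

import json

import numpy as np
import pytest

from malfseg.core_io import (
    Atlas,
    LabelMap,
    Volume,
    downsample,
    normalize_intensity,
    read_atlas_dir,
    read_labelmap,
    read_volume,
    reorient,
    resample_to,
    write_atlas,
    write_volume,
)


def test_volume_validation():
    with pytest.raises(ValueError):
        Volume(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        Volume(np.zeros((4, 4, 4)), spacing=(1, 0, 1))
    with pytest.raises(ValueError):
        Volume(np.full((2, 2, 2), np.nan))
    with pytest.raises(ValueError):
        Volume(np.zeros((2, 2, 2)), orientation="XYZ")


def test_volume_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    vol = Volume(rng.random((6, 7, 8)), spacing=(1.0, 1.5, 2.0))
    p = tmp_path / "v.nii.gz"
    write_volume(vol, p)
    back = read_volume(p)
    assert back.shape == vol.shape
    assert np.allclose(back.data, vol.data, atol=1e-6)
    assert back.spacing == pytest.approx(vol.spacing)


def test_labelmap_roundtrip_with_sidecar(tmp_path):
    lm = LabelMap(np.arange(27).reshape(3, 3, 3) % 3,
                  scheme={1: "a", 2: "b"})
    p = tmp_path / "seg.nii.gz"
    write_volume(lm, p)
    assert json.loads((tmp_path / "seg.labels.json").read_text()) == {
        "1": "a", "2": "b"}
    back = read_labelmap(p)
    assert (back.data == lm.data).all()
    assert back.scheme == lm.scheme


def test_read_labelmap_without_sidecar(tmp_path):
    lm = LabelMap(np.ones((3, 3, 3), dtype=np.int32), scheme={1: "x"})
    p = tmp_path / "seg.nii.gz"
    write_volume(lm, p)
    (tmp_path / "seg.labels.json").unlink()
    back = read_labelmap(p)
    assert back.scheme == {1: "label-1"}


def test_reorient_roundtrip_marker():
    data = np.zeros((4, 5, 6))
    data[1, 2, 3] = 1.0
    vol = Volume(data, spacing=(1, 2, 3), orientation="RAS")
    flipped = reorient(vol, "LPI")
    assert flipped.orientation == "LPI"
    assert flipped.data[4 - 2, 5 - 3, 6 - 4] == 1.0
    back = reorient(flipped, "RAS")
    assert (back.data == vol.data).all()
    assert back.spacing == vol.spacing


def test_downsample_block_mean_oracle():
    data = np.arange(64, dtype=float).reshape(4, 4, 4)
    vol = Volume(data, spacing=(1, 1, 1))
    ds = downsample(vol, 2)
    assert ds.shape == (2, 2, 2)
    assert ds.spacing == (2, 2, 2)
    assert ds.data[0, 0, 0] == pytest.approx(
        data[:2, :2, :2].mean())
    assert ds.data[1, 1, 1] == pytest.approx(data[2:, 2:, 2:].mean())


def test_downsample_label_mode_and_ties():
    lab = np.zeros((2, 2, 2), dtype=np.int32)
    lab[0, 0, 0] = lab[0, 0, 1] = lab[0, 1, 0] = lab[0, 1, 1] = 2
    lab[1, 0, 0] = lab[1, 0, 1] = lab[1, 1, 0] = lab[1, 1, 1] = 5
    lm = LabelMap(lab, scheme={2: "a", 5: "b"})
    ds = downsample(lm, 2)
    # 4-4 tie resolves to the smallest label
    assert ds.data[0, 0, 0] == 2


def test_downsample_rejects_bad_factor():
    vol = Volume(np.zeros((4, 4, 4)))
    with pytest.raises(ValueError):
        downsample(vol, 0)
    with pytest.raises(ValueError):
        downsample(vol, 1.5)
    # non-dividing factors use ceil semantics
    assert downsample(vol, 3).shape == (2, 2, 2)


def test_resample_to_identity():
    rng = np.random.default_rng(0)
    vol = Volume(rng.random((8, 8, 8)))
    out = resample_to(vol, vol)
    assert np.allclose(out.data, vol.data, atol=1e-12)


def test_resample_to_half_resolution_center_alignment():
    data = np.zeros((8, 8, 8))
    data[:4] = 1.0
    vol = Volume(data, spacing=(1, 1, 1))
    ref = Volume(np.zeros((4, 4, 4)), spacing=(2, 2, 2))
    out = resample_to(vol, ref)
    assert out.shape == (4, 4, 4)
    assert out.data.max() <= 1.0 and out.data.min() >= 0.0


def test_normalize_intensity_clamps_to_unit_interval():
    rng = np.random.default_rng(3)
    vol = Volume(rng.normal(100, 20, (16, 16, 16)))
    out = normalize_intensity(vol)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
    # monotone: ordering preserved away from the clamped tails
    med = np.median(vol.data)
    assert out.data[vol.data > med].mean() > out.data[vol.data < med].mean()


def test_atlas_dir_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    atlas = Atlas(
        image=Volume(rng.random((6, 6, 6))),
        labels_level1=LabelMap(np.ones((6, 6, 6), np.int32),
                               {1: "LV", 2: "GM", 3: "WM", 4: "CSF",
                                5: "skull", 6: "background"}),
        labels_level2=LabelMap(2 * np.ones((6, 6, 6), np.int32), {2: "s"}),
        id="phantom-00",
    )
    write_atlas(atlas, tmp_path)
    back = read_atlas_dir(tmp_path)
    assert len(back) == 1
    assert back[0].id == "phantom-00"
    assert np.allclose(back[0].image.data, atlas.image.data, atol=1e-6)
    assert back[0].labels_level1.scheme == atlas.labels_level1.scheme
    assert back[0].labels_level2.scheme == {2: "s"}


def test_read_atlas_dir_missing(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_atlas_dir(tmp_path / "nope")
    with pytest.raises(ValueError):
        read_atlas_dir(tmp_path)
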