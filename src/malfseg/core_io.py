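"""Domain containers and NIfTI plumbing shared by all pipeline stages.

The working objects are deliberately small: a :class:`Volume` is a 3-D
scalar grid with physical voxel spacing and a 3-letter anatomical
orientation code (e.g. ``RAS``), and a :class:`LabelMap` is an integer grid
aligned to such a volume, with 0 reserved for unlabeled background.  An
:class:`Atlas` pairs an intensity image with one or two label maps: six
global labels for the skull-stripping level and a structure-level scheme
for the second level.

Coordinate conventions: voxel indices are 0-based, deformations elsewhere
in the package are expressed in voxel units on the working grid, and
grids are assumed axis-aligned (oblique NIfTI headers are rejected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nio
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume",
    "LabelMap",
    "Atlas",
    "LEVEL1_NAMES",
    "read_volume",
    "read_labelmap",
    "write_volume",
    "reorient",
    "downsample",
    "resample_to",
    "normalize_intensity",
    "write_atlas",
    "read_atlas_dir",
]

#: canonical level-1 (skull-stripping) scheme: six global labels
LEVEL1_NAMES = {1: "LV", 2: "GM", 3: "WM", 4: "CSF", 5: "skull", 6: "background"}

#: the four global labels grouped into the brain mask
BRAIN_LABEL_NAMES = ("LV", "GM", "WM", "CSF")

_AXIS_OF = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
_SIGN_OF = {"R": 1, "L": -1, "A": 1, "P": -1, "S": 1, "I": -1}


@dataclass
class Volume:
    """A 3-D scalar image with voxel spacing (mm) and orientation code."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        if len(self.orientation) != 3 or any(c not in _AXIS_OF for c in self.orientation):
            raise ValueError(f"invalid orientation code {self.orientation!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else data,
            spacing=kw.get("spacing", self.spacing),
            orientation=kw.get("orientation", self.orientation),
        )


@dataclass
class LabelMap:
    """Integer label grid; 0 means unlabeled background.

    ``scheme`` maps label index -> structure name for every nonzero value.
    """

    data: np.ndarray
    scheme: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.any(self.data != np.round(self.data)):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("LabelMap values must be non-negative")
        self.scheme = {int(k): str(v) for k, v in self.scheme.items()}
        self.spacing = tuple(float(s) for s in self.spacing)
        present = set(np.unique(self.data).tolist()) - {0}
        unknown = present - set(self.scheme)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from scheme")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def reference_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> list[int]:
        """Sorted label indices declared in the scheme."""
        return sorted(self.scheme)


@dataclass
class Atlas:
    """A deformable atlas: intensity image plus per-level label maps."""

    image: Volume
    labels_level1: LabelMap | None = None
    labels_level2: LabelMap | None = None
    id: str = "atlas"

    def __post_init__(self) -> None:
        for lm in (self.labels_level1, self.labels_level2):
            if lm is not None and lm.shape != self.image.shape:
                raise ValueError("atlas label map grid does not match image grid")
        if self.labels_level1 is not None:
            names = set(self.labels_level1.scheme.values())
            required = set(LEVEL1_NAMES.values())
            if names != required:
                raise ValueError(
                    f"level-1 scheme must contain exactly {sorted(required)}, got {sorted(names)}"
                )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine_from(spacing, orientation) -> np.ndarray:
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for i, code in enumerate(orientation):
        aff[_AXIS_OF[code], i] = _SIGN_OF[code] * spacing[i]
    return aff


def _check_axis_aligned(affine: np.ndarray) -> None:
    rot = affine[:3, :3]
    # each column must have exactly one nonzero entry (signed permutation)
    nz = np.abs(rot) > 1e-6 * max(1.0, np.abs(rot).max())
    if not (np.all(nz.sum(axis=0) == 1) and np.all(nz.sum(axis=1) == 1)):
        raise ValueError("oblique (non-axis-aligned) orientation is not supported")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1/2 file as a :class:`Volume`.

    Trailing singleton dimensions are squeezed; oblique headers and
    non-3-D images raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got shape {data.shape} in {path}")
    affine = img.affine
    _check_axis_aligned(affine)
    orientation = "".join(nio.aff2axcodes(affine))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite values")
    return Volume(data=data, spacing=spacing, orientation=orientation)


def read_labelmap(path: str | Path, scheme: dict[int, str] | None = None) -> LabelMap:
    """Read a NIfTI label image; the scheme comes from a JSON sidecar
    (``<stem>.labels.json``) unless given explicitly."""
    vol = read_volume(path)
    if scheme is None:
        side = _sidecar_path(Path(path))
        if side.exists():
            scheme = {int(k): v for k, v in json.loads(side.read_text()).items()}
        else:
            scheme = {int(v): f"label-{int(v)}" for v in np.unique(vol.data) if v != 0}
    return LabelMap(
        data=np.round(vol.data).astype(np.int32),
        scheme=scheme,
        spacing=vol.spacing,
        orientation=vol.orientation,
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_volume(volume: Volume | LabelMap, path: str | Path) -> None:
    """Write a Volume (float32) or LabelMap (int16/int32 + JSON sidecar)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = _affine_from(volume.spacing, volume.orientation)
    if isinstance(volume, LabelMap):
        dtype = np.int16 if volume.data.max(initial=0) < 2**15 else np.int32
        img = nib.Nifti1Image(volume.data.astype(dtype), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
        _sidecar_path(path).write_text(
            json.dumps({str(k): v for k, v in volume.scheme.items()}, indent=1)
        )
    else:
        img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Orientation and resampling primitives
# ---------------------------------------------------------------------------


def reorient(volume: Volume | LabelMap, target: str):
    """Permute/flip axes so the orientation code equals ``target``.

    Physical content is unchanged; this is a pure axis permutation and
    flip (the axial-standardization step that precedes registration).
    """
    if len(target) != 3 or any(c not in _AXIS_OF for c in target):
        raise ValueError(f"invalid target orientation {target!r}")
    if {_AXIS_OF[c] for c in target} != {0, 1, 2}:
        raise ValueError(f"target orientation {target!r} does not span 3 axes")
    cur = nio.axcodes2ornt(tuple(volume.orientation))
    tgt = nio.axcodes2ornt(tuple(target))
    tr = nio.ornt_transform(cur, tgt)
    data = nio.apply_orientation(volume.data, tr)
    perm = tr[:, 0].astype(int)
    spacing = tuple(volume.spacing[perm[i]] for i in range(3))
    if isinstance(volume, LabelMap):
        return LabelMap(data=data, scheme=volume.scheme, spacing=spacing, orientation=target)
    return Volume(data=data, spacing=spacing, orientation=target)


def _block_reduce_mean(data: np.ndarray, factor: int) -> np.ndarray:
    out = data.astype(np.float64)
    for ax in range(3):
        n = out.shape[ax]
        idx = np.arange(0, n, factor)
        sums = np.add.reduceat(out, idx, axis=ax)
        counts = np.minimum(idx + factor, n) - idx
        shape = [1, 1, 1]
        shape[ax] = len(idx)
        out = sums / counts.reshape(shape)
    return out


def downsample(volume: Volume | LabelMap, factor: int):
    """Down-sample by an integer factor: block mean for scalar volumes,
    block mode (ties -> smallest label index) for label maps.

    Output shape per axis is ceil(n/factor); spacing is multiplied.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return volume.copy_with() if isinstance(volume, Volume) else LabelMap(
            volume.data.copy(), volume.scheme, volume.spacing, volume.orientation
        )
    spacing = tuple(s * factor for s in volume.spacing)
    if isinstance(volume, LabelMap):
        values = np.unique(volume.data)
        counts = np.stack(
            [_block_reduce_mean((volume.data == v).astype(np.float64), factor) for v in values]
        )
        # argmax returns the first maximum -> smallest label wins ties
        data = values[np.argmax(counts, axis=0)].astype(np.int32)
        return LabelMap(data=data, scheme=volume.scheme, spacing=spacing,
                        orientation=volume.orientation)
    data = _block_reduce_mean(volume.data, factor)
    return Volume(data=data, spacing=spacing, orientation=volume.orientation)


def _physical_coords(reference: Volume, moving_spacing) -> list[np.ndarray]:
    # shared origin at the center of voxel (0,0,0); both grids axis-aligned
    return [
        np.arange(reference.shape[i]) * reference.spacing[i] / moving_spacing[i]
        for i in range(3)
    ]


def resample_to(moving: Volume | LabelMap, reference: Volume, interp: str = "linear"):
    """Resample ``moving`` onto the grid of ``reference``.

    Label maps must use nearest-neighbour interpolation; voxels that fall
    outside the moving field of view are set to 0.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if moving.orientation != reference.orientation:
        raise ValueError("orientations differ; reorient before resampling")
    if isinstance(moving, LabelMap) and interp == "linear":
        raise ValueError("label maps must be resampled with nearest interpolation")
    axes = _physical_coords(reference, moving.spacing)
    coords = np.meshgrid(*axes, indexing="ij")
    order = 0 if interp == "nearest" else 1
    out = map_coordinates(
        moving.data.astype(np.float64), coords, order=order, mode="constant", cval=0.0
    )
    if isinstance(moving, LabelMap):
        return LabelMap(
            data=np.round(out).astype(np.int32),
            scheme=moving.scheme,
            spacing=reference.spacing,
            orientation=reference.orientation,
        )
    return Volume(data=out, spacing=reference.spacing, orientation=reference.orientation)


def normalize_intensity(
    volume: Volume,
    mask: np.ndarray | None = None,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> Volume:
    """Rescale to [0, 1] by percentile clamping (1st-99th by default).

    Gives the Gaussian-mixture intensity models a stable scale across
    acquisitions with different global contrast.  Raw values are kept by
    the caller for any outputs.  ``mask`` restricts percentile estimation
    (e.g. to brain voxels of a skull-stripped image); masked-out voxels
    are mapped through the same affine rescaling.
    """
    data = volume.data.astype(np.float64)
    sample = data[mask] if mask is not None else data
    if sample.size == 0:
        raise ValueError("empty mask for intensity normalization")
    lo, hi = np.percentile(sample, [p_low, p_high])
    if hi <= lo:
        hi = lo + 1.0
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return Volume(data=out, spacing=volume.spacing, orientation=volume.orientation)


def write_atlas(atlas: Atlas, out_dir: str | Path) -> None:
    """Write one atlas into a directory as ``<id>_image.nii.gz`` plus
    ``<id>_level1.nii.gz`` / ``<id>_level2.nii.gz`` label maps (each with
    its JSON scheme sidecar); absent label levels are skipped."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.image, out / f"{atlas.id}_image.nii.gz")
    if atlas.labels_level1 is not None:
        write_volume(atlas.labels_level1, out / f"{atlas.id}_level1.nii.gz")
    if atlas.labels_level2 is not None:
        write_volume(atlas.labels_level2, out / f"{atlas.id}_level2.nii.gz")


def read_atlas_dir(path: str | Path) -> list[Atlas]:
    """Read every atlas from a directory written by :func:`write_atlas`.

    Atlases are identified by ``*_image.nii.gz`` files and returned sorted
    by id; label levels are optional per atlas.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"atlas directory not found: {root}")
    atlases = []
    for img_path in sorted(root.glob("*_image.nii.gz")):
        aid = img_path.name[: -len("_image.nii.gz")]
        lv1 = root / f"{aid}_level1.nii.gz"
        lv2 = root / f"{aid}_level2.nii.gz"
        atlases.append(Atlas(
            image=read_volume(img_path),
            labels_level1=read_labelmap(lv1) if lv1.exists() else None,
            labels_level2=read_labelmap(lv2) if lv2.exists() else None,
            id=aid,
        ))
    if not atlases:
        raise ValueError(f"no '*_image.nii.gz' atlases found in {root}")
    return atlases
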