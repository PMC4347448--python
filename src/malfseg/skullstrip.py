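"""Level-1 fast fusion: skull-stripping via six global labels.

Subject and atlas images are down-sampled by a factor of two and
registered with a short flow (T = 2), which together make this level
cheap; six global labels (LV, GM, WM, CSF, skull, image background) are
then fused, the four brain labels are grouped into an initial mask, and
the mask is morphologically cleaned (largest component, hole filling,
closing/opening) after being carried back to the full-resolution grid by
linear interpolation of the fused brain posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates
from skimage.morphology import ball

from .core_io import (
    Atlas,
    BRAIN_LABEL_NAMES,
    LabelMap,
    Volume,
    downsample,
    normalize_intensity,
)
from .malf import MALFConfig, run_malf
from .registration import deform_label_priors, register

log = logging.getLogger(__name__)

__all__ = [
    "BrainMask",
    "SkullStripConfig",
    "strip",
    "group_brain_labels",
    "postprocess_mask",
    "mask_dice_on_slices",
]


@dataclass
class BrainMask:
    """Binary brain mask on the full-resolution subject grid."""

    mask: LabelMap
    provenance: dict = dc_field(default_factory=dict)


@dataclass
class SkullStripConfig:
    downsample_factor: int = 2
    timesteps: int = 2              # T for the level-1 registrations
    reg_iters: int = 40
    sigma_fluid: float = 2.0
    sigma_diffusion: float = 1.0
    sigma_ratio: float = 1.0
    smooth_radius: int = 2          # closing/opening structuring radius
    mask_threshold: float = 0.5
    malf: MALFConfig = dc_field(default_factory=lambda: MALFConfig(
        components_default=2, keep_joints=False))


def group_brain_labels(level1: LabelMap) -> np.ndarray:
    """Union of the four global brain labels (LV, GM, WM, CSF)."""
    names = set(level1.scheme.values())
    unknown = names - {"LV", "GM", "WM", "CSF", "skull", "background"}
    if unknown:
        raise ValueError(f"unknown level-1 labels: {sorted(unknown)}")
    brain_ids = [k for k, v in level1.scheme.items() if v in BRAIN_LABEL_NAMES]
    return np.isin(level1.data, brain_ids)


def postprocess_mask(mask: np.ndarray, smooth_radius: int = 2) -> np.ndarray:
    """Largest component, 3-D hole fill, then closing and opening.

    The result is a single connected component with no enclosed cavities;
    an empty input returns empty (logged).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        log.warning("postprocess_mask: empty input mask")
        return mask.copy()

    def largest_component(m):
        lab, n = ndimage.label(m, structure=np.ones((3, 3, 3), dtype=bool))
        if n <= 1:
            return m
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        return lab == counts.argmax()

    out = largest_component(mask)
    out = ndimage.binary_fill_holes(out)  # 6-connected background
    if smooth_radius > 0:
        selem = ball(smooth_radius)
        out = ndimage.binary_closing(out, structure=selem)
        out = ndimage.binary_opening(out, structure=selem)
    # morphology can in principle re-split or re-open cavities; re-enforce
    out = largest_component(out)
    out = ndimage.binary_fill_holes(out)
    return out


def mask_dice_on_slices(
    auto_mask: np.ndarray,
    ref_mask: np.ndarray,
    slice_axis: int,
    slice_indices,
) -> list[float]:
    """2-D Dice on pre-selected slices (the slice-wise validation used for
    skull-stripping)."""
    auto_mask = np.asarray(auto_mask).astype(bool)
    ref_mask = np.asarray(ref_mask).astype(bool)
    if auto_mask.shape != ref_mask.shape:
        raise ValueError("masks are on different grids")
    n = auto_mask.shape[slice_axis]
    out = []
    for idx in slice_indices:
        if not 0 <= idx < n:
            raise IndexError(f"slice index {idx} out of range for axis size {n}")
        a = np.take(auto_mask, idx, axis=slice_axis)
        b = np.take(ref_mask, idx, axis=slice_axis)
        denom = int(a.sum()) + int(b.sum())
        out.append(1.0 if denom == 0 else 2.0 * int((a & b).sum()) / denom)
    return out


def upsample_posterior(posterior_ds: np.ndarray, factor: int, full_shape) -> np.ndarray:
    """Linearly interpolate a block-mean down-sampled scalar field back to
    the full grid, honoring the half-voxel offset of block centers."""
    axes = [
        (np.arange(n) + 0.5) / factor - 0.5 for n in full_shape
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(posterior_ds.astype(np.float64), coords, order=1,
                           mode="nearest")


def strip(
    subject: Volume,
    atlases: list[Atlas],
    config: SkullStripConfig | None = None,
) -> tuple[BrainMask, Volume]:
    """Skull-strip a (preprocessed) subject with a set of level-1 atlases.

    Returns the full-resolution brain mask and the masked subject (raw
    intensities inside the mask, zero outside).
    """
    cfg = config or SkullStripConfig()
    if len(atlases) < 1:
        raise ValueError("at least one atlas is required")
    for a in atlases:
        if a.labels_level1 is None:
            raise ValueError(f"atlas {a.id} lacks level-1 labels")
        if a.image.shape != subject.shape:
            raise ValueError(f"atlas {a.id} grid does not match subject")

    f = cfg.downsample_factor
    subj_norm = normalize_intensity(subject)
    subj_ds = downsample(subj_norm, f)

    stacks = []
    label_ids = None
    for a in atlases:
        img_ds = downsample(normalize_intensity(a.image), f)
        lab_ds = downsample(a.labels_level1, f)
        diffeo = register(
            img_ds, subj_ds, T=cfg.timesteps,
            sigma_fluid=cfg.sigma_fluid, sigma_diffusion=cfg.sigma_diffusion,
            iters=cfg.reg_iters, sigma_ratio=cfg.sigma_ratio, pyramid_levels=1,
        )
        priors, ids = deform_label_priors(lab_ds, diffeo)
        if label_ids is None:
            label_ids = ids
        elif ids != label_ids:
            raise ValueError("level-1 schemes differ across atlases")
        stacks.append(priors)

    labeling_ds, state = run_malf(subj_ds.data, stacks, label_ids,
                                  config=cfg.malf)

    scheme = atlases[0].labels_level1.scheme
    brain_idx = [i for i, lab in enumerate(label_ids)
                 if scheme.get(lab) in BRAIN_LABEL_NAMES]
    brain_post_ds = state.fused[brain_idx].sum(axis=0)
    brain_post = upsample_posterior(brain_post_ds, f, subject.shape)
    mask = postprocess_mask(brain_post >= cfg.mask_threshold, cfg.smooth_radius)

    mask_map = LabelMap(mask.astype(np.int32), {1: "brain"},
                        subject.spacing, subject.orientation)
    stripped = Volume(subject.data * mask, subject.spacing, subject.orientation)
    prov = {
        "downsample_factor": f,
        "timesteps": cfg.timesteps,
        "reg_iters": cfg.reg_iters,
        "smooth_radius": cfg.smooth_radius,
        "n_atlases": len(atlases),
        "em_iterations": state.n_iterations,
    }
    brain = BrainMask(mask=mask_map, provenance=prov)
    brain.level1_labeling = LabelMap(labeling_ds.astype(np.int32), scheme,
                                     subj_ds.spacing, subj_ds.orientation)
    brain.fusion_state = state
    return brain, stripped
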