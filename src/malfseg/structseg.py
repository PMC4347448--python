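"""Level-2 full-resolution fusion: subcortical and ventricular structures.

Skull-stripped subject and atlas images are registered at the original
resolution with the default flow discretization (T = 10) and the
structure-level label schemes are fused.  Only the neighbourhood reached
by the deformed atlas labels can receive a nonzero label: voxels outside
the union of deformed atlas ROIs (dilated by 2 voxels) remain unlabeled,
mirroring the fact that the atlas schemes only cover a cuboid region of
interest around the structures.

The module also provides the atlas-construction helpers: the cuboid ROI
around the structures, the local GM/WM/CSF tissue labels inside it (a
3-class Gaussian-mixture classifier with spatial mode filtering), and the
skull/background split of the non-brain region by intensity thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core_io import Atlas, LabelMap, Volume, normalize_intensity
from .malf import FusionState, MALFConfig, run_malf
from .registration import deform_label_priors, register

log = logging.getLogger(__name__)

__all__ = [
    "StructSegConfig",
    "segment_structures",
    "cuboid_roi",
    "build_local_tissue_labels",
    "make_skull_background_labels",
]


@dataclass
class StructSegConfig:
    timesteps: int = 10             # T for the level-2 registrations
    reg_iters: int = 8              # fine-level iterations per timestep
    coarse_iters: int = 25          # coarse pyramid iterations per timestep
    pyramid_levels: int = 2
    sigma_fluid: float = 2.0
    sigma_diffusion: float = 1.0
    sigma_ratio: float = 1.0
    roi_dilation: int = 2
    malf: MALFConfig = dc_field(default_factory=lambda: MALFConfig(
        keep_joints=False))


def _components_for(scheme: dict[int, str]) -> dict[int, int]:
    """2 Gaussians for broad tissue-like labels, 1 for small structures."""
    comp: dict[int, int] = {0: 3}
    tissueish = ("local", "GM", "WM", "CSF", "background")
    for lab, name in scheme.items():
        comp[lab] = 2 if any(t in name for t in tissueish) or name == "LV" else 1
    return comp


def segment_structures(
    stripped_subject: Volume,
    atlases: list[Atlas],
    config: StructSegConfig | None = None,
) -> tuple[LabelMap, FusionState]:
    """Segment the level-2 scheme on a skull-stripped subject.

    All atlases must carry level-2 labels with an identical scheme and be
    skull-stripped themselves.
    """
    cfg = config or StructSegConfig()
    if len(atlases) < 1:
        raise ValueError("at least one atlas is required")
    scheme = None
    for a in atlases:
        if a.labels_level2 is None:
            raise ValueError(f"atlas {a.id} lacks level-2 labels")
        if scheme is None:
            scheme = a.labels_level2.scheme
        elif a.labels_level2.scheme != scheme:
            raise ValueError("level-2 schemes differ across atlases")
        if a.image.shape != stripped_subject.shape:
            raise ValueError(f"atlas {a.id} grid does not match subject")

    subj_mask = stripped_subject.data > 0
    subj_norm = normalize_intensity(stripped_subject, mask=subj_mask)
    label_ids = [0] + sorted(scheme)

    # register inside the joint head bounding box only: the brain occupies
    # a fraction of the field of view, so this is a pure speedup
    union = subj_mask.copy()
    for a in atlases:
        union |= a.image.data > 0
    if not union.any():
        raise ValueError("subject and atlases are empty")
    head_box = tuple(
        slice(max(int(i.min()) - 3, 0), min(int(i.max()) + 4, n))
        for i, n in zip(np.nonzero(union), stripped_subject.shape)
    )
    subj_box = Volume(subj_norm.data[head_box], subj_norm.spacing,
                      subj_norm.orientation)

    stacks = []
    for a in atlases:
        a_mask = a.image.data > 0
        img_norm = normalize_intensity(a.image, mask=a_mask)
        img_box = Volume(img_norm.data[head_box], img_norm.spacing,
                         img_norm.orientation)
        diffeo = register(
            img_box, subj_box, T=cfg.timesteps,
            sigma_fluid=cfg.sigma_fluid, sigma_diffusion=cfg.sigma_diffusion,
            iters=cfg.reg_iters, sigma_ratio=cfg.sigma_ratio,
            pyramid_levels=cfg.pyramid_levels, coarse_iters=cfg.coarse_iters,
        )
        lab_box = LabelMap(a.labels_level2.data[head_box], scheme,
                           a.labels_level2.spacing, a.labels_level2.orientation)
        priors, _ = deform_label_priors(lab_box, diffeo, label_ids=label_ids)
        stacks.append(priors)

    # voxels reachable by any deformed atlas label, dilated by 2 voxels
    allowed = np.zeros(subj_box.shape, dtype=bool)
    for st in stacks:
        allowed |= st[1:].sum(axis=0) > 0.01
    if cfg.roi_dilation > 0:
        allowed = ndimage.binary_dilation(
            allowed, iterations=cfg.roi_dilation,
            structure=ndimage.generate_binary_structure(3, 1),
        )
    if not allowed.any():
        raise ValueError("deformed atlas labels do not reach the subject grid")
    bbox = ndimage.find_objects(allowed.astype(np.int8))[0]

    malf_cfg = cfg.malf
    if not malf_cfg.components_per_label:
        from dataclasses import replace

        malf_cfg = replace(malf_cfg, components_per_label=_components_for(scheme))
    sub_stacks = [st[(slice(None),) + tuple(bbox)] for st in stacks]
    labeling_box, state = run_malf(
        subj_box.data[tuple(bbox)], sub_stacks, label_ids, config=malf_cfg
    )

    labeling_head = np.zeros(subj_box.shape, dtype=np.int32)
    labeling_head[tuple(bbox)] = labeling_box
    labeling_head[~allowed] = 0
    labeling = np.zeros(stripped_subject.shape, dtype=np.int32)
    labeling[head_box] = labeling_head
    out = LabelMap(labeling, scheme, stripped_subject.spacing,
                   stripped_subject.orientation)
    state.roi_bbox = tuple(
        (h.start + s.start, h.start + s.stop)
        for h, s in zip(head_box, bbox)
    )
    return out, state


def cuboid_roi(
    structure_masks: list[np.ndarray],
    margin: int = 5,
    shape=None,
) -> tuple[slice, slice, slice]:
    """Axis-aligned bounding cuboid of the union of the structure masks,
    expanded by ``margin`` voxels and clamped to the grid."""
    if not structure_masks:
        raise ValueError("no structure masks given")
    union = np.zeros_like(np.asarray(structure_masks[0]), dtype=bool)
    for m in structure_masks:
        union |= np.asarray(m).astype(bool)
    if not union.any():
        raise ValueError("all structure masks are empty")
    shape = union.shape if shape is None else tuple(shape)
    idx = np.nonzero(union)
    bounds = []
    for ax in range(3):
        lo = max(int(idx[ax].min()) - margin, 0)
        hi = min(int(idx[ax].max()) + margin + 1, shape[ax])
        bounds.append(slice(lo, hi))
    return tuple(bounds)


def _gmm_1d(values: np.ndarray, n_classes: int, n_iter: int = 50):
    """Deterministic 1-D GMM (quantile init); returns (means, assignments)."""
    mu = np.quantile(values, (np.arange(n_classes) + 0.5) / n_classes)
    var = np.full(n_classes, max(values.var() / n_classes, 1e-6))
    w = np.full(n_classes, 1.0 / n_classes)
    v = values[:, None]
    for _ in range(n_iter):
        logp = (-0.5 * (v - mu) ** 2 / var - 0.5 * np.log(2 * np.pi * var)
                + np.log(np.maximum(w, 1e-300)))
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        resp = p / p.sum(axis=1, keepdims=True)
        mass = resp.sum(axis=0)
        if np.any(mass <= 0):
            break
        w = mass / mass.sum()
        mu = (resp * v).sum(axis=0) / mass
        var = np.maximum((resp * (v - mu) ** 2).sum(axis=0) / mass, 1e-6)
    order = np.argsort(mu)
    logp = (-0.5 * (v - mu[order]) ** 2 / var[order]
            - 0.5 * np.log(2 * np.pi * var[order])
            + np.log(np.maximum(w[order], 1e-300)))
    return mu[order], np.argmax(logp, axis=1)


def build_local_tissue_labels(
    atlas_image: Volume,
    structure_labels: LabelMap,
    roi: tuple[slice, slice, slice],
    mode_filter: bool = True,
) -> LabelMap:
    """Label ROI voxels not covered by structures as local CSF/GM/WM.

    A 3-class Gaussian-mixture classifier on intensities, classes named by
    ascending mean (CSF < GM < WM for T1-like contrast), followed by a 3^3
    spatial mode filter.  Structure labels are never overwritten; voxels
    outside the ROI (or with zero intensity, i.e. outside the stripped
    brain) remain 0.
    """
    data = atlas_image.data
    labels = structure_labels.data.copy()
    roi_mask = np.zeros(atlas_image.shape, dtype=bool)
    roi_mask[tuple(roi)] = True
    unassigned = roi_mask & (labels == 0) & (data > 0)
    if not unassigned.any():
        log.warning("build_local_tissue_labels: ROI has no unassigned voxels")
        return LabelMap(labels, structure_labels.scheme,
                        structure_labels.spacing, structure_labels.orientation)
    _, assign = _gmm_1d(data[unassigned].astype(np.float64), 3)
    cls = np.full(atlas_image.shape, -1, dtype=np.int8)
    cls[unassigned] = assign
    if mode_filter:
        votes = np.stack([
            ndimage.uniform_filter((cls == c).astype(np.float32), size=3)
            for c in range(3)
        ])
        cls_f = np.argmax(votes, axis=0).astype(np.int8)
        cls[unassigned] = cls_f[unassigned]
    base = max(structure_labels.scheme, default=0)
    names = ["local CSF", "local GM", "local WM"]  # ascending mean
    scheme = dict(structure_labels.scheme)
    for c, name in enumerate(names):
        sel = unassigned & (cls == c)
        if sel.any():
            labels[sel] = base + 1 + c
            scheme[base + 1 + c] = name
    return LabelMap(labels, scheme, structure_labels.spacing,
                    structure_labels.orientation)


def make_skull_background_labels(
    head_image: Volume,
    brain_mask: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the non-brain region into skull (>= threshold) and image
    background by intensity thresholding (Otsu when unspecified)."""
    brain = np.asarray(brain_mask).astype(bool)
    nonbrain = ~brain
    vals = head_image.data[nonbrain]
    if threshold is None:
        if vals.size == 0 or np.ptp(vals) == 0:
            threshold = np.inf  # nothing to call skull
        else:
            threshold = float(threshold_otsu(vals))
    skull = nonbrain & (head_image.data >= threshold)
    background = nonbrain & ~skull
    return skull, background
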