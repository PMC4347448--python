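"""Dice overlap computation and the leave-one-out experiment harness.

Validation mirrors the atlas-based protocol: each atlas in turn is
treated as the to-be-segmented subject, stripped and segmented with the
remaining atlases, and compared against its own ground-truth labels with
the Dice similarity coefficient 2|A∩B|/(|A|+|B|).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import Atlas, LabelMap, Volume
from .skullstrip import SkullStripConfig, group_brain_labels, strip
from .structseg import StructSegConfig, segment_structures

log = logging.getLogger(__name__)

__all__ = ["dice", "dice_per_label", "leave_one_out", "leave_one_out_detailed",
           "summarize_loo"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on the same grid.

    Both masks empty is defined as 1.0 (logged); empty vs non-empty is 0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        log.warning("dice: both masks empty; defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_per_label(
    auto: LabelMap,
    ref: LabelMap,
    scheme: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-label Dice table with columns (label, name, dice, absent).

    ``absent`` flags labels missing from both maps (their Dice is the
    empty-vs-empty convention, 1.0).
    """
    if auto.shape != ref.shape:
        raise ValueError("label maps are on different grids")
    if scheme is None:
        if auto.scheme != ref.scheme:
            raise ValueError("schemes differ; pass an explicit scheme")
        scheme = auto.scheme
    rows = []
    for lab in sorted(scheme):
        a = auto.data == lab
        r = ref.data == lab
        absent = not (a.any() or r.any())
        d = 1.0 if absent else (
            0.0 if not (a.any() and r.any())
            else 2.0 * int((a & r).sum()) / (int(a.sum()) + int(r.sum()))
        )
        rows.append({"label": lab, "name": scheme[lab], "dice": d,
                     "absent": absent})
    return pd.DataFrame(rows)


def _strip_with_truth(atlas: Atlas) -> Volume:
    """Atlas-side skull-stripping from its own level-1 ground truth."""
    mask = group_brain_labels(atlas.labels_level1)
    return Volume(atlas.image.data * mask, atlas.image.spacing,
                  atlas.image.orientation)


def leave_one_out_detailed(
    atlas_set: list[Atlas],
    strip_config: SkullStripConfig | None = None,
    seg_config: StructSegConfig | None = None,
) -> list[dict]:
    """Run the full two-level pipeline for each held-out atlas.

    Returns one dict per fold with keys ``subject_id``, ``brain_dice``,
    ``table`` (per-structure Dice with reference voxel counts),
    ``strip_state`` and ``seg_state`` (the two fusion diagnostics).  The
    held-out atlas contributes only its intensity image; its labels are
    used solely as the evaluation reference.
    """
    if len(atlas_set) < 3:
        raise ValueError("leave-one-out requires at least 3 atlases")
    folds = []
    for i, held in enumerate(atlas_set):
        others = [a for j, a in enumerate(atlas_set) if j != i]
        brain, stripped = strip(held.image, others, strip_config)
        truth_mask = group_brain_labels(held.labels_level1)
        seg_atlases = [
            Atlas(image=_strip_with_truth(a), labels_level1=a.labels_level1,
                  labels_level2=a.labels_level2, id=a.id)
            for a in others
        ]
        seg, seg_state = segment_structures(stripped, seg_atlases, seg_config)
        table = dice_per_label(seg, held.labels_level2)
        table["ref_voxels"] = [
            int((held.labels_level2.data == lab).sum()) for lab in table["label"]
        ]
        folds.append({
            "subject_id": held.id,
            "brain_dice": dice(brain.mask.data > 0, truth_mask),
            "table": table,
            "strip_state": brain.fusion_state,
            "seg_state": seg_state,
        })
    return folds


def leave_one_out(
    atlas_set: list[Atlas],
    strip_config: SkullStripConfig | None = None,
    seg_config: StructSegConfig | None = None,
) -> pd.DataFrame:
    """Long-format leave-one-out Dice table.

    Columns are (subject_id, structure, dice, stage); the skull-stripping
    row per subject uses structure name ``brain``.
    """
    rows = []
    for fold in leave_one_out_detailed(atlas_set, strip_config, seg_config):
        rows.append({
            "subject_id": fold["subject_id"],
            "structure": "brain",
            "dice": fold["brain_dice"],
            "stage": "skullstrip",
        })
        for _, row in fold["table"].iterrows():
            rows.append({
                "subject_id": fold["subject_id"],
                "structure": row["name"],
                "dice": float(row["dice"]),
                "stage": "structseg",
            })
    return pd.DataFrame(rows, columns=["subject_id", "structure", "dice", "stage"])


def summarize_loo(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd Dice per structure across held-out subjects."""
    g = results.groupby(["stage", "structure"])["dice"]
    out = g.agg(["mean", "std", "min", "count"]).reset_index()
    return out.rename(columns={"mean": "dice_mean", "std": "dice_sd",
                               "min": "dice_min", "count": "n"})
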