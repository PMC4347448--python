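"""Estimator-style front end to the two-level fusion pipeline.

The multi-atlas segmenter is naturally a lazy estimator in the
scikit-learn sense: ``fit`` stores (and validates) the atlas set, and
``predict`` carries it onto a new subject.  Parameters follow the
``get_params``/``set_params`` protocol so the estimators compose with
scikit-learn model selection; fitted attributes carry the usual trailing
underscore.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .core_io import Atlas, LabelMap, Volume
from .evaluation import dice_per_label
from .malf import MALFConfig
from .preprocessing import apply_bias_correction, estimate_bias
from .skullstrip import BrainMask, SkullStripConfig, strip
from .structseg import StructSegConfig, segment_structures

__all__ = ["SkullStripper", "StructureSegmenter", "MALFPipeline"]


def _check_atlases(atlases, level: int):
    if not isinstance(atlases, (list, tuple)) or len(atlases) < 1:
        raise ValueError("fit expects a non-empty list of Atlas objects")
    for a in atlases:
        if not isinstance(a, Atlas):
            raise TypeError(f"expected Atlas, got {type(a).__name__}")
        if level == 1 and a.labels_level1 is None:
            raise ValueError(f"atlas {a.id} lacks level-1 labels")
        if level == 2 and a.labels_level2 is None:
            raise ValueError(f"atlas {a.id} lacks level-2 labels")
    return list(atlases)


class SkullStripper(BaseEstimator):
    """Level-1 fast fusion skull-stripper (down-sampled, T = 2).

    Parameters mirror :class:`~malfseg.skullstrip.SkullStripConfig`.
    """

    def __init__(self, downsample_factor: int = 2, timesteps: int = 2,
                 reg_iters: int = 40, sigma_fluid: float = 2.0,
                 sigma_diffusion: float = 1.0, sigma_ratio: float = 1.0,
                 smooth_radius: int = 2, mask_threshold: float = 0.5,
                 max_em_iters: int = 10):
        self.downsample_factor = downsample_factor
        self.timesteps = timesteps
        self.reg_iters = reg_iters
        self.sigma_fluid = sigma_fluid
        self.sigma_diffusion = sigma_diffusion
        self.sigma_ratio = sigma_ratio
        self.smooth_radius = smooth_radius
        self.mask_threshold = mask_threshold
        self.max_em_iters = max_em_iters

    def _config(self) -> SkullStripConfig:
        return SkullStripConfig(
            downsample_factor=self.downsample_factor,
            timesteps=self.timesteps, reg_iters=self.reg_iters,
            sigma_fluid=self.sigma_fluid, sigma_diffusion=self.sigma_diffusion,
            sigma_ratio=self.sigma_ratio, smooth_radius=self.smooth_radius,
            mask_threshold=self.mask_threshold,
            malf=MALFConfig(components_default=2, keep_joints=False,
                            max_iters=self.max_em_iters),
        )

    def fit(self, X, y=None):
        """Store the atlas set (a list of Atlas with level-1 labels)."""
        self.atlases_ = _check_atlases(X, level=1)
        return self

    def predict(self, subject: Volume) -> BrainMask:
        """Estimate the brain mask of a subject volume."""
        self._check_fitted()
        brain, stripped = strip(subject, self.atlases_, self._config())
        self.last_stripped_ = stripped
        return brain

    def transform(self, subject: Volume) -> Volume:
        """Return the skull-stripped subject volume."""
        self._check_fitted()
        _, stripped = strip(subject, self.atlases_, self._config())
        return stripped

    def _check_fitted(self):
        if not hasattr(self, "atlases_"):
            raise RuntimeError("SkullStripper is not fitted; call fit(atlases)")


class StructureSegmenter(BaseEstimator):
    """Level-2 full-resolution fusion segmenter (T = 10).

    ``fit`` expects skull-stripped atlases; ``predict`` expects a
    skull-stripped subject volume.
    """

    def __init__(self, timesteps: int = 10, reg_iters: int = 8,
                 coarse_iters: int = 25, pyramid_levels: int = 2,
                 sigma_fluid: float = 2.0, sigma_diffusion: float = 1.0,
                 sigma_ratio: float = 1.0, roi_dilation: int = 2,
                 max_em_iters: int = 10):
        self.timesteps = timesteps
        self.reg_iters = reg_iters
        self.coarse_iters = coarse_iters
        self.pyramid_levels = pyramid_levels
        self.sigma_fluid = sigma_fluid
        self.sigma_diffusion = sigma_diffusion
        self.sigma_ratio = sigma_ratio
        self.roi_dilation = roi_dilation
        self.max_em_iters = max_em_iters

    def _config(self) -> StructSegConfig:
        return StructSegConfig(
            timesteps=self.timesteps, reg_iters=self.reg_iters,
            coarse_iters=self.coarse_iters, pyramid_levels=self.pyramid_levels,
            sigma_fluid=self.sigma_fluid, sigma_diffusion=self.sigma_diffusion,
            sigma_ratio=self.sigma_ratio, roi_dilation=self.roi_dilation,
            malf=MALFConfig(keep_joints=False, max_iters=self.max_em_iters),
        )

    def fit(self, X, y=None):
        self.atlases_ = _check_atlases(X, level=2)
        return self

    def predict(self, stripped_subject: Volume) -> LabelMap:
        if not hasattr(self, "atlases_"):
            raise RuntimeError("StructureSegmenter is not fitted")
        seg, state = segment_structures(stripped_subject, self.atlases_,
                                        self._config())
        self.fusion_state_ = state
        return seg


class MALFPipeline(BaseEstimator):
    """Full three-step pipeline: bias correction, skull-strip, segment."""

    def __init__(self, bias_degree: int = 3, correct_bias: bool = True,
                 strip_params: dict | None = None,
                 segment_params: dict | None = None):
        self.bias_degree = bias_degree
        self.correct_bias = correct_bias
        self.strip_params = strip_params
        self.segment_params = segment_params

    def fit(self, X, y=None):
        """X: atlases carrying both label levels, already skull-stripped
        on the level-2 side is not required -- stripping uses level-1
        ground truth."""
        atlases = _check_atlases(X, level=1)
        _check_atlases(atlases, level=2)
        self.stripper_ = SkullStripper(**(self.strip_params or {})).fit(atlases)
        from .evaluation import _strip_with_truth

        seg_atlases = [
            Atlas(image=_strip_with_truth(a), labels_level1=a.labels_level1,
                  labels_level2=a.labels_level2, id=a.id)
            for a in atlases
        ]
        self.segmenter_ = StructureSegmenter(**(self.segment_params or {})).fit(
            seg_atlases
        )
        return self

    def predict(self, subject: Volume) -> LabelMap:
        """Segment a raw head volume end to end."""
        if not hasattr(self, "stripper_"):
            raise RuntimeError("MALFPipeline is not fitted")
        vol = subject
        if self.correct_bias:
            bias = estimate_bias(vol, degree=self.bias_degree)
            vol = apply_bias_correction(vol, bias)
            self.bias_ = bias
        self.brain_mask_ = self.stripper_.predict(vol)
        stripped = self.stripper_.last_stripped_
        self.stripped_ = stripped
        seg = self.segmenter_.predict(stripped)
        self.fusion_state_ = self.segmenter_.fusion_state_
        return seg

    def score(self, subject: Volume, truth: LabelMap) -> float:
        """Mean per-structure Dice against a reference segmentation."""
        seg = self.predict(subject)
        table = dice_per_label(seg, truth)
        return float(table.loc[~table["absent"], "dice"].mean())
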