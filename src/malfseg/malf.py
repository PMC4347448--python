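"""Multi-atlas likelihood fusion (MALF).

The segmentation label field W is estimated by maximum a posteriori from
the observed image I: W_hat = argmax_W p(I, W), where the joint is a
fusion of per-atlas likelihoods,

    p(I, W) = sum_a p(I, W | A = a) * pi_A(a),

with pi_A the atlas prior (uniform by default).  Per atlas and voxel the
joint factorizes into an intensity likelihood times a deformed label
prior:

    p(I(x), W(x)=k | a) = p(I(x) | k, a) * p(W(x)=k | phi_a, a),

where p(I(x)|k,a) is a per-label Gaussian mixture (with a small uniform
contamination term for robustness) and the prior channel is the atlas
label map warped by the estimated diffeomorphism phi_a.

Treating the generating atlas and the label as per-voxel latent
variables, :func:`run_malf` alternates an exact E-step (per-voxel
responsibilities over (atlas, label), whose label marginal is the fused
posterior) with a generalized M-step (per-atlas, per-label weighted GMM
refits accepted only when they do not decrease the weighted likelihood).
The per-voxel marginal log-likelihood is therefore non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "LabelGMM",
    "IntensityModel",
    "FusionState",
    "fit_intensity_model",
    "atlas_joint_likelihood",
    "fuse",
    "map_estimate",
    "run_malf",
    "MALFConfig",
]

#: uniform contamination weight mixed into every per-label density
CONTAMINATION = 1e-3


@dataclass
class LabelGMM:
    """1-D Gaussian mixture for one label's intensity distribution."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.variances <= 0):
            raise ValueError("weights must be >= 0 and variances > 0")

    def pdf(self, values: np.ndarray) -> np.ndarray:
        """Density including the uniform contamination term on [0, 1]."""
        v = np.asarray(values, dtype=np.float64)[..., None]
        g = np.exp(-0.5 * (v - self.means) ** 2 / self.variances) / np.sqrt(
            2.0 * np.pi * self.variances
        )
        gmm = (g * self.weights).sum(axis=-1)
        return (1.0 - CONTAMINATION) * gmm + CONTAMINATION


@dataclass
class IntensityModel:
    """Per-label Gaussian-mixture intensity models for one atlas."""

    models: dict[int, LabelGMM]
    flagged: set[int] = field(default_factory=set)

    def labels(self) -> list[int]:
        return sorted(self.models)


@dataclass
class FusionState:
    """Fused posterior and diagnostics of one MALF run."""

    atlas_priors: np.ndarray
    labels: list[int]
    fused: np.ndarray                      # (L, *grid) posterior q(k|x)
    labeling: np.ndarray                   # (*grid,) int argmax labels
    per_atlas_joint: list[np.ndarray] | None
    objective_trace: list[float] = field(default_factory=list)
    #: per-iteration max |sum_k q(k|x) - 1| of the fused posterior
    normalization_trace: list[float] = field(default_factory=list)
    n_zero_voxels: int = 0
    n_iterations: int = 0
    converged: bool = False


@dataclass
class MALFConfig:
    """Tunables of the fusion EM."""

    max_iters: int = 10
    change_tol: float = 1e-3       # stop when < 0.1% of voxels change label
    prior_floor: float = 1e-4      # floor on deformed priors (avoids zero-locking)
    variance_floor: float = 1e-6   # on normalized [0,1] intensities
    min_label_mass: float = 10.0   # below this a label gets a broad fallback
    components_default: int = 2
    components_per_label: dict[int, int] = field(default_factory=dict)
    gmm_iters: int = 30
    keep_joints: bool = True


_FALLBACK = LabelGMM(weights=[1.0], means=[0.5], variances=[1.0 / 12.0])


def _weighted_quantile_init(values, weights, n_comp):
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    cw /= cw[-1]

    def at_quantiles(qs):
        return values[order[np.searchsorted(cw, qs).clip(0, len(values) - 1)]]

    means = at_quantiles((np.arange(n_comp) + 0.5) / n_comp).astype(np.float64)
    if len(np.unique(means)) < n_comp:
        # concentrated mass collapsed the quantiles onto one value; EM can
        # never separate coincident components, so de-collapse with a
        # deterministic farthest-point sweep over a quantile candidate grid
        cand = np.unique(at_quantiles(np.linspace(0.0, 1.0, 65)))
        if len(cand) >= n_comp:
            chosen = [means[0]]
            for _ in range(n_comp - 1):
                dist = np.min(np.abs(cand[:, None] - np.asarray(chosen)), axis=1)
                chosen.append(cand[int(np.argmax(dist))])
            means = np.sort(np.asarray(chosen, dtype=np.float64))
    var = max(np.average((values - np.average(values, weights=weights)) ** 2,
                         weights=weights), 1e-6)
    return (np.full(n_comp, 1.0 / n_comp), means,
            np.full(n_comp, var / max(n_comp, 1)))


def _fit_label_gmm(values, weights, n_comp, var_floor, n_iter,
                   init: LabelGMM | None):
    """Weighted EM for a 1-D GMM; warm-startable; deterministic."""
    if init is not None and len(init.weights) == n_comp:
        w, mu, var = init.weights.copy(), init.means.copy(), init.variances.copy()
    else:
        w, mu, var = _weighted_quantile_init(values, weights, n_comp)
    v = values[:, None]
    prev_ll = -np.inf
    for _ in range(n_iter):
        logp = (-0.5 * (v - mu) ** 2 / var
                - 0.5 * np.log(2.0 * np.pi * var) + np.log(np.maximum(w, 1e-300)))
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((weights * (np.log(tot[:, 0]) + m[:, 0])).sum())
        rw = resp * weights[:, None]
        mass = rw.sum(axis=0)
        if np.any(mass <= 0):
            break
        w = mass / mass.sum()
        mu = (rw * v).sum(axis=0) / mass
        var = np.maximum((rw * (v - mu) ** 2).sum(axis=0) / mass, var_floor)
        if ll - prev_ll < 1e-9 * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return LabelGMM(weights=w / w.sum(), means=mu, variances=var)


def fit_intensity_model(
    subject: np.ndarray,
    label_priors: np.ndarray,
    labels: list[int],
    components_per_label: int | dict[int, int] = 2,
    config: MALFConfig | None = None,
    init_model: IntensityModel | None = None,
) -> IntensityModel:
    """Fit per-label GMMs to subject intensities with per-voxel weights.

    ``label_priors`` has shape ``(L, *grid)`` aligned with ``labels``.
    Labels whose total weight falls below ``min_label_mass`` voxels get a
    single broad fallback Gaussian and are flagged.
    """
    cfg = config or MALFConfig()
    if label_priors.shape[0] != len(labels):
        raise ValueError("label_priors channel count does not match labels")
    vals = subject.ravel().astype(np.float64)
    models: dict[int, LabelGMM] = {}
    flagged: set[int] = set()
    for i, lab in enumerate(labels):
        w = label_priors[i].ravel().astype(np.float64)
        sel = w > 1e-4
        mass = float(w[sel].sum())
        if mass < cfg.min_label_mass:
            models[lab] = _FALLBACK
            flagged.add(lab)
            continue
        if isinstance(components_per_label, dict):
            n_comp = components_per_label.get(lab, cfg.components_default)
        else:
            n_comp = int(components_per_label)
        init = init_model.models.get(lab) if init_model is not None else None
        if init_model is not None and lab in init_model.flagged:
            init = None
        models[lab] = _fit_label_gmm(vals[sel], w[sel], n_comp,
                                     cfg.variance_floor, cfg.gmm_iters, init)
    return IntensityModel(models=models, flagged=flagged)


def atlas_joint_likelihood(
    subject: np.ndarray,
    deformed_priors: np.ndarray,
    model: IntensityModel,
    labels: list[int],
    prior_floor: float = 1e-4,
) -> np.ndarray:
    """Per-voxel per-label joint p(I(x), W(x)=k | a) as a (L, *grid) array.

    joint(x,k) = gmm_density(I(x); model_k) * max(prior(x,k), prior_floor).
    """
    if deformed_priors.shape[0] != len(labels):
        raise ValueError("prior channel count does not match labels")
    missing = [lab for lab in labels if lab not in model.models]
    if missing:
        raise ValueError(f"model lacks labels {missing}")
    joint = np.empty((len(labels),) + subject.shape, dtype=np.float64)
    for i, lab in enumerate(labels):
        joint[i] = model.models[lab].pdf(subject) * np.maximum(
            deformed_priors[i], prior_floor
        )
    return joint


def fuse(
    per_atlas_joint: np.ndarray | list[np.ndarray],
    atlas_priors: np.ndarray,
    fallback_priors: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Fuse per-atlas joints: sum over atlases with prior pi_A, then
    normalize over labels per voxel.

    Voxels where every atlas assigns zero joint mass fall back to the
    average deformed prior (or uniform); the count is returned.
    """
    stack = np.asarray(per_atlas_joint, dtype=np.float64)
    pa = np.asarray(atlas_priors, dtype=np.float64)
    if not np.isclose(pa.sum(), 1.0, atol=1e-8):
        raise ValueError("atlas priors must sum to 1")
    if stack.shape[0] != pa.shape[0]:
        raise ValueError("atlas prior length does not match joint stack")
    fused = np.tensordot(pa, stack, axes=(0, 0))
    total = fused.sum(axis=0)
    zero = total <= 0.0
    n_zero = int(zero.sum())
    if n_zero:
        if fallback_priors is None:
            fused[:, zero] = 1.0 / fused.shape[0]
        else:
            fb = np.tensordot(pa, np.asarray(fallback_priors, dtype=np.float64),
                              axes=(0, 0))
            fb_tot = fb.sum(axis=0)
            fb_tot[fb_tot <= 0] = 1.0
            fused[:, zero] = (fb / fb_tot)[:, zero]
        total = fused.sum(axis=0)
    fused /= total
    return fused, n_zero


def map_estimate(fused: np.ndarray, labels: list[int]) -> np.ndarray:
    """Per-voxel argmax over labels; ties break to the smallest label."""
    order = np.argsort(labels)
    arr = np.asarray(labels)[order]
    idx = np.argmax(np.asarray(fused)[order], axis=0)  # first max = smallest label
    return arr[idx]


def _weighted_loglik(vals: np.ndarray, w: np.ndarray, gmm: LabelGMM) -> float:
    return float((w * np.log(np.maximum(gmm.pdf(vals), 1e-300))).sum())


def run_malf(
    subject: np.ndarray,
    prior_stacks: list[np.ndarray],
    labels: list[int],
    atlas_priors: np.ndarray | None = None,
    config: MALFConfig | None = None,
) -> tuple[np.ndarray, FusionState]:
    """EM alternation to the MAP segmentation.

    ``prior_stacks`` holds one (L, *grid) deformed-prior stack per atlas,
    aligned with ``labels`` (which must be sorted ascending).  Returns the
    label array and the :class:`FusionState` (fused posterior, objective
    trace, diagnostics).
    """
    if len(prior_stacks) == 0:
        raise ValueError("empty atlas list")
    if list(labels) != sorted(labels):
        raise ValueError("labels must be sorted ascending")
    cfg = config or MALFConfig()
    A = len(prior_stacks)
    pa = (np.full(A, 1.0 / A) if atlas_priors is None
          else np.asarray(atlas_priors, dtype=np.float64))
    if not np.isclose(pa.sum(), 1.0, atol=1e-8):
        raise ValueError("atlas priors must sum to 1")
    subj = np.asarray(subject, dtype=np.float64)
    grid_shape = subj.shape
    L = len(labels)
    stacks = [np.asarray(p, dtype=np.float32) for p in prior_stacks]
    for st in stacks:
        if st.shape != (L,) + grid_shape:
            raise ValueError("prior stack shape mismatch")

    comp = cfg.components_per_label or cfg.components_default
    # initialization: per-atlas models from the deformed priors themselves
    models = [
        fit_intensity_model(subj, st, labels, comp, cfg) for st in stacks
    ]

    labeling = None
    trace: list[float] = []
    norm_trace: list[float] = []
    joints: list[np.ndarray] = []
    fused = None
    n_zero = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_iters + 1):
        # E-step: per-atlas joints, fused posterior, responsibilities
        joints = [
            atlas_joint_likelihood(subj, stacks[a], models[a], labels,
                                   cfg.prior_floor)
            for a in range(A)
        ]
        denom = np.zeros(grid_shape, dtype=np.float64)
        for a in range(A):
            denom += pa[a] * joints[a].sum(axis=0)
        n_zero = int((denom <= 0).sum())
        denom_safe = np.where(denom > 0, denom, 1.0)
        trace.append(float(np.log(denom_safe).sum()))
        fused = np.zeros((L,) + grid_shape, dtype=np.float64)
        for a in range(A):
            fused += pa[a] * joints[a]
        fused /= denom_safe
        norm_trace.append(float(np.abs(fused.sum(axis=0) - 1.0).max()))
        new_labeling = map_estimate(fused, labels)
        if labeling is not None:
            changed = float((new_labeling != labeling).mean())
            if changed < cfg.change_tol:
                labeling = new_labeling
                converged = True
                break
        labeling = new_labeling
        if it == cfg.max_iters:
            break
        # M-step (generalized): per-atlas weighted refits, accepted only if
        # they do not decrease the weighted log-likelihood
        for a in range(A):
            gamma = (pa[a] / denom_safe) * joints[a]  # responsibilities
            new_model = fit_intensity_model(subj, gamma.astype(np.float32),
                                            labels, comp, cfg, init_model=models[a])
            kept: dict[int, LabelGMM] = {}
            flg = set(new_model.flagged)
            vals = subj.ravel()
            for i, lab in enumerate(labels):
                w = gamma[i].ravel()
                old = models[a].models[lab]
                new = new_model.models[lab]
                # full-weight comparison keeps the generalized M-step exact
                if _weighted_loglik(vals, w, new) >= _weighted_loglik(vals, w, old):
                    kept[lab] = new
                else:
                    kept[lab] = old
            models[a] = IntensityModel(models=kept, flagged=flg)

    state = FusionState(
        atlas_priors=pa,
        labels=list(labels),
        fused=fused,
        labeling=labeling,
        per_atlas_joint=[j.astype(np.float32) for j in joints] if cfg.keep_joints else None,
        objective_trace=trace,
        normalization_trace=norm_trace,
        n_zero_voxels=n_zero,
        n_iterations=it,
        converged=converged,
    )
    if n_zero:
        log.warning("fusion: %d voxels had zero joint mass", n_zero)
    return labeling, state
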