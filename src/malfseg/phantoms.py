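"""Synthetic T1-like head phantoms with ground-truth labels.

The generator instantiates the pipeline's own generative model: a
piecewise-constant base head (ellipsoidal skull shell, CSF rim, cortical
GM shell, WM core, two lateral-ventricle horns, and twelve paired
"subcortical" blobs with deliberately ambiguous contrast between GM and
WM) is carried through an independent random smooth diffeomorphism per
subject, then degraded by a smooth multiplicative polynomial bias field
and additive Gaussian noise.

Two photometric presets emulate the two contrast regimes the pipeline
must cover: ``highfield`` (crisp 3T-MPRAGE-like contrast, low noise) and
``lowfield`` (1.5T-SPGR-like: class means compressed toward mid-gray and
doubled noise).

Everything is seeded explicitly; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import Atlas, LabelMap, Volume, LEVEL1_NAMES
from .registration import Diffeomorphism, apply_deformation, deform_label_priors
from .malf import map_estimate

__all__ = [
    "PhantomSpec",
    "make_base_phantom",
    "random_diffeomorphism",
    "make_phantom",
    "make_phantom_set",
    "make_atlas_set",
    "add_noise_and_bias",
]

#: level-2 structure catalogue: name, center offset (voxels, 64-grid),
#: ellipsoid semi-axes (voxels).  Paired left/right via the x offset sign.
_STRUCTURES = [
    ("caudate", (8.5, 7.5, 5.5), (2.6, 4.2, 2.6)),
    ("putamen", (13.0, 0.5, 0.0), (4.4, 6.4, 4.6)),
    ("globus pallidus", (7.0, -0.5, -5.5), (2.7, 3.5, 2.7)),
    ("thalamus", (5.0, -8.5, 2.5), (4.2, 6.0, 4.8)),
    ("hippocampus", (10.0, -9.5, -4.0), (2.5, 4.2, 2.5)),
    ("amygdala", (10.5, 9.5, -4.5), (2.8, 3.4, 2.8)),
]

#: tissue means, normalized [0,1] scale (T1-like ordering)
_HIGHFIELD_MEANS = {
    "background": 0.02,
    "CSF": 0.15,
    "LV": 0.15,
    "GM": 0.45,
    "WM": 0.75,
    "skull": 0.55,
}
_BLOB_MEANS = {
    "caudate": 0.52,
    "putamen": 0.56,
    "globus pallidus": 0.60,
    "thalamus": 0.54,
    "hippocampus": 0.50,
    "amygdala": 0.58,
}


@dataclass
class PhantomSpec:
    """Parameters of the phantom family (defaults: high-contrast preset)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    tissue_means: dict = field(default_factory=lambda: dict(_HIGHFIELD_MEANS))
    blob_means: dict = field(default_factory=lambda: dict(_BLOB_MEANS))
    noise_sigma: float = 0.02
    bias_degree: int = 2
    bias_amplitude: float = 0.05
    warp_amplitude: float = 2.0     # max displacement, voxels
    warp_smoothness: float = 6.0    # Gaussian sigma of the velocity fields
    roi_margin: int = 5
    seed: int = 0

    @classmethod
    def highfield(cls, **kw) -> "PhantomSpec":
        return cls(**kw)

    @classmethod
    def lowfield(cls, **kw) -> "PhantomSpec":
        """Compress class means toward mid-gray and double the noise."""
        means = {k: 0.5 + 0.6 * (v - 0.5) for k, v in _HIGHFIELD_MEANS.items()}
        blobs = {k: 0.5 + 0.6 * (v - 0.5) for k, v in _BLOB_MEANS.items()}
        return cls(tissue_means=means, blob_means=blobs, noise_sigma=0.04, **kw)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                        indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def make_base_phantom(spec: PhantomSpec | None = None) -> Atlas:
    """Build the noise-free base phantom with both label levels.

    The image is exactly piecewise-constant at the class means; every
    level-2 structure has at least 100 voxels at the default 64-cube.
    Overlapping structure geometry raises.
    """
    spec = spec or PhantomSpec()
    shape = tuple(spec.shape)
    s = min(shape) / 64.0  # geometric scale relative to the reference grid
    center = tuple((n - 1) / 2.0 for n in shape)

    def ell(offset, radii):
        c = tuple(center[i] + offset[i] * s for i in range(3))
        r = tuple(max(ri * s, 1.0) for ri in radii)
        return _ellipsoid(shape, c, r)

    outer = ell((0, 0, 0), (28, 25, 22))      # outside: background
    head = ell((0, 0, 0), (25, 22, 20))       # skull shell = outer - head
    brain = ell((0, 0, 0), (23, 20, 18))      # CSF rim = head - brain
    wm = ell((0, 0, 0), (20, 17, 15))         # GM shell = brain - wm

    lv = ell((-4.5, 2.0, 2.0), (2.0, 5.0, 2.6)) | ell((4.5, 2.0, 2.0),
                                                      (2.0, 5.0, 2.6))
    if (lv & ~wm).any():
        raise ValueError("ventricle geometry escapes the WM core")

    level2 = np.zeros(shape, dtype=np.int32)
    scheme2: dict[int, str] = {}
    occupied = lv.copy()
    lab = 0
    struct_masks = []
    for name, offset, radii in _STRUCTURES:
        for side, sign in (("left", -1), ("right", 1)):
            lab += 1
            off = (sign * offset[0], offset[1], offset[2])
            m = ell(off, radii)
            if (m & ~wm).any():
                raise ValueError(f"{side} {name} escapes the WM core")
            if (m & occupied).any():
                raise ValueError(f"{side} {name} overlaps another structure")
            if m.sum() < 100 * s ** 3:
                raise ValueError(f"{side} {name} smaller than 100 voxels")
            level2[m] = lab
            scheme2[lab] = f"{side} {name}"
            occupied |= m
            struct_masks.append(m)

    lv_label = lab + 1
    level2[lv] = lv_label
    scheme2[lv_label] = "LV"

    # level-1 global labels: blobs count as (deep) gray matter
    level1 = np.zeros(shape, dtype=np.int32)
    name_to_id1 = {v: k for k, v in LEVEL1_NAMES.items()}
    level1[~outer] = name_to_id1["background"]
    level1[outer & ~head] = name_to_id1["skull"]
    level1[head & ~brain] = name_to_id1["CSF"]
    level1[brain & ~wm] = name_to_id1["GM"]
    level1[wm] = name_to_id1["WM"]
    level1[level2 > 0] = name_to_id1["GM"]
    level1[lv] = name_to_id1["LV"]

    # cuboid ROI around the 12 structures; remaining brain voxels inside it
    # become local tissue labels
    from .structseg import cuboid_roi

    roi = cuboid_roi(struct_masks, margin=int(round(spec.roi_margin * s)),
                     shape=shape)
    roi_mask = np.zeros(shape, dtype=bool)
    roi_mask[roi] = True
    local_base = lv_label
    local_ids = {"local CSF": local_base + 1, "local GM": local_base + 2,
                 "local WM": local_base + 3}
    unassigned = roi_mask & (level2 == 0) & brain
    level2[unassigned & (brain & ~wm)] = local_ids["local GM"]
    level2[unassigned & wm & ~lv] = local_ids["local WM"]
    csf_in_roi = roi_mask & (level2 == 0) & (head & ~brain)
    level2[csf_in_roi] = local_ids["local CSF"]
    for name, i in local_ids.items():
        scheme2[i] = name

    # image: class means, blobs and LV override their global tissue
    means = spec.tissue_means
    image = np.empty(shape, dtype=np.float64)
    for lab1, name in LEVEL1_NAMES.items():
        image[level1 == lab1] = means[name]
    for lab2, name in scheme2.items():
        base = name.replace("left ", "").replace("right ", "")
        if base in spec.blob_means:
            image[level2 == lab2] = spec.blob_means[base]
    image[lv] = means["LV"]

    vol = Volume(image)
    return Atlas(
        image=vol,
        labels_level1=LabelMap(level1, LEVEL1_NAMES.copy()),
        labels_level2=LabelMap(level2, scheme2),
        id="base",
    )


def random_diffeomorphism(
    shape,
    amplitude: float,
    smoothness: float,
    seed: int,
    T: int = 8,
) -> Diffeomorphism:
    """Random smooth invertible warp: a Gaussian random velocity field,
    smoothed and scaled to a maximum displacement of ``amplitude`` voxels,
    integrated over ``T`` Euler steps.

    Raises if positivity of the Jacobian cannot be restored after 8
    amplitude halvings.
    """
    if amplitude < 0 or smoothness <= 0:
        raise ValueError("amplitude must be >= 0 and smoothness > 0")
    shape = tuple(shape)
    if amplitude == 0:
        return Diffeomorphism.identity(shape, T=T)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((3,) + shape)
    v = np.stack([gaussian_filter(v[c], smoothness) for c in range(3)])
    mag = np.sqrt((v ** 2).sum(axis=0)).max()
    v *= amplitude / max(mag, 1e-12)
    v = v.astype(np.float32)
    for _ in range(9):
        diffeo = Diffeomorphism(velocities=[v] * T, T=T)
        if diffeo.min_jacobian() > 0:
            return diffeo
        v = (0.5 * v).astype(np.float32)
    raise ValueError("amplitude too large: Jacobian not positive after 8 halvings")


def add_noise_and_bias(
    volume: Volume,
    noise_sigma: float,
    bias_degree: int,
    bias_amplitude: float,
    seed: int,
) -> Volume:
    """Apply a random polynomial gain (mean 1 over the foreground) and
    additive Gaussian noise."""
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    data = volume.data.astype(np.float64)
    out = data.copy()
    if bias_amplitude > 0 and bias_degree > 0:
        from .preprocessing import _poly_basis

        basis = _poly_basis(volume.shape, int(bias_degree))
        coeffs = rng.standard_normal(basis.shape[0])
        coeffs[0] = 0.0
        g = np.tensordot(coeffs, basis, axes=(0, 0))
        span = np.abs(g).max()
        if span > 0:
            g = g / span
        gain = np.exp(bias_amplitude * g)
        fg = data > 0.5 * data.mean()
        gain /= gain[fg].mean() if fg.any() else gain.mean()
        out = out * gain
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=volume.shape)
    return Volume(out, volume.spacing, volume.orientation)


def _warp_atlas(base: Atlas, diffeo: Diffeomorphism) -> Atlas:
    """Warp image (linear) and both label levels (one-hot argmax)."""
    image = apply_deformation(base.image, diffeo, interp="linear")
    out_labels = []
    for lm in (base.labels_level1, base.labels_level2):
        priors, ids = deform_label_priors(lm, diffeo)
        lab = map_estimate(priors, ids)
        out_labels.append(LabelMap(lab.astype(np.int32), lm.scheme,
                                   lm.spacing, lm.orientation))
    return Atlas(image=image, labels_level1=out_labels[0],
                 labels_level2=out_labels[1], id=base.id)


def make_phantom(
    spec: PhantomSpec | None = None,
    seed: int = 0,
    base: Atlas | None = None,
    id: str | None = None,
) -> Atlas:
    """One phantom subject: the base warped by a seeded random
    diffeomorphism, then degraded by a seeded bias field and noise."""
    spec = spec or PhantomSpec()
    base = base or make_base_phantom(spec)
    rng = np.random.default_rng(seed)
    s_warp = int(rng.integers(2 ** 31))
    s_noise = int(rng.integers(2 ** 31))
    idx = id if id is not None else f"phantom-{seed:02d}"
    if spec.warp_amplitude > 0:
        diffeo = random_diffeomorphism(spec.shape, spec.warp_amplitude,
                                       spec.warp_smoothness, s_warp)
        atlas = _warp_atlas(base, diffeo)
    else:
        atlas = Atlas(image=base.image.copy_with(),
                      labels_level1=base.labels_level1,
                      labels_level2=base.labels_level2, id=idx)
    image = add_noise_and_bias(atlas.image, spec.noise_sigma,
                               spec.bias_degree, spec.bias_amplitude,
                               s_noise)
    return Atlas(image=image, labels_level1=atlas.labels_level1,
                 labels_level2=atlas.labels_level2, id=idx)


def make_phantom_set(
    n: int,
    spec: PhantomSpec | None = None,
    first_seed: int = 0,
) -> list[Atlas]:
    """``n`` phantoms with consecutive seeds ``first_seed .. first_seed+n-1``,
    sharing one base geometry (built once)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    base = make_base_phantom(spec)
    return [make_phantom(spec, seed=first_seed + i, base=base)
            for i in range(n)]


def make_atlas_set(
    n: int,
    spec: PhantomSpec | None = None,
    seed: int | None = None,
) -> tuple[list[Atlas], Atlas]:
    """Generate ``n`` atlas phantoms plus one independently drawn subject.

    Each phantom is the base warped by its own random diffeomorphism with
    its own bias field and noise realization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    base = make_base_phantom(spec)

    def draw(idx: str) -> Atlas:
        return make_phantom(spec, seed=int(rng.integers(2 ** 31)),
                            base=base, id=idx)

    atlases = [draw(f"phantom-{i:02d}") for i in range(n)]
    subject = draw("subject")
    return atlases, subject
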