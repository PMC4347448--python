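"""Intensity inhomogeneity correction.

MR coils impose a smooth multiplicative gain ("bias field") on the image.
Before either fusion level we estimate this gain with an iterative
log-domain polynomial fit: foreground voxels are classified into a few
tissue classes, the class-mean log intensity is subtracted, and the
residual is regressed on a low-degree polynomial basis over normalized
coordinates.  Alternating classification and regression (3 iterations by
default) separates anatomy from the smooth gain.  The recovered field is
normalized to zero mean log-gain over the foreground, so correction
changes only the spatial shading, not the global brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core_io import LabelMap, Volume

__all__ = ["BiasField", "estimate_bias", "apply_bias_correction"]


@dataclass
class BiasField:
    """Smooth multiplicative gain field with its polynomial coefficients."""

    coefficients: np.ndarray
    field: Volume

    def __post_init__(self) -> None:
        if np.any(self.field.data <= 0):
            raise ValueError("bias field must be strictly positive")


def _poly_basis(shape, degree: int) -> np.ndarray:
    """Monomials of total degree <= degree over [-1,1]^3; (n_terms, *shape)."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    terms = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                terms.append((X ** i) * (Y ** j) * (Z ** k))
    return np.stack(terms)


def _classify_1d(values: np.ndarray, n_classes: int, n_iter: int = 10) -> np.ndarray:
    """Deterministic 1-D k-means (quantile init) returning class means."""
    centers = np.quantile(values, (np.arange(n_classes) + 0.5) / n_classes)
    for _ in range(n_iter):
        assign = np.argmin(np.abs(values[:, None] - centers), axis=1)
        for c in range(n_classes):
            sel = assign == c
            if sel.any():
                centers[c] = values[sel].mean()
        centers = np.sort(centers)
    assign = np.argmin(np.abs(values[:, None] - centers), axis=1)
    return centers[assign]


def estimate_bias(
    volume: Volume,
    mask: LabelMap | np.ndarray | None = None,
    degree: int = 3,
    n_iter: int = 3,
    n_classes: int = 3,
) -> BiasField:
    """Estimate a smooth multiplicative gain field.

    ``mask`` restricts the fit to foreground voxels; without one, an Otsu
    threshold separates foreground from background.  ``degree`` 0 yields a
    constant field of 1 (the normalization removes any global gain).
    """
    data = volume.data.astype(np.float64)
    if not np.any(data > 0):
        raise ValueError("volume has no positive intensities")
    if mask is None:
        fg = data > threshold_otsu(data)
    else:
        fg = (mask.data if isinstance(mask, LabelMap) else np.asarray(mask)) > 0
    if fg.sum() < 10:
        raise ValueError("foreground mask is (nearly) empty")
    basis = _poly_basis(volume.shape, int(degree))
    B = basis[:, fg].T  # (n_fg, n_terms)
    eps = 1e-6 * max(float(data[fg].mean()), 1e-12)
    logv = np.log(np.maximum(data[fg], eps))
    coeffs = np.zeros(B.shape[1])
    gain_fg = B @ coeffs
    for _ in range(max(int(n_iter), 1)):
        corrected = logv - gain_fg
        class_mean = _classify_1d(corrected, n_classes)
        residual = logv - class_mean  # anatomy removed; what's left is gain
        coeffs, *_ = np.linalg.lstsq(B, residual, rcond=None)
        gain_fg = B @ coeffs
    # zero-mean log gain over the foreground
    offset = gain_fg.mean()
    coeffs = coeffs.copy()
    coeffs[0] -= offset  # constant monomial is the first basis term
    full = np.tensordot(coeffs, basis, axes=(0, 0))
    fieldvol = Volume(np.exp(full), volume.spacing, volume.orientation)
    return BiasField(coefficients=coeffs, field=fieldvol)


def apply_bias_correction(volume: Volume, bias: BiasField) -> Volume:
    """Divide the image by the gain field, voxelwise."""
    if volume.shape != bias.field.shape:
        raise ValueError("volume and bias field grids differ")
    return Volume(volume.data / bias.field.data, volume.spacing, volume.orientation)
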