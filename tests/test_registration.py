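"""Diffeomorphic registration: flows, Jacobians, prior deformation."""

from __future__ import annotations

import numpy as np
import pytest

from malfseg.core_io import LabelMap, Volume
from malfseg.registration import (
    Diffeomorphism,
    apply_deformation,
    deform_label_priors,
    integrate,
    jacobian_determinant,
    register,
)


def _blob(n=48, center=None, sigma=8.0):
    c = (n - 1) / 2.0 if center is None else None
    ax = np.arange(n, dtype=np.float32)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    cx, cy, cz = center if center is not None else (c, c, c)
    return np.exp(-(((X - cx) / sigma) ** 2 + ((Y - cy) / sigma) ** 2
                    + ((Z - cz) / sigma) ** 2)).astype(np.float32)


def test_identity_diffeomorphism():
    d = Diffeomorphism.identity((8, 8, 8), T=4)
    assert np.abs(d.forward).max() == 0.0
    assert np.abs(d.inverse).max() == 0.0
    assert d.min_jacobian() == pytest.approx(1.0)
    assert d.composition_residual() == pytest.approx(0.0)


def test_integrate_constant_velocity_translation():
    """A constant velocity v integrated over T steps displaces by ~T*v/T
    per convention: total displacement equals the summed step fields."""
    shape = (16, 16, 16)
    v = np.zeros((3,) + shape, dtype=np.float32)
    v[0] = 1.0  # one voxel per unit time along x
    fwd, inv = integrate([v] * 4, T=4)
    interior = (slice(4, 12),) * 3
    assert fwd[0][interior] == pytest.approx(1.0, abs=1e-3)
    assert inv[0][interior] == pytest.approx(-1.0, abs=1e-2)


def test_jacobian_determinant_identity_and_scaling():
    shape = (12, 12, 12)
    ident = Diffeomorphism.identity(shape, T=1)
    assert jacobian_determinant(ident).data == pytest.approx(1.0)
    # uniform linear compression along x: u_x = -0.25 x => dphi/dx = 0.75
    grid = np.arange(12, dtype=np.float32)
    u = np.zeros((3,) + shape, dtype=np.float32)
    u[0] = -0.25 * grid[:, None, None]
    d = Diffeomorphism(velocities=[u], T=1, forward=u, inverse=-u)
    det = jacobian_determinant(d).data
    interior = (slice(2, 10),) * 3
    assert det[interior] == pytest.approx(0.75, abs=1e-6)


def test_registration_identity_returns_zero_warp():
    img = Volume(_blob())
    d = register(img, img, T=2, iters=10)
    assert np.abs(d.forward).max() == 0.0
    assert d.min_jacobian() == pytest.approx(1.0)


def test_registration_recovers_translation():
    """Atlas = subject translated by 2 voxels along x: the recovered mean
    displacement in the blob interior is within 0.5 voxel of (2, 0, 0)."""
    moving = Volume(_blob(center=(24.0, 24.0, 24.0)))
    fixed = Volume(_blob(center=(26.0, 24.0, 24.0)))
    d = register(moving, fixed, T=2, iters=40, sigma_fluid=4.0,
                 sigma_diffusion=2.0)
    interior = moving.data > 0.5
    assert abs(d.forward[0][interior].mean() - 2.0) <= 0.5
    assert abs(d.forward[1][interior].mean()) <= 0.5
    assert abs(d.forward[2][interior].mean()) <= 0.5
    assert d.min_jacobian() > 0


def test_registration_energy_monotone():
    moving = Volume(_blob(center=(24.0, 24.0, 24.0)))
    fixed = Volume(_blob(center=(26.0, 25.0, 24.0)))
    d = register(moving, fixed, T=2, iters=15)
    tr = d.energy_trace
    assert len(tr) > 2
    for prev, nxt in zip(tr, tr[1:]):
        assert nxt <= prev + 1e-12


def test_apply_deformation_translation_oracle():
    """Warping by a known uniform translation shifts the image content."""
    data = np.zeros((16, 16, 16), dtype=np.float32)
    data[8, 8, 8] = 1.0
    shape = data.shape
    v = np.zeros((3,) + shape, dtype=np.float32)
    v[0] = 2.0
    fwd, inv = integrate([v], T=1)
    d = Diffeomorphism(velocities=[v], T=1, forward=fwd, inverse=inv)
    out = apply_deformation(Volume(data), d, interp="linear")
    assert out.data[10, 8, 8] == pytest.approx(1.0, abs=0.05)
    assert out.data[8, 8, 8] == pytest.approx(0.0, abs=0.05)


def test_deform_label_priors_partition_of_unity():
    rng = np.random.default_rng(0)
    lab = rng.integers(0, 4, size=(12, 12, 12)).astype(np.int32)
    lm = LabelMap(lab, scheme={1: "a", 2: "b", 3: "c"})
    v = rng.standard_normal((3, 12, 12, 12)).astype(np.float32)
    from scipy.ndimage import gaussian_filter

    v = np.stack([gaussian_filter(v[c], 3.0) for c in range(3)])
    v *= 1.5 / max(np.sqrt((v ** 2).sum(0)).max(), 1e-9)
    d = Diffeomorphism(velocities=[v] * 2, T=2)
    priors, ids = deform_label_priors(lm, d)
    assert ids == [0, 1, 2, 3]
    sums = priors.sum(axis=0)
    assert np.abs(sums - 1.0).max() <= 1e-5
    assert priors.min() >= 0.0


def test_deform_label_priors_identity_one_hot():
    lab = np.zeros((8, 8, 8), dtype=np.int32)
    lab[2:5, 2:5, 2:5] = 2
    lm = LabelMap(lab, scheme={2: "s"})
    d = Diffeomorphism.identity((8, 8, 8), T=1)
    priors, ids = deform_label_priors(lm, d)
    assert ids == [0, 2]
    assert (priors[1] == (lab == 2)).all()


def test_register_grid_mismatch_raises():
    with pytest.raises(ValueError):
        register(Volume(np.zeros((8, 8, 8))), Volume(np.zeros((10, 10, 10))),
                 T=2)
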