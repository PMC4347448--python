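"""Time-discretized diffeomorphic registration.

The hidden deformation connecting each atlas to the subject is modeled as
the flow of ``T`` per-timestep velocity fields: the map is the composition
of ``T`` Euler steps ``x -> x + v_t(x)/T``.  ``T`` is the first-class
discretization control of the framework: a small ``T`` (2) approximates
small deformations cheaply for the down-sampled skull-stripping level,
while the default ``T`` (10) allows larger, more accurate deformations at
full resolution.

The solver is a greedy fluid-style optimizer: timesteps are optimized in
sequence, each by normalized gradient ("demons"-type) iterations with a
fluid smoothing of the force (``sigma_fluid``) and a diffusion smoothing
of the accumulated step field (``sigma_diffusion``).  Steps are accepted
only if they decrease the energy (SSD plus a velocity-magnitude penalty
weighted by ``sigma_ratio``), so the energy trace is non-increasing.  The
diffeomorphic contract is enforced per timestep: every step map must keep
a strictly positive Jacobian determinant (halving the step up to 8 times
if needed), which guarantees positivity of the composed map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .core_io import Volume, LabelMap

__all__ = [
    "Diffeomorphism",
    "register",
    "integrate",
    "apply_deformation",
    "deform_label_priors",
    "jacobian_determinant",
]


def _identity_grid(shape) -> np.ndarray:
    """(3, *shape) array of voxel coordinates."""
    axes = [np.arange(n, dtype=np.float32) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij")).astype(np.float32)


def _sample(data: np.ndarray, coords: np.ndarray, order: int = 1,
            mode: str = "constant") -> np.ndarray:
    return map_coordinates(data, coords, order=order, mode=mode, cval=0.0,
                           prefilter=False)


def _sample_field(fieldarr: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample a (3, *shape) displacement field at given coordinates,
    extending by the border value so displacements do not snap to zero
    at the edge of the grid."""
    return np.stack([_sample(fieldarr[c], coords, order=1, mode="nearest")
                     for c in range(3)])


def _compose(outer: np.ndarray, inner: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Displacement of ``f o g`` where f(x)=x+outer(x), g(x)=x+inner(x)."""
    return inner + _sample_field(outer, grid + inner)


def _det3(J: np.ndarray) -> np.ndarray:
    """Determinant of a (3,3,...) Jacobian stack."""
    a, b, c = J[0]
    d, e, f = J[1]
    g, h, i = J[2]
    return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)


def _displacement_jacobian_det(disp: np.ndarray) -> np.ndarray:
    """det(I + grad u) by central differences, for u a (3,*shape) field."""
    J = np.empty((3, 3) + disp.shape[1:], dtype=np.float64)
    for i in range(3):
        grads = np.gradient(disp[i].astype(np.float64), axis=(0, 1, 2))
        for j in range(3):
            J[i, j] = grads[j]
        J[i, i] += 1.0
    return _det3(J)


@dataclass
class Diffeomorphism:
    """Invertible smooth coordinate map stored as T velocity fields.

    ``forward`` and ``inverse`` are cached displacement fields (voxel
    units) for the composed map and its inverse.
    """

    velocities: list[np.ndarray]
    T: int
    forward: np.ndarray | None = None
    inverse: np.ndarray | None = None
    smoothing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if len(self.velocities) != self.T:
            raise ValueError(f"expected {self.T} velocity fields, got {len(self.velocities)}")
        if self.forward is None or self.inverse is None:
            self.forward, self.inverse = integrate(self.velocities, self.T)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.forward.shape[1:]

    @classmethod
    def identity(cls, shape, T: int = 1) -> "Diffeomorphism":
        zero = [np.zeros((3,) + tuple(shape), dtype=np.float32) for _ in range(T)]
        return cls(velocities=zero, T=T)

    def min_jacobian(self) -> float:
        return float(_displacement_jacobian_det(self.forward).min())

    def composition_residual(self) -> float:
        """Mean |phi(phi^-1(x)) - x| over the interior (2-voxel margin)."""
        grid = _identity_grid(self.shape)
        resid = _compose(self.forward, self.inverse, grid)
        mag = np.sqrt((resid ** 2).sum(axis=0))
        interior = tuple(slice(2, -2) for _ in range(3))
        return float(mag[interior].mean())


def integrate(velocities: list[np.ndarray], T: int) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate T velocity fields into forward/inverse displacements.

    The forward map is ``psi_{T-1} o ... o psi_0`` with
    ``psi_t(x) = x + v_t(x)/T``; the inverse composes the first-order step
    inverses in reverse order and is then refined by 5 fixed-point
    iterations.  A constant velocity field v therefore yields a total
    displacement of v (pure translation).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if len(velocities) != T:
        raise ValueError(f"expected {T} velocity fields, got {len(velocities)}")
    shape = velocities[0].shape[1:]
    grid = _identity_grid(shape)
    fwd = np.zeros((3,) + shape, dtype=np.float32)
    for v in velocities:
        # phi <- psi_t o phi : u(x) <- u(x) + (v/T)(x + u(x))
        fwd = fwd + _sample_field(v / T, grid + fwd)
    inv = np.zeros((3,) + shape, dtype=np.float32)
    for v in velocities:
        # phi^-1 = psi_0^-1 o ... o psi_{T-1}^-1, built inside-out
        step = -v / T
        inv = step + _sample_field(inv, grid + step)
    for _ in range(5):  # fixed-point refinement of the inverse
        inv = -_sample_field(fwd, grid + inv)
    return fwd.astype(np.float32), inv.astype(np.float32)


def jacobian_determinant(diffeo: Diffeomorphism) -> Volume:
    """Central-difference Jacobian determinant of the forward map."""
    return Volume(data=_displacement_jacobian_det(diffeo.forward))


def apply_deformation(volume: Volume | LabelMap, diffeo: Diffeomorphism,
                      interp: str = "linear"):
    """Warp a volume: output(x) = input(phi^-1(x)); out-of-field voxels 0."""
    if volume.shape != diffeo.shape:
        raise ValueError(f"grid mismatch: {volume.shape} vs {diffeo.shape}")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if isinstance(volume, LabelMap) and interp == "linear":
        raise ValueError("label maps must be warped with nearest interpolation")
    grid = _identity_grid(volume.shape)
    coords = grid + diffeo.inverse
    order = 0 if interp == "nearest" else 1
    out = _sample(volume.data.astype(np.float64), coords, order=order, mode="constant")
    if isinstance(volume, LabelMap):
        return LabelMap(np.round(out).astype(np.int32), volume.scheme,
                        volume.spacing, volume.orientation)
    return Volume(out, volume.spacing, volume.orientation)


def deform_label_priors(labels: LabelMap, diffeo: Diffeomorphism,
                        label_ids: list[int] | None = None) -> tuple[np.ndarray, list[int]]:
    """Warp one-hot label channels with linear interpolation.

    Returns ``(priors, label_ids)`` where ``priors`` has shape
    ``(L, *grid)``; channels sum to 1 everywhere (linear interpolation
    preserves the partition of unity; pre-images outside the field of
    view extend the border label).  When ``label_ids`` is None all labels
    present in the scheme plus (if present in the data) label 0 are used.
    """
    if labels.shape != diffeo.shape:
        raise ValueError(f"grid mismatch: {labels.shape} vs {diffeo.shape}")
    if label_ids is None:
        label_ids = sorted(labels.scheme)
        if 0 in labels.data:
            label_ids = [0] + label_ids
    grid = _identity_grid(labels.shape)
    coords = grid + diffeo.inverse
    priors = np.empty((len(label_ids),) + labels.shape, dtype=np.float32)
    for i, lab in enumerate(label_ids):
        onehot = (labels.data == lab).astype(np.float32)
        priors[i] = _sample(onehot, coords, order=1, mode="nearest")
    np.clip(priors, 0.0, 1.0, out=priors)
    return priors, list(label_ids)


# ---------------------------------------------------------------------------
# Greedy per-timestep solver
# ---------------------------------------------------------------------------


def _smooth_field(fieldarr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return fieldarr
    return np.stack([gaussian_filter(fieldarr[c], sigma) for c in range(3)])


def _optimize_timesteps(
    atlas: np.ndarray,
    subject: np.ndarray,
    steps: list[np.ndarray],
    iters: int,
    sigma_fluid: float,
    sigma_diffusion: float,
    sigma_ratio: float,
    step_size: float,
    energy_trace: list[float],
) -> list[np.ndarray]:
    """Optimize the per-timestep step fields w_t (the warp is the
    composition of x + w_t applied to the atlas).  ``steps`` are warm
    starts and are modified in place."""
    shape = atlas.shape
    grid = _identity_grid(shape)
    T = len(steps)
    lam = 1e-2 * sigma_ratio  # weight of the field-smoothness penalty
    eps = 1e-12

    def roughness(field_arr: np.ndarray) -> float:
        r = 0.0
        for c in range(3):
            for g in np.gradient(field_arr[c], axis=(0, 1, 2)):
                r += float((g ** 2).mean())
        return r

    def energy_of(w_arr, warped_arr):
        return (float(((warped_arr - subject) ** 2).mean())
                + lam * roughness(w_arr))

    u_prev = np.zeros((3,) + shape, dtype=np.float32)  # composed warp so far
    for t in range(T):
        w = steps[t]
        moving = _sample(atlas, grid + u_prev, order=1).astype(np.float32)
        warped = _sample(moving, grid + w, order=1).astype(np.float32)
        energy = energy_of(w, warped)
        energy_trace.append(energy)
        step = step_size
        for _ in range(iters):
            diff = warped - subject
            grads = np.stack(np.gradient(warped, axis=(0, 1, 2))).astype(np.float32)
            denom = (grads ** 2).sum(axis=0) + diff ** 2 + eps
            force = -(diff / denom) * grads
            force = _smooth_field(force, sigma_fluid)
            # cap the per-iteration increment at 1 voxel
            mag = np.sqrt((force ** 2).sum(axis=0)).max()
            if mag > 0:
                force *= min(1.0, 1.0 / mag)
            accepted = False
            s = step
            for _ in range(6):
                # gradient step then diffusion smoothing of the total field;
                # the smoothness term lets regularization trade off SSD
                cand = _smooth_field(w + s * force, sigma_diffusion).astype(np.float32)
                cand_warp = _sample(moving, grid + cand, order=1).astype(np.float32)
                cand_energy = energy_of(cand, cand_warp)
                if cand_energy < energy - 1e-12:
                    w, warped, energy = cand, cand_warp, cand_energy
                    accepted = True
                    break
                s *= 0.5
            energy_trace.append(energy)
            if not accepted:
                break
        # enforce a positive Jacobian for this step map (halve up to 8x);
        # positivity of every step implies positivity of the composition
        for _ in range(8):
            if _displacement_jacobian_det(w).min() > 0.05:
                break
            w = (0.5 * w).astype(np.float32)
        else:
            w = np.zeros_like(w)
        steps[t] = w
        # C_t = C_{t-1} o (id + w_t): the next stage warps the atlas through
        # all accepted steps so far
        u_prev = _compose(u_prev, w, grid)
    return steps


def _downsample2(arr: np.ndarray) -> np.ndarray:
    from .core_io import _block_reduce_mean

    return _block_reduce_mean(arr, 2).astype(np.float32)


def _upsample_steps(steps: list[np.ndarray], target_shape) -> list[np.ndarray]:
    out = []
    for w in steps:
        factors = [t / s for t, s in zip(target_shape, w.shape[1:])]
        up = np.stack([zoom(w[c], factors, order=1, grid_mode=True, mode="nearest")
                       for c in range(3)])
        for c in range(3):
            up[c] *= factors[c]
        out.append(up.astype(np.float32))
    return out


def register(
    atlas_image: Volume,
    subject_image: Volume,
    T: int = 10,
    sigma_fluid: float = 2.0,
    sigma_diffusion: float = 1.0,
    iters: int = 12,
    sigma_ratio: float = 1.0,
    pyramid_levels: int = 1,
    coarse_iters: int = 30,
    step_size: float = 1.0,
    init: Diffeomorphism | None = None,
) -> Diffeomorphism:
    """Estimate the diffeomorphism carrying the atlas onto the subject.

    Images must share a grid and be intensity-normalized.  With
    ``pyramid_levels`` > 1 the velocities are first estimated on
    block-mean down-sampled images and then refined at full resolution.
    The returned map satisfies SSD(atlas o phi^-1, subject) <=
    SSD(atlas, subject) and the diffeomorphic invariants.
    """
    if atlas_image.shape != subject_image.shape:
        raise ValueError("atlas and subject grids differ")
    if T < 1:
        raise ValueError("T must be a positive integer")
    A = atlas_image.data.astype(np.float32)
    S = subject_image.data.astype(np.float32)
    shapes = [A.shape]
    pyramids = [(A, S)]
    for _ in range(pyramid_levels - 1):
        A2, S2 = _downsample2(pyramids[-1][0]), _downsample2(pyramids[-1][1])
        pyramids.append((A2, S2))
        shapes.append(A2.shape)
    energy_trace: list[float] = []
    steps: list[np.ndarray] | None = None
    if init is not None:
        if init.T != T:
            raise ValueError("init diffeomorphism has a different T")
        steps = [(-v / T).astype(np.float32) for v in init.velocities]
    for level in range(len(pyramids) - 1, -1, -1):
        Al, Sl = pyramids[level]
        if steps is None:
            steps = [np.zeros((3,) + Al.shape, dtype=np.float32) for _ in range(T)]
        elif steps[0].shape[1:] != Al.shape:
            steps = _upsample_steps(steps, Al.shape)
        scale = 2 ** level
        n_iters = coarse_iters if level > 0 else iters
        steps = _optimize_timesteps(
            Al, Sl, steps, n_iters,
            sigma_fluid / scale if level > 0 else sigma_fluid,
            sigma_diffusion / scale if level > 0 else sigma_diffusion,
            sigma_ratio, step_size, energy_trace,
        )
    velocities = [(-T * w).astype(np.float32) for w in steps]
    diffeo = Diffeomorphism(
        velocities=velocities, T=T,
        smoothing={"sigma_fluid": sigma_fluid, "sigma_diffusion": sigma_diffusion,
                   "sigma_ratio": sigma_ratio},
    )
    diffeo.energy_trace = energy_trace  # diagnostic attribute
    return diffeo
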