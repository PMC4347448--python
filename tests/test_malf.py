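"""Fusion algebra: intensity models, joints, fusion, EM behavior."""

from __future__ import annotations

import numpy as np
import pytest

from malfseg.malf import (
    CONTAMINATION,
    LabelGMM,
    MALFConfig,
    atlas_joint_likelihood,
    fit_intensity_model,
    fuse,
    map_estimate,
    run_malf,
)


def test_label_gmm_validation():
    with pytest.raises(ValueError):
        LabelGMM(weights=[0.5, 0.4], means=[0, 1], variances=[1, 1])
    with pytest.raises(ValueError):
        LabelGMM(weights=[1.0], means=[0], variances=[0.0])


def test_label_gmm_pdf_matches_formula():
    g = LabelGMM(weights=[0.3, 0.7], means=[0.2, 0.8], variances=[0.01, 0.04])
    x = np.array([0.2, 0.5, 0.8])
    want = np.zeros(3)
    for w, m, v in zip(g.weights, g.means, g.variances):
        want += w * np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2 * np.pi * v)
    want = (1 - CONTAMINATION) * want + CONTAMINATION
    assert g.pdf(x) == pytest.approx(want, rel=1e-12)


def test_fit_intensity_model_recovers_two_classes(rng):
    n = 4000
    vals = np.concatenate([rng.normal(0.3, 0.02, n), rng.normal(0.7, 0.02, n)])
    rng.shuffle(vals)
    subject = vals.reshape(20, 20, 20)
    pri = np.ones((1, 20, 20, 20), dtype=np.float32)
    model = fit_intensity_model(subject, pri, [1], components_per_label=2)
    mu = np.sort(model.models[1].means)
    assert mu[0] == pytest.approx(0.3, abs=0.02)
    assert mu[1] == pytest.approx(0.7, abs=0.02)


def test_fit_intensity_model_low_mass_fallback():
    subject = np.full((4, 4, 4), 0.5)
    pri = np.zeros((1, 4, 4, 4), dtype=np.float32)  # no support
    model = fit_intensity_model(subject, pri, [1])
    assert 1 in model.flagged
    assert model.models[1].variances[0] == pytest.approx(1.0 / 12.0)


def test_fit_intensity_model_concentrated_mass_separates_components(rng):
    """Most of the label's mass on one value must not collapse the GMM:
    the minority class keeps its own component."""
    vals = np.full(8000, 0.1)
    vals[:400] = rng.normal(0.9, 0.01, 400)
    rng.shuffle(vals)
    subject = vals.reshape(20, 20, 20)
    pri = np.ones((1, 20, 20, 20), dtype=np.float32)
    model = fit_intensity_model(subject, pri, [1], components_per_label=3)
    # density at the minority mode must be far above contamination level
    assert model.models[1].pdf(np.array([0.9]))[0] > 1.0


def test_atlas_joint_likelihood_scalar_oracle():
    g = LabelGMM(weights=[1.0], means=[0.5], variances=[0.01])
    model_pdf = g.pdf(np.array([0.4]))[0]
    from malfseg.malf import IntensityModel

    model = IntensityModel(models={0: g, 7: g})
    subject = np.full((2, 2, 2), 0.4)
    priors = np.stack([np.full((2, 2, 2), 0.25, dtype=np.float32),
                       np.full((2, 2, 2), 0.75, dtype=np.float32)])
    joint = atlas_joint_likelihood(subject, priors, model, [0, 7])
    assert joint[0] == pytest.approx(model_pdf * 0.25, rel=1e-12)
    assert joint[1] == pytest.approx(model_pdf * 0.75, rel=1e-12)
    # prior floor kicks in at zero prior
    priors0 = np.stack([np.zeros((2, 2, 2), dtype=np.float32),
                        np.ones((2, 2, 2), dtype=np.float32)])
    joint = atlas_joint_likelihood(subject, priors0, model, [0, 7],
                                   prior_floor=1e-4)
    # float32 priors: the floor constant rounds at ~1e-8 relative error
    assert joint[0] == pytest.approx(model_pdf * 1e-4, rel=1e-6)


def test_fuse_zero_mass_fallback():
    joints = [np.zeros((2, 3, 3, 3))]
    fused, n_zero = fuse(joints, np.array([1.0]))
    assert n_zero == 27
    assert fused.sum(axis=0) == pytest.approx(1.0)
    assert fused[0] == pytest.approx(0.5)


def test_fuse_atlas_prior_validation():
    joints = [np.ones((2, 2, 2, 2))] * 2
    with pytest.raises(ValueError):
        fuse(joints, np.array([0.9, 0.2]))


def test_map_estimate_tie_breaks_to_smallest_label():
    fused = np.full((3, 2, 2, 2), 1 / 3)
    lab = map_estimate(fused, [4, 2, 9])
    assert (lab == 2).all()


def test_run_malf_atlas_permutation_invariant(rng):
    subject = rng.random((10, 10, 10))
    stacks = []
    for _ in range(3):
        p = rng.random((3, 10, 10, 10)).astype(np.float32)
        p /= p.sum(axis=0)
        stacks.append(p)
    lab1, st1 = run_malf(subject, stacks, [0, 1, 2])
    lab2, st2 = run_malf(subject, stacks[::-1], [0, 1, 2])
    assert (lab1 == lab2).all()
    assert st1.objective_trace == pytest.approx(st2.objective_trace)


def test_run_malf_duplicate_atlas_invariant(rng):
    """Duplicating every atlas (halving the atlas prior) leaves the fused
    posterior unchanged."""
    subject = rng.random((8, 8, 8))
    p = rng.random((2, 8, 8, 8)).astype(np.float32)
    p /= p.sum(axis=0)
    # single E-step: exact invariance
    cfg = MALFConfig(max_iters=1)
    _, st1 = run_malf(subject, [p], [0, 1], config=cfg)
    _, st2 = run_malf(subject, [p, p], [0, 1], config=cfg)
    assert np.abs(st1.fused - st2.fused).max() <= 1e-12
    # full EM: the MAP labeling agrees
    lab1, _ = run_malf(subject, [p], [0, 1])
    lab2, _ = run_malf(subject, [p, p], [0, 1])
    assert (lab1 == lab2).all()


def test_run_malf_unsorted_labels_raise(rng):
    subject = rng.random((4, 4, 4))
    p = rng.random((2, 4, 4, 4)).astype(np.float32)
    with pytest.raises(ValueError):
        run_malf(subject, [p], [2, 1])


def test_run_malf_objective_monotone_on_random_instances():
    for seed in range(5):
        r = np.random.default_rng(seed)
        subject = r.random((12, 12, 12))
        stacks = []
        for _ in range(2):
            p = r.random((4, 12, 12, 12)).astype(np.float32)
            p /= p.sum(axis=0)
            stacks.append(p)
        _, st = run_malf(subject, stacks, [0, 1, 2, 3],
                         config=MALFConfig(max_iters=6, change_tol=0.0))
        tr = st.objective_trace
        for a, b in zip(tr, tr[1:]):
            assert b >= a - 1e-8
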