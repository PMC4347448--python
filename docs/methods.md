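# Methods

This note documents what each stage of the pipeline computes and the
concrete algorithmic choices made where the general method leaves room.

## Model

Given a subject image $I$ and atlases $(I_a, L_a)$, the segmentation is
the MAP estimate of the label field $W$ under a likelihood that is fused
over atlases:

$$ p(I, W) \;=\; \sum_a \pi_a \, p(I, W \mid a), \qquad
   p(I, W \mid a) \;=\; \prod_x p\bigl(I(x) \mid W(x)\bigr)\,
   p_a\bigl(W(x)\bigr), $$

where $p_a(W(x))$ is atlas $a$'s label prior deformed into subject
space and $p(I(x) \mid k)$ is a per-label Gaussian mixture over subject
intensities. The atlas prior $\pi_a$ is uniform. Per voxel, the fused
posterior is the $\pi_a$-weighted sum of the per-atlas joints,
normalized over labels; the labeling is its arg-max (ties broken to the
smallest label index).

## Registration

Atlas images are warped to the subject by a greedy diffeomorphic
registration: the total map is a composition of $T$ small displacement
fields, each kept diffeomorphic by capping the per-step displacement at
one voxel and rejecting steps whose Jacobian determinant would become
non-positive. The per-step update is a demons-style force, smoothed
before (fluid) and after (diffusion) composition; a step is accepted
only if it decreases an elastic energy (mean squared intensity residual
plus a small field-roughness penalty, weight $10^{-2}$, which leaves
uniform translations unpenalized). Level 1 uses $T = 2$, level 2 uses
$T = 10$ with a two-level coarse-to-fine pyramid. Label priors are
deformed by warping the one-hot channels with trilinear interpolation
and border extension, which preserves the per-voxel partition of unity.

## EM fusion

The intensity mixtures and the fused posterior are estimated jointly by
EM on the per-voxel marginal log-likelihood
$\sum_x \log \sum_{a,k} \pi_a\, p(I(x)\mid k)\, p_a(k \mid x)$.
The E-step computes responsibilities over (atlas, label); the M-step
refits each label's Gaussian mixture from its responsibility-weighted
intensities and is accepted only if the objective does not decrease
(generalized EM), which makes the objective provably non-decreasing.
Numerical guards: a prior floor of $10^{-4}$ before normalization, a
$10^{-3}$ uniform contamination component in every mixture, a variance
floor of $10^{-6}$, a broad fallback density for labels with
effectively no support, and a deterministic farthest-point re-spread of
quantile-initialized component means when they collapse.

## Level 1: skull stripping

The head volume is intensity-normalized and down-sampled by 2; all
atlases are registered at the down-sampled grid and fused over the six
global labels. The brain mask is the union posterior of LV/GM/WM/CSF,
up-sampled to full resolution with block-center alignment, thresholded
at 0.5, and post-processed: keep the largest 26-connected component,
fill internal cavities, and smooth the boundary with a closing+opening
by a small ball. Per-slice Dice against a reference mask is available
for slice-wise inspection.

## Level 2: structure segmentation

Runs at full resolution on skull-stripped images, restricted to a
cuboid region spanning the subject and atlas foregrounds (3-voxel
margin). The atlas-side level-2 scheme contains the structures (LV plus
paired subcortical nuclei) and local GM/WM/CSF filler labels that
complete a cuboid ROI around the structures; the filler keeps the
likelihood model honest at structure borders. Voxels outside the
deformed atlas ROI remain unlabeled (0). Atlas construction
(`build-atlas`) derives the filler labels with a 3-class 1-D Gaussian
mixture followed by a 3-cube spatial mode filter, and splits non-brain
voxels into skull/background by Otsu thresholding.

## Preprocessing

The smooth multiplicative bias field is modeled as the exponential of a
low-degree 3-D polynomial in normalized coordinates, fitted by
alternating a 3-class intensity classification with a weighted
least-squares fit of the log-gain over the Otsu foreground; the
log-gain is centered to mean zero so correction preserves overall
brightness.

## Phantoms

The generator builds a deterministic base head (ellipsoidal skull shell,
CSF rim, GM/WM compartments, LV horns, six paired subcortical blobs
with deliberately ambiguous GM-to-WM contrast) and derives each subject
by a seeded random smooth diffeomorphism plus Gaussian noise and a
polynomial bias field. Two photometric presets ship: `highfield`
(high contrast, low noise) and `lowfield` (means compressed toward 0.5,
doubled noise). All randomness is seed-explicit.

## Evaluation

Dice similarity $2|A \cap B| / (|A| + |B|)$, per label and per mask
(empty-vs-empty defined as 1). The leave-one-out harness holds each
atlas out in turn, strips and segments it with the rest (the held-out
labels are used only as the evaluation reference), and reports long- and
summary-format tables.
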