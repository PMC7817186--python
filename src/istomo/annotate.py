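"""Classical watershed annotation of cell conjugates and STAPLE consensus.

Training labels for the distance-regression network come from a
four-hyper-parameter pipeline: (i) seed locations for each cell,
(ii) an RI threshold defining the cell boundary, (iii) a morphological
size merging over-segmented grains, and (iv) the standard deviation of
the Gaussian smoothing kernel.  A marker-based watershed on the seed
distance transform then splits the foreground into the two cells.

Multiple annotations of the same volume (different parameter choices or
raters) are merged by STAPLE — an expectation-maximization estimate of
the latent true segmentation together with each rater's sensitivity p
and specificity q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.segmentation import watershed

from .io import CellMaskPair, ShapeError, Tomogram, ValidationError


class EmptySegmentationError(ValueError):
    """Thresholding left no foreground to segment."""


class SeedError(ValueError):
    """A seed point does not lie in the segmentable foreground."""


@dataclass
class AnnotationParams:
    """The four manual hyper-parameters of the annotation pipeline."""

    seeds_effector: Sequence[tuple[int, int, int]]
    seeds_target: Sequence[tuple[int, int, int]]
    ri_threshold: float = 1.345
    dilation_size: int = 1
    gaussian_sigma: float = 1.0

    def __post_init__(self) -> None:
        if len(self.seeds_effector) == 0 or len(self.seeds_target) == 0:
            raise ValidationError("each cell needs at least one seed")
        if self.dilation_size < 0 or self.gaussian_sigma < 0:
            raise ValidationError("dilation size and sigma must be >= 0")

    def validate_against(self, tom: Tomogram) -> None:
        if self.ri_threshold <= tom.medium_ri:
            raise ValidationError(
                f"RI threshold {self.ri_threshold} must exceed the medium "
                f"RI {tom.medium_ri}")
        for z, y, x in [*self.seeds_effector, *self.seeds_target]:
            if not (0 <= z < tom.shape[0] and 0 <= y < tom.shape[1]
                    and 0 <= x < tom.shape[2]):
                raise ValidationError(f"seed {(z, y, x)} outside grid {tom.shape}")


def annotate_cells(tom: Tomogram, params: AnnotationParams) -> CellMaskPair:
    """Watershed annotation: smooth, threshold, merge grains, split by seeds.

    Steps: Gaussian smoothing (sigma), foreground = smoothed RI above the
    threshold, binary closing with a Euclidean ball of the dilation size
    (merges over-segmented grains without inflating the cell volume), then
    a marker-based watershed on the distance-to-nearest-seed map restricted
    to the foreground.  Labels are keyed to effector/target by seed
    identity, so the output is invariant to seed-list order up to the
    mask naming.
    """
    params.validate_against(tom)
    vol = tom.values.astype(np.float64)
    if params.gaussian_sigma > 0:
        vol = ndimage.gaussian_filter(vol, params.gaussian_sigma)
    fg = vol > params.ri_threshold
    if params.dilation_size > 0:
        fg = ndimage.binary_closing(fg, structure=ball(params.dilation_size))
    if not fg.any():
        raise EmptySegmentationError(
            f"threshold {params.ri_threshold} leaves no foreground")

    markers = np.zeros(tom.shape, dtype=np.int32)
    for label, seeds in ((1, params.seeds_effector), (2, params.seeds_target)):
        for z, y, x in seeds:
            if not fg[z, y, x]:
                raise SeedError(f"seed {(z, y, x)} lies outside the foreground")
            markers[z, y, x] = label

    # flood from the seeds outward: elevation = Euclidean distance to the
    # nearest seed (deterministic raster-order tie-break inside watershed)
    seed_dist = ndimage.distance_transform_edt(markers == 0)
    labels = watershed(seed_dist, markers=markers, mask=fg)
    return CellMaskPair(effector=labels == 1, target=labels == 2, pitch=tom.pitch)


# ---------------------------------------------------------------------
# STAPLE consensus
# ---------------------------------------------------------------------


@dataclass
class StapleResult:
    """EM consensus over binary annotations.

    ``probability`` is the posterior foreground probability per voxel;
    ``sensitivity``/``specificity`` are the per-rater performance levels;
    ``log_likelihood`` records the (monotonically non-decreasing) EM
    objective per iteration.
    """

    probability: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    iterations: int
    log_likelihood: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValidationError("consensus probabilities must lie in [0, 1]")
        for v in (self.sensitivity, self.specificity):
            if np.any((v < 0) | (v > 1)):
                raise ValidationError("p and q must lie in [0, 1]")

    @property
    def consensus(self) -> np.ndarray:
        return self.probability >= 0.5


def staple_consensus(
    masks: Sequence[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> StapleResult:
    """Binary STAPLE: EM estimation of the latent truth and rater quality.

    E-step: posterior truth probability from the current sensitivities,
    specificities and the prior (the mean foreground fraction of the
    input masks).  M-step: re-estimate each rater's p and q against the
    posterior.  Stops when the parameter change drops below ``tol`` or at
    ``max_iter``.
    """
    if len(masks) == 0:
        raise ValidationError("need at least one annotation")
    shape = np.asarray(masks[0]).shape
    D = np.stack([np.asarray(m).astype(bool).reshape(-1) for m in masks], axis=1)
    if any(np.asarray(m).shape != shape for m in masks):
        raise ShapeError("all annotations must share one shape")
    if not D.any():
        raise ValidationError("all annotations are empty: consensus undefined")

    n_vox, n_raters = D.shape
    # collapse identical rater-decision patterns (at most 2^raters of them)
    patterns, inverse, counts = np.unique(D, axis=0, return_inverse=True,
                                          return_counts=True)
    Dp = patterns.astype(np.float64)       # (n_patterns, n_raters)
    wts = counts.astype(np.float64)

    prior = float(D.mean())
    p = np.full(n_raters, 0.99)
    q = np.full(n_raters, 0.99)
    eps = 1e-12
    loglik: list[float] = []
    W = None
    for it in range(1, max_iter + 1):
        pc = np.clip(p, eps, 1 - eps)
        qc = np.clip(q, eps, 1 - eps)
        # E-step on the compressed patterns
        log_a = Dp @ np.log(pc) + (1 - Dp) @ np.log(1 - pc)
        log_b = Dp @ np.log(1 - qc) + (1 - Dp) @ np.log(qc)
        num = prior * np.exp(log_a)
        den = num + (1 - prior) * np.exp(log_b)
        W = num / np.maximum(den, eps)
        loglik.append(float(wts @ np.log(np.maximum(den, eps))))
        # M-step
        wW = wts * W
        wV = wts * (1 - W)
        sum_w = wW.sum()
        sum_v = wV.sum()
        p_new = (Dp.T @ wW) / max(sum_w, eps)
        q_new = ((1 - Dp).T @ wV) / max(sum_v, eps)
        change = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if change < tol:
            break

    probability = W[inverse].reshape(shape)
    return StapleResult(probability=probability, sensitivity=p, specificity=q,
                        iterations=it, log_likelihood=np.asarray(loglik))
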