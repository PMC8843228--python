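"""Intensity standardization and histology-to-MRI landmark registration.

Standardization follows the landmark-matching (Nyul-style) scheme: for
each conventional image type, intensity landmarks (1st percentile,
deciles 10-90, 99th percentile) are computed over a foreground mask
(Otsu threshold) of each training image and averaged into a standard
scale; a new image is mapped by monotone piecewise-linear interpolation
of its own landmarks onto the standard ones, with linear extrapolation
from the end segments.

Registration between the histology plane and the MR plane of interest
uses a local weighted mean (LWM) transform inferred from control-point
pairs: a second-degree bivariate polynomial is fitted (least squares)
to each control point's ``n`` nearest neighbors, and the transform at
any location is the radially weighted mean of the local polynomials
whose compactly supported weight ``(1 - (r/R)^3)^3`` is positive there
(``R`` = distance to the n-th nearest control point).  Outside all
neighborhoods the nearest control point's polynomial extrapolates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core_io import NON_TUMOR, ImageGrid, ViabilityMap

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


class DegenerateScaleError(ValueError):
    """Image has no usable intensity spread for standardization."""


@dataclass
class StandardScale:
    """Landmark percentiles and their standardized target intensities."""

    percentiles: np.ndarray
    targets: np.ndarray

    def __post_init__(self):
        self.percentiles = np.asarray(self.percentiles, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if np.any(np.diff(self.targets) <= 0):
            raise DegenerateScaleError(
                "standard-scale landmarks must be strictly increasing")


def _foreground(values: np.ndarray) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size == 0 or finite.min() == finite.max():
        raise DegenerateScaleError("constant image")
    thr = threshold_otsu(finite)
    mask = values > thr
    if mask.sum() < 10:  # pathological threshold; fall back to all voxels
        mask = np.isfinite(values)
    return mask


def _landmarks(values: np.ndarray, percentiles) -> np.ndarray:
    mask = _foreground(values)
    lm = np.percentile(values[mask], percentiles)
    if np.any(np.diff(lm) <= 0):
        raise DegenerateScaleError(
            "image landmarks are not strictly increasing")
    return lm


def learn_standard_scale(images, percentiles=DEFAULT_PERCENTILES
                         ) -> StandardScale:
    """Average landmark intensities across training images of one type.

    With a single training image the standard scale equals its own
    landmarks, so standardization is the identity on it.
    """
    if not images:
        raise ValueError("need at least one training image")
    lms = [
        _landmarks(np.asarray(getattr(img, "values", img), dtype=np.float64),
                   percentiles)
        for img in images
    ]
    return StandardScale(np.asarray(percentiles, dtype=np.float64),
                         np.mean(lms, axis=0))


def standardize_intensity(image, scale: StandardScale):
    """Map an image onto the standard scale (monotone, piecewise linear).

    Out-of-range intensities are extrapolated linearly from the first
    and last landmark segments.  Returns the same container type as the
    input (:class:`ImageGrid` in, :class:`ImageGrid` out).
    """
    values = np.asarray(getattr(image, "values", image), dtype=np.float64)
    src = _landmarks(values, scale.percentiles)
    dst = scale.targets
    out = np.interp(values, src, dst)
    # linear extrapolation beyond the end landmarks
    lo = values < src[0]
    hi = values > src[-1]
    if lo.any():
        slope = (dst[1] - dst[0]) / (src[1] - src[0])
        out[lo] = dst[0] + slope * (values[lo] - src[0])
    if hi.any():
        slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
        out[hi] = dst[-1] + slope * (values[hi] - src[-1])
    if isinstance(image, ImageGrid):
        return image.with_values(out)
    return out


# ---------------------------------------------------------------------------
# Local weighted mean transform
# ---------------------------------------------------------------------------

class InsufficientLandmarksError(ValueError):
    """Fewer control points than a local quadratic needs."""


def _poly_design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * y, x ** 2, y ** 2])


def _affine_design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y])


@dataclass
class LWMTransform:
    """Local weighted mean mapping from source to target plane coords."""

    src: np.ndarray            # (p, 2) source control points
    dst: np.ndarray            # (p, 2) target control points
    coeffs: np.ndarray         # (p, 6, 2) per-point polynomial coefficients
    radii: np.ndarray          # (p,) support radius per control point
    n_neighbors: int

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map ``(m, 2)`` source-plane points to the target plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        design = _poly_design(pts)                      # (m, 6)
        local = np.einsum("md,pdo->mpo", design, self.coeffs)  # (m, p, 2)
        d = np.linalg.norm(pts[:, None, :] - self.src[None, :, :], axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = d / self.radii[None, :]
        w = np.where(rr < 1.0, (1.0 - rr ** 3) ** 3, 0.0)
        wsum = w.sum(axis=1)
        inside = wsum > 0
        out = np.empty((pts.shape[0], 2))
        if inside.any():
            out[inside] = (np.einsum("mp,mpo->mo", w[inside],
                                     local[inside])
                           / wsum[inside, None])
        if (~inside).any():
            # outside every neighborhood: nearest control point's polynomial
            nearest = d[~inside].argmin(axis=1)
            out[~inside] = local[~inside, nearest]
        return out


def fit_lwm_transform(src_points, dst_points,
                      n_neighbors: int = 8) -> LWMTransform:
    """Fit the LWM transform from paired control points.

    Requires at least 6 pairs (a second-order bivariate polynomial has 6
    coefficients); a degenerate (e.g. collinear) neighborhood falls back
    to an affine local fit with a warning.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=np.float64))
    p = src.shape[0]
    if p < 6:
        raise InsufficientLandmarksError(
            f"need at least 6 control-point pairs, got {p}")
    if dst.shape != src.shape:
        raise ValueError("source/target control point counts differ")
    n = int(min(max(n_neighbors, 6), p))

    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    order = np.argsort(d, axis=1)
    coeffs = np.zeros((p, 6, 2))
    radii = np.empty(p)
    for i in range(p):
        nbr = order[i, :n]
        radii[i] = d[i, nbr[-1]]
        A = _poly_design(src[nbr])
        if np.linalg.matrix_rank(A) < 6:
            logger.warning(
                "degenerate neighborhood at control point %d; "
                "falling back to an affine local fit", i)
            Aa = _affine_design(src[nbr])
            sol, *_ = np.linalg.lstsq(Aa, dst[nbr], rcond=None)
            coeffs[i, :3] = sol
        else:
            sol, *_ = np.linalg.lstsq(A, dst[nbr], rcond=None)
            coeffs[i] = sol
        if radii[i] <= 0:
            raise ValueError("duplicate control points")
    return LWMTransform(src=src, dst=dst, coeffs=coeffs, radii=radii,
                        n_neighbors=n)


def warp_label_map(histology: ViabilityMap, transform: LWMTransform,
                   target: ImageGrid) -> ViabilityMap:
    """Transfer histology labels onto an MR-plane lattice.

    For every MR pixel center, the transform maps its physical position
    into histology-plane coordinates and the nearest histology label is
    taken (no label interpolation); positions mapping outside the
    histology map become ``non_tumor``.
    """
    nx, ny = target.values.shape[:2]
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    phys = np.column_stack([
        target.origin[0] + ix.ravel() * target.spacing[0],
        target.origin[1] + iy.ravel() * target.spacing[1],
    ])
    mapped = transform(phys)
    hx = np.rint((mapped[:, 0] - histology.origin[0])
                 / histology.spacing[0]).astype(np.int64)
    hy = np.rint((mapped[:, 1] - histology.origin[1])
                 / histology.spacing[1]).astype(np.int64)
    hnx, hny = histology.values.shape
    inside = (hx >= 0) & (hx < hnx) & (hy >= 0) & (hy < hny)
    labels = np.full(nx * ny, NON_TUMOR, dtype=np.int16)
    labels[inside] = histology.values[hx[inside], hy[inside]]
    return ViabilityMap(labels.reshape(nx, ny), spacing=target.spacing[:2],
                        origin=target.origin[:2])
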