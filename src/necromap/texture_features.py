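"""Windowed per-pixel features: original value, 4 moments, 19 Haralick.

For every tumor pixel a square window of side ``W`` is centered on it
(truncated at image borders only), the window is gray-level quantized to
``G`` levels over the tumor region's intensity range, and a direction
invariant gray-level co-occurrence matrix (GLCM) is accumulated from the
eight distance-1 neighbor directions.  Nineteen Haralick-type texture
statistics plus four ordinary sample moments and the original pixel value
give a 24-element feature vector per pixel.

Notes on conventions (both the implementation and its documentation of
record):

* gray levels are 1-based (``1..G``) and enter the formulas as values;
* ``0 log 0 = 0`` everywhere; natural logarithms;
* *difference variance* is the variance of the difference histogram
  ``p_{|i-j|}`` (one of two variants found in the literature);
* *sum of squares* uses the marginal mean (``sum_i (i - mu_x)^2 p_x(i)``),
  and *sum variance* is centered on the sum average;
* features with vanishing denominators (correlation, the information
  measures of correlation) are defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

#: Canonical feature order.
STATISTICAL_NAMES = ("mean", "variance", "skewness", "kurtosis")
HARALICK_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "imc1",
    "imc2",
    "inverse_difference",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares",
    "sum_variance",
)
FEATURE_NAMES = ("original",) + STATISTICAL_NAMES + HARALICK_NAMES

#: Distance-1 neighbor offsets; with their opposites these are the eight
#: directions (left, right, up, down and the four diagonals).
_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

DEFAULT_W_GRID = (3, 9, 15)
DEFAULT_G_GRID = (50, 100, 200)


@dataclass
class FeatureSpec:
    """Window side length W (odd) and number of gray levels G."""

    W: int = 3
    G: int = 50

    def __post_init__(self):
        if self.W % 2 != 1 or self.W < 1:
            raise ValueError("W must be an odd positive integer")
        if self.G < 2:
            raise ValueError("G must be at least 2")

    @property
    def feature_names(self):
        return FEATURE_NAMES


@dataclass
class FeatureStack:
    """Per-pixel feature matrix for one image type at one (W, G)."""

    positions: np.ndarray        # (q, 2) int lattice indices
    X: np.ndarray                # (q, 24)
    spec: FeatureSpec = field(default_factory=FeatureSpec)
    image_type: str = ""

    @property
    def q(self) -> int:
        return self.X.shape[0]

    @property
    def r(self) -> int:
        return self.X.shape[1]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df.insert(0, "y", self.positions[:, 1])
        df.insert(0, "x", self.positions[:, 0])
        return df


def quantize_gray_levels(values: np.ndarray, mask: np.ndarray,
                         G: int) -> np.ndarray:
    """Linear min-max quantization into integer levels ``1..G``.

    The intensity range is taken over the masked (tumor) region so that
    neighboring windows share one gray scale; the masked maximum maps to
    level ``G`` and out-of-range intensities clip to the end levels.
    """
    if G < 2:
        raise ValueError("G must be at least 2")
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty quantization mask")
    lo = values[mask].min()
    hi = values[mask].max()
    if hi <= lo:
        warnings.warn("constant masked region: all pixels map to level 1")
        return np.ones(values.shape, dtype=np.int32)
    levels = np.floor((values - lo) / (hi - lo) * G).astype(np.int32) + 1
    return np.clip(levels, 1, G)


def compute_glcm(window: np.ndarray, G: int) -> np.ndarray:
    """Direction invariant GLCM of one integer window.

    The eight symmetric distance-1 co-occurrence matrices are summed and
    normalized to total 1.  Pixel pairs extending outside the window are
    not counted.
    """
    window = np.asarray(window)
    if window.min() < 1 or window.max() > G:
        raise ValueError("window entries must lie in [1, G]")
    counts = _accumulate_counts(window.astype(np.int64), G)
    total = counts.sum()
    if total == 0:  # single-pixel window: degenerate but well defined
        g = int(window.ravel()[0]) - 1
        counts[g, g] = 1.0
        total = 1.0
    return counts / total


def _accumulate_counts(window: np.ndarray, G: int) -> np.ndarray:
    counts = np.zeros((G, G), dtype=np.float64)
    for dx, dy in _OFFSETS:
        a = window[max(dx, 0):window.shape[0] + min(dx, 0),
                   max(dy, 0):window.shape[1] + min(dy, 0)]
        b = window[max(-dx, 0):window.shape[0] + min(-dx, 0),
                   max(-dy, 0):window.shape[1] + min(-dy, 0)]
        np.add.at(counts, (a.ravel() - 1, b.ravel() - 1), 1.0)
        np.add.at(counts, (b.ravel() - 1, a.ravel() - 1), 1.0)
    return counts


def haralick_features(glcm: np.ndarray) -> np.ndarray:
    """The 19 texture statistics of one normalized symmetric GLCM.

    Internally the matrix is reduced to the compact support of its
    occupied gray levels (the statistics only involve nonzero entries
    and their level values), which makes per-window evaluation cheap
    even for large ``G``.
    """
    P = np.asarray(glcm, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    occupied = np.nonzero(P.sum(axis=1) + P.sum(axis=0) > 0)[0]
    if occupied.size == 0:
        raise ValueError("empty GLCM")
    levels = (occupied + 1).astype(np.float64)
    return _haralick_compact(P[np.ix_(occupied, occupied)], levels)


def haralick_stack(P: np.ndarray) -> np.ndarray:
    """Haralick statistics for a stack of GLCMs, ``(q, G, G) -> (q, 19)``."""
    P = np.asarray(P, dtype=np.float64)
    return np.stack([haralick_features(P[i]) for i in range(P.shape[0])])


def _haralick_compact(P: np.ndarray, lv: np.ndarray) -> np.ndarray:
    """Statistics of a GLCM restricted to its occupied levels ``lv``."""
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = px @ lv
    muy = py @ lv
    varx = max(px @ lv**2 - mux**2, 0.0)
    vary = max(py @ lv**2 - muy**2, 0.0)

    D = lv[:, None] - lv[None, :]
    absD = np.abs(D)
    autoc = float(lv @ P @ lv)
    contrast = float((P * D**2).sum())
    dissim = float((P * absD).sum())
    homog = float((P / (1.0 + D**2)).sum())
    invdiff = float((P / (1.0 + absD)).sum())

    # Sum histogram p_{x+y} over occupied level sums.
    lsum = (lv[:, None] + lv[None, :]).astype(np.int64)
    psum = np.bincount(lsum.ravel(), weights=P.ravel())
    ks = np.nonzero(psum)[0].astype(np.float64)
    ps = psum[np.nonzero(psum)[0]]
    sum_avg = float(ks @ ps)
    sum_ent = float(-xlogy(ps, ps).sum())
    sum_var = float(((ks - sum_avg) ** 2 * ps).sum())
    mu2 = mux + muy
    shade = float(((ks - mu2) ** 3 * ps).sum())
    prom = float(((ks - mu2) ** 4 * ps).sum())

    # Difference histogram p_{|x-y|}.
    ldiff = absD.astype(np.int64)
    pdiff = np.bincount(ldiff.ravel(), weights=P.ravel())
    ds = np.arange(pdiff.size, dtype=np.float64)
    dmean = float(ds @ pdiff)
    diff_var = float(((ds - dmean) ** 2 * pdiff).sum())
    diff_ent = float(-xlogy(pdiff, pdiff).sum())

    energy = float((P ** 2).sum())
    entropy = float(-xlogy(P, P).sum())
    maxprob = float(P.max())

    sig = np.sqrt(varx * vary)
    corr = (autoc - mux * muy) / sig if sig > 1e-12 else 0.0

    hx = float(-xlogy(px, px).sum())
    hy = float(-xlogy(py, py).sum())
    # For the canonical definitions HXY1 and HXY2 both reduce to HX + HY
    # (expand log(px*py) and marginalize); the brute-force double sums in
    # the test oracle confirm this numerically.
    hxy1 = hx + hy
    hxy2 = hx + hy
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 1e-12 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0)))

    return np.array([
        autoc, prom, shade, contrast, corr, diff_ent, diff_var, dissim,
        energy, entropy, homog, imc1, imc2, invdiff, maxprob,
        sum_avg, sum_ent, varx, sum_var,
    ])


def statistical_features(window: np.ndarray) -> np.ndarray:
    """Sample moments (mean, population variance, skewness, kurtosis).

    Skewness and (non-excess) kurtosis of a zero-variance window are 0.
    """
    w = np.asarray(window, dtype=np.float64).ravel()
    if w.size == 0:
        raise ValueError("empty window")
    mean = w.mean()
    d = w - mean
    var = np.mean(d**2)
    if var <= 0:
        return np.array([mean, 0.0, 0.0, 0.0])
    skew = np.mean(d**3) / var**1.5
    kurt = np.mean(d**4) / var**2
    return np.array([mean, var, skew, kurt])


def extract_feature_stack(image, aoi, spec: FeatureSpec,
                          image_type: str = "") -> FeatureStack:
    """24-element feature vectors for every AOI pixel of one image.

    ``image`` / ``aoi`` may be :class:`~necromap.core_io.ImageGrid` /
    :class:`~necromap.core_io.MaskGrid` or plain 2-D arrays.  Windows may
    include non-AOI pixels that lie inside the image; they are truncated
    only at image borders.
    """
    values = getattr(image, "values", image)
    mask = getattr(aoi, "values", aoi)
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if values.ndim != 2:
        raise ValueError("feature extraction operates on a 2-D plane")
    if values.shape != mask.shape:
        raise ValueError("image and AOI lattices differ")
    if not mask.any():
        raise ValueError("empty AOI")

    positions = np.argwhere(mask)
    q = positions.shape[0]
    G, W = spec.G, spec.W
    h = W // 2
    levels = quantize_gray_levels(values, mask, G)

    from ._fast_texture import HAVE_NUMBA, stack_features
    if HAVE_NUMBA:
        X = stack_features(values, levels, positions, W)
    else:  # reference path; the compiled kernel is tested against it
        har = np.empty((q, len(HARALICK_NAMES)))
        stats = np.empty((q, 4))
        nx, ny = values.shape
        for idx, (x, y) in enumerate(positions):
            x0, x1 = max(x - h, 0), min(x + h + 1, nx)
            y0, y1 = max(y - h, 0), min(y + h + 1, ny)
            win = levels[x0:x1, y0:y1]
            # work on the compact support of the window's gray levels
            uniq, inv = np.unique(win, return_inverse=True)
            counts = _accumulate_counts(inv.reshape(win.shape) + 1, uniq.size)
            total = counts.sum()
            if total == 0:
                counts[0, 0] = 1.0
                total = 1.0
            har[idx] = _haralick_compact(counts / total,
                                         uniq.astype(np.float64))
            stats[idx] = statistical_features(values[x0:x1, y0:y1])
        X = np.column_stack([values[mask], stats, har])
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite feature values")
    return FeatureStack(positions=positions, X=X, spec=spec,
                        image_type=image_type)
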