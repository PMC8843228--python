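"""Per-image fuzzy c-means segmentation and weighted-majority fusion.

Each MR image (or derived map) contributes a *fuzzy necrosis map*: the
membership of every tumor-AOI pixel to the necrotic cluster of a
two-cluster fuzzy c-means (FCM) partition of that image's selected
features.  The per-image maps are then fused by a weighted majority rule
into one binary viability map.

The FCM iteration alternates the classical updates: cluster centers are
membership^m-weighted means of the feature vectors, and memberships are
inverse squared-distance ratios with exponent ``1/(m - 1)``.  The
defaults follow the study protocol: ``c = 2`` clusters, fuzziness
``m = 2``, and center-shift stopping threshold ``eps = 1e-5``.

The weighted majority rule as commonly written uses weights summing to
the number of maps ``s`` against a threshold of ``s/2``; stated with
weights summing to 1 the threshold ``1/2`` is the exactly equivalent
normalized form, which is what this module uses: a pixel is necrotic iff
``sum_k w_k u_i^k > 1/2`` with ``sum_k w_k = 1`` (ties fall to viable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FCMResult:
    """Outcome of one fuzzy c-means run."""

    U: np.ndarray              # (q, c) memberships, rows sum to 1
    V: np.ndarray              # (c, r) cluster centers
    objective: float           # final value of the clustering objective
    objective_trace: np.ndarray
    iterations: int
    final_center_shift: float


@dataclass
class FuzzyNecrosisMap:
    """Per-AOI-pixel necrosis memberships from one image's FCM."""

    u: np.ndarray              # (q,) in [0, 1]
    image_type: str = ""
    necrosis_cluster: int = 0
    necrosis_centroid: Optional[np.ndarray] = None  # standardized features
    necrosis_direction: Optional[np.ndarray] = None  # V_nec - V_viable, unit
    agreement: Optional[float] = None


@dataclass
class WeightVector:
    """Nonnegative fusion weights summing to 1, on a grid of step t."""

    weights: np.ndarray
    step: float = 0.1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def s(self) -> int:
        return self.weights.size


@dataclass
class BinaryViabilityMap:
    """Binary per-pixel labels on the AOI (1 = necrotic, 0 = viable)."""

    y: np.ndarray
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y).astype(bool)


def _objective(X, U, V, m):
    d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
    return float(((U ** m) * d2).sum())


def _update_memberships(X, V, m):
    d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        # Analytic limit: a pixel sitting exactly on a center belongs to
        # it crisply (split evenly if it coincides with several).
        rows = np.where(any_zero)[0]
        U[rows] = 0.0
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return U


def fcm_cluster(X: np.ndarray, c: int = 2, m: float = 2.0,
                eps: float = 1e-5, seed=0, max_iter: int = 300,
                n_restarts: int = 3) -> FCMResult:
    """Fuzzy c-means partition of a feature matrix.

    Memberships are initialized uniformly at random (rows normalized),
    seeded; ``n_restarts`` independent starts are run and the solution
    with the lowest final objective is kept.  Iteration stops when the
    Frobenius norm of the center change falls below ``eps``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    q, r = X.shape
    if q == 0:
        raise ValueError("empty feature matrix")
    if q < c:
        raise ValueError(f"need at least c={c} pixels, got {q}")

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            # D^2-weighted (k-means++ style) center seeding: with heavy
            # class imbalance the small-cluster optimum has the lower
            # objective but a vanishing basin under random memberships,
            # so the first restart starts from spread-out centers.
            centers = [X[rng.integers(q)]]
            for _ in range(c - 1):
                d2 = np.min(
                    ((X[:, None, :] - np.asarray(centers)[None]) ** 2)
                    .sum(axis=2), axis=1)
                tot = d2.sum()
                if tot <= 0:
                    centers.append(X[rng.integers(q)])
                else:
                    centers.append(X[rng.choice(q, p=d2 / tot)])
            U = _update_memberships(X, np.asarray(centers), m)
        else:
            U = rng.uniform(size=(q, c))
            U /= U.sum(axis=1, keepdims=True)
        trace = []
        shift = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            Um = U ** m
            V = (Um.T @ X) / Um.sum(axis=0)[:, None]
            U = _update_memberships(X, V, m)
            trace.append(_objective(X, U, V, m))
            if it > 1:
                shift = float(np.linalg.norm(V - V_prev))
                if shift < eps:
                    break
            V_prev = V
        res = FCMResult(U=U, V=V, objective=trace[-1],
                        objective_trace=np.asarray(trace), iterations=it,
                        final_center_shift=shift)
        if best is None or res.objective < best.objective:
            best = res
    return best


def assign_necrosis_cluster(result: FCMResult,
                            labels: Optional[np.ndarray] = None,
                            reference_centroid: Optional[np.ndarray] = None,
                            reference_direction: Optional[np.ndarray] = None,
                            mean_adc_feature: Optional[np.ndarray] = None,
                            image_type: str = "") -> FuzzyNecrosisMap:
    """Designate which FCM cluster is necrosis.

    Training mode (``labels`` given, boolean, True = necrotic): the
    cluster whose hard assignment agrees best with the histology-derived
    labels is designated necrotic; its centroid and the necrotic-minus-
    viable center direction are retained for later inference.  Inference
    mode: with ``reference_direction`` (preferred — invariant to the
    necrosis fraction of the case being predicted, unlike absolute
    centroid positions under per-case feature standardization) the
    cluster whose center lies further along the stored direction wins;
    with ``reference_centroid`` the nearer center wins.  A training tie
    falls to the cluster with the higher mean of the ADC feature when
    one is supplied, otherwise it is an error.
    """
    U, V = result.U, result.V
    if U.shape[1] != 2:
        raise ValueError("necrosis designation assumes c = 2")
    if labels is not None:
        labels = np.asarray(labels, dtype=bool)
        hard0 = U[:, 0] > 0.5
        agree = np.array([np.mean(hard0 == labels),
                          np.mean(~hard0 == labels)])
        if abs(agree[0] - agree[1]) < 1e-12:
            if mean_adc_feature is None:
                raise ValueError(
                    "agreement tie: supply an ADC feature or designate "
                    "the necrosis cluster manually")
            k = int(np.argmax([mean_adc_feature[0], mean_adc_feature[1]]))
        else:
            k = int(np.argmax(agree))
        return FuzzyNecrosisMap(u=U[:, k].copy(), image_type=image_type,
                                necrosis_cluster=k,
                                necrosis_centroid=V[k].copy(),
                                agreement=float(agree[k]))
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=np.float64)
        k = int(np.argmax(V @ ref))
        return FuzzyNecrosisMap(u=U[:, k].copy(), image_type=image_type,
                                necrosis_cluster=k,
                                necrosis_centroid=V[k].copy())
    if reference_centroid is not None:
        ref = np.asarray(reference_centroid, dtype=np.float64)
        d = ((V - ref[None, :]) ** 2).sum(axis=1)
        k = int(np.argmin(d))
        return FuzzyNecrosisMap(u=U[:, k].copy(), image_type=image_type,
                                necrosis_cluster=k,
                                necrosis_centroid=V[k].copy())
    raise ValueError(
        "provide histology labels, a reference direction or a centroid")


def designate_by_sign(result: FCMResult, anchor_positions,
                      consensus_signs, image_type: str = ""
                      ) -> FuzzyNecrosisMap:
    """Designate the necrosis cluster by intensity-polarity consensus.

    ``consensus_signs`` is the cohort-mean sign of the necrotic-minus-
    viable center difference on the anchor features (the original pixel
    value and the window mean, whose polarity — e.g. necrosis darker on
    post-contrast T1, brighter on ADC — does not depend on the necrosis
    fraction of the case being predicted).  The cluster whose center
    differences match the consensus signs is necrosis.
    """
    V = result.V
    if V.shape[0] != 2:
        raise ValueError("necrosis designation assumes c = 2")
    ai = list(anchor_positions)
    s = np.sign(V[0, ai] - V[1, ai])
    k = 0 if float(s @ np.asarray(consensus_signs, dtype=np.float64)) > 0 \
        else 1
    return FuzzyNecrosisMap(u=result.U[:, k].copy(), image_type=image_type,
                            necrosis_cluster=k,
                            necrosis_centroid=V[k].copy())


def weighted_majority(maps: list, weights: WeightVector) -> BinaryViabilityMap:
    """Fuse fuzzy necrosis maps into a binary viability map.

    ``y_i = 1`` iff the weighted sum of necrosis memberships exceeds 1/2
    under normalized weights; an exact tie is viable (strict inequality).
    """
    if len(maps) != weights.s:
        raise ValueError(f"{len(maps)} maps but {weights.s} weights")
    us = [np.asarray(getattr(mp, "u", mp), dtype=np.float64) for mp in maps]
    q = us[0].size
    if any(u.size != q for u in us):
        raise ValueError("fuzzy maps must share one AOI pixel list")
    stacked = np.stack(us, axis=1)          # (q, s)
    score = stacked @ weights.weights
    return BinaryViabilityMap(y=score > 0.5)


def necrosis_percentage(vmap: BinaryViabilityMap) -> float:
    """Percent necrotic pixels, ``100 * sum(y_i) / q``."""
    y = vmap.y
    if y.size == 0:
        raise ValueError("empty viability map")
    return 100.0 * float(y.sum()) / y.size


def zscore_features(X: np.ndarray):
    """Standardize columns to zero mean, unit variance (constant -> 0)."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def standardize_features(X: np.ndarray, trim: float = 5.0,
                         winsor: float = 20.0):
    """Median-center, scale by the trimmed standard deviation, winsorize.

    FCM's Euclidean metric is scale sensitive, so each selected feature
    is standardized over the AOI pixels before clustering.  The scale is
    the standard deviation of the inner ``100 - 2*trim`` percent of each
    feature.  Compared with a plain z-score this (i) keeps a small
    (<``trim``%) tissue compartment out of the scale estimate, so its
    separation from the dominant compartment is not compressed — a plain
    z-score caps any feature's standardized class separation at
    ``1/sqrt(f(1-f))`` and provably prevents two-cluster FCM from
    isolating a ~1% minority class however strong the raw contrast —
    and (ii) tames heavy-tailed texture statistics (cluster prominence
    and friends) whose outliers would otherwise dominate the metric.
    Standardized values are finally clipped to ``[-winsor, winsor]`` so
    that no single feature's extreme tail can dominate the clustering
    objective, while a genuinely separated minority compartment (capped
    separation ~``winsor`` per feature, summed over features) still
    overwhelms any within-cluster split.
    """
    X = np.asarray(X, dtype=np.float64)
    med = np.median(X, axis=0)
    lo, hi = np.percentile(X, [trim, 100.0 - trim], axis=0)
    scales = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        inner = col[(col >= lo[j]) & (col <= hi[j])]
        s = inner.std() if inner.size else 0.0
        if s <= 1e-12:
            s = col.std()
        if s <= 1e-12:
            s = 1.0
        scales[j] = s
    Z = np.clip((X - med) / scales, -winsor, winsor)
    return Z, med, scales
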