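"""Model training and evaluation.

Training follows the study protocol end to end: conventional images are
intensity standardized; histology labels are transferred onto the MR
plane of interest through the control-point transform; 24-element
feature stacks are extracted for every image type over the (W, G) grid;
ANOVA keeps the significant features; each image yields a fuzzy
necrosis map by two-cluster FCM on its selected features; and fusion
weights for an MRI subset are found by brute force over the discrete
simplex ``{w : w_k = z_k t, sum w_k = 1}``, minimizing either the mean
(*min-avg*) or the maximum (*min-max*) absolute error between the
MRI-estimated and histology necrosis percentages across cases.  The
(W, G) pair with the lowest optimized objective wins.

Evaluation reports per-case absolute errors, Dice and
Szymkiewicz-Simpson (overlap) coefficients of the necrotic pixel sets,
responder calls at the 90% necrosis threshold, and whole-tumor (VOI)
necrosis obtained by running the per-plane pipeline on every slice.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (ADC, CONV_TYPES, NECROTIC, NON_TUMOR, ImageGrid,
                      MaskGrid, MRICase, SubsetSpec)
from .fcm_fusion import (BinaryViabilityMap, FuzzyNecrosisMap, WeightVector,
                         assign_necrosis_cluster, designate_by_sign,
                         fcm_cluster, necrosis_percentage,
                         standardize_features, weighted_majority)
from .feature_selection import SignificanceTable, select_features
from .preprocess import (fit_lwm_transform, learn_standard_scale,
                         standardize_intensity, warp_label_map)
from .texture_features import FeatureSpec, extract_feature_stack

logger = logging.getLogger(__name__)

DEFAULT_W_GRID = (3, 9, 15)
DEFAULT_G_GRID = (50, 100, 200)
DEFAULT_WG_GRID = tuple((W, G) for W in DEFAULT_W_GRID
                        for G in DEFAULT_G_GRID)
DEFAULT_STEP = 0.1
GRID_CAP = 1_000_000


# ---------------------------------------------------------------------------
# Weight grid and objectives
# ---------------------------------------------------------------------------

def enumerate_weight_grid(s: int, t: float,
                          cap: int = GRID_CAP) -> np.ndarray:
    """All s-tuples of nonnegative multiples of t summing to 1.

    Returned in ascending lexicographic order; the count is the
    stars-and-bars number ``C(1/t + s - 1, s - 1)``.
    """
    if s < 1:
        raise ValueError("subset size must be at least 1")
    M = int(round(1.0 / t))
    if abs(M * t - 1.0) > 1e-9:
        raise ValueError(f"step {t} does not divide 1")
    n = comb(M + s - 1, s - 1)
    if n > cap:
        raise ValueError(
            f"weight grid has {n} vectors (> cap {cap}); use a coarser t")
    rows = []

    def rec(prefix, remaining, pos):
        if pos == s - 1:
            rows.append(prefix + [remaining])
            return
        for z in range(remaining + 1):
            rec(prefix + [z], remaining - z, pos + 1)

    rec([], M, 0)
    out = np.asarray(rows, dtype=np.float64) * t
    assert out.shape == (n, s)
    return out


def objective_value(estimates, truths, objective: str) -> float:
    """Mean (*min_avg*) or maximum (*min_max*) absolute error."""
    est = np.asarray(estimates, dtype=np.float64)
    tru = np.asarray(truths, dtype=np.float64)
    if est.size == 0 or est.shape != tru.shape:
        raise ValueError("need aligned, nonempty estimate/truth lists")
    err = np.abs(est - tru)
    if objective == "min_avg":
        return float(err.mean())
    if objective == "min_max":
        return float(err.max())
    raise ValueError(f"unknown objective {objective!r}")


def evaluate_weight_grid(U_list, wgrid: np.ndarray,
                         chunk: int = 0) -> np.ndarray:
    """Necrosis percentage per (case, weight vector).

    ``U_list`` holds one ``(q, s)`` membership matrix per case; the
    result is an ``(n_cases, n_weights)`` array of ``N_AOI`` values.
    """
    n_w = wgrid.shape[0]
    N = np.empty((len(U_list), n_w))
    WT = np.ascontiguousarray(wgrid.T, dtype=np.float32)
    for ci, U in enumerate(U_list):
        U32 = np.ascontiguousarray(U, dtype=np.float32)
        q = U.shape[0]
        if chunk <= 0:  # keep the score block around 20M floats
            chunk = max(1000, int(2e7 / max(q, 1)))
        for j0 in range(0, n_w, chunk):
            j1 = min(j0 + chunk, n_w)
            score = U32 @ WT[:, j0:j1]
            N[ci, j0:j1] = 100.0 * (score > 0.5).sum(axis=0) / q
    return N


def optimize_weights(U_list, truths, t: float = DEFAULT_STEP,
                     objective: str = "min_avg", cap: int = GRID_CAP):
    """Brute-force search of the fusion weights on the t-grid.

    Returns ``(WeightVector, objective value, per-case N at optimum)``;
    ties resolve to the first vector in lexicographic order.
    """
    s = U_list[0].shape[1]
    wgrid = enumerate_weight_grid(s, t, cap=cap)
    N = evaluate_weight_grid(U_list, wgrid)
    err = np.abs(N - np.asarray(truths, dtype=np.float64)[:, None])
    vals = err.mean(axis=0) if objective == "min_avg" else err.max(axis=0)
    if objective not in ("min_avg", "min_max"):
        raise ValueError(f"unknown objective {objective!r}")
    k = int(np.argmin(vals))
    return (WeightVector(wgrid[k], step=t), float(vals[k]), N[:, k].copy())


def select_wg(results: dict):
    """Argmin over (W, G); ties break toward smaller W, then smaller G."""
    if not results:
        raise ValueError("no evaluated (W, G) pairs")
    return min(sorted(results), key=lambda k: (results[k], k))


# ---------------------------------------------------------------------------
# Set-similarity metrics and responder rule
# ---------------------------------------------------------------------------

def dice_coefficient(a, b) -> float:
    """``2|A ∩ B| / (|A| + |B|)``; two empty sets count as identical."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def overlap_coefficient(a, b) -> float:
    """Szymkiewicz-Simpson ``|A ∩ B| / min(|A|, |B|)``.

    1 whenever one set contains the other; NaN (missing) if either set
    is empty, to avoid spurious zeros in all-viable cases.
    """
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    na, nb = int(a.sum()), int(b.sum())
    if min(na, nb) == 0:
        return float("nan")
    return int((a & b).sum()) / min(na, nb)


def classify_responder(necrosis_percent: float) -> str:
    """``good`` iff necrosis >= 90%, else ``poor``."""
    if not 0.0 <= necrosis_percent <= 100.0:
        raise ValueError("necrosis percent must lie in [0, 100]")
    return "good" if necrosis_percent >= 90.0 else "poor"


# ---------------------------------------------------------------------------
# Per-case preparation
# ---------------------------------------------------------------------------

def _stable_seed(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) % (2 ** 31)


@dataclass
class CaseData:
    """Cached per-case inputs to training: stacks + transferred labels."""

    case_id: str
    positions: np.ndarray          # (q, 2) AOI pixel indices
    stacks: dict                   # (image_type, W, G) -> FeatureStack
    hist_labels: np.ndarray        # (q,) transferred histology labels
    n_hist: float

    @property
    def q(self) -> int:
        return self.positions.shape[0]

    @property
    def tumor_labeled(self) -> np.ndarray:
        return self.hist_labels != NON_TUMOR

    @property
    def necrotic_labels(self) -> np.ndarray:
        return self.hist_labels == NECROTIC


def standardize_conventional(cases, image_types=CONV_TYPES):
    """Learn per-type standard scales on the cohort and apply in place."""
    scales = {}
    for name in image_types:
        imgs = [c.images[name] for c in cases if name in c.images]
        if not imgs:
            continue
        scales[name] = learn_standard_scale(imgs)
        for c in cases:
            if name in c.images:
                c.images[name] = standardize_intensity(c.images[name],
                                                       scales[name])
    return scales


def transfer_histology_labels(case: MRICase) -> np.ndarray:
    """Histology labels on the AOI pixel list via the LWM transform."""
    if case.histology is None or case.control_points is None:
        raise ValueError("case lacks histology or control points")
    cps = case.control_points
    transform = fit_lwm_transform(
        cps[["x_mr", "y_mr"]].to_numpy(),
        cps[["x_hist", "y_hist"]].to_numpy())
    aoi = case.aoi()
    target = ImageGrid(np.zeros(aoi.shape), aoi.spacing, aoi.origin)
    warped = warp_label_map(case.histology, transform, target)
    return warped.values[aoi.values]


def prepare_case(case: MRICase, image_types, wg_grid=DEFAULT_WG_GRID,
                 with_labels: bool = True) -> CaseData:
    """Extract all feature stacks (and labels) for one case's AOI."""
    aoi = case.aoi()
    positions = np.argwhere(aoi.values)
    stacks = {}
    for name in image_types:
        if name not in case.images:
            continue
        plane = case.poi_image(name)
        for (W, G) in wg_grid:
            stacks[(name, W, G)] = extract_feature_stack(
                plane, aoi, FeatureSpec(W=W, G=G), image_type=name)
    labels = (transfer_histology_labels(case) if with_labels
              else np.full(positions.shape[0], NON_TUMOR, dtype=np.int16))
    return CaseData(case_id=case.case_id, positions=positions,
                    stacks=stacks, hist_labels=labels,
                    n_hist=float(case.n_hist)
                    if case.n_hist is not None else float("nan"))


# ---------------------------------------------------------------------------
# Fuzzy maps
# ---------------------------------------------------------------------------

@dataclass
class CaseFuzzy:
    """FCM outcome per (image type, W, G) for one case."""

    results: dict        # key -> FCMResult (U over all AOI pixels)
    training_maps: dict  # key -> FuzzyNecrosisMap (histology-designated)


def compute_case_fuzzy(case_data: CaseData, selection: dict,
                       seed: int = 0,
                       labels_available: bool = True) -> CaseFuzzy:
    """Run per-image FCM on selected features; designate via histology.

    Cluster designation (which cluster is necrosis) uses only pixels
    that carry a tumor label in the transferred histology map.  With
    ``labels_available=False`` (pure inference on an unlabeled case)
    only the raw FCM results are produced; designation then happens at
    prediction time through the model's polarity consensus.
    """
    results, maps = {}, {}
    valid = case_data.tumor_labeled
    nec = case_data.necrotic_labels
    for key, sel in selection.items():
        if key not in case_data.stacks or not sel:
            continue
        stack = case_data.stacks[key]
        X, _, _ = standardize_features(stack.X[:, sel])
        res = fcm_cluster(X, c=2, m=2.0, eps=1e-5,
                          seed=_stable_seed(case_data.case_id, key, seed))
        results[key] = res
        if not labels_available:
            continue
        sub = type(res)(U=res.U[valid], V=res.V, objective=res.objective,
                        objective_trace=res.objective_trace,
                        iterations=res.iterations,
                        final_center_shift=res.final_center_shift)
        adc_means = None
        if key[0] == ADC:
            orig = stack.X[:, 0]
            hard0 = res.U[:, 0] > 0.5
            adc_means = [orig[hard0].mean() if hard0.any() else -np.inf,
                         orig[~hard0].mean() if (~hard0).any() else -np.inf]
        desig = assign_necrosis_cluster(sub, labels=nec[valid],
                                        mean_adc_feature=adc_means,
                                        image_type=key[0])
        k = desig.necrosis_cluster
        direction = res.V[k] - res.V[1 - k]
        norm = np.linalg.norm(direction)
        maps[key] = FuzzyNecrosisMap(
            u=res.U[:, k].copy(), image_type=key[0], necrosis_cluster=k,
            necrosis_centroid=res.V[k].copy(),
            necrosis_direction=direction / (norm if norm > 0 else 1.0),
            agreement=desig.agreement)
    return CaseFuzzy(results=results, training_maps=maps)


def _anchor_positions(selection, key):
    """Positions of the intensity-anchored features (original value and
    window mean) inside the selected-feature list; falls back to all
    selected features if neither survived screening."""
    sel = selection[key]
    ai = [i for i, j in enumerate(sel) if j in (0, 1)]
    return ai if ai else list(range(len(sel)))


ANCHOR_FEATURES = (0, 1)  # original value and window mean


def raw_anchor_references(case_data: dict, ids, members, wg) -> dict:
    """Pooled raw-unit class means of the anchor features per image.

    The anchor features (original value, window mean) are in comparable
    units across cases — conventional images are intensity standardized
    and the derived maps are physical quantities — so their pooled
    necrotic / viable means serve as absolute class references for the
    single-class guard at prediction time.
    """
    W, G = wg
    out = {}
    for img in members:
        key = (img, W, G)
        if img in CONV_TYPES:
            # Landmark standardization aligns histograms, not tissue
            # classes: a nearly single-class tumor gets its class level
            # remapped toward the cohort-mixed landmarks, so
            # standardized conventional intensities are not absolutely
            # comparable across cases.  Physical derived maps are.
            out[img] = (None, None)
            continue
        nec_rows, via_rows = [], []
        for cid in ids:
            cd = case_data[cid]
            if key not in cd.stacks:
                continue
            X = cd.stacks[key].X[:, list(ANCHOR_FEATURES)]
            valid = cd.tumor_labeled
            nec = cd.necrotic_labels
            if (valid & nec).any():
                nec_rows.append(X[valid & nec].mean(axis=0))
            if (valid & ~nec).any():
                via_rows.append(X[valid & ~nec].mean(axis=0))
        out[img] = (np.mean(nec_rows, axis=0) if nec_rows else None,
                    np.mean(via_rows, axis=0) if via_rows else None)
    return out


def _designate_u(res, polarity_entry, raw_anchor_values=None,
                 anchor_ref=None, guard_frac: float = 0.995):
    """Necrosis membership vector for one image's FCM at inference.

    Normally the polarity consensus decides which cluster is necrosis.
    When raw anchor values and class references are available, a
    single-class guard fires if the per-pixel nearest-reference
    classification is unanimous beyond ``guard_frac`` — then the whole
    plane is assigned crisply to that class.  An all-viable or
    all-necrotic plane has no second class for the polarity rule to
    find (FCM splits within-class noise instead), but its raw anchor
    values sit unambiguously around one class reference.
    """
    ai, cvec = polarity_entry
    if raw_anchor_values is not None and anchor_ref is not None and \
            anchor_ref[0] is not None and anchor_ref[1] is not None:
        nec_ref, via_ref = anchor_ref
        d_nec = np.linalg.norm(raw_anchor_values - np.asarray(nec_ref),
                               axis=1)
        d_via = np.linalg.norm(raw_anchor_values - np.asarray(via_ref),
                               axis=1)
        frac_nec = float(np.mean(d_nec < d_via))
        if frac_nec >= guard_frac:
            return np.ones(res.U.shape[0])
        if frac_nec <= 1.0 - guard_frac:
            return np.zeros(res.U.shape[0])
    return designate_by_sign(res, ai, cvec).u


def polarity_consensus(case_fuzzy: dict, ids, selection: dict, members,
                       wg) -> dict:
    """Cohort-consensus polarity per image type at one (W, G).

    For each image, the mean (over training cases) sign of the necrotic-
    minus-viable cluster-center difference on the anchor features.  The
    polarity (necrosis darker on post-contrast T1, brighter on ADC, ...)
    is invariant to a case's necrosis fraction, unlike absolute centroid
    coordinates under per-case feature standardization, so it designates
    clusters reliably at inference time.
    """
    W, G = wg
    out = {}
    for img in members:
        key = (img, W, G)
        ai = _anchor_positions(selection, key)
        signs = [np.sign(case_fuzzy[cid].training_maps[key]
                         .necrosis_direction[ai])
                 for cid in ids if key in case_fuzzy[cid].training_maps]
        out[img] = (ai, np.mean(signs, axis=0))
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    subset: SubsetSpec
    objective: str
    wg: tuple                     # chosen (W, G)
    weights: WeightVector
    members: tuple                # image types actually fused (selection
                                  # may drop an image at some settings)
    selected: dict                # image type -> feature indices at wg
    centroids: dict               # image type -> reference necrosis centroid
    directions: dict              # image type -> necrosis-vs-viable direction
    polarity: dict                # image type -> (anchor idx, consensus sign)
    anchor_refs: dict             # image type -> raw (necrotic, viable) means
    training_objective: float
    step: float = DEFAULT_STEP
    per_wg_objective: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "subset": self.subset.name,
            "objective": self.objective,
            "W": self.wg[0], "G": self.wg[1],
            "weights": [float(w) for w in self.weights.weights],
            "members": list(self.members),
            "selected": {k: list(map(int, v))
                         for k, v in self.selected.items()},
            "centroids": {k: [float(x) for x in v]
                          for k, v in self.centroids.items()},
            "directions": {k: [float(x) for x in v]
                           for k, v in self.directions.items()},
            "polarity": {k: {"anchors": list(map(int, a)),
                             "consensus": [float(x) for x in c]}
                         for k, (a, c) in self.polarity.items()},
            "anchor_refs": {k: {"necrotic": [float(x) for x in n],
                                "viable": [float(x) for x in v]}
                            for k, (n, v) in self.anchor_refs.items()
                            if n is not None and v is not None},
            "training_objective": self.training_objective,
            "step": self.step,
        }

    @classmethod
    def from_dict(cls, d, subset: Optional[SubsetSpec] = None):
        from .core_io import SUBSETS
        subset = subset or SUBSETS[d["subset"]]
        return cls(
            subset=subset, objective=d["objective"],
            wg=(int(d["W"]), int(d["G"])),
            weights=WeightVector(np.asarray(d["weights"]),
                                 step=float(d.get("step", DEFAULT_STEP))),
            members=tuple(d["members"]),
            selected={k: list(map(int, v))
                      for k, v in d["selected"].items()},
            centroids={k: np.asarray(v)
                       for k, v in d.get("centroids", {}).items()},
            directions={k: np.asarray(v)
                        for k, v in d.get("directions", {}).items()},
            polarity={k: (list(map(int, e["anchors"])),
                          np.asarray(e["consensus"]))
                      for k, e in d.get("polarity", {}).items()},
            anchor_refs={k: (np.asarray(e["necrotic"]),
                             np.asarray(e["viable"]))
                         for k, e in d.get("anchor_refs", {}).items()},
            training_objective=float(d.get("training_objective", 0.0)),
            step=float(d.get("step", DEFAULT_STEP)))


def _members_with_selection(subset: SubsetSpec, selection: dict, wg):
    W, G = wg
    out = []
    for img in subset.members:
        if selection.get((img, W, G)):
            out.append(img)
    return tuple(out)


def _membership_matrix(fuzzy: CaseFuzzy, members, wg,
                       polarity: Optional[dict] = None,
                       case_data=None,
                       anchor_refs: Optional[dict] = None) -> np.ndarray:
    cols = []
    W, G = wg
    for img in members:
        key = (img, W, G)
        if polarity is None:
            cols.append(fuzzy.training_maps[key].u)
        else:
            raw = None
            if case_data is not None and key in case_data.stacks:
                raw = case_data.stacks[key].X[:, list(ANCHOR_FEATURES)]
            ref = anchor_refs.get(img) if anchor_refs else None
            cols.append(_designate_u(fuzzy.results[key], polarity[img],
                                     raw_anchor_values=raw,
                                     anchor_ref=ref))
    return np.stack(cols, axis=1)


def _reference_stats(case_fuzzy, ids, members, wg):
    """Mean necrosis centroid and unit direction over training cases."""
    W, G = wg
    centroids, directions = {}, {}
    for img in members:
        key = (img, W, G)
        maps = [case_fuzzy[cid].training_maps[key] for cid in ids
                if key in case_fuzzy[cid].training_maps]
        centroids[img] = np.mean([m.necrosis_centroid for m in maps], axis=0)
        d = np.mean([m.necrosis_direction for m in maps], axis=0)
        n = np.linalg.norm(d)
        directions[img] = d / (n if n > 0 else 1.0)
    return centroids, directions


def train_model(case_data: dict, case_fuzzy: dict, selection: dict,
                subset: SubsetSpec, objective: str = "min_avg",
                t: float = DEFAULT_STEP, wg_grid=DEFAULT_WG_GRID,
                case_ids=None) -> TrainedModel:
    """Optimize fusion weights and (W, G) for one MRI subset.

    ``case_data`` / ``case_fuzzy`` map case ids to prepared inputs;
    cases missing a subset member modality are skipped (their count
    reduces n, mirroring incomplete advanced-MRI acquisitions).
    """
    ids = list(case_ids if case_ids is not None else case_data)
    per_wg = {}
    fits = {}
    for wg in wg_grid:
        members = _members_with_selection(subset, selection, wg)
        if not members:
            logger.warning("no usable images for %s at %s", subset.name, wg)
            continue
        U_list, truths = [], []
        for cid in ids:
            fuzzy = case_fuzzy[cid]
            if any((img, wg[0], wg[1]) not in fuzzy.training_maps
                   for img in members):
                continue
            U_list.append(_membership_matrix(fuzzy, members, wg))
            truths.append(case_data[cid].n_hist)
        if not U_list:
            continue
        wvec, val, _ = optimize_weights(U_list, truths, t=t,
                                        objective=objective)
        per_wg[wg] = val
        fits[wg] = (wvec, members)
    if not per_wg:
        raise ValueError(f"subset {subset.name}: no trainable (W, G)")
    wg = select_wg(per_wg)
    val = per_wg[wg]
    wvec, members = fits[wg]
    W, G = wg
    centroids, directions = _reference_stats(case_fuzzy, ids, members, wg)
    polarity = polarity_consensus(case_fuzzy, ids, selection, members, wg)
    anchor_refs = raw_anchor_references(case_data, ids, members, wg)
    selected = {img: selection[(img, W, G)] for img in members}
    return TrainedModel(subset=subset, objective=objective, wg=wg,
                        weights=wvec, members=members, selected=selected,
                        centroids=centroids, directions=directions,
                        polarity=polarity, anchor_refs=anchor_refs,
                        training_objective=val, step=t,
                        per_wg_objective=per_wg)


def predict_case_aoi(model: TrainedModel, case_fuzzy: CaseFuzzy,
                     case_data=None,
                     use_training_designation: bool = False):
    """Fused necrosis estimate for one case's AOI.

    Inference designates each image's necrosis cluster by the model's
    stored polarity consensus (plus the raw-anchor single-class guard
    when ``case_data`` supplies the raw feature stacks);
    ``use_training_designation`` keeps the histology-derived
    designation instead (training-protocol readout).
    """
    U = _membership_matrix(
        case_fuzzy, model.members, model.wg,
        polarity=None if use_training_designation else model.polarity,
        case_data=case_data,
        anchor_refs=None if use_training_designation
        else model.anchor_refs)
    vmap = weighted_majority(
        [U[:, k] for k in range(U.shape[1])], model.weights)
    return necrosis_percentage(vmap), vmap


def loo_predictions(case_data: dict, case_fuzzy: dict, selection: dict,
                    subset: SubsetSpec, objective: str = "min_avg",
                    t: float = DEFAULT_STEP, wg_grid=DEFAULT_WG_GRID):
    """Leave-one-out necrosis estimates for every case.

    For each fold, fusion weights are refit on the remaining cases by
    the brute-force search, and (W, G) is chosen by the *worst inner
    leave-one-out error* within the training fold (selecting by
    training error was observed to pick scales that fit the fold but
    collapse on held-out cases; taking the worst inner error rather
    than the mean vetoes scales that collapse on any single training
    case).  Both the training-fold membership matrices and the
    held-out case use the inference-time designation (polarity
    consensus plus the raw-anchor guard), never histology: this keeps
    training and prediction consistent, so an image whose designation
    is unreliable reveals itself during weight fitting instead of only
    on the held-out case.
    """
    ids = list(case_data)
    truths = np.array([case_data[cid].n_hist for cid in ids])
    members_by_wg, wgrids = {}, {}
    for wg in wg_grid:
        members = _members_with_selection(subset, selection, wg)
        if not members:
            continue
        if any((img, wg[0], wg[1]) not in case_fuzzy[cid].training_maps
               for cid in ids for img in members):
            continue
        members_by_wg[wg] = members
        s = len(members)
        if s not in wgrids:
            wgrids[s] = enumerate_weight_grid(s, t)
    if not members_by_wg:
        raise ValueError(f"subset {subset.name}: no trainable (W, G)")

    # Designated membership columns differ between folds only when the
    # fold consensus flips a designation, which is rare; N(w) rows are
    # cached by their flip pattern so the expensive weight-grid
    # evaluation is shared across folds.
    row_cache = {}

    def designated_matrix(cid, wg, polarity, anchor_refs):
        cols, pattern = [], []
        W, G = wg
        for img in members_by_wg[wg]:
            key = (img, W, G)
            raw = case_data[cid].stacks[key].X[:, list(ANCHOR_FEATURES)]
            u = _designate_u(case_fuzzy[cid].results[key], polarity[img],
                             raw_anchor_values=raw,
                             anchor_ref=anchor_refs.get(img))
            cols.append(u)
            ref_u = case_fuzzy[cid].training_maps[key].u
            same = bool(np.array_equal(u > 0.5, ref_u > 0.5))
            pattern.append(same)
        return np.stack(cols, axis=1), tuple(pattern)

    def n_row(cid, wg, polarity, anchor_refs):
        U, pattern = designated_matrix(cid, wg, polarity, anchor_refs)
        key = (cid, wg, pattern)
        if key not in row_cache:
            row_cache[key] = evaluate_weight_grid(
                [U], wgrids[U.shape[1]])[0]
        return row_cache[key]

    out = {}
    for i, held in enumerate(ids):
        train_ids = [c for c in ids if c != held]
        tr_idx = np.array([j for j in range(len(ids)) if j != i])
        inner_cv, picks, train_obj = {}, {}, {}
        fold_refs = {}
        for wg, members in members_by_wg.items():
            polarity = polarity_consensus(case_fuzzy, train_ids,
                                          selection, members, wg)
            anchor_refs = raw_anchor_references(case_data, train_ids,
                                                members, wg)
            fold_refs[wg] = (polarity, anchor_refs)
            N = np.stack([n_row(c, wg, polarity, anchor_refs)
                          for c in train_ids])
            E = np.abs(N - truths[tr_idx][:, None])
            # inner LOO within the training fold scores this (W, G)
            inner_errs = []
            for jj in range(len(train_ids)):
                inner = np.array([x for x in range(len(train_ids))
                                  if x != jj])
                vals = (E[inner].mean(axis=0) if objective == "min_avg"
                        else E[inner].max(axis=0))
                inner_errs.append(E[jj, int(vals.argmin())])
            # worst-case inner error: a scale that collapses on any
            # single training case is vetoed, not averaged away
            inner_cv[wg] = float(np.max(inner_errs))
            # weights for this (W, G) are fit on the whole training fold
            vals = (E.mean(axis=0) if objective == "min_avg"
                    else E.max(axis=0))
            k = int(vals.argmin())
            picks[wg] = k
            train_obj[wg] = float(vals[k])
        wg = select_wg(inner_cv)
        members = members_by_wg[wg]
        wvec = WeightVector(wgrids[len(members)][picks[wg]], step=t)
        W, G = wg
        polarity, anchor_refs = fold_refs[wg]
        centroids, directions = _reference_stats(case_fuzzy, train_ids,
                                                 members, wg)
        model = TrainedModel(
            subset=subset, objective=objective, wg=wg, weights=wvec,
            members=members,
            selected={img: selection[(img, W, G)] for img in members},
            centroids=centroids, directions=directions, polarity=polarity,
            anchor_refs=anchor_refs,
            training_objective=train_obj[wg], step=t,
            per_wg_objective=inner_cv)
        n_aoi, vmap = predict_case_aoi(model, case_fuzzy[held],
                                       case_data=case_data[held])
        out[held] = {"n_aoi": n_aoi, "vmap": vmap, "model": model}
    return out


# ---------------------------------------------------------------------------
# VOI estimation
# ---------------------------------------------------------------------------

def estimate_voi_necrosis(model: TrainedModel, case: MRICase,
                          seed: int = 0):
    """Whole-tumor necrosis by running the per-plane pipeline slice-wise.

    Returns ``(N_VOI, viability volume)``; slices with fewer pixels than
    clusters are skipped with a warning.
    """
    if case.voi is None:
        raise ValueError("case has no VOI")
    W, G = model.wg
    volume = np.zeros(case.voi.shape, dtype=np.int8)
    n_necrotic = 0
    n_total = 0
    for z in range(case.voi.shape[2]):
        mask = case.voi.values[:, :, z]
        q = int(mask.sum())
        if q == 0:
            continue
        if q < 2:
            logger.warning("slice %d has %d pixel(s); skipped", z, q)
            continue
        cols = []
        for img in model.members:
            plane = ImageGrid(case.images[img].values[:, :, z],
                              case.images[img].spacing[:2])
            stack = extract_feature_stack(
                plane, MaskGrid(mask, role="AOI"), FeatureSpec(W=W, G=G),
                image_type=img)
            X, _, _ = standardize_features(stack.X[:, model.selected[img]])
            res = fcm_cluster(X, c=2, m=2.0, eps=1e-5,
                              seed=_stable_seed(case.case_id, img, z, seed))
            u = _designate_u(res, model.polarity[img],
                             raw_anchor_values=stack.X[:,
                                                       list(ANCHOR_FEATURES)],
                             anchor_ref=model.anchor_refs.get(img))
            cols.append(u)
        vmap = weighted_majority(cols, model.weights)
        plane_out = np.zeros(mask.shape, dtype=np.int8)
        plane_out[mask] = np.where(vmap.y, NECROTIC, 1)
        volume[:, :, z] = plane_out
        n_necrotic += int(vmap.y.sum())
        n_total += q
    if n_total == 0:
        raise ValueError("VOI contains no usable slices")
    return 100.0 * n_necrotic / n_total, volume


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

def evaluate_cases(model: TrainedModel, case_data: dict, case_fuzzy: dict,
                   predictions: Optional[dict] = None) -> pd.DataFrame:
    """Per-case report: errors, Dice/overlap, responder calls.

    ``predictions`` may carry leave-one-out estimates (``{id: {"n_aoi",
    "vmap"}}``); otherwise the model's own training-designation readout
    is used.  Dice/overlap compare the histology-transferred necrotic
    pixel set with the MRI-estimated one on the AOI.
    """
    rows = []
    for cid, cd in case_data.items():
        if predictions is not None and cid in predictions:
            n_aoi = predictions[cid]["n_aoi"]
            vmap = predictions[cid]["vmap"]
        else:
            n_aoi, vmap = predict_case_aoi(model, case_fuzzy[cid],
                                           use_training_designation=True)
        a_nec = cd.necrotic_labels
        b_nec = vmap.y
        rows.append({
            "case_id": cid,
            "n_hist": cd.n_hist,
            "n_aoi": n_aoi,
            "abs_error": abs(n_aoi - cd.n_hist),
            "dice": dice_coefficient(a_nec, b_nec),
            "overlap": overlap_coefficient(a_nec, b_nec),
            "responder_hist": classify_responder(cd.n_hist),
            "responder_mri": classify_responder(n_aoi),
        })
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame) -> dict:
    """Cohort mean +/- SEM of the evaluation columns."""
    out = {}
    for col in ("abs_error", "dice", "overlap"):
        vals = report[col].dropna().to_numpy()
        out[col] = {"mean": float(np.mean(vals)),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else 0.0,
                    "n": int(len(vals))}
    out["responder_accuracy"] = float(
        (report.responder_hist == report.responder_mri).mean())
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def prepare_cohort(cases, image_types, wg_grid=DEFAULT_WG_GRID,
                   alpha: float = 0.05, seed: int = 0,
                   standardize: bool = True):
    """Standardize, label-transfer, extract, screen and cluster a cohort.

    Returns ``(case_data, case_fuzzy, significance table)``.
    """
    if standardize:
        standardize_conventional(cases)
    case_data = {}
    for case in cases:
        case_data[case.case_id] = prepare_case(case, image_types, wg_grid)
    stacks_by_case = {cid: cd.stacks for cid, cd in case_data.items()}
    # ANOVA pools only pixels carrying a tumor label in histology.
    filt_stacks, filt_labels = {}, {}
    for cid, cd in case_data.items():
        valid = cd.tumor_labeled
        filt_stacks[cid] = {
            k: type(st)(positions=st.positions[valid], X=st.X[valid],
                        spec=st.spec, image_type=st.image_type)
            for k, st in cd.stacks.items()}
        filt_labels[cid] = cd.necrotic_labels[valid]
    sig = select_features(filt_stacks, filt_labels, alpha=alpha)
    case_fuzzy = {cid: compute_case_fuzzy(cd, sig.selected, seed=seed)
                  for cid, cd in case_data.items()}
    return case_data, case_fuzzy, sig
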