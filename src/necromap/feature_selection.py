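"""ANOVA screening of features for necrosis-vs-viable discrimination.

For every image type, feature and (W, G), pixels are pooled across the
training cases into a necrotic and a viable group (labels transferred
from histology) and a one-way fixed-effects ANOVA with unequal sample
sizes tests whether the feature differs between the groups.  A feature
is *highly significant* if P < 0.001, *significant* if
0.001 <= P < 0.05 and *not significant* otherwise; only the first two
tiers enter the classifier.  No multiple-testing correction is applied
by default (a Benjamini-Hochberg option exists behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .texture_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

HIGHLY_SIGNIFICANT = "highly_significant"
SIGNIFICANT = "significant"
NOT_SIGNIFICANT = "not_significant"


def tier_of(p: float, high: float = 0.001, low: float = 0.05) -> str:
    """Three-tier label; a pure function of p and the two cutoffs."""
    if p < high:
        return HIGHLY_SIGNIFICANT
    if p < low:
        return SIGNIFICANT
    return NOT_SIGNIFICANT


def anova_p(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """One-way fixed-effects F-test p-value for two unequal groups.

    Degenerate inputs: zero within-group variance with equal means gives
    p = 1 (no evidence), with unequal means p = 0 (perfect separation).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.size + b.size < 3:
        raise ValueError("combined sample size must be at least 3")
    if a.var() == 0 and b.var() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        logger.debug("degenerate ANOVA input, p=%g", p)
        return p
    _, p = stats.f_oneway(a, b)
    return float(p)


@dataclass
class SignificanceTable:
    """Per-(image, feature, W, G) p-values and tiers, plus selections."""

    table: pd.DataFrame
    #: (image_type, W, G) -> sorted list of selected feature indices
    selected: dict

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def heatmap(self, W: int, G: int, ax=None):
        """Three-tier significance heatmap (features x image types)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        sub = self.table[(self.table.W == W) & (self.table.G == G)]
        images = sorted(sub.image_type.unique())
        mat = np.full((len(FEATURE_NAMES), len(images)), 2.0)
        code = {HIGHLY_SIGNIFICANT: 0, SIGNIFICANT: 1, NOT_SIGNIFICANT: 2}
        for _, row in sub.iterrows():
            mat[FEATURE_NAMES.index(row.feature),
                images.index(row.image_type)] = code[row.tier]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(mat, cmap=ListedColormap(["#9ecae1", "#4292c6", "#084594"]),
                  vmin=0, vmax=2, aspect="auto")
        ax.set_xticks(range(len(images)), images, rotation=90)
        ax.set_yticks(range(len(FEATURE_NAMES)), FEATURE_NAMES, fontsize=6)
        ax.set_title(f"W={W}, G={G}")
        return ax


def select_features(stacks_by_case: dict, labels_by_case: dict,
                    alpha: float = 0.05, bh_correction: bool = False
                    ) -> SignificanceTable:
    """Screen pooled features and select the significant ones.

    Parameters
    ----------
    stacks_by_case
        ``{case_id: {(image_type, W, G): FeatureStack}}`` for the
        training cases.
    labels_by_case
        ``{case_id: boolean array}`` aligned with each case's AOI pixel
        list, True = necrotic (histology-transferred).  Pixels labeled
        non-tumor in histology must already be excluded by the caller or
        marked via a separate mask; here every pixel is pooled into one
        of the two groups.
    alpha
        Selection threshold on the (optionally BH-adjusted) p-value.
    """
    keys = sorted({k for stacks in stacks_by_case.values() for k in stacks})
    rows = []
    selected = {}
    pooled_nec_any = False
    pooled_via_any = False
    for key in keys:
        image_type, W, G = key
        nec_cols, via_cols = [], []
        for case_id, stacks in stacks_by_case.items():
            if key not in stacks:
                continue
            X = stacks[key].X
            lab = np.asarray(labels_by_case[case_id], dtype=bool)
            nec_cols.append(X[lab])
            via_cols.append(X[~lab])
        nec = np.concatenate(nec_cols, axis=0) if nec_cols else np.empty((0, 0))
        via = np.concatenate(via_cols, axis=0) if via_cols else np.empty((0, 0))
        if nec.shape[0] == 0:
            raise ValueError("no pixels of class 'necrotic' in pooled data")
        if via.shape[0] == 0:
            raise ValueError("no pixels of class 'viable' in pooled data")
        pooled_nec_any = pooled_via_any = True
        ps = np.array([anova_p(nec[:, j], via[:, j])
                       for j in range(nec.shape[1])])
        p_adj = ps
        if bh_correction:
            order = np.argsort(ps)
            ranked = ps[order] * len(ps) / (np.arange(len(ps)) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            p_adj = np.empty_like(ps)
            p_adj[order] = np.clip(adj, 0, 1)
        sel = [j for j in range(len(ps)) if p_adj[j] < alpha]
        selected[key] = sel
        if not sel:
            logger.warning(
                "no significant features for %s at (W=%d, G=%d); the image "
                "will be dropped from subsets at this setting",
                image_type, W, G)
        for j, p in enumerate(ps):
            rows.append({"image_type": image_type, "feature":
                         FEATURE_NAMES[j], "W": W, "G": G, "p_value": p,
                         "tier": tier_of(p),
                         "n_necrotic": nec.shape[0],
                         "n_viable": via.shape[0]})
    return SignificanceTable(table=pd.DataFrame(rows), selected=selected)
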