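"""Two-condition differential statistics on log2 (phospho)proteome matrices.

The core contrast is treated-vs-control within one genotype: a per-feature
two-sample t-test on log2 intensities with Benjamini-Hochberg control of the
false discovery rate (significance at FDR < 0.1 by default).  Phospho
matrices are first restricted to confidently localized class I sites
(localization probability >= 0.75).  Also provides replicate QC (pairwise
Pearson correlation), cross-context comparison of significant sets, and
hierarchical clustering of modulated features.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import CLASS_I_THRESHOLD, OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.1


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone after sorting, each adjusted value >= its raw value, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:  # m=1 step-up is the identity
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialTable:
    """Per-feature differential result for one contrast.

    ``table`` is indexed by feature with columns ``log2fc`` (treated minus
    control mean), ``t_stat``, ``df``, ``p_value``, ``fdr``, ``significant``,
    ``n_treated``, ``n_control``.  Features with fewer than two complete
    values in either group are excluded and listed in ``excluded``.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    fdr_threshold: float
    excluded: tuple[str, ...] = ()
    n_loc_filtered: int = 0

    @property
    def features(self) -> pd.Index:
        return self.table.index

    def significant_features(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def signed_significant(self, direction: str) -> set[str]:
        """Significant features changed 'up' or 'down' (by log2fc sign)."""
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        sig = self.table[self.table["significant"]]
        mask = sig["log2fc"] > 0 if direction == "up" else sig["log2fc"] < 0
        return set(sig.index[mask])


def differential_stats(
    matrix: OmicsMatrix,
    contrast: tuple[str, str],
    fdr_threshold: float = DEFAULT_FDR,
    flavor: str = "student",
    min_per_group: int = 2,
    loc_prob_threshold: float = CLASS_I_THRESHOLD,
) -> DifferentialTable:
    """Per-feature t-test between two conditions of an intensity matrix.

    Parameters
    ----------
    contrast:
        ``(treated_condition, control_condition)`` labels of the form
        ``'<genotype>.<treatment>'``; log2fc is treated minus control.
    flavor:
        ``'student'`` (pooled-variance, default) or ``'welch'``.
    """
    treated_cond, control_cond = contrast
    if flavor not in ("student", "welch"):
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must lie in (0, 1]")
    mat = matrix.class_i(loc_prob_threshold)
    n_loc_filtered = matrix.n_features - mat.n_features
    cols_t = mat.columns_for(treated_cond)
    cols_c = mat.columns_for(control_cond)
    if not cols_t:
        raise ValueError(f"condition {treated_cond!r} absent from sample annotations")
    if not cols_c:
        raise ValueError(f"condition {control_cond!r} absent from sample annotations")

    a = mat.values[cols_t].to_numpy(dtype=float)
    b = mat.values[cols_c].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    keep = (n1 >= min_per_group) & (n2 >= min_per_group)
    excluded = tuple(np.asarray(mat.features)[~keep])
    if excluded:
        logger.info("excluded %d features with <%d complete values per group",
                    len(excluded), min_per_group)
    a, b, n1, n2 = a[keep], b[keep], n1[keep], n2[keep]
    features = pd.Index(np.asarray(mat.features)[keep], name="feature")

    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        log2fc = m1 - m2
        if flavor == "student":
            df = n1 + n2 - 2.0
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate zero-variance features: no spread and no shift -> null
    # (t=0, p=1); no spread but a shift -> infinitely confident (p=0)
    zero_se = ~np.isfinite(t)
    t = np.where(zero_se & (log2fc == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (log2fc != 0), np.sign(log2fc) * np.inf, t)
    p = np.where(zero_se & (log2fc == 0), 1.0, p)
    p = np.where(zero_se & (log2fc != 0), 0.0, p)

    fdr = bh_adjust(p) if len(p) else np.array([])
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
            "n_treated": n1.astype(int),
            "n_control": n2.astype(int),
        },
        index=features,
    )
    return DifferentialTable(
        table=table,
        contrast=(treated_cond, control_cond),
        fdr_threshold=fdr_threshold,
        excluded=excluded,
        n_loc_filtered=n_loc_filtered,
    )


def replicate_correlation(
    matrix: OmicsMatrix, floor: float = 0.75
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson correlation between samples (pairwise-complete values).

    Returns the correlation matrix and a QC report flagging replicate pairs
    (same genotype and treatment) whose correlation falls below ``floor`` or
    is undefined (fewer than two overlapping non-missing values).
    """
    if len(matrix.values.columns) < 2:
        raise ValueError("replicate QC needs at least two samples")
    corr = matrix.values.corr(method="pearson", min_periods=2)
    warnings = []
    for s1, s2 in itertools.combinations(sorted(matrix.samples), 2):
        a1, a2 = matrix.samples[s1], matrix.samples[s2]
        if (a1.genotype, a1.treatment) != (a2.genotype, a2.treatment):
            continue
        r = corr.loc[s1, s2]
        if np.isnan(r):
            warnings.append({"pair": [s1, s2], "r": None, "reason": "undefined"})
        elif r < floor:
            warnings.append({"pair": [s1, s2], "r": float(r), "reason": "below_floor"})
    report = {
        "floor": floor,
        "n_pairs_checked": sum(
            1
            for s1, s2 in itertools.combinations(matrix.samples.values(), 2)
            if (s1.genotype, s1.treatment) == (s2.genotype, s2.treatment)
        ),
        "warnings": warnings,
    }
    return corr, report


def compare_significant_sets(tables: dict[str, DifferentialTable]) -> dict:
    """Overlap of significant features across >= 2 contexts (the 'common core')."""
    if len(tables) < 2:
        raise ValueError("need at least two contexts to compare")
    sig = {ctx: t.significant_features() for ctx, t in tables.items()}
    inter = set.intersection(*sig.values())
    union = set.union(*sig.values())
    return {
        "per_context": {ctx: sorted(s) for ctx, s in sorted(sig.items())},
        "per_context_counts": {ctx: len(s) for ctx, s in sorted(sig.items())},
        "intersection": sorted(inter),
        "intersection_count": len(inter),
        "union": sorted(union),
        "union_count": len(union),
        "only": {
            ctx: sorted(s - set.union(*(o for c, o in sig.items() if c != ctx)))
            for ctx, s in sorted(sig.items())
        },
    }


def cluster_features(
    matrix: OmicsMatrix,
    k: int,
    features=None,
) -> pd.Series:
    """Hierarchical clustering of (significant) feature profiles into k clusters.

    Rows are z-scored across samples, distance is 1 - Pearson correlation,
    linkage is average, and the tree is cut into ``k`` clusters.  Features
    are processed in lexicographic order and clusters renumbered 1..k by
    first appearance, so the output is deterministic.
    """
    feats = sorted(features) if features is not None else sorted(matrix.features)
    feats = [f for f in feats if f in matrix.values.index]
    if k < 1 or k > len(feats):
        raise ValueError(f"k must lie in 1..{len(feats)}, got {k}")
    data = matrix.values.loc[feats].to_numpy(dtype=float)
    if np.isnan(data).any():
        # complete-case columns only for the clustering distance
        keep_cols = ~np.isnan(data).any(axis=0)
        data = data[:, keep_cols]
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (data - mu) / sd
    z[~np.isfinite(z)] = 0.0  # flat profiles: maximally uninformative
    if k == 1 or len(feats) == 1:
        return pd.Series(1, index=pd.Index(feats, name="feature"), name="cluster")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(z)
    r = np.nan_to_num(r, nan=0.0)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for label in raw:
        if label not in relabel:
            relabel[label] = len(relabel) + 1
    out = pd.Series([relabel[l] for l in raw], index=pd.Index(feats, name="feature"),
                    name="cluster")
    return out
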