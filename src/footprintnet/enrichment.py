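"""Over-representation analysis and phenotype arithmetic.

ORA tests each gene set for over-representation in a query (e.g. the nodes
of a mechanistic model, or the phosphosites up-regulated by treatment)
against a measured-feature universe with a one-sided hypergeometric test;
multiplicity is controlled with Benjamini-Hochberg and the enrichment score
is -log10(adjusted p), so a score above 3 corresponds to adjusted p below
1e-3.  Kinase-substrate set enrichment applies the same machinery with each
regulator's target-site set as a gene set.

Also implements the two small phenotype formulas used to compare treatment
arms: treatment-induced relative apoptosis and the Bliss-independence
excess for drug combinations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .activity import RegulonSet
from .differential import DifferentialTable, bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ENRICH_FDR = 0.05
DEFAULT_ES_THRESHOLD = 3.0

RESULT_COLUMNS = [
    "set_name", "overlap", "set_size", "query_size", "universe_size",
    "fold_enrichment", "p_value", "adjusted_p", "enrichment_score",
    "significant", "es_above_threshold",
]


def ora(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = DEFAULT_ENRICH_FDR,
    es_threshold: float = DEFAULT_ES_THRESHOLD,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in the query.

    Set membership and the query are intersected with the universe first;
    query items outside the universe are dropped with a warning.  For a
    universe of size M, a set of size K, a query of size n and overlap k the
    p-value is P(X >= k) with X ~ Hypergeom(M, K, n).
    """
    universe = {str(u) for u in universe}
    if not universe:
        raise ValueError("the universe must be non-empty")
    query = {str(q) for q in query}
    outside = query - universe
    if outside:
        logger.warning("dropped %d query items outside the universe", len(outside))
        query &= universe
    M, n = len(universe), len(query)
    names, overlaps, sizes, folds, pvals = [], [], [], [], []
    for name, members in collection.items():
        members_u = members & universe
        K = len(members_u)
        k = len(members_u & query)
        names.append(name)
        overlaps.append(k)
        sizes.append(K)
        folds.append((k / n) / (K / M) if n and K else np.nan)
        pvals.append(min(float(stats.hypergeom.sf(k - 1, M, K, n)), 1.0) if K else 1.0)
    if not names:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    pvals = np.asarray(pvals)
    adj = bh_adjust(pvals)
    with np.errstate(divide="ignore"):
        es = -np.log10(adj)
    order = np.lexsort((np.asarray(names, dtype=object), adj))
    return pd.DataFrame(
        {
            "set_name": np.asarray(names, dtype=object)[order],
            "overlap": np.asarray(overlaps)[order],
            "set_size": np.asarray(sizes)[order],
            "query_size": n,
            "universe_size": M,
            "fold_enrichment": np.asarray(folds)[order],
            "p_value": pvals[order],
            "adjusted_p": adj[order],
            "enrichment_score": es[order],
            "significant": adj[order] < alpha,
            "es_above_threshold": es[order] > es_threshold,
        },
        columns=RESULT_COLUMNS,
    )


def kinase_set_enrichment(
    diff_phospho: DifferentialTable,
    regulons: RegulonSet,
    direction: str = "up",
    alpha: float = DEFAULT_ENRICH_FDR,
    es_threshold: float = DEFAULT_ES_THRESHOLD,
) -> pd.DataFrame:
    """Substrate-set enrichment among significantly changed phosphosites.

    Query = significant class I sites changed in ``direction``; one set per
    regulator (its target sites); universe = all measured class I sites.
    A small adjusted p for a kinase's set means its substrates are
    over-represented among the regulated sites — evidence the kinase's
    activity changed.
    """
    if len(regulons) == 0:
        raise ValueError("regulons must be non-empty")
    universe = set(diff_phospho.table.index.astype(str))
    query = diff_phospho.signed_significant(direction)
    collection = GeneSetCollection(
        {reg: {t for t, _ in regulon.targets} for reg, regulon in regulons.items()}
    )
    return ora(query, collection, universe, alpha=alpha, es_threshold=es_threshold)


def relative_apoptosis(
    dead_treated: float, dead_control: float, viable_control: float
) -> float:
    """Treatment-induced apoptosis relative to the viable control population.

    ``100 * (dead_treated - dead_control) / viable_control``; negative values
    indicate protection.
    """
    if viable_control <= 0:
        raise ValueError("viable_control must be > 0")
    if dead_treated < 0 or dead_control < 0:
        raise ValueError("cell fractions must be >= 0")
    return 100.0 * (dead_treated - dead_control) / viable_control


def bliss_excess(f_a: float, f_b: float, f_ab: float) -> float:
    """Excess kill of a drug combination over Bliss independence.

    The Bliss expectation for independent agents with kill fractions
    ``f_a`` and ``f_b`` is ``f_a + f_b - f_a * f_b``; a positive excess of
    the observed combination kill ``f_ab`` over it indicates synergy, about
    zero additivity, negative antagonism.
    """
    for name, val in (("f_a", f_a), ("f_b", f_b), ("f_ab", f_ab)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    return f_ab - (f_a + f_b - f_a * f_b)
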