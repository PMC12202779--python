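"""Alpha diversity, rarefaction, group comparison, beta-diversity distances.

Alpha metrics are the standard amplicon set (observed features, bias-corrected
Chao1, Shannon in bits, Gini-Simpson). Beta distances are Bray-Curtis on raw
counts, Jaccard on presence/absence, and unweighted UniFrac on a phylogeny.
Alpha metric values are delegated to scikit-bio; pairwise distances to
scipy/scikit-bio.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as _alpha
from skbio.diversity import beta_diversity as _beta_diversity

from .errors import GroupingError, MetricError
from .io import OtuTable

__all__ = [
    "ALPHA_METRICS",
    "alpha_diversity",
    "alpha_table",
    "rarefy",
    "rarefaction_curve",
    "kruskal_wallis",
    "beta_distance",
    "unweighted_unifrac",
]

ALPHA_METRICS = ("observed", "chao1", "shannon", "simpson")


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise MetricError("counts must be a 1-D vector")
    if counts.size == 0 or counts.sum() <= 0:
        raise MetricError("all-zero or empty count vector")
    if counts.min() < 0:
        raise MetricError("negative counts")
    return counts


def alpha_diversity(counts: Sequence[int], metric: str,
                    shannon_base: float = 2.0,
                    chao1_bias_corrected: bool = True) -> float:
    """One sample's alpha diversity.

    observed: number of taxa with count > 0. chao1 (bias-corrected):
    S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton counts.
    shannon: -sum p log p, base 2 by default (bits). simpson: Gini-Simpson
    1 - sum p^2.
    """
    counts = _check_counts(counts)
    if metric == "observed":
        return float(_alpha.observed_features(counts))
    if metric == "chao1":
        return float(_alpha.chao1(counts, bias_corrected=chao1_bias_corrected))
    if metric == "shannon":
        return float(_alpha.shannon(counts, base=shannon_base))
    if metric == "simpson":
        return float(_alpha.simpson(counts))
    raise MetricError(f"unknown alpha metric {metric!r}")


def alpha_table(table: OtuTable, metrics: Sequence[str] = ALPHA_METRICS,
                **kwargs) -> pd.DataFrame:
    """Per-sample alpha diversity table (samples x metrics)."""
    rows = {s: {m: alpha_diversity(table.counts[:, i], m, **kwargs)
                for m in metrics}
            for i, s in enumerate(table.sample_ids)}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(metrics))


def rarefy(counts: Sequence[int], depth: int, seed: int) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    counts = _check_counts(counts).astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise MetricError(f"rarefaction depth {depth} exceeds total {total}")
    if depth == total:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefaction_curve(table: OtuTable, depths: Sequence[int], reps: int = 10,
                      seed: int = 0, truncate: bool = False) -> pd.DataFrame:
    """Mean observed richness per sample over a grid of rarefaction depths.

    Depths must be ascending and, unless ``truncate`` is set, no larger than
    the shallowest sample; with ``truncate`` a sample's own total caps its
    depths. Replicate subsamples share one seeded generator stream, so the
    whole curve is a pure function of (table, depths, reps, seed).
    """
    depths = list(depths)
    if not depths:
        raise MetricError("empty depth grid")
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise MetricError("depth grid must be strictly ascending")
    totals = table.counts.sum(axis=0)
    if not truncate and depths[-1] > totals.min():
        raise MetricError(
            f"max depth {depths[-1]} exceeds shallowest sample ({totals.min()})")
    rng = np.random.default_rng(seed)
    out = np.full((table.n_samples, len(depths)), np.nan)
    for i, s in enumerate(table.sample_ids):
        col = table.counts[:, i]
        for j, d in enumerate(depths):
            if d > totals[i]:
                continue
            obs = [np.count_nonzero(rng.multivariate_hypergeometric(col, d))
                   if d < totals[i] else np.count_nonzero(col)
                   for _ in range(reps)]
            out[i, j] = float(np.mean(obs))
    return pd.DataFrame(out, index=list(table.sample_ids), columns=depths)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups."""
    if len(groups) < 2:
        raise GroupingError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise GroupingError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise GroupingError("need >= 3 observations in total")
    h, p = kruskal(*groups)
    return float(h), float(p)


def beta_distance(table: OtuTable, metric: str) -> DistanceMatrix:
    """Pairwise sample dissimilarity: Bray-Curtis on counts or Jaccard on
    presence/absence."""
    X = table.counts.T.astype(np.float64)
    if (X.sum(axis=1) <= 0).any():
        bad = table.sample_ids[int(np.argmax(X.sum(axis=1) <= 0))]
        raise MetricError(f"sample {bad!r} has zero total count")
    if table.n_samples < 2:
        raise MetricError("need >= 2 samples")
    if metric == "bray_curtis":
        d = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(X > 0, metric="jaccard")
    else:
        raise MetricError(f"unknown beta metric {metric!r}")
    return DistanceMatrix(squareform(d), ids=list(table.sample_ids))


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / (shared + unique) branch length between
    the communities' subtrees."""
    leaf_names = {t.name for t in tree.tips()}
    missing = [o for i, o in enumerate(table.otu_ids)
               if table.counts[i].any() and o not in leaf_names]
    if missing:
        raise MetricError(
            f"OTU {missing[0]!r} has reads but is not a leaf of the tree")
    present = [i for i, o in enumerate(table.otu_ids) if o in leaf_names]
    sub_ids = [table.otu_ids[i] for i in present]
    X = table.counts[present, :].T
    return _beta_diversity("unweighted_unifrac", X,
                           ids=list(table.sample_ids), taxa=sub_ids, tree=tree)
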