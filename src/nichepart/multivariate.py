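"""Ordination, PERMANOVA, and differential-taxon detection.

PCoA is classical metric scaling: eigendecompose the Gower double-centred
matrix of squared dissimilarities; axes with positive eigenvalues carry the
embedding, negative eigenvalues are reported but their axes dropped. NMDS
minimises Kruskal stress-1 by alternating a pool-adjacent-violators isotonic
fit of configuration distances on dissimilarity ranks with a Guttman
(SMACOF) configuration update; the best of several seeded restarts is kept.

PERMANOVA partitions the total sum of squared dissimilarities into among- and
within-group parts and referenes the pseudo-F to a permutation null built by
shuffling group labels. The differential-taxon detector is a deliberately
simplified LEfSe-style screen: a per-taxon Kruskal-Wallis test followed by a
log10 effect size on the counts-per-million scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .errors import GroupingError, MetricError
from .io import OtuTable, SampleMetadata

__all__ = [
    "Ordination",
    "PermanovaResult",
    "DifferentialTaxon",
    "pcoa",
    "nmds",
    "isotonic_fit",
    "permanova",
    "pairwise_permanova",
    "bh_adjust",
    "differential_taxa",
]


@dataclass(frozen=True)
class Ordination:
    ids: tuple[str, ...]
    coords: np.ndarray = field(repr=False)
    method: str = "pcoa"
    eigenvalues: np.ndarray | None = field(default=None, repr=False)
    proportion_explained: np.ndarray | None = field(default=None, repr=False)
    stress: float | None = None
    converged: bool = True


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    df_among: int
    df_within: int
    method: str = "monte_carlo"  # or "exhaustive"


@dataclass(frozen=True)
class DifferentialTaxon:
    taxon: str
    enriched_group: str
    kw_p: float
    effect_size: float


# ---------------------------------------------------------------------------
# ordination


def pcoa(D: DistanceMatrix) -> Ordination:
    """Classical metric scaling (principal coordinates analysis)."""
    n = D.shape[0]
    if n < 3:
        raise MetricError("PCoA needs >= 3 samples")
    d2 = np.asarray(D.data, dtype=np.float64) ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1])) * 1e-12 if n else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    coords = coords - coords.mean(axis=0)  # numerically exact centring
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return Ordination(ids=tuple(D.ids), coords=coords, method="pcoa",
                      eigenvalues=eigvals, proportion_explained=prop)


def isotonic_fit(x: Sequence[float]) -> np.ndarray:
    """Least-squares monotone non-decreasing fit (pool adjacent violators)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise MetricError("isotonic fit of an empty vector")
    return isotonic_regression(x).x


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d * d))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((d - dhat) ** 2)) / denom)


def _nmds_single(D: np.ndarray, X: np.ndarray, max_iter: int, tol: float,
                 ) -> tuple[np.ndarray, float, list[float], bool]:
    """One NMDS run from an initial configuration.

    Alternates isotonic disparities (on the fixed dissimilarity ranks) with a
    Guttman transform; an update is only accepted while stress-1 decreases,
    so the recorded stress history is non-increasing by construction.
    """
    n = D.shape[0]
    delta = squareform(D, checks=False)
    order = np.argsort(delta, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)

    def disparities(d: np.ndarray) -> np.ndarray:
        dhat = isotonic_fit(d[order])[inv]
        # rescale so the Guttman step targets distances on the current scale
        ss = float(np.sum(dhat * dhat))
        if ss > 0:
            dhat = dhat * math.sqrt(float(np.sum(d * d)) / ss)
        return dhat

    d = pdist(X)
    dhat = disparities(d)
    history = [_stress1(d, dhat)]
    converged = False
    for _ in range(max_iter):
        # Guttman transform with the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        Bmat = -squareform(ratio, checks=False)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X_new = (Bmat @ X) / n
        d_new = pdist(X_new)
        dhat_new = disparities(d_new)
        s_new = _stress1(d_new, dhat_new)
        if s_new > history[-1] - 1e-15:
            converged = s_new >= history[-1] - tol
            break
        X, d, dhat = X_new, d_new, dhat_new
        history.append(s_new)
        if history[-2] - history[-1] < tol:
            converged = True
            break
    X = X - X.mean(axis=0)
    return X, history[-1], history, converged


def nmds(D: DistanceMatrix, k: int = 2, seed: int = 0, restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-7,
         return_history: bool = False):
    """Non-metric MDS minimising Kruskal stress-1.

    The first restart starts from the PCoA configuration (truncated or padded
    to ``k`` axes); the rest add seeded Gaussian jitter. Non-convergence is
    flagged on the result, never raised.
    """
    n = D.shape[0]
    if k < 1 or n < k + 1:
        raise MetricError("NMDS needs n >= k + 1 and k >= 1")
    Dm = np.asarray(D.data, dtype=np.float64)
    base = pcoa(D).coords
    if base.shape[1] >= k:
        base = base[:, :k]
    else:
        base = np.hstack([base, np.zeros((n, k - base.shape[1]))])
    scale = max(Dm.max(), 1e-12)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(restarts, 1)):
        X0 = base if r == 0 else base + rng.normal(0.0, 0.1 * scale, base.shape)
        X, stress, history, conv = _nmds_single(Dm, X0.copy(), max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history, conv)
    X, stress, history, conv = best
    ord_ = Ordination(ids=tuple(D.ids), coords=X, method="nmds",
                      stress=stress, converged=conv)
    return (ord_, history) if return_history else ord_


# ---------------------------------------------------------------------------
# PERMANOVA


def _align_labels(D: DistanceMatrix, meta: SampleMetadata,
                  ) -> tuple[np.ndarray, list[str]]:
    labels = [meta.group_of(s) for s in D.ids]
    uniq: dict[str, int] = {}
    for g in labels:
        uniq.setdefault(g, len(uniq))
    return np.array([uniq[g] for g in labels]), list(uniq)


def _pseudo_F(d2: np.ndarray, label_idx: np.ndarray, n_groups: int,
              group_sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for one or many label assignments.

    ``label_idx``: (n,) or (P, n) integer group indices. Uses
    SS_total = sum_{i<j} d_ij^2 / N and SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2.
    """
    n = d2.shape[0]
    single = label_idx.ndim == 1
    L = label_idx[None, :] if single else label_idx
    M = np.zeros((L.shape[0], n, n_groups))
    M[np.arange(L.shape[0])[:, None], np.arange(n)[None, :], L] = 1.0
    within = np.einsum("pig,ij,pjg->pg", M, d2, M) / 2.0
    ss_within = (within / group_sizes[None, :]).sum(axis=1)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    F = (ss_among / df_among) / (ss_within / df_within)
    return F[0] if single else F


def permanova(D: DistanceMatrix, meta: SampleMetadata, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with label permutations.

    Monte-Carlo p uses the standard +1 correction,
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1). When ``n_perm`` meets or
    exceeds the number of distinct label orderings the test switches to
    exhaustive enumeration of all orderings (identity included), so
    p = #{F >= F_obs} / N! exactly and Monte-Carlo p equals exhaustive p in
    that regime.
    """
    if n_perm < 1:
        raise MetricError("n_perm must be >= 1")
    label_idx, groups = _align_labels(D, meta)
    g = len(groups)
    if g < 2:
        raise GroupingError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(label_idx, minlength=g)
    if sizes.min() < 2:
        raise GroupingError("every group needs >= 2 samples")
    n = D.shape[0]
    d2 = np.asarray(D.data, dtype=np.float64) ** 2
    F_obs = float(_pseudo_F(d2, label_idx, g, sizes))

    n_total = math.factorial(n)
    if n_perm >= n_total - 1:
        perms = np.array(list(itertools.permutations(range(n))))
        F_perm = _pseudo_F(d2, label_idx[perms], g, sizes)
        p = float(np.sum(F_perm >= F_obs - 1e-12) / n_total)
        return PermanovaResult(pseudo_F=F_obs, p=p, n_permutations=n_total,
                               df_among=g - 1, df_within=n - g,
                               method="exhaustive")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    F_perm = _pseudo_F(d2, label_idx[perms], g, sizes)
    p = float((np.sum(F_perm >= F_obs - 1e-12) + 1) / (n_perm + 1))
    return PermanovaResult(pseudo_F=F_obs, p=p, n_permutations=n_perm,
                           df_among=g - 1, df_within=n - g)


def pairwise_permanova(D: DistanceMatrix, meta: SampleMetadata,
                       n_perm: int = 999, seed: int = 0,
                       ) -> list[dict]:
    """Per-pair PERMANOVA on restricted submatrices, BH-adjusted p-values."""
    labels = sorted(set(meta.group_of(s) for s in D.ids))
    if len(labels) < 2:
        raise GroupingError("need >= 2 groups")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(len(labels) * (len(labels) - 1) // 2)]
    results = []
    k = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = (labels[i], labels[j])
            ids = [s for s in D.ids if meta.group_of(s) in pair]
            sub = D.filter(ids)
            res = permanova(sub, meta, n_perm=n_perm, seed=child_seeds[k])
            results.append({"group_j": pair[0], "group_k": pair[1],
                            "result": res})
            k += 1
    adj = bh_adjust([r["result"].p for r in results])
    for r, q in zip(results, adj):
        r["p_adjusted"] = float(q)
        r["adjust_method"] = "bh"
    return results


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise MetricError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential taxa


def differential_taxa(table: OtuTable, meta: SampleMetadata,
                      alpha: float = 0.05, effect_threshold: float = 2.0,
                      seed: int = 0) -> list[DifferentialTaxon]:
    """Simplified LEfSe-style screen for group-enriched taxa.

    Per taxon: (1) Kruskal-Wallis on within-sample relative abundances across
    groups at level ``alpha``; (2) for survivors, an effect size in the LEfSe
    convention, the log10 difference between the highest and lowest group
    mean abundance on the counts-per-million scale. With one taxon scored at
    a time the linear-discriminant axis coincides with the abundance feature
    itself, so no explicit projection is needed. Taxa must pass both
    thresholds; results are sorted by effect size, descending.
    """
    meta_sub = SampleMetadata({s: meta.group_of(s) for s in table.sample_ids})
    meta_sub.require_inferential(min_per_group=1)
    labels = [meta_sub.group_of(s) for s in table.sample_ids]
    groups = sorted(set(labels))
    idx_by_group = {g: [i for i, l in enumerate(labels) if l == g]
                    for g in groups}
    totals = table.counts.sum(axis=0).astype(np.float64)
    if (totals <= 0).any():
        raise MetricError("sample with zero total count")
    cpm = table.counts / totals * 1e6
    out: list[DifferentialTaxon] = []
    for t, row in zip(table.otu_ids, cpm):
        samples = [row[idx_by_group[g]] for g in groups]
        if np.ptp(row) == 0:  # identical in all samples: no signal
            continue
        try:
            _, p = kruskal(*samples)
        except ValueError:  # all values identical within the test
            continue
        if not (p <= alpha):
            continue
        means = np.array([s.mean() for s in samples])
        diff = means.max() - means.min()
        if diff <= 0:
            continue
        effect = math.log10(diff)
        if effect >= effect_threshold:
            out.append(DifferentialTaxon(
                taxon=t, enriched_group=groups[int(np.argmax(means))],
                kw_p=float(p), effect_size=float(effect)))
    out.sort(key=lambda r: r.effect_size, reverse=True)
    return out
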