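"""Trophic-niche statistics: Levins breadth, Pianka overlap, Krebs banding.

Levins niche breadth ``B = 1 / sum_j P_j**2`` ranges from 1 (a single
resource) to ``n`` (uniform use of ``n`` resources) and measures diet
generalism. Hurlbert's standardised breadth ``B_std = (B - 1) / (n - 1)``
rescales to [0, 1] so breadths at ranks with different taxon counts are
comparable. Pianka's overlap

    O_jk = sum_i p_ij * p_ik / sqrt(sum_i p_ij**2 * sum_i p_ik**2)

is the cosine-style symmetric index of shared resource use, interpreted on
Krebs' bands: O > 0.3 significant overlap, O > 0.6 highly significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, MetricError
from .prep import DietProfile

__all__ = [
    "NicheBreadthResult",
    "OverlapResult",
    "levins_breadth",
    "pianka_overlap",
    "classify_overlap",
    "breadth_table",
    "overlap_matrix",
]

#: Krebs interpretation thresholds (strict inequalities).
SIGNIFICANT_OVERLAP = 0.3
HIGHLY_SIGNIFICANT_OVERLAP = 0.6


@dataclass(frozen=True)
class NicheBreadthResult:
    group: str
    rank: str
    B: float
    B_std: float
    n_taxa: int


@dataclass(frozen=True)
class OverlapResult:
    group_j: str
    group_k: str
    rank: str
    O: float
    band: str


def levins_breadth(profile: DietProfile) -> NicheBreadthResult:
    """Levins breadth B = 1/sum(p^2) with Hurlbert's standardisation.

    For a single-taxon axis (n_taxa == 1) B is trivially 1 and the
    standardised breadth is reported as 0 (no scope for generalism).
    """
    p = profile.p
    if p.size == 0:
        raise EmptyResultError("cannot compute breadth of an empty profile")
    B = 1.0 / float(np.sum(p * p))
    n = profile.n_taxa
    B_std = (B - 1.0) / (n - 1.0) if n > 1 else 0.0
    return NicheBreadthResult(group=profile.group, rank=profile.rank,
                              B=B, B_std=B_std, n_taxa=n)


def _aligned(profile_j: DietProfile, profile_k: DietProfile,
             ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-impute both profiles onto the union of their taxa."""
    union: dict[str, int] = {}
    for t in profile_j.taxa + profile_k.taxa:
        union.setdefault(t, len(union))
    pj = np.zeros(len(union))
    pk = np.zeros(len(union))
    for t, v in zip(profile_j.taxa, profile_j.p):
        pj[union[t]] = v
    for t, v in zip(profile_k.taxa, profile_k.p):
        pk[union[t]] = v
    return pj, pk


def pianka_overlap(profile_j: DietProfile, profile_k: DietProfile) -> OverlapResult:
    """Pianka's symmetric overlap on the union of the two resource axes."""
    if profile_j.rank != profile_k.rank:
        raise MetricError(
            f"rank mismatch: {profile_j.rank!r} vs {profile_k.rank!r}")
    pj, pk = _aligned(profile_j, profile_k)
    denom = np.sqrt(np.sum(pj * pj) * np.sum(pk * pk))
    O = float(np.sum(pj * pk) / denom)
    O = min(max(O, 0.0), 1.0)  # guard float drift past the Cauchy-Schwarz bound
    return OverlapResult(group_j=profile_j.group, group_k=profile_k.group,
                         rank=profile_j.rank, O=O, band=classify_overlap(O))


def classify_overlap(O: float) -> str:
    """Krebs band for an overlap index: strict > at both 0.3 and 0.6."""
    if not (0.0 <= O <= 1.0):
        raise MetricError(f"overlap index {O} outside [0, 1]")
    if O > HIGHLY_SIGNIFICANT_OVERLAP:
        return "highly_significant"
    if O > SIGNIFICANT_OVERLAP:
        return "significant"
    return "below"


def breadth_table(profiles: Iterable[DietProfile],
                  ranks: Sequence[str] = ("class", "order", "family", "genus"),
                  ) -> pd.DataFrame:
    """Group x rank table of Levins breadths (the multi-rank breadth summary).

    Every group must have a profile at every requested rank.
    """
    by_key: dict[tuple[str, str], DietProfile] = {}
    groups: dict[str, None] = {}
    for pr in profiles:
        by_key[(pr.group, pr.rank)] = pr
        groups.setdefault(pr.group)
    rows = {}
    for g in groups:
        row = {}
        for r in ranks:
            if (g, r) not in by_key:
                raise MetricError(f"missing profile for group {g!r} at rank {r!r}")
            row[f"{r}_level"] = levins_breadth(by_key[(g, r)]).B
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"{r}_level" for r in ranks])


def overlap_matrix(profiles: Sequence[DietProfile]) -> list[OverlapResult]:
    """All unordered pairwise Pianka overlaps among same-rank profiles."""
    out = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            out.append(pianka_overlap(profiles[i], profiles[j]))
    return out
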