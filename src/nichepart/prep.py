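"""Filtering, taxonomic aggregation, and per-consumer diet profiles.

These operations turn a raw OTU count table into the relative-abundance
diet profiles on which the niche statistics operate: screen out non-plant
(contaminant/unassigned) OTUs, optionally drop rare taxa, collapse counts to
a taxonomic rank, and normalise per consumer species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import EmptyResultError, GroupingError, MetricError
from .io import RANKS, UNASSIGNED, OtuTable, SampleMetadata, TaxonLineage

__all__ = [
    "DietProfile",
    "filter_plant_otus",
    "screen_low_abundance",
    "aggregate_to_rank",
    "group_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DietProfile:
    """One consumer group's relative-abundance vector over taxa at one rank.

    Invariants: p >= 0, sums to 1 (within 1e-9), one probability per taxon,
    no duplicate taxon names.
    """

    group: str
    rank: str
    taxa: tuple[str, ...]
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if len(self.taxa) != p.shape[0] or p.ndim != 1:
            raise MetricError("profile taxa and probabilities misaligned")
        if len(set(self.taxa)) != len(self.taxa):
            raise MetricError("duplicate taxon names in profile")
        if p.size == 0:
            raise EmptyResultError(f"empty diet profile for group {self.group!r}")
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise MetricError(
                f"profile for {self.group!r} is not a probability vector "
                f"(min={p.min():.3g}, sum={p.sum():.12g})")
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "p", p)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.taxa, self.p.tolist()))


def filter_plant_otus(table: OtuTable, tax: Mapping[str, TaxonLineage]) -> OtuTable:
    """Retain exactly the OTUs flagged as land plants; counts untouched.

    Mirrors the manual screening step that separates genuine diet (plant)
    sequences from host, microbial and unassignable amplicons.
    """
    keep = [o for o in table.otu_ids
            if o in tax and tax[o].is_plant]
    if not keep:
        raise EmptyResultError("no plant OTUs retained after screening")
    log.info("plant screen: retained %d of %d OTUs", len(keep), table.n_otus)
    return table.select_otus(keep)


def screen_low_abundance(table: OtuTable, min_prop: float = 0.01,
                         min_samples: int = 1) -> OtuTable:
    """Retain taxa reaching a within-sample relative abundance >= ``min_prop``
    in at least ``min_samples`` samples.

    With the defaults this generalises the common 1% reporting threshold to
    an explicit screen. ``min_prop=0`` is the identity.
    """
    if not (0 <= min_prop < 1):
        raise MetricError("min_prop must be in [0, 1)")
    if min_samples < 1:
        raise MetricError("min_samples must be >= 1")
    totals = table.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, table.counts / totals, 0.0)
    hits = (rel >= min_prop).sum(axis=1)
    keep = [o for o, h in zip(table.otu_ids, hits) if h >= min_samples]
    if not keep:
        raise EmptyResultError("abundance screen removed every taxon")
    return table.select_otus(keep)


def rank_membership(otu_ids: tuple[str, ...], tax: Mapping[str, TaxonLineage],
                    rank: str) -> list[str]:
    """Taxon name at ``rank`` per OTU; unassigned pooled under one label."""
    if rank not in RANKS:
        raise MetricError(f"unknown rank {rank!r}; expected one of {RANKS}")
    pooled = f"{UNASSIGNED}_{rank}"
    out = []
    for o in otu_ids:
        lin = tax.get(o)
        name = lin.name_at(rank) if lin is not None else UNASSIGNED
        out.append(pooled if name == UNASSIGNED else name)
    return out


def aggregate_matrix(matrix: np.ndarray, otu_ids: tuple[str, ...],
                     tax: Mapping[str, TaxonLineage], rank: str,
                     keep_unassigned: bool = True,
                     ) -> tuple[list[str], np.ndarray]:
    """Sum rows of ``matrix`` by taxon name at ``rank`` (first-appearance order).

    Works on any real-valued matrix (counts or probabilities) so that exact
    generating probabilities and sampled counts aggregate identically.
    """
    names = rank_membership(otu_ids, tax, rank)
    pooled = f"{UNASSIGNED}_{rank}"
    order: dict[str, int] = {}
    for n in names:
        if n not in order and (keep_unassigned or n != pooled):
            order[n] = len(order)
    agg = np.zeros((len(order), matrix.shape[1]), dtype=matrix.dtype)
    for row, n in zip(matrix, names):
        if n in order:
            agg[order[n]] += row
    return list(order), agg


def aggregate_to_rank(table: OtuTable, tax: Mapping[str, TaxonLineage],
                      rank: str, keep_unassigned: bool = True) -> OtuTable:
    """Collapse an OTU table to a taxon-by-sample table at one rank.

    OTUs without an assignment at ``rank`` are pooled under one
    ``Unassigned_<rank>`` row (column sums are then preserved exactly) or
    dropped when ``keep_unassigned`` is False.
    """
    taxa, agg = aggregate_matrix(table.counts, table.otu_ids, tax, rank,
                                 keep_unassigned)
    if not taxa:
        raise EmptyResultError(f"no taxa left after aggregating to {rank}")
    return OtuTable(tuple(taxa), table.sample_ids, agg)


def group_profile(table: OtuTable, meta: SampleMetadata, group: str,
                  mode: str = "pooled", rank: str = "otu",
                  drop_unassigned: bool = True) -> DietProfile:
    """Build a consumer group's diet profile from its samples' counts.

    ``pooled`` sums counts over the group's samples then normalises;
    ``mean-of-proportions`` normalises each sample first, averages, and
    renormalises. The two agree when all samples have equal depth, and
    pooled weights deep samples more. Taxa named ``Unassigned_*`` are
    excluded (before normalisation) unless ``drop_unassigned`` is False,
    since diet composition is reported over identified taxa.
    """
    samples = [s for s in table.sample_ids if meta.groups.get(s) == group]
    if not samples:
        raise GroupingError(f"group {group!r} has no samples in table")
    sub = table.select_samples(samples)
    counts = sub.counts.astype(np.float64)
    taxa = list(sub.otu_ids)
    if drop_unassigned:
        keep = [i for i, t in enumerate(taxa) if not t.startswith(f"{UNASSIGNED}_")
                and t != UNASSIGNED]
        taxa = [taxa[i] for i in keep]
        counts = counts[keep, :]
    if counts.size == 0 or counts.sum() <= 0:
        raise GroupingError(f"group {group!r} has no reads to profile")
    if mode == "pooled":
        tot = counts.sum(axis=1)
        p = tot / tot.sum()
    elif mode == "mean-of-proportions":
        col_tot = counts.sum(axis=0)
        pos = col_tot > 0
        if not pos.any():
            raise GroupingError(f"group {group!r} has no non-empty samples")
        props = counts[:, pos] / col_tot[pos]
        p = props.mean(axis=1)
        p = p / p.sum()
    else:
        raise MetricError(f"unknown profile mode {mode!r}")
    return DietProfile(group=group, rank=rank, taxa=tuple(taxa), p=p)
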