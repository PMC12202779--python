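"""Data model and readers/writers for the tabular and tree formats the pipeline touches.

The canonical table dialect is tab-separated UTF-8 with sample ids in the
header row and OTU ids in the first column, matching common amplicon-pipeline
exports. Taxonomy uses prefixed lineage strings in the style
``c__Magnoliopsida; o__Sapindales; f__Sapindaceae; g__Koelreuteria; s__K.paniculata``.
Trees are Newick with branch lengths; distance matrices are
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import (
    DuplicateIdError,
    GroupingError,
    LineageParseError,
    TableParseError,
    TreeParseError,
)

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "DEFAULT_PLANT_CLASSES",
    "OtuTable",
    "TaxonLineage",
    "SampleMetadata",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "validate_inputs",
]

#: Taxonomic ranks modelled, coarse to fine. Phylum/kingdom are not tracked;
#: the diet analyses report class through species only.
RANKS: tuple[str, ...] = ("class", "order", "family", "genus", "species")

UNASSIGNED = "Unassigned"

_PREFIX_TO_RANK = {"c__": "class", "o__": "order", "f__": "family",
                   "g__": "genus", "s__": "species"}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIX_TO_RANK.items()}

#: Land-plant (Viridiplantae) classes used to flag an OTU as a plausible diet
#: item. Configurable: pass your own whitelist to :func:`read_taxonomy`.
DEFAULT_PLANT_CLASSES: frozenset[str] = frozenset({
    "Magnoliopsida", "Liliopsida", "Bryopsida", "Polypodiopsida",
    "Pinopsida", "Ginkgoopsida",
})


@dataclass(frozen=True)
class OtuTable:
    """Non-negative integer count matrix, OTU rows x sample columns.

    Invariants (checked on construction): counts are integral and >= 0,
    and neither id axis contains duplicates.
    """

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise TableParseError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise TableParseError(
                    f"non-integer count at OTU {self.otu_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise TableParseError(
                f"negative count at OTU {self.otu_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        for axis_name, ids in (("OTU", self.otu_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DuplicateIdError(f"duplicate {axis_name} id {i!r}")
                seen.add(i)
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.otu_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())

    def select_otus(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in keep]
        return OtuTable(tuple(keep), self.sample_ids, self.counts[idx, :])

    def select_samples(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OtuTable(self.otu_ids, tuple(keep), self.counts[:, idx])

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)].copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.otu_ids == other.otu_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered rank->name assignment for one OTU, class through species.

    ``is_plant`` flags whether the class-rank assignment falls inside a
    Viridiplantae class whitelist; the diet analyses only consider plant OTUs.
    Missing ranks hold :data:`UNASSIGNED`; a named rank below an unassigned
    one is permitted and treated as an assignment gap.
    """

    names: tuple[str, ...]  # aligned with RANKS
    is_plant: bool

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise LineageParseError(
                f"lineage needs {len(RANKS)} ranks, got {len(self.names)}")
        object.__setattr__(self, "names", tuple(self.names))

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(zip(RANKS, self.names))

    def to_string(self) -> str:
        parts = [f"{_RANK_TO_PREFIX[r]}{n}" for r, n in zip(RANKS, self.names)
                 if n != UNASSIGNED]
        return "; ".join(parts)

    @classmethod
    def unassigned(cls) -> "TaxonLineage":
        return cls((UNASSIGNED,) * len(RANKS), False)


def parse_lineage(lineage: str,
                  plant_classes: frozenset[str] = DEFAULT_PLANT_CLASSES
                  ) -> TaxonLineage:
    """Parse a prefixed lineage string into a :class:`TaxonLineage`."""
    names = {r: UNASSIGNED for r in RANKS}
    for part in lineage.split(";"):
        part = part.strip()
        if not part:
            continue
        prefix = part[:3]
        if prefix not in _PREFIX_TO_RANK:
            raise LineageParseError(f"unknown rank prefix in {part!r}")
        name = part[3:].strip()
        names[_PREFIX_TO_RANK[prefix]] = name or UNASSIGNED
    is_plant = names["class"] in plant_classes
    return TaxonLineage(tuple(names[r] for r in RANKS), is_plant)


@dataclass(frozen=True)
class SampleMetadata:
    """Mapping sample id -> consumer-species (group) label."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", dict(self.groups))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, sample_id: str) -> str:
        try:
            return self.groups[sample_id]
        except KeyError:
            raise GroupingError(f"sample {sample_id!r} has no group") from None

    def group_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g)
        return tuple(seen)

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.groups.items() if g == group)

    def require_inferential(self, min_per_group: int = 2) -> None:
        """Raise unless there are >= 2 groups each with >= min_per_group samples."""
        labels = self.group_labels()
        if len(labels) < 2:
            raise GroupingError("inferential operations need >= 2 groups")
        for g in labels:
            n = len(self.samples_in(g))
            if n < min_per_group:
                raise GroupingError(
                    f"group {g!r} has {n} samples; need >= {min_per_group}")


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(path: str | Path, sep: str = "\t") -> OtuTable:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) < 2:
        raise TableParseError(f"{path}: header must list at least one sample")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise DuplicateIdError(f"{path}: duplicate sample id {dup!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DuplicateIdError(f"{path}: duplicate OTU id {dup!r}")
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise TableParseError(f"{path}: non-numeric cell ({exc})") from exc
    return OtuTable(tuple(map(str, df.index)), tuple(sample_ids), counts)


def write_otu_table(table: OtuTable, path: str | Path, sep: str = "\t") -> None:
    table.to_dataframe().rename_axis("otu_id").to_csv(
        Path(path), sep=sep, encoding="utf-8")


def read_taxonomy(path: str | Path,
                  plant_classes: frozenset[str] = DEFAULT_PLANT_CLASSES,
                  ) -> dict[str, TaxonLineage]:
    """Read a two-column TSV ``otu_id<TAB>lineage`` into a lineage mapping.

    A header line starting with ``otu_id`` is accepted and skipped.
    """
    path = Path(path)
    out: dict[str, TaxonLineage] = {}
    with path.open("r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if ln == 1 and fields[0].lower() in {"otu_id", "feature id", "#otu id"}:
                continue
            otu = fields[0]
            lineage = fields[1] if len(fields) > 1 else ""
            if otu in out:
                raise DuplicateIdError(f"{path}:{ln}: duplicate OTU id {otu!r}")
            out[otu] = parse_lineage(lineage, plant_classes)
    return out


def write_taxonomy(tax: Mapping[str, TaxonLineage], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lin in tax.items():
            fh.write(f"{otu}\t{lin.to_string()}\n")


def lineages_for_table(table: OtuTable, tax: Mapping[str, TaxonLineage],
                       ) -> dict[str, TaxonLineage]:
    """Align a lineage mapping to a table; absent OTUs become fully unassigned."""
    out: dict[str, TaxonLineage] = {}
    missing: list[str] = []
    for otu in table.otu_ids:
        lin = tax.get(otu)
        if lin is None:
            missing.append(otu)
            lin = TaxonLineage.unassigned()
        out[otu] = lin
    if missing:
        warnings.warn(
            f"{len(missing)} OTU(s) without taxonomy treated as unassigned "
            f"(first: {missing[0]!r})", stacklevel=2)
    return out


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column TSV ``sample_id<TAB>group``; header optional."""
    path = Path(path)
    groups: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TableParseError(f"{path}:{ln}: expected two columns")
            if ln == 1 and fields[0].lower() in {"sample_id", "sample", "#sampleid"}:
                continue
            sid, group = fields[0], fields[1]
            if sid in groups:
                raise DuplicateIdError(f"{path}:{ln}: duplicate sample id {sid!r}")
            groups[sid] = group
    if not groups:
        raise TableParseError(f"{path}: no samples found")
    return SampleMetadata(groups)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, group in meta.groups.items():
            fh.write(f"{sid}\t{group}\n")


def read_newick(path: str | Path) -> TreeNode:
    path = Path(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise TreeParseError(f"{path}: {exc}") from exc
    leaves = list(tree.tips())
    if not leaves:
        raise TreeParseError(f"{path}: tree has no leaves")
    names = [t.name for t in leaves]
    if len(set(names)) != len(names):
        raise TreeParseError(f"{path}: duplicate leaf names")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise TreeParseError(f"{path}: negative branch length")
    if n_missing:
        warnings.warn(f"{path}: {n_missing} missing branch length(s) set to 0",
                      stacklevel=2)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def validate_inputs(table: OtuTable, tax: Mapping[str, TaxonLineage],
                    meta: SampleMetadata) -> None:
    """Joint consistency check: table samples covered by metadata, OTUs by taxonomy."""
    missing_samples = [s for s in table.sample_ids if s not in meta.groups]
    if missing_samples:
        raise GroupingError(
            f"{len(missing_samples)} sample(s) missing from metadata "
            f"(first: {missing_samples[0]!r})")
    lineages_for_table(table, tax)
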