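"""Synthetic diet-metabarcoding data with known niche ground truth.

The generator emulates the structure of a fecal rbcL metabarcoding study of
three sympatric consumer species: a nested plant taxonomy
(class > order > family > genus > OTU), species-specific diet profiles built
from a shared base distribution plus disjoint private components, lognormal
per-sample read depths, Dirichlet-multinomial overdispersion between samples
of the same species, and a contaminant (non-plant / unassigned) read
fraction to exercise the screening step.

Ground truth is defined at OTU level and aggregated upward, so the true
breadth and overlap values at every rank are mutually consistent; estimates
computed from simulated counts can be compared against them directly.

All randomness flows from a single master seed through
``numpy.random.SeedSequence.spawn`` (the seed-splitting rule), so every
output is a pure function of (spec, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import MetricError
from .io import (
    OtuTable,
    SampleMetadata,
    TaxonLineage,
    write_metadata,
    write_newick,
    write_otu_table,
    write_taxonomy,
)
from .niche import levins_breadth, pianka_overlap
from .prep import DietProfile, aggregate_matrix

__all__ = [
    "TaxonomySpec",
    "SimConfig",
    "SimTruth",
    "build_taxonomy",
    "make_diet_profiles",
    "simulate_dataset",
    "recovery_experiment",
]

#: Viridiplantae class names used for generated plant lineages (these are the
#: classes the plant whitelist recognises).
_PLANT_CLASS_NAMES = ("Magnoliopsida", "Liliopsida", "Bryopsida",
                      "Polypodiopsida", "Pinopsida", "Ginkgoopsida")
_NONPLANT_CLASS_NAMES = ("Insecta", "Agaricomycetes", "Malacostraca")

TRUTH_RANKS = ("class", "order", "family", "genus")


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape of the generated plant taxonomy (a balanced product design).

    Defaults give 3x3x2x2x2 = 72 plant OTUs in 36 genera, 18 families,
    9 orders and 3 classes, plus 356 contaminant OTUs for a raw table of
    428 OTUs — the scale of a real fecal rbcL survey where most raw OTUs
    are non-diet sequences.
    """

    n_classes: int = 3
    orders_per_class: int = 3
    families_per_order: int = 2
    genera_per_family: int = 2
    otus_per_genus: int = 2
    contaminant_otus: int = 356
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "orders_per_class", "families_per_order",
                     "genera_per_family", "otus_per_genus"):
            if getattr(self, name) < 1:
                raise MetricError(f"{name} must be positive")
        if self.contaminant_otus < 0:
            raise MetricError("contaminant_otus must be >= 0")
        if self.n_classes > len(_PLANT_CLASS_NAMES):
            raise MetricError(
                f"at most {len(_PLANT_CLASS_NAMES)} plant classes supported")

    @property
    def n_plant_otus(self) -> int:
        return (self.n_classes * self.orders_per_class * self.families_per_order
                * self.genera_per_family * self.otus_per_genus)


@dataclass(frozen=True)
class SimConfig:
    """Sampling design and noise model for a synthetic dataset.

    ``mean_depth`` is the median per-sample read depth (lognormal across
    samples with log-sd ``depth_dispersion``); the study-scale value is 1e5
    reads per sample, the quick default 5,000. ``theta`` is the Dirichlet
    concentration multiplier: sample compositions are drawn from
    Dirichlet(theta * p_g), so larger theta means samples track the species
    profile more tightly. ``shared_fraction`` (alpha) mixes a community-wide
    base diet into each species' private component; higher alpha raises
    pairwise overlap. ``contaminant_fraction`` is the expected share of reads
    from non-plant OTUs before screening.
    """

    n_groups: int = 3
    samples_per_group: int = 18
    mean_depth: int = 5000
    depth_dispersion: float = 0.3
    theta: float = 50.0
    shared_fraction: float | Sequence[float] = 0.4
    contaminant_fraction: float = 0.1
    base_concentration: float = 0.5
    private_concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2 or self.samples_per_group < 1:
            raise MetricError("need >= 2 groups and >= 1 sample per group")
        if self.mean_depth < 1:
            raise MetricError("mean_depth must be positive")
        if not (0 <= self.contaminant_fraction < 1):
            raise MetricError("contaminant_fraction must be in [0, 1)")
        for a in self.alphas:
            if not (0.0 <= a <= 1.0):
                raise MetricError("shared_fraction values must lie in [0, 1]")

    @property
    def alphas(self) -> tuple[float, ...]:
        a = self.shared_fraction
        if np.isscalar(a):
            return (float(a),) * self.n_groups
        a = tuple(float(x) for x in a)
        if len(a) != self.n_groups:
            raise MetricError("one shared_fraction per group required")
        return a

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(f"sp{g + 1}" for g in range(self.n_groups))


@dataclass(frozen=True)
class SimTruth:
    """Generating probabilities and their exact niche statistics.

    ``true_B`` / ``true_O`` are computed by the niche module from the exact
    generating probabilities aggregated to each rank — never from sampled
    counts — so they are the recovery targets for the estimation pipeline.
    """

    group_labels: tuple[str, ...]
    otu_ids: tuple[str, ...]
    profiles: np.ndarray = field(repr=False)  # (n_groups, n_plant_otus)
    true_B: Mapping[str, Mapping[str, float]]  # rank -> group -> B
    true_O: Mapping[str, Mapping[tuple[str, str], float]]  # rank -> pair -> O
    config: SimConfig = None
    spec: TaxonomySpec = None


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(master).spawn(n)]


def build_taxonomy(spec: TaxonomySpec) -> tuple[dict[str, TaxonLineage], TreeNode]:
    """Generate lineages for all OTUs and a random coalescent-style tree
    over the plant OTUs (unit-exponential branch lengths)."""
    tax: dict[str, TaxonLineage] = {}
    plant_ids: list[str] = []
    k = 0
    for c in range(spec.n_classes):
        cname = _PLANT_CLASS_NAMES[c]
        for o in range(spec.orders_per_class):
            oname = f"Order_{c + 1}_{o + 1}"
            for f in range(spec.families_per_order):
                fname = f"Family_{c + 1}_{o + 1}_{f + 1}"
                for g in range(spec.genera_per_family):
                    gname = f"Genus_{c + 1}_{o + 1}_{f + 1}_{g + 1}"
                    for s in range(spec.otus_per_genus):
                        k += 1
                        otu = f"OTU_{k:04d}"
                        sname = f"{gname}_sp{s + 1}"
                        tax[otu] = TaxonLineage(
                            (cname, oname, fname, gname, sname), True)
                        plant_ids.append(otu)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    for j in range(spec.contaminant_otus):
        otu = f"CONT_{j + 1:04d}"
        if j % 2 == 0:
            tax[otu] = TaxonLineage.unassigned()
        else:
            cname = _NONPLANT_CLASS_NAMES[j % len(_NONPLANT_CLASS_NAMES)]
            tax[otu] = TaxonLineage(
                (cname, "Unassigned", "Unassigned", "Unassigned",
                 "Unassigned"), False)
    tree = _random_coalescent(plant_ids, rng)
    return tax, tree


def _random_coalescent(leaf_names: Sequence[str],
                       rng: np.random.Generator) -> TreeNode:
    nodes = [TreeNode(name=n) for n in leaf_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[a, b])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _truth_profiles_by_rank(otu_ids: Sequence[str], profiles: np.ndarray,
                            tax: Mapping[str, TaxonLineage],
                            group_labels: Sequence[str], rank: str,
                            ) -> list[DietProfile]:
    taxa, agg = aggregate_matrix(profiles.T, tuple(otu_ids), tax, rank)
    return [DietProfile(group=g, rank=rank, taxa=tuple(taxa),
                        p=agg[:, gi] / agg[:, gi].sum())
            for gi, g in enumerate(group_labels)]


def make_diet_profiles(tax: Mapping[str, TaxonLineage],
                       config: SimConfig,
                       spec: TaxonomySpec | None = None) -> SimTruth:
    """Construct species diet profiles p_g = alpha_g*q + (1-alpha_g)*r_g.

    ``q`` is a community-wide base distribution over all plant OTUs and each
    ``r_g`` is a private distribution on a disjoint block of OTUs, both drawn
    from symmetric Dirichlets. alpha_g = 1 for all groups gives identical
    diets (all pairwise overlaps 1); alpha_g = 0 gives disjoint diets
    (overlaps 0). True B and O per rank are computed from the exact p_g.
    """
    plant_ids = [o for o, lin in tax.items() if lin.is_plant]
    g = config.n_groups
    if len(plant_ids) < g:
        raise MetricError("need at least one private OTU per group")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = len(plant_ids)
    q = rng.dirichlet(np.full(n, config.base_concentration))
    block = np.array_split(rng.permutation(n), g)
    profiles = np.zeros((g, n))
    alphas = config.alphas
    for gi in range(g):
        r = np.zeros(n)
        r[block[gi]] = rng.dirichlet(
            np.full(block[gi].size, config.private_concentration))
        profiles[gi] = alphas[gi] * q + (1.0 - alphas[gi]) * r
        profiles[gi] /= profiles[gi].sum()
    labels = config.group_labels
    true_B: dict[str, dict[str, float]] = {}
    true_O: dict[str, dict[tuple[str, str], float]] = {}
    for rank in TRUTH_RANKS:
        prof = _truth_profiles_by_rank(plant_ids, profiles, tax, labels, rank)
        true_B[rank] = {p.group: levins_breadth(p).B for p in prof}
        true_O[rank] = {}
        for i in range(g):
            for j in range(i + 1, g):
                res = pianka_overlap(prof[i], prof[j])
                true_O[rank][(labels[i], labels[j])] = res.O
    return SimTruth(group_labels=labels, otu_ids=tuple(plant_ids),
                    profiles=profiles, true_B=true_B, true_O=true_O,
                    config=config, spec=spec)


def simulate_dataset(truth: SimTruth, config: SimConfig,
                     tax: Mapping[str, TaxonLineage] | None = None,
                     tree: TreeNode | None = None,
                     out_dir: str | Path | None = None,
                     ) -> tuple[OtuTable, SampleMetadata]:
    """Draw a count table from the generating model; optionally write files.

    Per sample: depth ~ round(lognormal(log mean_depth, depth_dispersion));
    contaminant reads ~ Binomial(depth, contaminant_fraction) spread over the
    contaminant OTUs with a shared Dirichlet profile; plant reads ~
    Multinomial(depth - contaminants, Dirichlet(theta * p_g)).

    Written files (counts.tsv, taxonomy.tsv, metadata.tsv, tree.nwk,
    truth.json) round-trip through the package readers and are byte-stable
    for a fixed seed.
    """
    seeds = _child_seeds(config.seed, 3)
    rng = np.random.default_rng(seeds[1])
    plant_ids = list(truth.otu_ids)
    cont_ids = ([o for o, lin in tax.items() if not lin.is_plant]
                if tax is not None else [])
    cont_profile = (rng.dirichlet(np.full(len(cont_ids), 0.3))
                    if cont_ids else None)
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    cols: list[np.ndarray] = []
    mu = np.log(config.mean_depth)
    for gi, glabel in enumerate(truth.group_labels):
        p = truth.profiles[gi]
        support = p > 0
        for si in range(config.samples_per_group):
            sid = f"{glabel}_s{si + 1:02d}"
            sample_ids.append(sid)
            groups[sid] = glabel
            depth = max(1, int(round(rng.lognormal(mu, config.depth_dispersion))))
            n_cont = (rng.binomial(depth, config.contaminant_fraction)
                      if cont_ids and config.contaminant_fraction > 0 else 0)
            comp = np.zeros_like(p)
            comp[support] = rng.dirichlet(config.theta * p[support])
            col = np.zeros(len(plant_ids) + len(cont_ids), dtype=np.int64)
            col[:len(plant_ids)] = rng.multinomial(depth - n_cont, comp)
            if n_cont:
                col[len(plant_ids):] = rng.multinomial(n_cont, cont_profile)
            cols.append(col)
    table = OtuTable(tuple(plant_ids + cont_ids), tuple(sample_ids),
                     np.column_stack(cols))
    meta = SampleMetadata(groups)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_otu_table(table, out_dir / "counts.tsv")
        write_metadata(meta, out_dir / "metadata.tsv")
        if tax is not None:
            write_taxonomy(tax, out_dir / "taxonomy.tsv")
        if tree is not None:
            write_newick(tree, out_dir / "tree.nwk")
        _write_truth_json(truth, out_dir / "truth.json")
    return table, meta


def _write_truth_json(truth: SimTruth, path: Path) -> None:
    payload = {
        "group_labels": list(truth.group_labels),
        "true_B": {r: dict(v) for r, v in truth.true_B.items()},
        "true_O": {r: {f"{a}|{b}": o for (a, b), o in v.items()}
                   for r, v in truth.true_O.items()},
        "config": asdict(truth.config) if truth.config else None,
        "taxonomy_spec": asdict(truth.spec) if truth.spec else None,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def estimate_niche(table: OtuTable, tax: Mapping[str, TaxonLineage],
                   meta: SampleMetadata, ranks: Sequence[str] = TRUTH_RANKS,
                   mode: str = "pooled",
                   ) -> tuple[dict[str, dict[str, float]],
                              dict[str, dict[tuple[str, str], float]]]:
    """Plant-screen, aggregate, profile, and compute B-hat / O-hat per rank."""
    from .prep import aggregate_to_rank, filter_plant_otus, group_profile

    plant = filter_plant_otus(table, tax)
    labels = sorted(set(meta.groups[s] for s in table.sample_ids))
    B_hat: dict[str, dict[str, float]] = {}
    O_hat: dict[str, dict[tuple[str, str], float]] = {}
    for rank in ranks:
        agg = aggregate_to_rank(plant, tax, rank)
        profs = [group_profile(agg, meta, g, mode=mode, rank=rank)
                 for g in labels]
        B_hat[rank] = {p.group: levins_breadth(p).B for p in profs}
        O_hat[rank] = {}
        for i in range(len(profs)):
            for j in range(i + 1, len(profs)):
                O_hat[rank][(labels[i], labels[j])] = \
                    pianka_overlap(profs[i], profs[j]).O
    return B_hat, O_hat


def recovery_experiment(configs: Sequence[SimConfig],
                        seeds: Sequence[int],
                        spec: TaxonomySpec | None = None,
                        ranks: Sequence[str] = TRUTH_RANKS) -> pd.DataFrame:
    """Simulate -> screen -> profile -> niche, against ground truth.

    Returns a tidy frame with one row per (config, seed, rank, statistic,
    group-or-pair): the true value, the estimate, and their error.
    """
    if not configs:
        raise MetricError("empty config grid")
    spec = spec or TaxonomySpec()
    rows = []
    for ci, cfg in enumerate(configs):
        for seed in seeds:
            cfg_run = SimConfig(**{**asdict(cfg), "seed": int(seed)})
            tax, tree = build_taxonomy(
                TaxonomySpec(**{**asdict(spec), "seed": int(seed)}))
            truth = make_diet_profiles(tax, cfg_run)
            table, meta = simulate_dataset(truth, cfg_run, tax=tax, tree=tree)
            B_hat, O_hat = estimate_niche(table, tax, meta, ranks=ranks)
            for rank in ranks:
                for g, b_true in truth.true_B[rank].items():
                    b_est = B_hat[rank][g]
                    rows.append({"config": ci, "seed": seed, "rank": rank,
                                 "statistic": "B", "unit": g,
                                 "truth": b_true, "estimate": b_est,
                                 "abs_error": abs(b_est - b_true),
                                 "rel_error": abs(b_est - b_true) / b_true})
                for pair, o_true in truth.true_O[rank].items():
                    o_est = O_hat[rank][pair]
                    rows.append({"config": ci, "seed": seed, "rank": rank,
                                 "statistic": "O", "unit": "|".join(pair),
                                 "truth": o_true, "estimate": o_est,
                                 "abs_error": abs(o_est - o_true),
                                 "rel_error": (abs(o_est - o_true) / o_true
                                               if o_true > 0 else np.nan)})
    return pd.DataFrame(rows)
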