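"""End-to-end driver: simulated (or on-disk) inputs through every analysis.

One call runs the full study pipeline — plant screening, rank aggregation,
diet profiles, niche breadth/overlap, alpha/beta diversity with group tests,
PCoA/NMDS ordination, overall and pairwise PERMANOVA, and the
differential-taxon screen — and writes every result as TSV/JSON with
deterministic formatting, so a fixed seed reproduces the output tree
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diversity import alpha_table, beta_distance, kruskal_wallis, \
    unweighted_unifrac
from .io import OtuTable, SampleMetadata, TaxonLineage, read_metadata, \
    read_newick, read_otu_table, read_taxonomy
from .multivariate import differential_taxa, nmds, pairwise_permanova, pcoa, \
    permanova
from .niche import breadth_table, levins_breadth, overlap_matrix
from .prep import aggregate_to_rank, filter_plant_otus, group_profile
from .simulate import SimConfig, TaxonomySpec, build_taxonomy, \
    make_diet_profiles, simulate_dataset

__all__ = ["run_pipeline", "load_inputs"]

PROFILE_RANKS = ("class", "order", "family", "genus")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t", float_format="%.10g",
                                       encoding="utf-8")


def load_inputs(in_dir: str | Path):
    """Read counts.tsv, taxonomy.tsv, metadata.tsv (and tree.nwk if present)."""
    in_dir = Path(in_dir)
    table = read_otu_table(in_dir / "counts.tsv")
    tax = read_taxonomy(in_dir / "taxonomy.tsv")
    meta = read_metadata(in_dir / "metadata.tsv")
    tree_path = in_dir / "tree.nwk"
    tree = read_newick(tree_path) if tree_path.exists() else None
    return table, tax, meta, tree


def run_pipeline(seed: int, out_dir: str | Path,
                 config: SimConfig | None = None,
                 spec: TaxonomySpec | None = None,
                 in_dir: str | Path | None = None,
                 n_perm: int = 999, nmds_restarts: int = 8,
                 profile_mode: str = "pooled") -> dict:
    """Run every analysis stage and write its outputs under ``out_dir``.

    With ``in_dir`` the pipeline analyses an existing dataset; otherwise it
    simulates one (parameters from ``config``/``spec``, randomness from
    ``seed``) and writes the generated inputs alongside the results.
    Returns a dictionary of the in-memory results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = None
    if in_dir is not None:
        table, tax, meta, tree = load_inputs(in_dir)
    else:
        spec = spec or TaxonomySpec(seed=seed)
        config = config or SimConfig(seed=seed)
        tax, tree = build_taxonomy(spec)
        truth = make_diet_profiles(tax, config, spec)
        input_dir = out_dir / "inputs"
        simulate_dataset(truth, config, tax=tax, tree=tree, out_dir=input_dir)
        # read back through the package readers: the analysis consumes files,
        # not in-memory generator state
        table, tax, meta, tree = load_inputs(input_dir)

    plant = filter_plant_otus(table, tax)
    groups = sorted(set(meta.groups[s] for s in table.sample_ids))

    # --- niche statistics at every reporting rank
    profiles = []
    for rank in PROFILE_RANKS:
        agg = aggregate_to_rank(plant, tax, rank)
        profiles += [group_profile(agg, meta, g, mode=profile_mode, rank=rank)
                     for g in groups]
    btable = breadth_table(profiles, ranks=PROFILE_RANKS)
    _write_tsv(btable, out_dir / "niche_breadth.tsv", "group")
    breadths = {p.group + ":" + p.rank: levins_breadth(p) for p in profiles}
    genus_profiles = [p for p in profiles if p.rank == "genus"]
    overlaps = overlap_matrix(genus_profiles)
    _dump_json({f"{o.group_j}|{o.group_k}": {"O": o.O, "band": o.band}
                for o in overlaps}, out_dir / "niche_overlap_genus.json")

    # --- alpha diversity + group comparison (plant OTU level)
    alpha = alpha_table(plant)
    _write_tsv(alpha, out_dir / "alpha_diversity.tsv", "sample_id")
    alpha_tests = {}
    for metric in alpha.columns:
        vals = [alpha.loc[list(meta.samples_in(g)), metric].to_numpy()
                for g in groups]
        h, p = kruskal_wallis(vals)
        alpha_tests[metric] = {"H": h, "p": p}
    _dump_json(alpha_tests, out_dir / "alpha_group_tests.json")

    # --- beta diversity, ordination, PERMANOVA (Bray-Curtis is the primary
    # distance; Jaccard and unweighted UniFrac written alongside)
    distances = {"bray_curtis": beta_distance(plant, "bray_curtis"),
                 "jaccard": beta_distance(plant, "jaccard")}
    if tree is not None:
        distances["unweighted_unifrac"] = unweighted_unifrac(plant, tree)
    for name, D in distances.items():
        _write_tsv(pd.DataFrame(D.data, index=list(D.ids), columns=list(D.ids)),
                   out_dir / f"distance_{name}.tsv", "sample_id")
    D = distances["bray_curtis"]
    pc = pcoa(D)
    _write_tsv(pd.DataFrame(pc.coords[:, :2], index=list(pc.ids),
                            columns=["PCo1", "PCo2"]),
               out_dir / "pcoa_coords.tsv", "sample_id")
    _dump_json({"proportion_explained":
                [float(x) for x in pc.proportion_explained[:5]],
                "negative_eigenvalues":
                int(np.sum(pc.eigenvalues < -1e-9))},
               out_dir / "pcoa_summary.json")
    nm = nmds(D, k=2, seed=seed, restarts=nmds_restarts)
    _write_tsv(pd.DataFrame(nm.coords, index=list(nm.ids),
                            columns=["NMDS1", "NMDS2"]),
               out_dir / "nmds_coords.tsv", "sample_id")
    _dump_json({"stress": nm.stress, "converged": nm.converged},
               out_dir / "nmds_summary.json")

    overall = permanova(D, meta, n_perm=n_perm, seed=seed)
    pairwise = pairwise_permanova(D, meta, n_perm=n_perm, seed=seed)
    _dump_json({
        "overall": {"pseudo_F": overall.pseudo_F, "p": overall.p,
                    "df_among": overall.df_among,
                    "df_within": overall.df_within,
                    "n_permutations": overall.n_permutations},
        "pairwise": [{"groups": [r["group_j"], r["group_k"]],
                      "pseudo_F": r["result"].pseudo_F,
                      "p": r["result"].p, "p_adjusted": r["p_adjusted"],
                      "adjust_method": r["adjust_method"]} for r in pairwise],
    }, out_dir / "permanova.json")

    # --- differential taxa at genus rank
    genus_table = aggregate_to_rank(plant, tax, "genus", keep_unassigned=False)
    diff = differential_taxa(genus_table, meta, seed=seed)
    diff_df = pd.DataFrame(
        [{"taxon": d.taxon, "enriched_group": d.enriched_group,
          "kw_p": d.kw_p, "effect_size": d.effect_size} for d in diff],
        columns=["taxon", "enriched_group", "kw_p", "effect_size"])
    diff_df.to_csv(out_dir / "differential_taxa.tsv", sep="\t", index=False,
                   float_format="%.10g", encoding="utf-8")

    return {"table": table, "meta": meta, "truth": truth,
            "breadth_table": btable, "breadths": breadths,
            "overlaps": overlaps, "alpha": alpha, "alpha_tests": alpha_tests,
            "distances": distances, "pcoa": pc, "nmds": nm,
            "permanova": overall, "pairwise_permanova": pairwise,
            "differential_taxa": diff}
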