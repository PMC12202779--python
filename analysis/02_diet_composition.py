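#!/usr/bin/env python
"""Screen to plant OTUs and tabulate diet composition per rank.

Reads the dataset from results/data/, removes contaminant/unassigned OTUs,
aggregates to each reporting rank, and writes per-species relative-abundance
composition tables, flagging taxa above the 1% reporting threshold.
"""

from pathlib import Path

import pandas as pd

from nichepart import filter_plant_otus, group_profile, aggregate_to_rank
from nichepart.pipeline import load_inputs

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table, tax, meta, _ = load_inputs(ROOT / "data")
    plant = filter_plant_otus(table, tax)
    print(f"plant screen: {table.n_otus} raw OTUs -> {plant.n_otus} retained")
    groups = sorted(meta.group_labels())
    for rank in ("class", "order", "family", "genus"):
        agg = aggregate_to_rank(plant, tax, rank)
        comp = pd.DataFrame({
            g: group_profile(agg, meta, g, rank=rank).as_dict()
            for g in groups
        }).fillna(0.0)
        comp = comp.loc[comp.max(axis=1).sort_values(ascending=False).index]
        out = ROOT / f"composition_{rank}.tsv"
        comp.rename_axis("taxon").to_csv(out, sep="\t", float_format="%.6g")
        major = (comp > 0.01).any(axis=1).sum()
        print(f"{rank}: {len(comp)} taxa, {major} above the 1% threshold "
              f"in at least one species -> {out.name}")
        if rank == "order":
            top = comp.sum(axis=1).nlargest(3)
            share = comp.loc[top.index].mean(axis=1).sum()
            print(f"  top orders {list(top.index)} jointly average "
                  f"{share:.1%} of the diet")


if __name__ == "__main__":
    main()
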