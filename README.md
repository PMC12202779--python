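# nichepart

Trophic-niche differentiation analysis for diet DNA-metabarcoding data.

Sympatric consumer species can coexist by partitioning food resources. Diet
metabarcoding (e.g., plant rbcL amplicons from fecal samples) yields an
OTU-by-sample count table per consumer; this package turns such tables into
the quantities ecologists use to describe niche structure:

- **Levins niche breadth** `B = 1/Σ_j P_j²` per species and taxonomic rank
  (1 = one food item, n = uniform use of n items), with Hurlbert's
  standardised form `B_std = (B−1)/(n−1)`;
- **Pianka niche overlap**
  `O_jk = Σ_i p_ij p_ik / √(Σ p_ij² · Σ p_ik²)` per species pair, banded by
  Krebs' criteria (`O > 0.3` significant, `O > 0.6` highly significant);
- alpha diversity (observed, Chao1, Shannon, Simpson) with Kruskal–Wallis
  group tests, rarefaction curves, and beta diversity (Bray–Curtis,
  Jaccard, unweighted UniFrac);
- PCoA and NMDS ordination, PERMANOVA with BH-adjusted pairwise contrasts,
  and a simplified LEfSe-style differential-taxon screen;
- a Dirichlet-multinomial simulator that generates study-scale datasets
  (3 species × 18 fecal samples, ~1e5 reads/sample, 428 raw OTUs of which
  72 are plant) with exact ground-truth breadth and overlap for recovery
  testing.

It is organised as an analysis project: the library lives in
`src/nichepart/` (IO, screening/profiles, niche statistics, diversity,
multivariate tests, simulation), and the numbered drivers in `analysis/`
run the study end to end, writing tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/03_niche_breadth_overlap.py
```

prints (seed 42):

```
Levins niche breadth (B = 1/sum p^2):
     class_level  order_level  family_level  genus_level
sp1       2.9312       6.8379       11.2468      14.3513
sp2       2.6524       7.0239       12.2977      16.7923
sp3       2.9638       7.0533       10.5661      13.6886

Pianka genus-level overlap (Krebs bands: >0.3 significant, >0.6 highly significant):
  sp1|sp2: O = 0.4413  [significant]
  sp1|sp3: O = 0.4253  [significant]
  sp2|sp3: O = 0.368  [significant]

true vs estimated genus breadth:
  sp1: true 14.879  est 14.351
  sp2: true 15.327  est 16.792
  sp3: true 13.525  est 13.689
```

Breadth grows from class to genus because finer ranks expose more distinct
food items; every species uses 13–17 effective genera here, and all three
pairwise overlaps fall in the "significant" band — shared use of the common
flora with partial private specialisation. The last block compares each
estimate against the generator's exact truth for this dataset.

The remaining drivers (`02` composition tables, `04` diversity, `05`
ordination + PERMANOVA, `06` differential genera, `07` the recovery
experiment across depths) follow the same pattern and write their tables
to `results/`.

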