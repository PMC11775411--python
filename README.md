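# scatscape

Diet analysis of sympatric carnivores from scat DNA metabarcoding, with a
landscape-ecology layer linking what the animals eat to how fragmented and
human-dominated their habitat is. The package reimplements, as a tested
pipeline over fully synthetic or reconstructed inputs, the analysis chain
used in studies of leopard (*Panthera pardus*) and leopard cat
(*Prionailurus bengalensis*) feeding ecology in peri-urban forest mosaics:
OTU-table filtering, dietary composition and niche breadth, class-level
forest-fragmentation metrics, habitat context around scat locations, and
wildland–urban interface mapping. It is aimed at wildlife ecologists who
have post-denoising metabarcoding count tables and categorical land-cover
rasters and want the whole chain reproducible from one seed.

## The statistics

**Diet composition.** With `s_i` the number of scats containing prey taxon
*i*, `N = Σ s_i` the total prey occurrences and `n` the number of scats:

- percent occurrence `PO_i = 100 · s_i / N`
- frequency of occurrence `FO_i = 100 · s_i / n`
- standardized Levins niche breadth
  `B = 1 / Σ p_i²` with `p_i = s_i / N`, and `B_sta = (B − 1) / (N − 1)`,
  0 for a perfect specialist, 1 for a perfect generalist. The denominator
  uses the total number of prey items ingested (N), the reading under
  which the published leopard/leopard-cat values (0.18 / 0.07) are exact;
  the taxon-count alternative is available as an option.

**Filter chain** (count table → presence matrix): consensus BLAST
taxonomy per OTU (hits screened at ≥97% identity and ≥85% coverage, then
the deepest rank where one taxon holds ≥51% of at most 50 hits), a
minimum-read threshold equal to the largest per-OTU count in the negative
control, removal of non-vertebrate / family-level / unassigned /
predator-self OTUs, and presence iff a taxon's pooled relative abundance
in a scat strictly exceeds 1%.

**Fragmentation.** Patches are 8-connected components of a class on a
30 m grid. Six class metrics per analysis unit: patch density (per
100 ha), edge density (m/ha), mean patch area (ha), mean shape index
(`0.25·P/√A`, 1 for a square), mean core area (ha, 100 m edge depth) and
mean Euclidean nearest-neighbor distance (m). Units are ranked per metric
in the direction of increasing fragmentation and classified
low/moderate/high by the median of their six ranks.

**Interfaces.** Binary class layers are dilated by a 150 m circular focal
neighborhood; the forest–agriculture and forest–built-up interfaces are
the cellwise products of the focal layers, and their product is the
combined conflict-prone interface (FAB = FA ∧ FB).

**Reliance models.** Scat presence collapsed to prey-group × origin
indicators, PCA on their covariance, PC1 oriented so domestic-reliant
scats score positive; then `PC1 ~ forest patch + predator` (with a
two-way ANOVA including the interaction) and
`PC1 ~ forest proportion + edge distance + fragmentation level`.

## Worked example

```python
from scatscape import synthetic, diet

truth, presence = synthetic.fixture_from_tables("leopard", seed=1)
profile = diet.diet_profile(presence, truth.catalog)
print(profile.loc["Bos taurus", ["s", "po_percent", "fo_percent"]].tolist())
print(round(diet.levins_standardized(presence), 2))
```

prints `[9, 24.32, 45.0]` — cattle occur 9 times among the leopard's 37
prey items (24.32% PO) and in 9 of 20 scats (45% FO) — and `0.18`, the
leopard's standardized niche breadth. The numbered drivers under
`analysis/` run the full story and write their tables under `results/`:

```text
$ python analysis/01_reconstruct_diet.py
leopard: 13 prey taxa, N=37 items over 20 scats; Bsta=0.18
  Bos taurus: PO 24.32%, FO 45.0%
  ...
$ python analysis/03_landscape_fragmentation.py
        PD     ED     MPA   MSI     MCA    ENN  median_rank frag_class
SH    0.29  18.18  243.00  1.01  189.54    NaN          1.0        low
...
ID    6.58  31.60    1.44  1.00    0.00  180.0          5.5       high
most fragmented forests (dispersed small patches): ['NK', 'ID']
```

`analysis/02` shows the filter chain recovering the generating presence
matrix exactly in 100/100 noisy replicates; `analysis/04` maps buffer
composition, edge distances and the interface zones; `analysis/05` runs
the end-to-end pipeline (hashed manifest, deterministic under a fixed
seed) and fits the reliance models. The `scatscape` CLI exposes the same
pipeline (`scatscape run --seed 1 --out results/run`).

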