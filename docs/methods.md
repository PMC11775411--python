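# Methods notes

This note records the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Diet fixtures and what they can(not) reproduce

The bundled leopard and leopard-cat fixtures are reconstructed from
published diet-composition tables that report, per prey taxon, percent
occurrence (%PO with total N prey items) and frequency of occurrence
(%FO over n scats). Occurrence counts are recovered as
`round_half_up(%PO · N / 100)` with N = 37 (leopard, n = 20) and N = 76
(leopard cat, n = 26). Two internal consistency checks run on every load:
the counts re-sum exactly to N, and for every taxon the %FO
reconstruction `round_half_up(%FO · n / 100)` equals the %PO count —
i.e., one occurrence is one scat containing the taxon, with no
within-scat multiplicity. Both hold for both tables.

The published aggregates fix only the *marginals*. Which taxa co-occur in
which scat is not recoverable from them, so `fixture_from_tables`
scatters each taxon's occurrences uniformly at random (seeded, without
replacement) over scats. Consequences, by design:

- every statistic that depends only on column sums (PO, FO, Levins,
  group/origin PO) is exact and seed-invariant;
- scat-level aggregates (e.g. "16 of 20 scats contained domestic prey")
  are *not* reproduced and are flagged as fixture-dependent where
  reported;
- the published regression/ANOVA fits (R² = 0.80 and 0.32) require the
  unpublished per-scat matrix and are replaced by parameter-recovery
  checks on synthetic data (below).

## Read simulation

Each scat's reads are multinomial over its true prey taxa (sharing
`1 − noise_fraction` equally) plus `noise_taxa` contaminant OTUs sharing
`noise_fraction` (total). `noise_fraction` is capped at 0.05 and
validity requires the per-taxon share `noise_fraction / noise_taxa` to
stay below the 1% presence threshold, so noise is removable in
expectation; the generator warns otherwise. Noise lineages are vertebrate
but live in a dummy class/genus namespace, so they can never collide with
real prey names and are removed only by the abundance rule — which is the
behavior under test. A scat that drew no prey taxa yields pure
predator-host reads (host DNA survives blocking oligos in real assays),
which the host-exclusion filter removes, giving an all-absent row — the
correct recovery of an empty truth row. Defaults (10,000 reads/scat,
5 noise taxa at 2% total, ≤5 leaked reads per OTU in the negative
control) are ordinary magnitudes for a 12S metabarcoding run after
denoising. The generator does not emulate read-level errors, chimeras or
index hopping: those are removed upstream by denoisers, and the pipeline
deliberately starts at the count table.

## Filter-chain conventions

- Negative-control threshold: the *maximum* per-OTU read count in the
  control, applied globally; entries ≤ T are zeroed. This is the most
  common reading of "minimum read threshold derived from the negative
  control" and the most conservative that still uses the control. A
  missing control degrades to T = 0 with a warning rather than an error.
- Consensus "51%": implemented as fraction ≥ 0.51, so 26/50 passes and
  25/50 fails.
- OTUs are pooled to their assigned taxon *before* the 1% rule, because
  diet tables report genus-level prey (*Mus* spp.) and abundance must be
  judged at the reported rank.
- Relative abundance uses retained (post-taxonomy-filter) reads per scat.
  The alternative (all reads) changes boundary cases only; the choice is
  fixed rather than exposed because the chain's idempotence property
  depends on it.
- Presence is strict (> 1%): a taxon at exactly 1% is absent.

## Landscape metrics

Patches are 8-connected components; perimeter counts every cell face
against a different class, nodata, or the raster/unit boundary, so
clipped analysis units have closed outlines (this diverges from
FRAGSTATS border options that can discount boundary edge). Core cells
are defined by strict center-to-center Euclidean distance > edge depth
to every cell center outside the patch (computed with a per-patch
distance transform; FRAGSTATS cell-edge variants differ by sub-cell
amounts). ENN is the minimum boundary-cell center distance to the
nearest other patch of the same class, missing (not zero) with fewer
than two patches. All six metrics are verified cell-for-cell against a
brute-force flood-fill/exhaustive-distance oracle on 200 random rasters
up to 20 × 20.

Rank directions for the median-rank classifier: PD, ED, MSI, ENN rank
ascending (larger = more fragmented); MPA and MCA are inverted (smaller
patches and cores = more fragmented); ENN ascending follows the
interpretation that farther-apart patches mean more isolation. Ties get
average ranks; units are split into equal-count tertiles of the median
rank with tied medians kept together in the lower class; a fully
degenerate set (all medians equal) is classed uniformly "moderate"
because no gradient exists to split on.

## Spatial context

Circle membership is by cell-center inclusion (≤ radius), chosen because
it is exactly brute-forceable; buffer proportions are over non-nodata
cells, and truncation at the raster edge warns rather than fails.
Forest-edge distance is signed (positive inside forest) to the nearest
forest/other-class cell face; faces against nodata or the raster border
are not edges, since the quantity is the boundary between forest and
another mapped land use. The focal statistic for interface mapping is
presence-within-neighborhood (focal maximum of the binary layer), the
only focal type under which the subsequent binary multiplication is
meaningful; the published interface percentages (41%/48%/39%) require
the real land-cover rasters and are validated here only through the
algebraic properties (FAB = FA ∧ FB, monotonicity in radius) and the
brute-force focal oracle.

## Statistical layer

PCA runs on the covariance (not correlation) matrix of the group ×
origin indicators — the variables share the 0/1 scale. The PC1 sign is
fixed by an orientation rule of this package's own: scats containing at
least one domestic taxon must score at least as high on average as scats
with none. The exact grouping fed to the original analysis is not
enumerable from its description ("various taxa, mostly based on order
and class"); group × origin is the closest reconstruction and is the
documented contract here.

Model recovery runs at the study's size (n = 46): the simulated predator
effect (1.5 SD) must fall inside its 95% CI in ≥ 93% of 200 replicates,
and the overall F-test holds a 5% type-I error (±2 percentage points)
over 2,000 null simulations. The two-way ANOVA with interaction is
rank-deficient when some patch × predator cells are empty — as in the
real sampling design — and statsmodels' warning to that effect is
expected, with the interaction tested on the available cells.

## Synthetic landscape and pipeline

The default pipeline landscape is a 200 × 200-cell (30 m) grid — 6 × 6 km,
scaled down from the ~800 km² study region to keep a full run under a
second while retaining every qualitative feature: six named forests with
graded patch structure (large compact SH/PH/CH/NJ, medium fragments NK,
many small dispersed fragments ID), an agricultural matrix, a built-up
core abutting one forest (so the forest–built-up interface is non-empty)
and a water strip. Scats are placed on forest cells with the study's
per-forest counts (leopard SH7/NJ1/CH2/PH7/NK3; leopard cat
SH7/NJ2/CH9/PH6/ID2). The per-forest median-rank classification on this
landscape reproduces the qualitative published pattern (dispersed-small
geometry → "high"); the published numeric Table-3 median ranks depend on
the real rasters and are not targets.

Determinism: every random draw flows from `RunConfig.seed` through
`numpy.random.default_rng`; the manifest hashes every output file, and
byte-identity of two same-seed runs is asserted in the test suite.

## Known limitations

- No biomass-corrected diet models; prey mass is carried as metadata
  only.
- No CRS handling or reprojection; all geometry is planar meters.
- ENN uses boundary-cell center distances; FRAGSTATS edge-to-edge
  variants differ by up to one cell width.
- The hit-table simulator draws identities/coverages uniformly within
  configured ranges and models discordance as a single sibling taxon;
  real BLAST hit lists have richer structure (multiple sibling taxa,
  identity-rank correlation) that the consensus classifier would handle
  but the generator does not produce.
- Passing tests demonstrate correctness of the operators and recovery
  under the stated noise model, not the field accuracy of metabarcoding
  diet profiling itself (primer bias, secondary ingestion and degraded
  DNA are out of scope upstream of the count table).
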