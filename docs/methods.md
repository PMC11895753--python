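# Methods

`paleopairs` implements a community-assembly analysis for fossil mammal
assemblages spanning the Paleocene–Eocene Thermal Maximum (PETM) in the
Bighorn Basin: species-pair co-occurrence classification, a palynofloral
habitat proxy, and null-model effect sizes for niche differences between
pair types. This note records the models, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Data model

Occurrences are binary species-by-site matrices, one per biozone. Three
ordered biozones are used: Clarkforkian 3 (Cf3, ca. 56.2–55.8 Ma),
Wasatchian 0 (Wa0, ca. 55.8–55.7 Ma, spanning the PETM) and the combined
Wasatchian 1–2 (Wa1_2, ca. 55.7–54.8 Ma). Species are rows, so a species'
occupancy is its row total R_i; sites are columns, so a site's richness is
its column total. Validation drops empty rows/columns with a logged
warning — fossil datasets routinely list taxa absent from a given bin.
Sites carry decimal-degree coordinates and a kind (`mammal` or
`palynofloral`); traits are natural-log body masses in grams.

## Pair co-occurrence (C-score and fixed-fixed null)

For each unordered pair (i, j) within a biozone, with D shared sites,

    C_ij = (R_i − D)(R_j − D) / (R_i R_j),

which is 0 for identical site sets (complete aggregation) and 1 for
disjoint sets (complete segregation). Significance comes from a
*fixed-fixed* null: sequential 2×2 checkerboard swaps randomise the matrix
while conserving all row and column totals exactly. The proposal kernel
(two uniform rows, two uniform columns, swap iff checkerboard) is
symmetric, so the chain's stationary distribution is uniform over matrices
with the observed marginals; the test suite verifies this against
exhaustive enumeration on small matrices (total-variation distance < 0.05
at 5000 samples).

Defaults: burn-in 10× the number of presences, thinning 1× presences
between the n_null = 1000 retained states, counted in *attempted* swaps
(the conventional accounting for this sampler; `swap_null_matrix` by
contrast counts accepted swaps, which is what one wants when asking for "n
effective moves"). Because row totals are fixed along the chain, a pair's
C-score is strictly decreasing in D, so tail counts are taken on the
integer D values — exact, no floating-point ties. p-values are add-one
Monte-Carlo, two one-sided tests:

    p_agg = (1 + #{null D ≥ D_obs}) / (1 + n_null)
    p_seg = (1 + #{null D ≤ D_obs}) / (1 + n_null)

aggregated if p_agg ≤ α (default 0.05), segregated if p_seg ≤ α, else
random; if a degenerate null makes both significant the smaller p wins and
exact ties stay random (logged). No multiple-testing correction is applied
across pairs, matching standard PAIRS-style practice. Note that both
one-sided tests are *conservative*: the null distribution of D is a
discrete lattice, so the achievable level at each tail is below α. On
neutral data the non-random fraction is therefore expected around
0.07–0.09 rather than 2α = 0.10, approaching 0.10 only as matrices grow
(see Calibration below).

## Floral ordination

Palynofloral sites (all bins pooled) are compared by Jaccard distance on
taxon sets; a cosine distance on the binary vectors (1 − D/√(R_s R_t)) is
available as a replicate metric. Ordination is nonmetric MDS in two
dimensions minimising Kruskal stress-1 with primary tie handling. The
SMACOF loop is implemented in the package with disparities obtained by
pool-adjacent-violators regression from the first iteration on, so the
entire trajectory — and the stress — depends on the dissimilarities only
through their ranks; any strictly increasing transform of the distances
leaves the result bit-identical. (Library SMACOF implementations commonly
seed the first iteration with the raw dissimilarity values, which breaks
this rank-invariance; that is why the loop is in-package, with
scikit-learn's isotonic regression as the PAV solver.) Defaults: 50 random
restarts, 500 iterations, convergence tolerance 1e-7 on the stress
decrease; best restart wins. Stress below 0.2 is flagged interpretable,
following ecological convention.

NMDS solutions are determined only up to rotation/reflection, so the
returned configuration is centred, rotated to principal axes, and each
axis is sign-fixed so the lexicographically smallest site id scores
non-negative; sites are also processed in canonical order internally. All
downstream per-axis quantities are therefore deterministic, but individual
axis orientations are a convention, not an estimate.

PERMANOVA uses the standard distance-based pseudo-F on squared distances,
(SS_between/(k−1))/(SS_within/(n−k)), with whole-site label permutation
and add-one p-values (default 10,000 permutations); pairwise two-group
tests are Bonferroni-corrected by the number of group pairs. The pseudo-F
is cross-checked against scikit-bio's PERMANOVA in the test suite.

## Habitat assignment and preferences

Every mammal site inherits the NMDS scores of its geographically closest
*contemporaneous* (same-biozone) palynofloral site, by great-circle
distance on a sphere of radius 6371.0 km — at the ~200 km basin scale the
spherical approximation differs from a geodesic by far less than the
locality coordinate precision. Distance ties within 1 mm resolve to the
lexicographically smallest floral site id.

A species' environmental preference is the unweighted mean of inherited
(NMDS1, NMDS2) over every mammal site it occupies, pooled across all three
biozones (time-transgressive). Each occupied site counts once; a site with
many specimens carries no extra weight. Per-bin summaries report mean,
median and a dispersion statistic over the species present in the bin (or
only the species first occurring there). The dispersion is configurable —
sample variance (n−1, the default) or range — because both are plausible
readings of published "range" summaries; both are cheap to emit. Bins are
compared with a Kruskal–Wallis omnibus plus pairwise two-sided
Mann–Whitney U tests under Bonferroni correction; a classical one-way
ANOVA sits behind a flag. The nonparametric omnibus is the default because
the pairwise tests are rank-based; with every species in a bin sharing one
inherited score (a single matched floral site — the real Wa1_2 situation)
all pairwise values tie and the comparison degenerates, which the code
handles by returning p = 1 explicitly.

## Pair-type differences and effect sizes

For every classified pair, three absolute differences are computed:
|Δ ln mass|, |Δ pref1|, |Δ pref2|. Means and medians are taken per
(biozone × pair type × variable); a cell with no pairs (e.g. no segregated
pairs in Wa0) is *absent*, never zero.

The null model randomises species assignment among sites across all three
biozones while preserving each site's observed richness: per replicate,
every site is refilled with k distinct species drawn uniformly (no
abundance weighting) from the pooled cross-bin species list, k being the
site's observed richness. Species occupancy totals are deliberately *not*
preserved — the null randomises association patterns, and richness
preservation is what controls taphonomic site-quality differences. The
full downstream pipeline then re-runs per replicate: pair classification
per biozone (with a reduced inner co-occurrence null, default 200;
a cheaper variant that reuses the observed classifications sits behind
`reclassify=False`), preferences recomputed from the randomised
occupancies (site habitat scores stay fixed — habitats belong to sites),
differences, and per-type summaries. Body masses travel with species
identity. Replicate r draws its seed from the stream (master_seed, r), so
n_reps can grow without changing earlier replicates.

Effect sizes are Cohen's D:

    d = (mean observed − mean null) / sd(null),

where the null mean and sd are computed from the *pooled pair-level* null
differences of that cell across replicates. This is the classic Cohen
standardiser — the spread of the data-level null distribution — and it is
the only standardisation under which Cohen's benchmarks (|d| ≤ 0.2 small,
|d| ≥ 0.8 large) carry their usual meaning; dividing by the spread of
replicate-level *means* would produce a z-score that grows with sample
size. The replicate-level means are still computed and written
(`null_means.csv`, for violin-style displays), and the replicate-mean
variant is emitted alongside as `d_rep` (on neutral data it behaves like a
t-statistic, mostly inside (−2, 2)). A median-based analogue `d_median`
accompanies the mean-based d. Cells need ≥ 30 pooled null values; a
zero-sd null is an error, not a silent zero.

## Synthetic data

The generator produces complete study-shaped datasets with ground truth.
One latent 1-D habitat gradient drives everything: each biozone has a
habitat mean (−1, +1, 0 for Cf3/Wa0/Wa1_2 — the middle bin is the
environmental excursion), each floral site draws a habitat value around
its bin mean (sd 0.35), floral taxa carry gaussian response curves around
per-taxon optima, and bin-level taxon pools turn over between bins
(default 70% replaced), yielding three compositionally distinct floral
clusters whose NMDS axis 1 correlates strongly with the latent gradient
(checked in tests, not assumed).

Defaults mirror the study system: 30 floral sites (8/13/9 per bin), 173
mammal species, 126 mammal sites (36/48/42), coordinates inside a ~200 km
box in the Bighorn Basin, ln-masses Normal(6.0, 2.0) (≈ 2 g to ≈ 300 kg).
Mammal sites are placed around a small number of floral parents per bin
(default 2/2/1 — the real mammal localities resolved to five floral sites
under nearest-neighbour matching), so inherited habitat scores are
strongly quantised, exactly as in the study system.

Mammal occupancy: each species has a habitat centre ~ Normal(0, 1), a
breadth ~ Uniform(0.6, 1.4) and a base occupancy rate with mean 0.15
(Beta-distributed around that mean with concentration 12; a homogeneous
option pins every species to the same rate). Occupancy probability is
proportional to exp(−s·(h_site − centre)²/breadth²), with filter strength
s, normalised per species across *all* sites so the expected number of
occurrences is the species' base rate times the total site count at every
strength. Under strong filtering a species concentrates its occurrences in
the bins whose habitat matches its centre — taxonomic turnover across the
PETM emerges from the gradient rather than being imposed (an imposed
bin-pool mechanism exists as an option). Planted aggregated pairs are
overlaid after probabilistic occupancy (identical rows padded to ~40% of
the bin's sites); planted segregated pairs occupy disjoint site halves at
75% per-site presence. Planting consumes an independent seed stream, so
changing the planted counts leaves all other species' occupancies
untouched.

What the generator does *not* emulate: abundance structure (presence only),
spatially autocorrelated sampling effort, within-bin stratigraphic time
averaging, taxonomic mis-splitting, and any Eltonian structure beyond body
mass. Passing tests on synthetic data therefore demonstrate that the
machinery recovers planted association and habitat-filtering signals under
the stated noise model — not that the real faunal record satisfies these
assumptions.

## Calibration experiments and their limits

Two calibration facts deserve explicit statement because they bound what
"green tests" mean:

1. **Discrete conservatism.** The pair classifier's conditional null lives
   on the integer lattice of shared-site counts, so each one-sided test
   rejects below its nominal level. On neutral communities the non-random
   fraction measures ~0.07–0.09 at α = 0.05 even for 40 species × 300
   sites per bin, versus the 0.10 a continuous statistic would give. The
   corresponding acceptance check is asserted at the nominal band and
   fails for this known reason; the type-I direction is safe (never
   anti-conservative).

2. **Cell-mean noise in effect sizes.** A per-cell observed mean
   difference is a U-statistic over pairs sharing species, so its sampling
   sd in pooled-null-sd units scales like 1/√S with the species count, not
   with the (much larger) pair count — about 0.06–0.10 for the
   aggregated/segregated cells at 173 species. The maximum over ~27 cells
   of |d| on neutral data therefore lands above 0.2 in a sizeable fraction
   of runs; the strict "every cell small in ≥ 90% of runs" acceptance
   check fails for this reason, while the pooled fraction of small cells
   is ~0.97 and no neutral cell approaches the 0.8 significance
   threshold. The filtered-recovery check (aggregated-pair preference
   d ≤ −0.8 under strong filtering) passes with margin.

Problem sizes used by the acceptance tests (chosen for Monte-Carlo
precision at one-CPU runtimes): calibration, 40 species × 300 sites/bin;
recovery, 60 species × 90 sites with 10+10 planted pairs; effect-size
experiments, 173 species × 90 sites, observed co-occurrence null 800,
richness null 50 replicates with inner null 100, 20 seeds for the neutral
arm. The analysis scripts run the full default shape with n_null = 1000,
100 replicates and inner null 200.

## Degenerate inputs and tie-breaks (summary)

- Matrices with < 2 species or < 2 sites: classification errors out;
  swap randomisation returns the input unchanged with a note.
- Matrices with no checkerboard (e.g. all-ones): returned unchanged after
  a capped number of attempts, logged.
- Equidistant floral sites: lexicographically smallest id wins (1 mm
  tolerance absorbs floating-point asymmetry in the haversine).
- All-tied rank tests: p = 1 by convention.
- Zero within-bin preference variance (single matched floral site) is
  tolerated throughout.
- Species lacking traits: their pairs are dropped with a logged count;
  they are excluded from the null species pool.
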