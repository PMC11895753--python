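# paleopairs

Community-assembly analysis for fossil mammal faunas across the
Paleocene–Eocene Thermal Maximum (PETM): which species pairs co-occur more
(aggregated) or less (segregated) than chance, and whether those pairs are
unusually similar or dissimilar in habitat preference (Grinnellian niche,
proxied by palynofloral ordination scores) and body mass (Eltonian niche).
Written for quantitative paleoecologists working with presence/absence
occurrence data binned into biozones — here the Bighorn Basin biozones
Cf3, Wa0 and Wa1–2 — but the machinery is generic.

## The statistics at its core

**Pair classification.** For species i, j with occupancies R_i, R_j
(row totals) and D shared sites, the scaled C-score is

    C_ij = (R_i − D)(R_j − D) / (R_i R_j)  ∈ [0, 1],

0 = complete aggregation, 1 = complete segregation. Each pair is tested
against a fixed-fixed null (sequential checkerboard swaps conserving all
row and column totals) with two one-sided add-one Monte-Carlo p-values at
α = 0.05.

**Habitat proxy.** Palynofloral sites are ordinated by nonmetric MDS
(Kruskal stress-1, Jaccard distances; PERMANOVA for biozone separation).
Every mammal site inherits the scores (NMDS1, NMDS2) of its nearest
contemporaneous floral site; a species' environmental preference is the
mean over its occupied sites, pooled time-transgressively across biozones.

**Effect sizes.** Absolute pair differences |Δ ln mass|, |Δ pref1|,
|Δ pref2| are averaged per (biozone × pair type) and compared to a
richness-preserving null — every site refilled with uniformly drawn
species, site richness conserved, the whole pipeline re-run per
replicate — via Cohen's D, d = (mean observed − mean null)/sd(null), with
|d| ≤ 0.2 small and |d| ≥ 0.8 large.

A synthetic-data generator (`paleopairs.synth`) produces study-shaped
datasets (173 species, 126 mammal sites, 30 floral sites in three bins)
driven by one latent habitat gradient, with tunable filtering strength and
plantable aggregated/segregated pairs, so every stage is testable with
known ground truth.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a
synthetic study-shaped dataset and write their tables under `results/`:

```
python analysis/01_generate_data.py
python analysis/02_ordinate_flora.py
python analysis/03_classify_pairs.py
python analysis/04_habitat_preferences.py
python analysis/05_effect_sizes.py
```

`02_ordinate_flora.py` prints

```
NMDS stress = 0.0970 (interpretable; limit 0.2)
PERMANOVA overall F = 8.92, p = 9.999e-05
  Cf3 vs Wa0: F = 8.83, Bonferroni p = 0.0003
  Cf3 vs Wa1_2: F = 9.13, Bonferroni p = 0.0003
  Wa0 vs Wa1_2: F = 8.87, Bonferroni p = 0.0003
```

— the three biozones form distinct floral clusters (stress well under the
0.2 interpretability limit), so the ordination is a usable habitat proxy.
`03_classify_pairs.py` prints the pair census:

```
biozone  aggregated  segregated  random  total_significant  total_pairs
    Cf3          59          49    3462                108         3570
    Wa0          86          48    4052                134         4186
  Wa1_2         125          69    8321                194         8515
```

— most pairs are random; significant pairs rise with richness across the
interval. `04_habitat_preferences.py` reports that the 126 mammal sites
resolve to just 5 distinct floral sites under nearest-neighbour matching
(the spatially clumped regime of the real basin), and that mean
preferences differ strongly between bins (Kruskal–Wallis p ≈ 3e-28 on
NMDS1). `05_effect_sizes.py` prints the effect-size table; on this
moderately filtered dataset every body-mass cell is small
(|d| ≤ 0.16 — mass plays no role in assembly, the functional-stasis
pattern), while preference cells are large: the observed communities are
habitat-structured throughout, so all pair types differ more in
preference than the richness null (which destroys habitat structure)
predicts, aggregated pairs least so.

The same pipeline runs from one YAML config via the CLI:

```
paleopairs synth --filter-strength 2.0 --seed 7 --out data/
paleopairs run --config run.yaml
```

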