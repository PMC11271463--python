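# enphylo

Species distribution modelling for **extremely rare species** — down to two
occurrence records — plus the tiered ensemble machinery, scenario
projection and climate × land-use interaction analysis needed to turn
per-species niche models into community-level change maps.

The package is aimed at spatial ecologists and conservation modellers who
face the "rare species modelling paradox": the taxa whose futures matter
most are exactly the ones with too few records for conventional SDMs.

## The method

Species are routed by occurrence-cell count into three tiers:

| cells   | route                                                       |
|---------|-------------------------------------------------------------|
| < 15    | phylogenetically imputed ENFA niche (the rare-species route) |
| 15–30   | ensemble of small (bivariate) models, AUC-weighted           |
| > 30    | GLM + RF + MaxEnt-style ensemble on all predictors           |

**Niche model.** For well-sampled species, Ecological-Niche Factor
Analysis contrasts used against available environment in background
z-score units: the marginality vector *m* (presence mean; overall
marginality *M* = ‖*m*‖/1.96) and specialization axes — directions
orthogonal to *m* maximizing the background-to-species variance ratio λ.
Habitat suitability is the chi-square survival probability of the
factor-space Mahalanobis distance D² to the presence centroid,
P(χ²_k ≥ D²).

**Rare species.** Niche traits [*m*; √λ₁·u₁; √λ₂·u₂] of well-sampled
relatives evolve with phylogenetic signal, so a rare tip's traits are
imputed as the Brownian-motion conditional expectation
μ̂ + C_to C_oo⁻¹ (x_obs − μ̂) on the phylogeny. Converting the imputed
niche into suitability needs at least five presence cells; species with
2–4 cells are topped up with **pseudo-presences**: chess-knight neighbours
of the reference cells ranked by environmental similarity (the Pearson
"angle" between standardized environment vectors), taking the
n = 5 − n_references best. Phylogenetic uncertainty is handled by
refitting over randomly perturbed trees (default 50) and keeping the
best-AUC replicate; models below AUC 0.7 are rejected.

**Evaluation.** Bootstrap cross-validation (with-replacement draw of the
80 % training portion, clean 20 % holdout, 10 repeats) scoring AUC, TSS
and the continuous Boyce index.

**Projection.** Fitted models are projected onto scenario stacks
(dynamic climate per GCM × SSP, dynamic land use per SSP, both), binarized
under three threshold schemes (SensSpec, MaxSensSpec, TenPerc) — 45
presence/absence maps per species under the default 3-GCM × 2-SSP
factorial — and cropped to the area reachable at 1 km/yr dispersal
(minimum convex polygon + 60 km buffer for a 2010→2070 horizon).

**Community change.** Binary maps stack into per-cell species richness,
loss L and gain G (SR_future = SR_current − L + G). Per cell, the loss (or
gain) counts under dynamic land use (a), dynamic climate (b) and the
combined scenario (c) classify the interaction: *only climate* (a=0,b>0),
*only LULC* (a>0,b=0), *synergistic* (c>a+b), *additive* (c=a+b),
*antagonistic* (c<a+b). Residual spatial autocorrelation is checked with
Moran's I correlograms.

Everything runs on simulated virtual species with known truth
(`enphylo.synthetic`), so parameter recovery is always measurable; real
runs consume ESRI ASCII grid rasters, occurrence CSVs and Newick trees.

## Worked example

```bash
python examples/01_rare_species_fit.py
```

```
species sp02: 3 reference cells + 2 pseudo-presences = 5 presence cells
chosen phylogeny replicate: 4 (0 = input tree)
cross-validated AUC: 0.924
Spearman rho vs true suitability: 0.777
```

A virtual species known from **three cells** is fitted through
phylogenetic imputation: two knight-move pseudo-presences complete the
five presence cells, the best of 20 tree replicates scores AUC 0.92, and
the resulting suitability map rank-correlates at ρ = 0.78 with the true
(normally unknowable) suitability surface.

`examples/02_enfa_niche.py` prints the ENFA niche summary of a
well-sampled species (marginality per layer, specialization eigenvalues);
`examples/03_scenarios_and_interactions.py` runs the full pipeline on a
compact system and prints the tier/skill table, diversity change under
the severe combined scenario, and the interaction-percentage tables.

A thin CLI wraps the same pipeline:

```bash
enphylo simulate --out fixture/ --seed 4 --species 32
enphylo run-all --fixture fixture/ --seed 4 --out run/
```

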