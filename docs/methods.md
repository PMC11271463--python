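# Methods

This note documents the models, the numerical choices and the places
where the design was genuinely open, in the order the pipeline runs them.

## Data model and geometry

All geometry is planar, in kilometres; geographic inputs must be
projected upstream. Grids are 0-based `(row, col)` with half-open cell
membership `[edge, next_edge)`; a point maps to
`floor((coord − origin)/cell_size)` on both axes, so the vertical axis
grows with the row index. Rasters are single-layer ESRI ASCII grids
(plain text); values are written with `%.17g` so float64 round-trips
bit-exactly. The nodata mask of a stack is the union over layers.

Occurrence cleaning keeps records whose *stated* coordinate precision
(a column of the source table, never inferred from trailing zeros) is at
least 2 decimal places, drops exact duplicates and out-of-bounds rows;
rasterization de-duplicates per cell. Background cells (default 10,000)
are drawn uniformly without replacement from the valid grid, optionally
within a caller-supplied ecoregion mask — how that mask is built is the
caller's decision, not the package's.

Collinearity screening is greedy: while any retained pair exceeds
|Pearson r| = 0.7 over the sampled cells, the layer with the largest mean
absolute correlation to the others is removed; ties remove the later
layer in input order; constant layers are removed first with a warning.

## ENFA and suitability

Layers are standardized to mean 0, sd 1 over the background cells
(population 1/n estimators throughout, so 5-point and 500-point fits
share conventions), and the same transformation is reused verbatim for
every scenario stack.

The marginality vector `m` is the presence mean in standardized space;
`M = ‖m‖/1.96` follows the ENFA convention (M ≈ 1 means a 1-sd shift at
the 95% envelope). Specialization axes are generalized eigenvectors of
the background covariance against the (ridged) presence covariance,
restricted to the orthogonal complement of `m` via a QR basis; the
eigenvalue λ is the background-to-species variance ratio. Each axis is
sign-fixed (largest-|loading| entry positive) so axes are comparable
across species. The retained factor basis is the marginality direction
followed by the top `min(k_spec, V−1, n_presences−3)` specialization
axes.

Suitability maps the factor-space Mahalanobis distance D² to the presence
centroid through the chi-square survival function with df = retained
factor count. This gives a calibrated [0, 1] scale; alternatives (rank or
max normalization) would preserve the ranking but not calibration. The
presence covariance in factor space is ridged by `1e-6·trace/k·I`.

## Phylogenetic imputation and the rare-species fit

The imputable trait encoding is `[m; √λ₁·u₁; …; √λ_s·u_s]` with s = 2 by
default: scaling axes by √λ lets specialization magnitude survive the
averaging implicit in conditional expectations. Imputation is exact
Brownian-motion conditioning: with C the phylogenetic covariance (shared
root-to-MRCA path lengths), the root state is estimated by GLS over
observed tips and the target's vector is `μ̂ + C_to C_oo⁻¹ (x_obs − μ̂)`
per dimension, with a per-dimension conditional variance reported.
`C_oo` is inverted with a pseudo-inverse so duplicated (zero-divergence)
tips stay exact rather than failing.

Pseudo-presences: the candidate set is the union of the 8 chess-knight
neighbours of the reference cells (off-grid, nodata and reference cells
excluded, stable row-major order). Candidates are ranked by the mean
Pearson correlation between their standardized environment vector and
each reference's vector — the mean, not the max, because 2–4 references
are few and all should count; ties break by geographic distance to the
nearest reference, then row-major index. The top `5 − n_references` are
promoted, so the presence set is always exactly 5 when 2–4 references
exist and enough candidates do.

Converting the imputed niche into suitability re-uses the Mahalanobis
machinery with one deliberate change. The presence cells supply the
factor-space **centroid**; they cannot supply the **metric**, because
pseudo-presences are selected for maximal environmental similarity to the
references and the empirical covariance of five such cells is
structurally near-singular — left alone it collapses suitability into a
spike around the presence cells. The imputed niche itself carries the
widths: along specialization axis j the species variance in standardized
units is 1/λ_j (capped at the background's 1), and along the marginality
axis — whose width the trait encoding does not carry — the median
marginality-axis presence variance across donor species serves as a
clade-level prior. The factor covariance diagonal is floored by these
widths. On the default fixture this lifts truth rank-correlation for
2–4-cell species from ≈ 0.36 to ≈ 0.74 without touching well-sampled
fits. The rare-species niche is thus genuinely *imputed*, not learned
from pseudo-presences.

Phylogenetic uncertainty: the fit is repeated over the input tree plus
`n_tree_reps − 1` (default 50 total) perturbed trees — one random
nearest-neighbour tip swap plus multiplicative log-normal branch jitter
(sd 0.1), seed-deterministic — and the replicate with the best mean
bootstrap AUC is kept; replicates below AUC 0.7 are rejected, and if all
are, the species is not modelled. Because selection maximizes AUC, the
reported TSS/Boyce of the chosen replicate may be slightly optimistic; no
correction is applied.

## Ensembles and evaluation

Tier bounds: < 15 cells → imputation route; 15–30 → ensemble of small
models (every C(V,2) bivariate layer pair per learner, members below AUC
0.7 dropped, survivors AUC-weighted); > 30 → all-predictor ensemble of
three learners. The learners: an unpenalized quadratic-logistic GLM
(linear + squared terms + pairwise products; ridge fallback with a
warning on perfect separation), a 500-tree random forest, and a
MaxEnt-style model — an L1-penalized presence–background logistic
regression on the same expanded features with balanced class weights,
penalty chosen from {0.01, 0.1, 1.0} by 5-fold cross-validation. The
penalized-logistic formulation is the standard statistical equivalence
used when a Java MaxEnt runtime is undesirable; it sits behind the
learner enum, so a different backend can be substituted.

Bootstrap evaluation: per replicate the presences (and independently the
background) are partitioned 80/20 at random, the training multiset is
drawn with replacement from the 80 % portion, and AUC (Mann–Whitney),
TSS (exhaustive threshold scan, presence rule score ≥ t) and the
continuous Boyce index (101 overlapping windows of width range/10, P/E
against window midpoints by Spearman; zero-background windows dropped,
NaN below 3 usable windows) are computed on the clean 20 % holdout.
Replicates whose holdout holds fewer than 2 presences are skipped — the
rare-species route relaxes this to 1, since 5-presence species always
leave a single test presence and AUC remains well-defined with one
positive. Ensemble averaging weights passing members by mean AUC.

## Projection, dispersal and community change

Thresholds come from training scores: SensSpec minimizes
|sensitivity − specificity|; MaxSensSpec maximizes TSS; ties resolve to
the stricter (higher) threshold. TenPerc is the nearest-rank 10th
percentile of training presence scores — the percentile reading of the
scheme, chosen over literal minimum-training-presence as the conservative
match to its name, and switchable. Binarization uses score ≥ threshold;
NaN cells are never presences.

The dispersal constraint is the minimum convex polygon of the occurrence
points (a segment for two) dilated by rate × horizon — 1 km/yr over
2010→2070 gives 60 km; both years are config values (future climate
layers may be labelled later than the horizon's end; the horizon is
deliberately independent). Cell membership is by centroid, with
occurrence cells always retained. The constraint only removes presences;
applying it twice equals applying it once.

Diversity: SR/L/G per cell from stacked binary maps, with the matched
(threshold, GCM, SSP) current map as each future map's baseline.
Interaction classification runs on integer per-combination counts —
never on averaged counts — with single-driver cells (a=0 or b=0) decided
before the c vs a+b comparison; a=b=0 with c>0 is synergistic (c exceeds
a+b=0) and is logged as its own diagnostic case. Percentages are computed
per combination over cells with any interaction, then averaged across
(threshold, GCM) combinations, separately per SSP and per mode
(loss/gain).

Moran's I correlograms on model residuals (observed 0/1 minus predicted
score at presence plus sampled background points) use binary distance-
class weights and permutation p-values (two-sided around the null mean
−1/(n−1)); the pipeline reports the across-class mean I and the fraction
of significant classes per species.

## The synthetic study system

The generator emulates the structure real runs would consume without any
downloads. Climate layers are a random planar gradient plus
Gaussian-kernel-smoothed white noise (kernel width = the spatial
correlation range, default 5 km; 0 gives white noise); land-cover layers
are Euclidean distance transforms from randomly seeded category patches.
The clade is a unit-height birth–death tree whose per-layer niche optima
evolve by Brownian motion (rate 1 by default), so climatic preferences
carry phylogenetic signal; optima in z-units are mapped to layer units by
each layer's valid-cell mean/sd, and Gaussian niche breadths are drawn
uniformly in 0.6–1.4 sd. The Gaussian (rather than threshold) truth
niche gives graded suitability so AUC and Boyce are informative, with
breadth controlling rarity. Occurrences are drawn without replacement
with probability proportional to true suitability.

Future scenarios reproduce the factorial shape of a 3-GCM × 2-SSP study:
the SSP analogue is shift magnitude (mild = half, severe = full), the GCM
analogue is independent additive jitter around the shared shift, and
dynamic land use relocates a fraction of the category patches (half the
fraction under the mild SSP) and recomputes distances. Dynamic-climate
stacks carry bit-identical land-cover layers and vice versa.

The default fixture is a 60 × 60 km grid, 5 climate + 3 land-cover
layers, 32 species with occurrence counts spread across the tree and the
three tiers, always including 2-, 3- and 4-cell species (rarity is
shuffled across tips so rare species have well-sampled relatives, as in
real clades). Tests and the acceptance script run this fixture with
fixed seeds; the heavier checks use subsets (e.g. the five richest
species for the ensemble-skill check, 20 tree replicates instead of 50
for rare fits) — sizes chosen to probe the same properties at a fraction
of the cost.

What passing tests do **not** show about real data: the virtual
landscape has no geographic barriers or connectivity structure, niches
are exactly Gaussian and noise-free, the phylogeny is known without
error beyond the injected perturbations, and detection is perfect —
recovery numbers here are upper bounds on what messy occurrence data
would give.

## Reproducibility

One master seed spawns per-stage, per-species sub-seeds by CRC-hashing
`"{seed}:{stage}:{species}"` (kept below 2³¹), so adding a species never
perturbs the others' results and reruns are bit-identical. The CLI's
stage subcommands recompute earlier stages deterministically from the
seed instead of deserializing fitted models (random forests have no
text representation); written grids and tables are the resumable
artifacts. Linear scorers and ENFA models serialize to JSON.

## Known limitations

- The knight-move criterion is one reading of "adjacent" pseudo-presence
  placement; it is isolated behind a single function for substitution.
- The buffer dispersal model ignores connectivity between suitable
  patches; projected gains are optimistic.
- AUC-based replicate selection biases the selected model's other
  metrics upward.
- Per-species ecoregion background masks are caller-supplied; the
  default background is the whole valid grid.
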