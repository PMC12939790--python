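# Methods

This note records the statistical model behind `metstab`, the choices made
where the literature leaves room, and what the synthetic tests do and do
not establish.

## Data model

The unit of input is a plot record (environment, genotype, block, role,
yield in t/ha). Augmented designs replicate only a few check cultivars
within blocks of each environment; test lines appear once per environment.
All index formulas operate on the genotype × environment cell-mean matrix
X with margins X̄ᵢ (genotype means), X̄ⱼ (environment means, also the
environmental index Eⱼ) and grand mean X̄. Cell values are raw replicate
means by default; an optional augmented-design adjustment subtracts each
block's check deviation (block check mean − environment check mean) from
its line plots before averaging. The default is no adjustment: the
downstream index formulas are defined on cell values, and adjustment is a
design-specific correction the user must opt into knowingly.

Missing cells are a hard error by default. The formulas assume a complete
matrix, and silent imputation changes every index; opt-in environment-mean
imputation is available and flags the imputed cells in the output. Yields
are stored in t/ha throughout; the reader never rescales units silently.

## Univariate indices

For genotype *i* over *n* environments:

- S²ᵢ = Σⱼ (X_ij − X̄ᵢ)² / (n−1); SDᵢ = √S²ᵢ; CVᵢ = 100·SDᵢ/X̄ᵢ (requires a
  positive mean).
- Ecovalence W²ᵢ = Σⱼ (X_ij − X̄ᵢ − X̄ⱼ + X̄)², the squared row norm of the
  double-centered matrix; Σᵢ W²ᵢ equals the interaction sum of squares
  exactly, which the tests exploit as a cross-check.
- Shukla's stability variance is computed in two modes and always reported
  side by side: `paper_literal` = W²ᵢ/(n−1), the per-row interaction mean
  square, and `classical` = [g(g−1)W²ᵢ − Σₘ W²ₘ] / [(g−1)(g−2)(n−1)],
  Shukla's (1972) unbiased variance-component estimator (needs g ≥ 3 and
  can go negative by sampling error). They differ in scale and can rank
  differently; the configuration selects which one feeds the rank
  aggregation (default `paper_literal`).
- Joint regression regresses the genotype's yields on the environmental
  index with the line anchored at (Ē, X̄ᵢ): slope bᵢ, deviation mean square
  S²dᵢ on n−2 df, and R²ᵢ. Because the regressor is the column-mean
  profile, the slopes average to exactly 1 — a property test. A
  zero-variance genotype has an undefined R² and is reported as missing
  (NaN) rather than 0 or 1. Two environments make S²d undefined (n−2
  divisor); that is a hard error, not a silent fallback.

## SID / RSID rank aggregation

Each index is ranked over genotypes (average ranks for ties, missing
values ranked last), the per-genotype ranks are combined by their harmonic
mean (SID), and the ascending rank of SID is the RSID. The harmonic mean
rewards being top-ranked by at least some indices; the arithmetic mean
rank is reported alongside. The aggregated set is the seven stability
indices (S², CV, W², σ², b, S²d, R²) without mean yield itself; a yield
rank can be added by configuration. Yield is instead displayed against the
aggregate rank, and genotypes are classified into quadrants: A = yield
above the mean and rank better than the mean rank, then B/C/D
counter-clockwise; genotypes exactly on a mean line go to the favorable
side and are flagged.

Ranking direction was the one genuinely open design point. Two modes are
provided:

- `stability` (default): each index is ranked in its stability-favorable
  direction — ascending for the dispersion measures (S², CV, W², σ²,
  S²d), descending for R², and by |b − 1| for the slope (closeness to
  average responsiveness). This is the direction under which the method
  behaves as a stability-selection tool: in simulations with planted
  zero-interaction, high-yield genotypes, those genotypes attain the top
  RSID positions and land in quadrant A (a property the test suite
  enforces).
- `yield_aligned`: each index's Pearson correlation with mean yield is
  computed and indices correlating negatively have their values inverted
  (reciprocals when all-positive, otherwise reversed ranks — identical
  orderings) before ascending ranking. This makes every index's rank-1 end
  point toward high yield. The two modes disagree precisely when the
  stable genotypes are also the high-yielding ones: then every dispersion
  index correlates negatively with yield and `yield_aligned` reverses its
  stability direction, pushing the most stable genotypes to the bottom.
  Because that behavior defeats the selection purpose, it is not the
  default, but it is kept for users who want a purely yield-concordant
  composite. Correlations with yield are computed and reported in both
  modes.

SID is invariant under strictly increasing transforms of any index column
(only ranks enter), harmonic ≤ arithmetic mean rank with equality iff all
ranks agree, and the result is independent of genotype input order — all
property-tested.

## Combined ANOVA and AMMI

Environment, genotype and interaction sums of squares come from the line
cell-mean matrix (checks excluded). The replicated checks estimate two
error strata, with degrees of freedom derived from the block labels
actually present, never hard-coded: replication-within-environment
(between-block SS of checks within each environment, df Σₑ(bₑ−1)) and the
residual (check × block interaction within environments, df
Σₑ(bₑ−1)(cₑ−1)). F(Environment) uses the replication mean square as
denominator; genotype, interaction and principal-component F-tests use the
check residual mean square. Without checks the user must supply an
external error mean square. The trial CV% is 100·√MS_residual / grand
mean. Significance codes are ***, **, * and ns at 0.001/0.01/0.05.

The interaction principal components are the SVD of the double-centered
matrix. Scores are stored in the symmetric √λ scaling so the product of
genotype and environment scores reconstructs the interaction; alternative
focusing conventions change only a column-wise rescaling. Each component's
sign is fixed so that the environment loading of largest magnitude is
positive — output is deterministic across linear-algebra backends.
Component degrees of freedom follow Gollob (g + n − 1 − 2k). AMMI
stability is the Euclidean norm of the first k (default 2) scaled genotype
scores; a genotype with no interaction sits exactly at the origin.

## GGE and which-won-where

The GGE decomposition is the SVD of the environment-centered matrix
(X_ij − X̄ⱼ), retaining genotype main effect plus interaction; the energy
identity Σλ² = SS_genotype + SS_interaction is tested. Default
preprocessing is centering only (the common "centering = 2, scaling = 0"
convention); division by environment standard deviations is available by
flag.

The which-won-where view takes the convex hull of the genotype markers in
PC1–PC2 and draws, through the origin, the outward normal of each hull
edge. The sector between the normals of a vertex's two adjacent edges is
that vertex's normal cone: every direction in it attains its maximum
projection at that vertex, so the vertex is the predicted winner for all
environments whose score vectors fall in the sector (the tests verify
winners against a direct max-projection scan). Sectors without
environments are still reported and flagged. An environment exactly on a
boundary ray joins the counter-clockwise sector, deterministically. A
collinear genotype cloud has no 2-D hull and raises a degenerate-hull
error. Proximity output reports genotype–environment distances and origin
distances in PC1–PC2 space, plus a broadly-favorable flag (positive PC1,
|PC2| at or below the genotype median).

## Correlations and clustering

Pearson correlations among yield and the indices use pairwise-complete
observations; p-values come from the t transform t = r·√((m−2)/(1−r²)),
two-sided, with no multiplicity correction on the primary output (a
Holm-adjusted matrix is emitted alongside). Hierarchical clustering of the
yield matrix defaults to Euclidean distance with Ward linkage on both
axes — nothing in the method constrains this choice, so it is configurable
and recorded in the output metadata. Leaf order uses optimal leaf
ordering, making the heatmap layout deterministic and invariant to input
row order. Heatmap values stay in raw t/ha by default; z-scoring per
genotype is opt-in.

## Synthetic trial generator

The generator samples the AMMI model directly: centered Gaussian genotype
effects (sd 0.8 t/ha) and environment effects (sd 1.5 t/ha) around μ = 7
t/ha, a rank-r interaction with prescribed λ² shares, and i.i.d. Gaussian
plot noise (sd 0.3 t/ha by default) — magnitudes chosen to resemble a
small-grain MET where environments dominate, genotypes matter, and the
interaction is real but smaller than the main effects. The default layout
is 40 unreplicated lines plus 4 checks in quadruplicate across 4
environments. The interaction score vectors are orthonormalized seeded
Gaussian draws built orthogonal to the constant vector (and zero on
planted-stable rows), so the planted interaction is exactly
double-centered: at zero noise the AMMI fit returns the planted shares,
scores and singular values to machine precision, planted-stable rows have
exactly zero ecovalence, and the Finlay–Wilkinson variant (cell mean =
genotype mean + bᵢ·(Eⱼ−Ē), slopes rescaled to mean 1 because the empirical
index enforces it) returns the planted slopes exactly. The interaction
magnitude is set by a per-cell scale `sd_gei` (total interaction SS =
sd_gei²·g·n); shares alone do not fix a magnitude. Optional block effects
(`sd_block`) and a yield bonus for planted-stable lines
(`planted_stable_advantage`) support the ANOVA and selection tests.

What the generator does **not** emulate: spatial field trend within
blocks, heteroscedastic or non-Gaussian plot error, check-by-environment
interaction (checks are additive stability references by default), and
missingness. Passing tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to field
artifacts real METs can contain.

## Numerical choices and limitations

- All margin identities are tested at 1e-8–1e-10 relative tolerance;
  zero-noise recovery at machine-precision tolerances.
- Average ranks for ties everywhere; rank sums are conserved.
- Reciprocal inversion is only order-reversing for all-positive columns;
  columns containing non-positive values are rank-reversed instead (the
  orderings coincide whenever both are defined).
- Matrices require at least 2 genotypes and 2 environments; joint
  regression requires 3 environments; the classical Shukla estimator
  requires 3 genotypes. Violations raise typed errors rather than
  returning silent NaN.
- Monte-Carlo checks in the test suite and acceptance script use 50–120
  replicates of trials up to 30 × 6 — sizes at which the whole suite runs
  in seconds while leaving Monte-Carlo standard errors small relative to
  the tested tolerances.
- The explained-share estimator is biased upward for trailing components
  under noise (noise spreads energy over all axes); the recovery tests
  allow for this with a noise-share-sized bias term.
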