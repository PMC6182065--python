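# Methods

`tendernet` implements a differential co-expression analysis for a
quantitative carcass phenotype — Warner-Bratzler shear force (SF,
kgf/cm²), the standard mechanical measure of beef tenderness — from
extreme-group selection through regulator scoring. Every stage can be run
against synthetic data with planted truth, so the pipeline's operating
characteristics are measurable without any external download.

## Animal model and extreme-group selection

Breeding values are predicted under the classical additive animal model

    y = Xβ + Zu + ε,   u ~ N(0, A σ²ₐ),   ε ~ N(0, I σ²ₑ),

with fixed effects for contemporary group (dummy-coded, first level
dropped) and age (centered linear covariate), and A the numerator
relationship matrix built from the pedigree by the tabular recursion
(aᵢⱼ = ½(a_{j,sire(i)} + a_{j,dam(i)}), aᵢᵢ = 1 + Fᵢ; unknown parents
contribute zero — no genetic groups). Henderson's mixed-model equations
are assembled densely and solved by direct inversion; per-animal accuracy
uses the standard prediction-error-variance definition
acc = √(1 − PEV/σ²ₐ), clamped to 0 with a warning if PEV exceeds σ²ₐ
numerically. Dense inversion of A and of the coefficient matrix is a
deliberate desk-scale choice (hundreds of animals); sparse-inverse
techniques would be needed beyond ~10⁴ animals.

Variance components default to EM-REML. The EM fixed point

    σ²ₐ ← (û′A⁻¹û + tr(A⁻¹C_uu)σ²ₑ)/q,   σ²ₑ ← (y′y − β̂′X′y − û′Z′y)/(n − r)

is evaluated in the REML-contrast eigenbasis: with K an orthonormal basis
of the orthogonal complement of col(X) and K′(ZAZ′)K = U diag(d) U′, both
updates reduce to O(n) sums over eigenvalues, so one eigendecomposition
buys arbitrarily many EM iterations. EM converges monotonically but
sublinearly near the σ²ₐ = 0 boundary; convergence is therefore judged by
the absolute step relative to the phenotypic variance (tol 1e-10, default
cap 100 000 iterations) with a boundary shortcut at σ²ₐ ≤ 1e-5·var(y).
Supplying both variance components bypasses REML entirely.

Animals are ranked on EBV and the n_high largest / n_low smallest are
labelled H and L (defaults 11 and 13). Ties break by animal ID and emit a
warning.

## Expression preparation

Three per-transcript count filters (order-independent predicates): drop
transcripts that are (a) all-zero, (b) below 2 total reads, or (c) zero in
at least ⌈n/5⌉+1 samples — at n = 24 this is the six-or-more-zeros rule.
Upper-quartile normalization computes each sample's 75th percentile of
non-zero counts (linear interpolation between order statistics, the
"type 7" convention) and divides by the geometric mean of those
percentiles, making the factors scale-free; after normalization the
non-zero upper quartiles agree across samples to 1e-9 relative. FPKM is
count·10⁹/(length_bp · total mapped reads), with totals taken as the
per-sample mapped-read counts carried by the matrix, not post-filter
column sums. Residual FPKM regresses each transcript's FPKM profile
(natural scale, no log) on the fixed-effect covariate design
(intercept + contemporary group + age + lane); redundant design columns
are dropped by pivoted QR before the least-squares solve.

## Quasi-negative-binomial differential expression

Counts are tested against SF as a continuous covariate (the H/L labels
are used only by the network stages). Per transcript, a log-linear NB GLM
is fitted by Fisher-scoring IRLS with offset log(UQ factor); the NB shape
α (var = m + αm²) is estimated by moments from a Poisson working fit, and
the SF column is dropped for the reduced model. The quasi layer absorbs
remaining misspecification: raw quasi-dispersion φ = deviance/df, a cubic
smoothing spline of log φ on log mean count gives the trend, and the
shrunk value is the df-weighted combination (df_resid·φ + prior_df·trend)
/ (df_resid + prior_df), prior_df defaulting to 10. The test statistic is
F = (deviance drop)/φ_shrunk referred to F(1, df_resid + prior_df).
Non-convergent transcripts are flagged and assigned p = 1, never dropped
silently. FDR control uses q-values: Storey's π₀ (λ-grid 0.05–0.95 with
spline smoothing; the minimum-π₀ fallback below 100 tests) by default,
plain Benjamini-Hochberg as an option; DE calls use q < 0.10.

Under pure-null simulations (2000 transcripts, 12 + 12 samples) the
per-seed fraction of p < 0.05 stays within [0.02, 0.09] and q < 0.10
yields zero discoveries in ≥ 80% of seeds; planted 4-fold changes at NB
dispersion 0.1 are recovered with median p ≪ 1e-3 (the acceptance suite
recomputes these).

## PCIT networks and differential hubbing

For each group separately, Pearson correlations of residual FPKM feed the
PCIT screen: for every gene trio the three first-order partial
correlations are computed, the trio tolerance ε is the mean of the finite
partial/direct ratios (exact-zero direct correlations are skipped; a trio
with no valid ratio eliminates nothing), and edge (x,y) is eliminated if
some third gene z satisfies |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|. An
exactly zero correlation is never a significant edge. The scan is
vectorised over pairs with a Python loop over the conditioning gene only;
a guard (default 5000 nodes) forces an explicit override before the O(n³)
cost becomes unreasonable. Group networks keep PCIT-surviving edges with
|r| ≥ 0.90 on the direct correlation — the magnitude cutoff applies after
PCIT significance. Zero-variance transcripts are excluded from
correlation with a logged warning but remain in the node universe as
isolated nodes.

Differential hubbing is DH = k_H − k_L, the difference in significant
connections between groups; target lists partition a hub's neighbours by
correlation sign.

## PIF and RIF

With e_H, e_L the group means of residual FPKM (which may be negative
after residualization; the formulas are applied as-is):

    PIF_i  = ½(e_H + e_L)·(e_H − e_L)
    RIF1_i = (1/n_DE) Σ_j PIF_j (r_ij^H − r_ij^L)²
    RIF2_i = (1/n_DE) Σ_j [(e_j^H r_ij^H)² − (e_j^L r_ij^L)²]

where j runs over DE targets (q < 0.10) and r_ij^g is the group-g Pearson
correlation if the pair passes that group's PCIT mask at |r| ≥ 0.90, else
zero. All transcripts are candidates; nothing is excluded by biotype.
Scores are z-standardized over all scored transcripts (a "nonzero-only"
standardization population is available as an option). PIF significance
is a convention — z-score, two-sided normal tail, BH adjustment — since
the score itself, not the p-value, is the ranking quantity. Under an
exact H/L swap RIF2 negates; RIF1 also negates because its PIF weights
flip sign (the squared wiring factor alone is swap-invariant).

## Enrichment

Over-representation uses the plain hypergeometric upper tail
P(X ≥ k) with N = |background|, K = |term ∩ background|, n = |query|,
BH-adjusted across terms (default cutoff FDR < 0.10). The background
defaults to all transcripts surviving the count filters. This is a
deliberate, documented substitution for web-service enrichment tools; no
modified EASE-style statistic is attempted.

## Synthetic data generator

The generator emulates the study design end to end; its defaults are the
package's study conditions.

* **Pedigree/phenotypes**: 33 unrelated sires × 10 progeny (dams unknown),
  h² = 0.3, σ²_p = 1 (kgf/cm²)², mean SF 8 kgf/cm². Progeny breeding
  values are u = ½u_sire + Mendelian term with variance ¾h²σ²_p (one
  unknown, non-inbred parent). Contemporary groups (4, round-robin,
  effects ~ N(0, 0.5²)) and a linear age effect (0.005 kgf/cm² per day,
  ages uniform on 600–900 d) complete the fixed effects.
* **Counts**: baseline natural-log means ~ N(3, 1.5²) (RNA-seq dynamic
  range), NB sampling via the gamma-Poisson mixture with background
  dispersion 0.1, per-sample library factors uniform on [0.7, 1.3].
  Per-sample totals are library_factor × 10⁶ nominal mapped reads — the
  simulated transcripts are a window on a larger transcriptome, so FPKM
  does not re-introduce planted-module signal through its denominator.
* **Planted structure** occupies deterministic, disjoint index blocks (DE,
  then hub modules, then regulators) and receives baseline log-mean 7 and
  dispersion capped at 2e-3, so that latent co-expression (log-scale
  loading τ = 0.5) survives counting noise. DE transcripts shift by
  ±lfc/2 (log2, alternating sign) between groups. Each hub drives a
  module through a shared per-sample factor active in its wired group
  only (alternating H, L); member loadings are **graded** over
  [hub_corr − 0.1, hub_corr] (default 0.97). Grading matters: with one
  shared loading ρ, any two members are forced by positive-semidefinite
  geometry into correlation ≈ ρ², so a ≥ 0.9-correlated module is a
  near-clique in which every member is as connected as the hub, and the
  designated hub is not identifiable by degree at n = 11–13. Graded
  loadings keep hub-member correlations high while pushing most
  member-member correlations below the edge threshold. Even so, the
  sampling lift of a lucky factor draw can promote one member past the
  hub, which is why recovery is asserted at the module level (top DH
  position of the wired direction inside the planted module, hub within
  the top 5) rather than as "hub strictly first". Regulators load on
  their own factor in both groups, with their assigned DE targets
  co-loading (default latent correlation 0.90) in group H only and no
  mean shift — so regulators surface in RIF but not PIF.
* All randomness flows from the master seed through named
  `numpy.random.Generator` streams; identical configurations reproduce
  byte-identical tables.

What the generator does **not** emulate: read-level artifacts, GC or
length biases, batch/lane effects on counts (lane exists only as a
covariate), miRNA biology, non-Gaussian latent structure, or dependence
between library size and biology. Passing recovery tests therefore show
the algorithms behave as specified under their own assumptions, not that
real tissue data are this benign.

## Problem sizes and numerical choices

Simulation-based checks run at 300 transcripts × 24 samples (networks) or
2000 × 24 (DE operating characteristics), 20 seeds; heritability recovery
uses 66 sires × 10 progeny (variance-component precision grows with
s·k², so fewer, larger half-sib families beat many small ones at equal n).
IRLS runs at most 50 iterations with deviance tolerance 1e-8 and linear
predictors clipped to ±30; the UQ reference is a geometric mean so factors
are scale-free; percentile interpolation is pinned by tests; ranking ties
break by transcript ID everywhere and degenerate inputs (all-equal EBVs,
zero-variance transcripts, empty DE sets) raise or warn explicitly rather
than proceeding silently.

## Known limitations

Dense linear algebra limits the animal model to desk scale. The quasi-NB
stage approximates the spline-shrunk quasi-likelihood family of methods
rather than reproducing any particular package numerically; its contract
is its operating characteristics. PCIT is O(n³) in transcripts. PIF
p-values are a labelled convention. The enrichment stage requires a
user-supplied term table and does not fetch ontologies.
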