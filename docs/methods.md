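# Methods

This note records the models, numerical choices and limitations behind
`edtia`, in the order the pipeline runs them.

## Formula screening, classes, and traits

Assigned CHNOSP formulas are screened with the standard negative-mode
assignment rules, applied to the nominal m/z of the deprotonated [M−H]⁻ ion
(the instrument mode this pipeline assumes): (1) nitrogen parity — odd N
implies even nominal m/z and vice versa; (2) C/3 ≤ H ≤ 2C+N+2; (3) N ≤ C and
O ≤ C; (4) O/C ∈ [0,1], H/C ≥ 0.3, N/C ≤ 1, DBE ≥ 0. The neutral-mass
parity convention was considered and rejected as inconsistent with
negative-mode ESI.

Van Krevelen compound classes use the conventional eight boxes on the
(O/C, H/C) plane. The printed box edges overlap, so we adopt half-open
[low, high) intervals on both axes, evaluated in a fixed order with first
match winning; every formula therefore maps to exactly one of nine labels
(eight classes plus "unclassified"). A point on a shared edge goes to the
later box (e.g. O/C = 0.3, H/C = 1.5 is "proteins", not "lipids").

Sixteen molecular traits are computed per formula: mass, C atoms, AI_mod,
DBE, DBE−O, DBE_AI, GFE, Kendrick defect (CH₂), NOSC, O/C, H/C, N/C, P/C,
S/C, thermodynamic growth yield, and the molecular N/P ratio. Conventions:

- DBE = 1 + C − H/2 + (N+P)/2, counting N and P as trivalent so that the
  DBE ≥ 0 screen is coherent on CHNOP formulas.
- NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C; GFE = 60.3 − 28.5·NOSC
  (kJ (mol C)⁻¹); the linear identity holds to machine precision and is
  tested.
- AI_mod = (1 + C − 0.5·O − S − 0.5·H)/(C − 0.5·O − S − N − P), clamped to 0
  when numerator or denominator is non-positive (standard convention).
- Kendrick defect = round(Kendrick mass) − Kendrick mass with
  round-half-away-from-zero; a floor variant is available via `kmd_floor`.
  The value lies in (−0.5, 0.5].
- Growth yield (`y_met`): a thermodynamic electron-equivalents model. The
  donor half-reaction energy per electron is GFE/(4 − NOSC); coupled to the
  O₂/H₂O acceptor (−78.72 kJ per e-eq) with a fixed synthesis cost
  (30 kJ per e-eq) and transfer efficiency 0.6, the yield fraction is
  1/(1 + ΔG_syn/(ε·ΔG_released)). It is strictly monotone in NOSC on the
  screened domain, which is the property downstream analyses rely on; the
  three constants are exposed as function arguments.
- Molecular N/P uses max(P, ε) to avoid division by zero; P = 0 yields a
  flagged large value (or 0 when N = 0).

Weighted trait means per sample are Σ trait_i·I_i / Σ I_i with relative
intensities I_i; they are invariant to rescaling a sample's intensities.
Molecule clustering uses Ward linkage on z-scored traits, default k = 10.

## Diversity and congruence

Richness counts strictly positive entries; beta diversity is Bray–Curtis
(a semimetric — the triangle inequality is deliberately not assumed
anywhere). NMDS minimizes Kruskal stress-1 (20 random starts, tolerance
1e-6) and the final configuration is rotated to its principal axes with a
deterministic sign convention so runs are comparable. The Mantel test
correlates off-diagonal entries and permutes rows and columns of one matrix
jointly, p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), default 999
permutations. Procrustes/PROTEST superimposes unit-trace centred
configurations; M² is the sum of squared pointwise residuals, p by row
permutation with the same +1 correction.

For breakpoint detection the composition score is the first
correspondence-analysis axis rather than a detrended ordination axis:
detrending is a visualization nicety, and breakpoint detection only needs a
monotone composition score. Piecewise-linear (segmented) regression fits
0..3 breakpoints by Muggeo-style iterative linearization — refitting with
gap covariates and updating each breakpoint by γ/β — hardened with three
deterministic starts and damped steps chosen greedily by profile RSS; a
start that stops improving is treated as a converged local optimum. BIC
(k = 2 + 2 per breakpoint) selects the breakpoint count; non-convergent
counts are dropped with a warning.

## Association inference and networks

Features present in fewer than half the samples are removed first (majority
rule). Spearman correlations are tie-corrected, two-sided, and deliberately
uncorrected for multiplicity (screening use). The per-molecule Δρ statistic
is mean positive ρ minus mean |negative ρ|, with one-signed molecules
flagged.

SparCC estimates basis correlations from log-ratio variances: with
t_ij = var log(x_i/x_j), the sparse approximation solves
Σ_j t_ij = (d−1)·w_i + Σ_{j≠i} w_j for basis variances w, then
ρ_ij = (w_i + w_j − t_ij)/(2√(w_i w_j)); the strongest remaining pair above
the exclusion threshold (default 0.1) is removed from the system each
iteration (default 20). Molecules and taxa are stacked into one
compositional vector per sample, because cross-block correlations require a
joint composition; intensities are scaled to a 10⁶ pseudo-count total and
zeros replaced by 0.5. The point estimate is the median over Dirichlet
(counts+1) resampled replicates (default 100; 0 gives the deterministic
plain-fraction estimate, exactly invariant to sample order); pseudo-p comes
from independently permuting each component across samples. Known
limitation: when one component's basis variance dominates (e.g. a strongly
blooming taxon) the sampling noise of t inflates |ρ| for its pairs — an
inherent property of the estimator that the calibration test bounds.

Networks threshold at |ρ| ≥ 0.30; link weights are round(|ρ|·10⁴), absolute
values taken for the negative network so the entropy machinery sees
non-negative integer interaction counts. Per-sample subnetworks are
node-induced on the molecules and genera with positive abundance in that
sample.

## Specialization indices and null model

H₂ is the Shannon entropy of p_ij over nonzero cells (nats). H₂max is the
entropy of the marginal-product table A_i·A_j/m² — the maximum-entropy table
with those margins in the real-valued relaxation (we use this rather than an
integer heuristic; the [0,1] clamp absorbs sub-nat discrepancies). H₂min
comes from greedy mass packing (repeatedly assign min of the largest
remaining row and column to one cell). H₂′ = (H₂max − H₂)/(H₂max − H₂min),
clamped to [0,1]; degenerate webs (single row/column, H₂max = H₂min) return
0 with a flag so per-sample sweeps never abort. d_i follows the KL form with
d_min = 0 (marginal-proportional profile) and d_max from greedily
concentrating the node's total on the partners with smallest totals, which
maximizes the KL term. Exhaustive enumeration over small margins confirms
the extremes bracket every realizable table.

The null model fixes row totals, column totals and the nonzero-cell count:
each replicate starts from a Patefield random table with the observed
margins, then applies margin-preserving 2×2 moves of variable amount —
zeroing a source cell when the fill must drop, sub-maximal amounts when it
must rise, with fill-neutral moves always accepted for mixing — until the
observed connectance is reached (with up to five restarts). Single-row or
single-column webs are fully determined by their margins and are returned
as-is. Near one-to-one webs with heterogeneous totals can be forced by
their margins to an (almost) unique table; in that case the generator
raises, and the pipeline records the scores without a null ensemble rather
than fabricating one. Null z-scores use z = (S_obs − mean)/sd, flagged NaN
when the ensemble variance is zero.

## Drivers and prediction

Forward selection is greedy by AIC with a 1e-9 tie tolerance. Variation
partitioning uses redundancy-analysis R² (multivariate responses allowed)
with Ezekiel adjustment and inclusion–exclusion over 2–3 groups; negative
adjusted fractions are reported unclipped, as is standard. Random-forest
importance is out-of-bag permutation accuracy importance computed per tree
from each tree's bootstrap seed and averaged over the forest (default 2000
trees).

The path model is recursive path analysis over fixed composites rather than
latent-variable maximum-likelihood SEM: composites reduce to chained
regressions, and the prediction equations need only the λ values. Composite
scores are fixed linear combinations of candidate indicators, weighted by a
multiple regression of the response on the z-scored block; indicators with
p ≤ 0.05 are kept (all kept if none reaches it, and constant indicators are
dropped first). All variables are z-scored before fitting, so the λ are
standardized coefficients; equation-by-equation OLS is the ML estimator for
a recursive system. Fit statistics come from the observed vs model-implied
covariance: χ² = (n−1)·F_ML, CFI against the independence baseline, SRMR on
standardized residual covariances; admissibility requires χ² p > 0.05,
CFI > 0.95 and SRMR < 0.05, and candidate specifications are ranked by AIC
(= χ² + 2·free parameters, equivalent for ranking). Exact numerical parity
with dedicated SEM software is not claimed. Training means and SDs of
temperature and nitrogen are frozen in the model file so scenario inputs are
standardized identically at prediction time (training-distribution
standardization is the default). Scenario deltas are Y_H₂(site, year) −
Y_H₂(site, baseline); predictions are exactly linear, so superposition holds
and is tested.

## Synthetic experiment

The generator emulates a two-mountainside microcosm study: 2 regions ×
5 elevations × 10 nutrient levels (0, 0.45, 1.80, 4.05, 7.65, 11.25, 15.75,
21.60, 28.80, 36.00 mg N L⁻¹) × 3 replicates = 300 samples; phosphate-P is
nitrate-N/14.93 at time zero. Temperatures come from a linear lapse-rate
model (−0.55 °C per 100 m) against a per-region reference, since only
regional ranges are known.

Peak tables: per-molecule log-normal baselines (SD 1.5 across molecules),
class-specific piecewise nutrient slopes with a configurable breakpoint
(default 4.05 mg N L⁻¹), temperature slopes, log-normal intensity noise
(default SD 0.3 — intensities are positive and right-skewed), and a
dynamic-range detection limit (peaks below 10⁻³ of the sample's base peak go
undetected) so per-sample richness varies as it does in real spectra. Rows
are normalized to sum to 1. Planted links: consumer links act negatively
and producer links positively on log-intensity through latent per-taxon
activities shared with the OTU generator; each linked taxon couples to
`links_per_taxon` molecules (default 3) and each linked molecule to
`taxa_per_molecule` taxa (default 1, effects scaled by 1/√k to keep signal
variance fixed). Linked molecules are minor but stable constituents
(baseline N(−1.5, 0.5) on the log scale): if they dominated a sample's
total intensity, closure of the relative abundances would leak their
fluctuations onto unlinked molecules and blur the planted structure.

OTU tables: log-normal taxon baselines with per-sample idiosyncratic noise
(SD 1.0), linked taxa driven by the shared latent activities, multinomial
sampling to exactly 20,000 reads per sample (rarefaction contract is
sum-exact). The "strong-signal" recovery scenario used in tests is the
default generator with link strength 1.2 on both sides, 200 molecules and
100 taxa — large enough that no single feature dominates the composition.

What the generator does not emulate: raw spectra, chromatography, mass
accuracy, chimeras, phylogenetic structure among taxa, true consumer-
resource dynamics (links are monotone co-variation, not kinetics), or the
climatic difference between regions beyond temperature offsets. Passing
recovery tests therefore show that the inference chain recovers monotone
planted associations under compositional closure and rarefaction noise —
not that it recovers mechanistic interactions in real sediments.

## Problem sizes and defaults

Statistical tests run at the sizes the claims name: 150-sample null
calibrations, 300-sample recovery runs with 200 molecules × 100 taxa,
100-replicate breakpoint simulations, 100-web null ensembles, 25-replicate
path-model recovery. The pipeline's demo defaults (120 formulas, 60 taxa,
20 SparCC bootstrap replicates, 199 in-pipeline permutations) keep a full
run around half a minute on one core; all counts are config fields.

## Known limitations

- SparCC inherits the sparsity assumption; dense true correlation or one
  dominant-variance component biases ρ (bounded, not eliminated, by the
  exclusion iterations).
- H₂max/d_max use real-valued relaxations/greedy allocations; indices are
  clamped to [0,1] rather than guaranteed to touch the bounds for every
  integer-feasible web.
- The swap-web sampler is a heuristic chain; it guarantees the constraints
  exactly but uniformity over the constrained table space only
  approximately.
- Fit indices for the path model are computed from standard covariance
  discrepancies and may differ in digits from dedicated SEM software.
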