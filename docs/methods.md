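# Methods

This note documents the models, numerical choices and limitations behind
`isletpheno`: what the synthetic cohort generator emulates, how each
analysis stage is defined, and which design decisions were genuinely open.

## Perifusion model and feature definitions

A perifusion run records insulin concentration in column effluent fractions
while the stimulus solution is switched on a fixed schedule.  The canonical
protocol set has three arms sampled at 1-min intervals, each beginning with
a 24-min recording at 3 mM basal glucose (after an unrecorded 60-min
equilibration), with 15-min basal washouts between stimuli:

- **Arm G**: 15 mM glucose (40 min = 15 min first phase + 25 min second
  phase), 6 mM glucose (25 min), 30 mM KCl (15 min).
- **Arm L**: 5 mM leucine at basal glucose (40 min), leucine + 6 mM glucose
  (25 min).
- **Arm F**: 1.5 mM oleate/palmitate at basal glucose (40 min), fat + 6 mM
  glucose (25 min).

The published material fixes the stimuli, the 15+25-min glucose phase
windows, the 0.4 mL/min flow and the 65-islet column load, but not the
washout durations or exact segment ordering; this protocol is one
consistent reading of the averaged-trace figures and is stored alongside
every simulated cohort (`protocol.yaml`) so that real data with a different
schedule can be analysed by supplying its own protocol.

Feature definitions:

- **Unit conversion**: rate (pmol·islet⁻¹·min⁻¹) = concentration (pmol/mL)
  × flow (mL/min) / islet count.
- **Segment AUC**: trapezoidal integral of (rate − baseline) over the
  segment on the native grid (no resampling or smoothing — the samples are
  the fractions), where baseline is the mean rate over the designated basal
  segment of the same arm.  Whether published per-segment AUCs subtract
  baseline is not stated; subtraction makes nutrient responses comparable
  across donors with different basal secretion and is the default, with a
  `baseline_mode="total"` option preserving the other reading.  Suppression
  below baseline yields negative area and is kept.
- **Phase decomposition**: first phase = AUC over the first 15 min of the
  segment, second phase = the remainder; window edges are interpolated
  linearly so the two parts partition the segment AUC exactly (a property
  test asserts the identity on every simulated trace).
- **Peak / time-to-peak**: maximum *sampled* rate within the first 15 min
  after the solution change, ties broken by the earliest time.  The search
  stays inside that window even for longer segments, per the definition of
  peak secretion as a single fraction within the first 15 min of a solution
  change.

## Synthetic cohort generator

`simulate_cohort` draws a cohort of `n_nd + n_t2d` donors (defaults
123 + 17).  Per donor: metadata (age, sex, BMI, HbA1c with the T2D group
stochastically higher, culture time, cold ischemia time, digestion time,
purity), a latent responder class (fat hyper-responder with probability
0.08, protein hyper-responder 0.09, otherwise typical), a log-normal
secretory capacity (CV 0.25), and independent log-normal per-stimulus
amplitude jitters (CV 0.2) that produce the donor-to-donor response
heterogeneity the study design exploits.  All noise distributions are
mean-1 log-normals, so group means are unbiased for the configured effects.

The secretion rate is

    rate(t) = B · c_d · (1 + Σ_s δ_s · j_{d,s} · h_{d,s} · shape_s(t − t_s))

with basal rate B = 0.08 pmol·islet⁻¹·min⁻¹, capacity c_d, T2D multiplier
δ_s (1 for ND donors), jitter j, hyper-responder scale h, and per-stimulus
shapes confined to their segments:

- glucose/leucine (biphasic): an alpha-function pulse
  (t/τ)·e^(1−t/τ) (τ = 4 min; 2 min for KCl) plus a saturating plateau
  1 − e^(−t/τ₂) (τ₂ = 10 min) — the minimal two-component shape with a
  distinct first-phase peak inside 15 min and a sustained second phase;
- fat (monophasic): saturating plateau only (τ = 15 min);
- KCl: sharp alpha pulse only.

T2D donors carry the stimulus-specific multipliers δ = 0.60 (15 mM
glucose), 0.65 (6 mM), 0.45 (fat and, by extension, fat + 6 mM glucose —
the combination has no separately printed value), 0.78 (KCl), 1.00
(leucine alone), 0.64 (leucine + 6 mM glucose), and a 3-min high-glucose
response delay implemented as a time shift renormalized to preserve the
segment integral, so the delay moves the peak without changing the dose:
time-to-peak shifts by exactly the configured minutes and segment-AUC group
ratios equal the configured multipliers exactly in the noise-free limit.

Hyper-responders get their defining nutrient amplitude rescaled so that the
noise-free nutrient-at-basal AUC is Uniform(1.1, 1.6) times their own 15 mM
glucose AUC (computed before T2D multipliers; measurement noise can still
flip borderline donors, so classification is not circular).  Fat
hyper-responders also scale the fat + 6 mM glucose segment and carry a
reduced (×0.7) KCl amplitude, matching their reported phenotype; protein
hyper-responders scale only the leucine-at-basal segment, because no
co-stimulation hyper-response is documented for them.  Measurements average
`n_tech_reps = 2` technical replicates with 10% multiplicative log-normal
assay CV, and traces are emitted as effluent concentrations so the analysis
side exercises the unit conversion.

### Paired omics matrices

A shared standard-normal gene factor z_g links the two platforms: mean
log₁₀ protein abundance is 5.5 + 0.7·(r·z + √(1−r²)·e) and mean RNA
log-expression is proportional to z, so the across-gene correlation of
means equals the configured `rna_protein_r` (default 0.5) up to sampling
noise.  Donor-level protein values add: 18 disjoint co-expression module
blocks (sizes Uniform{50..110}, chosen so 18 modules always fit in 2,000
proteins while covering most of the matrix, as co-expression structure does
in real proteomes) with loadings Uniform(0.25, 0.45) on per-donor latent
factors; selected factors are linearly coupled to donor traits (default:
module 1 ↔ fat AUC at strength 0.6, module 2 ↔ 15 mM glucose AUC 0.5,
module 3 ↔ leucine AUC 0.5, module 4 ↔ HbA1c −0.4); ±0.5·log₂ T2D shifts
for 100+100 planted differential proteins; marker-score shifts tied to a
per-donor Dirichlet cell composition (beta/alpha/delta/acinar, with lower
beta and higher alpha/acinar means in T2D); residual Gaussian noise with
SD 0.12 (log₁₀), a value at which the planted ±0.5 log₂FC effects are
recoverable at ≥90% sensitivity under BH at the cohort's group sizes
(verified by a Monte-Carlo power computation before the defaults were
frozen).  Missingness is abundance-dependent (logistic in the standardized
log-abundance, mean `missing_frac` = 0.05) plus 2% of features planted at
exactly 60% missingness to exercise the >50% filter deterministically.

RNA counts are gamma-Poisson (negative binomial) with gene-wise dispersion
Uniform(0.1, 0.5), log-normal library sizes (CV 0.3), per-gene×batch
log-normal location shifts (SD 0.25 log₂) and per-batch dispersion scale
factors across 4 batches, the same T2D differential structure (topped up to
150+150 genes from mid-expressed genes so planted effects survive the
low-count filter), and the same marker/composition coupling.

**What the generator does not emulate**: peptide-level quantification and
its shared-peptide ambiguity, missingness that is correlated across
co-eluting proteins, count overdispersion heavier than gamma-Poisson,
RNA-protein coupling at the *donor* level (within-gene correlation is null
by default except through markers/modules), isoforms, and any real
biological annotation.  Passing recovery tests therefore demonstrates that
the estimators are correct and well-calibrated under the declared
statistical structure — not that the pipeline is robust to every artefact
of real mass-spectrometry or RNA-seq data.

## Analysis stages

- **Classification**: strict inequality (a tie is typical); donors with
  non-positive 15 mM glucose AUC cannot be ranked against it, are flagged,
  and leave the prevalence denominator.  Prevalence CIs are Clopper-Pearson
  (exact binomial).
- **Group contrasts**: Welch *t* by default (the ND/T2D groups are very
  unequal in size: 123 vs 17), Mann-Whitney on request or as an automatic
  fallback for degenerate inputs; percent difference is computed on group
  means of baseline-subtracted AUCs; BH across all segment×metric rows of a
  summary table.
- **Proteome preprocessing** runs in the fixed order missingness filter
  (strictly >50% missing removed) → per-donor median normalization + log₁₀
  → imputation.  The imputer is a deterministic k-nearest-neighbour feature
  regression (k = 10 by absolute correlation, OLS on jointly observed
  donors, feature-mean fallback); it replaces the random-forest imputation
  used in the original workflow, trading some accuracy for determinism and
  a light dependency footprint — observed entries are never modified and
  the substitution is recorded in the processing log.
- **RNA preprocessing**: the low-count filter (<5 raw counts in >50%
  donors) → log₂(CPM+0.5), a monotone variance-stabilizing *substitute*
  (not claimed equivalent to a fitted VST) → per-gene, per-batch
  location/scale standardization to the pooled moments (an exact-moment
  substitute for empirical-Bayes batch correction; with ≥6 donors per batch
  the shrinkage it forgoes is second-order).  Singleton batches get
  location-only adjustment with a warning.  The network branch additionally
  trims the 15% lowest-mean-count genes and then the 15% lowest-variance
  transformed genes.
- **Differential abundance**: per-feature two-sided Student *t* on log
  abundance, log₂FC = Δlog₁₀/log₁₀2, BH across tested features,
  significance at q < 0.05; constant features get p = 1 and a flag.
  For RNA this OLS/t-test on log₂(CPM+0.5) with batch adjustment replaces
  the negative-binomial Wald test of the original workflow (a substitution,
  not an equivalence claim).
- **Trait association**: vectorized OLS `abundance ~ trait + T2D(0/1)
  [+ technical covariates]`, trait-coefficient t-test, one BH family per
  trait (all features surviving preprocessing).
- **Partial correlation** is double residualization on the covariate set
  with a t-test at n − 2 − |Z| degrees of freedom (equal to the recursive
  formula; an oracle test asserts agreement to 1e-10).  A variable fully
  explained by the covariates has a null residual; its partial correlation
  is 0 by convention.
- **RRHO**: genes ranked most-up to most-down by the signed score, ties
  broken by gene id for deterministic grids; each threshold pair is scored
  with an upper-tail (over-enrichment, positive −log₁₀ p) or lower-tail
  (under-enrichment, negative) hypergeometric test.  Step size 100 for
  universes ≥5,000 genes, else ⌈m/50⌉ so small synthetic universes still
  give a usable grid.  No permutation-based FWER correction is applied.
- **Network**: biweight midcorrelation with the standard 9·MAD tuning
  constant and Pearson fallback for MAD-zero features; signed adjacency
  ((1+cor)/2)^β with β = 8 (proteome) / 20 (RNA) taken as given (no
  scale-free fit scan); TOM with the shared-neighbour numerator excluding
  the pair itself; average-linkage clustering of 1 − TOM.  Module
  detection uses a **static cut at the largest gap in the sorted merge
  heights**: planted/tight modules merge low, background features attach
  near the top of the dendrogram, and the widest gap separates the two
  regimes.  A cut placed at a fixed fraction just below the maximal merge
  height was considered and rejected: background features attach to module
  clusters at heights *below* such a cut (a noise feature's TOM similarity
  to a module is an order of magnitude above noise-noise similarity), which
  contaminates every module; the largest-gap rule is parameter-free,
  deterministic, and degrades gracefully (pure noise → mostly unassigned;
  all-equal dissimilarity → a single module).  An absolute `cut_height`
  override remains available.  Clusters smaller than 30 features are
  unassigned (label 0); modules whose eigengenes correlate above 0.75 are
  merged iteratively; labels are ordered by size.  This is a deliberate
  simplification of dynamic tree cutting, adequate for planted-module
  recovery.
- **Eigengenes**: first right singular vector of the standardized module
  submatrix (unit norm over donors), sign-oriented to correlate positively
  with the module's mean standardized profile so higher scores mean higher
  abundance; variance explained is reported.  Module-trait maps use partial
  Pearson correlation given the four technical isolation covariates
  (purity, culture time, digestion time, cold ischemia time), BH over all
  module×trait cells at FDR 5%.
- **Composition**: per cell type, the oriented first PC of the standardized
  marker submatrix, shifted to non-negative and row-normalized in
  proportions mode.  This first-PC marker score replaces the reference
  marker-based decomposition package used originally; it is validated only
  on synthetic mixtures and yields *relative* scores, not absolute
  fractions.  Marker lists must be disjoint; types with fewer than two
  matrix-present markers are dropped with a warning.

## Problem sizes and determinism

Recovery checks run at the study's cohort scale (140 donors) with 25
simulation seeds for secretion quantities, 10 seeds for the omics
correlation, and a single seed for the full 2,000-protein network; the unit
suite uses smaller cohorts (≈40 donors, ≈300 features) that retain every
planted structure.  One seed fans out to per-stage child generators via
`numpy.random.SeedSequence.spawn`, so a cohort is bit-reproducible from its
config and the pipeline manifest hashes are stable across re-runs.

## Known limitations

- The static-cut module detector has no within-branch rescue step, so
  nested or strongly overlapping modules beyond the eigengene-merge rule
  are out of reach.
- Percent differences use group means; with 17 T2D donors and log-normal
  capacity spread the per-seed estimates are noisy (that is the point of
  seed-averaged recovery).
- The RNA differential stage on log-CPM is less powerful than a count
  model at these group sizes; differential-count totals are therefore not
  treated as recoverable quantities.
- Real-data use requires the user's own protocol YAML, marker lists and
  gene mapping; the bundled ones describe the synthetic cohort.
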