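# Methods

This note documents the models, the synthetic data, the numerical choices
and the limits of what the tests demonstrate.

## Cross-level prediction

**Mean.** The additive expectation of a cross's progeny mean is the
contribution-weighted midparent value.  Weights are the expected genome
shares: (1/2, 1/2) for two-way crosses, (1/4, 1/4, 1/2) for three-way with
the last-crossed parent at 1/2, and (1/4,)*4 for four-way.  The same
operation serves the genomic prediction (parental GEBVs) and the phenotypic
baseline (parental BLUEs).

**Variance.** For a two-way cross of inbred parents, a DH progeny draws at
each locus the maternal or paternal diplotype with probability 1/2, and a
linked locus pair stays in parental configuration with probability `q`.
With diplotype effects `m_j = 2*alpha_j*(maternal allele indicator)` and
`v_j` likewise, the family variance is the double sum over within-chromosome
locus pairs of `(q_jk/2 - 1/4)(m_j m_k + v_j v_k - m_j v_k - v_j m_k)`,
diagonal included.  Two instantiation choices needed fixing:

* *Scaling of `m`, `v`.*  "Twice the additive effect" admits several
  scalings; the one used here (`2*alpha*indicator`) is the one that exactly
  reproduces the enumerable cases — a single segregating locus gives
  variance `alpha^2` (DH values 0 or `2 alpha`, equiprobable), and the
  two-locus coupling case at r = 0.1 with unit effects gives 3.6.  The
  Monte-Carlo oracle (below) arbitrates the general case.
* *Source of `q`.*  Within a biparental F1 with zero generations of random
  mating between cross and DH induction, the parental-configuration
  probability is `q = 1 - r`, with `r` taken from the genetic map through
  the Haldane function `r = (1 - e^(-2d/100))/2` (d in cM).  A sample-LD
  estimate of `q` is not needed and not implemented; generations > 0 are
  rejected as out of scope.

All within-chromosome pairs are summed without a distance cutoff (O(p_c^2)
per chromosome; ~400 markers per chromosome is trivial).  Variance
prediction is restricted to two-way crosses; means support 2/3/4-way.
Negative variance estimates (possible with estimated effects) are clipped
to zero before the square root, with a warning.

**Oracle.** `mc_progeny` simulates N gametes of the F1 through the same
meiosis model and scores them with the marker effects.  It shares no code
path with the analytic formula beyond the map itself, and the two agree
within 2% relative error at N = 200,000 across random crosses — this is the
package's headline internal check.

**UFC.** `UFC_u = mean + i*h*sigma_G` with defaults i = 1.27 and h = 1 on
the prediction side; `UFC_mu = mean` is the variance-free alternative.  The
*observed* UFC uses the trait's own `sqrt(h2)` from the across-environment
analysis, because a family-specific heritability is not estimable on
unbalanced data.

## Meiosis model

Crossovers follow a Poisson process (no interference): count ~
Poisson(length in Morgans), breakpoints uniform.  Haldane's map function is
the matching pairwise summary, which keeps the simulator and the `q = 1-r`
variance formula mutually consistent.  Two samplers exist: an explicit
breakpoint sampler (used where realised crossover counts matter) and a
vectorised batch sampler that uses the Markov property of the
no-interference process — the source haplotype switches between adjacent
markers with probability `haldane(d)`.  At the marker loci the two are
distributionally identical; tests verify both against the closed form.

## Phenotypic analysis (two stages)

Stage 1, per environment: `y = mu + g + b + r + e` with genotype,
incomplete block (nested in replication) and replication random.  REML
variance components give the repeatability `s2_g / (s2_g + s2_e/nR)`.
Genotype BLUEs are then computed by GLS with genotype fixed, holding the
block/replication variance ratios at their REML estimates from the
genotype-random fit — the standard two-step practice; variance components
are not re-estimated under the fixed-genotype parameterisation.

Outlier screening is one pass per environment: records whose conditional
residual exceeds 4 residual SDs (configurable) under the preliminary
genotype-random fit are dropped and the fit refreshed.  The rule is
deliberately conservative; on clean simulated data it removes essentially
nothing.

Stage 2, across environments: `y = mu + g + u_env + e` on the stage-1
BLUEs; heritability is `s2_G / (s2_G + s2_e/nE)` with `nE` the mean number
of environments per genotype.  Across-environment BLUEs again come from a
fixed-genotype GLS at the stage-2 components.  A design in which every
genotype appears in a single environment is flagged as confounded.

**Family-specific variances** use the plot-level model across environments
(`y = mu + g + u_env + b(env) + r(env) + e`) with one genetic variance per
family.  Joint REML is attempted only for a handful of families (<= 4);
beyond that the shared components are fixed — environment variance from
stage 2, block/replication from the stage-1 averages, and the plot-level
residual as stage-1 residual plus the genotype-by-environment part of the
stage-2 residual — and each family's variance is profiled on its own
records (one bounded scalar optimisation per family, flagged as
"profiled").  This mirrors the fallback forced by non-convergent joint
models on unbalanced commercial data.  Families with one phenotyped member
get NaN and a flag.  The observed family mean is the arithmetic mean of
member across-environment BLUEs (a model-based family effect would be the
alternative; the arithmetic mean is simpler and is what the validation
correlates).

## REML engine

All mixed models run through one engine: `y = Xb + sum Z_i u_i + e` with
independent random terms.  The restricted likelihood is maximised over log
variance *ratios* `g_i = s2_i/s2_e`, with `s2_e` and the fixed effects
profiled analytically; all algebra uses the Woodbury identity at the size
of the total number of random levels, never n x n.  The largest
all-records factor (usually genotype) is additionally absorbed: its scaled
covariance `I + g Z Z'` is block-diagonal by level, reducing each
likelihood evaluation to group sums plus a small Cholesky over the
remaining factors — this is what makes programme-scale fits (thousands of
records, >1000 genotype levels) take milliseconds.  Optimiser:
golden-section for one free ratio, Nelder-Mead otherwise (objective
tolerance 1e-8, log-ratio bounds [-23, 16], variance floor 1e-10).
Balanced designs reproduce closed-form ANOVA estimators to <= 1e-6, which
is the engine's external anchor.

## Genomic prediction

Marker QC drops markers with minor allele frequency <= 0.05 or missing
rate >= 5% and mean-imputes the rest (2x allele frequency).  Frequencies
for centering and imputation are computed on the full matrix
(training + prediction), logged so a user can restrict them.  The GRM is
VanRaden's `(X-2P)(X-2P)'/(2 sum p(1-p))`.  GBLUP REML runs on the
eigendecomposition of the training-set GRM (one scalar ratio); RRBLUP is
solved in the same parameterisation and effects recovered through the dual
ridge solution, so GBLUP and RRBLUP fitted genetic values agree to
numerical precision (< 1e-6, verified over random instances).  The ridge
parameter is re-estimated per training fold in cross-validation.  Folds
with zero phenotypic variance are dropped from the CV mean with a warning.

## Synthetic breeding programme

The generator emulates a commercial winter-barley DH programme: five
cycles of 433/1026/1021/1020/1000 lines (a `scale` factor shrinks these
proportionally; the analysis drivers and programme-scale tests use 0.25,
i.e. ~1124 lines in ~87 families, keeping the mean family size of ~13),
347 families at full scale with intentionally unequal sizes (multinomial
over Dirichlet(1.3) weights), cross types 70/20/10% two-/three-/four-way,
parents drawn from founders plus all earlier cycles, 2898 markers on seven
150 cM chromosomes, founder allele frequencies uniform on (0.1, 0.9).
Trials are unbalanced: each cycle has its own 8 environments, genotypes
are allocated at random with a mean of 3.5 environments each (minimum 2),
two replications, incomplete blocks of 20 within replication.  Founders
receive sparse records (mean 1.5 environments) in the first cycle,
mirroring the thin parental information typical of such data — and making
the phenotypic-midparent baseline computable.

Three traits span the heritability range of the motivating system: an
early/flowering-type trait (h2 0.84, 40 QTL), a height-type trait (0.77,
120 QTL) and a yield-type trait (0.49, 300 QTL), with intercepts and
genetic variances set to plausible BBCH/cm/dt-per-ha magnitudes.  QTL are a
random marker subset with normal effects rescaled so the realised genetic
variance hits its target exactly.  Noise calibration inverts the
heritability estimator: the required stage-2 residual
`nE * s2_G * (1/h2 - 1)` is split 60% to genotype-by-environment and 40%
to plot error (block:residual 1:5), with environment variance equal to the
genetic variance and a small replication variance.  Realised heritabilities
land within ~0.05 of target in typical replicates.

What the generator does *not* emulate: selection during the programme
(family sizes are drawn, not selected), genotyping errors, dominance and
epistasis (DH lines are fully homozygous anyway), spatial field trends,
family-specific GxE.  Passing tests therefore show that the estimators and
predictors are correct under the stated model, not that real data meet the
model.

## Validation scenarios

Eligibility filters: two-way cross, >= 10 phenotyped members, estimated
genetic variance > 0.01 (all configurable).  The observed variance used for
filtering and validation is the REML family-variance estimate, not the raw
sample variance of member BLUEs.  Scenario "full_data" estimates marker
effects on everything and includes the phenotypic-midparent baseline;
"holdout_final_cycle" trains on all earlier cycles; "training_size" samples
genotypes (not families) uniformly without replacement from the earlier
cycles over a ladder of sizes, five samples per size.  At quarter scale the
earlier-cycle pool (~935 phenotyped lines) cannot furnish the 1000-genotype
rung, so drivers and tests cap the ladder at the available pool and treat
the largest attainable size as the top rung.  Prediction ability is the
Pearson correlation throughout.  The c-sweep applies `c = i*h` in [0, 5] to
*both* sides — observed `mean + c*sd` against predicted `mean + c*sd_pred`
(UFC_u) and against the predicted mean alone (UFC_mu) — so the two curves
coincide at c = 0 by construction.

## Problem sizes and determinism

Programme-scale studies (the 30-replicate mean-vs-variance comparison, the
training-size dispersion check) run at scale 0.25, chosen so a replicate's
full pipeline takes ~15-20 s and the studies complete comfortably on one
CPU.  The Monte-Carlo oracle uses 200,000 progeny per cross, at which the
sampling SE of the variance (~0.3%) sits well inside the 2% agreement
band.  Every random draw descends from a single seed through
`numpy.random.SeedSequence` spawning; identical seeds give bit-identical
datasets, fits and scenario results.

## Known limitations

* The family-variance profiling conditions on shared nuisance components
  estimated once; its uncertainty is therefore understated, and variances
  of very small families are noisy (hence the size filter).
* `q = 1-r` is exact only for zero generations of random mating between
  cross and DH induction; other breeding schemes (F2-derived, finite
  selfing) need a different `q` and are out of scope.
* The BLUE step holds variance components at their genotype-random REML
  estimates rather than re-estimating them under the fixed-genotype model;
  on the balanced and mildly unbalanced designs simulated here the
  difference is negligible.
* Prediction abilities on the synthetic programme are higher than one
  should expect on commercial data — the simulation is purely additive,
  marker-complete and free of pedigree errors, so it bounds the method's
  behaviour from above.
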