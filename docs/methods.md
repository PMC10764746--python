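# Methods

## The trial model and its assumptions

The package analyses plot-mean phenotypes (days to heading, averaged over
the plants of a plot before analysis) from a randomized-block trial of
substitution-line materials grown in several environments:

    y_hjk = mu + E_h + G_j + GE_hj + B_k(h) + e_hjk.

Environments are treated as fixed constants and genotypes, interactions,
blocks and plot error as independent Gaussian random effects with variances
sigma2_G, sigma2_GE, sigma2_B, sigma2_e. The fixed-vs-random split follows
the quantities the analysis must deliver — variance components and
heritabilities for G and GE — and is the conventional choice when the
environments are a handful of deliberately chosen seasons. Plots are
assumed homoscedastic across environments; within-plot plant-to-plant
variation is outside the model because plot means are the input unit.

## Estimation

**ANOVA / EMS.** The joint analysis of variance partitions the total sum of
squares into environments, blocks-within-environment, genotypes, G×E and
error (sequential sums of squares from the full fixed-effects fit; on the
balanced layouts the generator produces these equal the classical
partition). Expected mean squares under the random model give the
method-of-moments component estimates, and the F denominators follow the
EMS: genotypes are tested against G×E, G×E and blocks against error,
environments against blocks.

**MINQUE(1).** The primary variance-component estimator solves the MINQUE
normal equations tr(Q V_i Q V_j) theta_j = y' Q V_i Q y with the working
covariance built from prior values all equal to one and the fixed effects
projected out. A single pass is performed — iterating to convergence would
change the "all priors one" convention — though the estimate can be fed
back in as priors by the caller. On balanced designs MINQUE(1) coincides
with the ANOVA/EMS moments estimator; the test suite asserts agreement to
1e-8 relative, which doubles as a cross-check of both code paths. Negative
solutions (possible for any unbiased quadratic estimator) are truncated to
zero with a warning, because downstream prediction needs nonnegative
variance ratios; the raw values are retained on the result object.

**Prediction.** Two prediction modes exist side by side:

* `predict_blup` solves Henderson's mixed-model equations at the estimated
  variance ratios. Predictions shrink toward zero; a vanishing error
  variance is floored at 1e-12 of the total variance so the equations stay
  solvable, in which limit BLUP converges to the least-squares values.
  The raw GE solutions are centered within material and the removed mean is
  reallocated to G (it is genotype main-effect signal), which enforces the
  reporting convention that G sums to zero over materials and GE to zero
  over environments within each material. When sigma2_G is estimated at
  zero the model admits no genotype main effects, so G is exactly zero and
  the GE mean is discarded rather than reallocated.
* `predict_ls` returns the unshrunken least-squares values: centered
  material means for G and the interaction deviations for GE.

The pipeline reports BLUPs as the mixed-model predictions but feeds the
least-squares predictions into the effect decomposition. The reason is
calibration: every decomposed effect is a linear contrast of material
means, and with unshrunken inputs its t-test against the plot error
variance is exact, so stars mean what they claim. Shrunken inputs would
scale every contrast by a data-dependent factor and make the nominal test
conservative or undefined in degenerate cases. With the variance ratios of
a well-replicated trial the two versions differ by a few percent and the
decomposition identities hold for either.

## Effect decomposition

Effects use the substitution-line convention: `a` and `d` are deviations of
the homozygous and heterozygous single lines from the recipient — not the
classical midparent parameterization, so dominance ratios d/a must be read
accordingly. Pyramiding effects g are deviations of multi-segment
materials; dual epistasis is g minus the sum of constituent single effects;
for triples, "mixed" epistasis is g minus singles (all interaction lumped)
and pure triple epistasis is mixed minus the three dual terms. Identical
contrasts applied to the per-environment GE predictions give the
environment-interaction components in deviation coding.

Two estimators implement the same decomposition and are tested against each
other: the sequential differences above, and a least-squares fit of G on
the hierarchical indicator design (intercept, one column per single-locus
state, per pair-state and per triple). On the saturated 65-material design
the fit is exactly identified and reproduces the sequential estimates to
1e-9; on reduced designs it names aliased columns instead of silently
dropping them.

Three policies matter in practice:

* **Non-significant constituents are never zeroed.** Higher-order residuals
  subtract estimated values whether or not they carry stars; zeroing would
  bias every residual that contains a small constituent.
* **Unavailable constituents propagate.** If a single effect cannot be
  estimated (its material is absent), every residual needing it is flagged
  undefined rather than computed against an implicit zero.
* **Significance is per contrast, uncorrected.** SE = sqrt(sum(c^2) *
  sigma2_e / (n_env * n_blocks)) for main effects (the interaction
  deviations use the (1 - 1/n_env)/n_blocks variance), t against the ANOVA
  error degrees of freedom, stars at 0.05/0.01. Multiple-testing correction
  is deliberately off by default so counts of starred effects are
  comparable with conventional reports; with zero residual degrees of
  freedom the annotations are withheld.

Heritability is reported on the plot basis (general = sigma2_G / sigma2_P,
peculiar = sigma2_GE / sigma2_P with sigma2_P the plain component sum); an
entry-mean basis that divides GE, B and e by their replication is available
because published heritabilities rarely state which basis was used.

## Synthetic data

The generator emulates the study design the estimators assume: by default
3 environments × 3 blocks × the 65-material catalog (recipient, 8 single
states, 24 dual and 32 triple pyramids), with fixed environment shifts,
Gaussian blocks and plot error, and a truth model of per-locus a/d values,
dual and triple interactions and zero-sum G×E deviations. Three blocks per
environment is a design choice (the replicate count of such trials is
rarely published); it gives 384 error degrees of freedom at full scale. The
"study-like" preset draws every effect from the packaged reference tables
(unreported values enter as zero, and the unreported environment cells of
each interaction vector absorb the remainder so deviations sum to zero);
default noise levels (block SD 0.5 d, plot SD 1.5 d) are set so that
effects near 1.7 d sit at the edge of significance, matching how the
reference tables star their smallest effects. The generator does not
emulate spatial field trends, heteroscedastic environments or within-plot
variance, so passing tests certify the estimators under the stated model,
not robustness to those violations.

Ground truth is exported in the same schema as the effect reports, which
reduces parameter-recovery tests to table diffs: a noise-free simulation
followed by fit and decomposition must return every truth effect, including
all G×E deviations, to 1e-9 days.

## Reference tables and the network

The packaged reference CSVs hold the published effect values for the
four-QTL heading-date system. Blank cells are unreported (non-significant)
effects and load as unavailable; where the source does not tie an
interaction value to a specific environment the values occupy the leading
environment columns in reported order. Decomposition identities are only
asserted for combinations whose constituents are all reported — residuals
involving unreported singles (e.g. the *Hd1* additive) are undefined by
policy, and a few reported combinations are arithmetically inconsistent
with the reported constituents because the original estimates carried
unreported non-significant terms.

Network inference asks, for each ordered locus pair, how the focal locus's
effect changes in the background of the other (the delta equals the
epistasis between them). "Unchanged" is operationalized as: delta below 1.0
day in magnitude, or non-significant at alpha = 0.05 when p-values are
available — the magnitude floor exists because no numeric rule is standard.
A pair is independent when fewer than half of the evaluable evidence items
(four focal-state × background-state combinations) are active; otherwise
the summary relation is the majority sign of the active deltas, with ties
reported as ambiguous. The per-state detail is always retained because
heterozygous and homozygous substitutions of the same locus (notably
*Hd3a*) can be promoted and inhibited oppositely; the evaluable-evidence
denominator (rather than all four cells) keeps sparse tables from defaulting
to "related" on a single active cell.

## Numerical choices and limitations

* All randomness flows through a single integer seed per generator call;
  identical seeds give byte-identical tables, and pipeline artifacts embed
  the config hash and seed.
* MINQUE coefficient matrices with condition number above 1e12 raise an
  error naming the confounded components instead of returning garbage.
* Truncation of negative components, the BLUP error-variance floor and the
  1e-6 centering tolerances are the only hard-coded numerical guards.
* Monte-Carlo checks in the test suite run at reduced scale (20–25
  materials, 50–200 replicates) chosen so that unbiasedness and calibration
  are tested within a few seconds while keeping the Monte-Carlo standard
  errors small enough to be informative.
* REML/ML estimation, spatial trend modelling and QTL position inference
  are out of scope: loci are known a priori in an SSSL design, and the
  published heritabilities of the real trial are not reproducible without
  the raw field data, which is not distributed.
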