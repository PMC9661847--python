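# Methods

`pneumotyper` implements the computational chain used to quantify how much
of the lung (BAL) microbiota is seeded from upstream body sites — saliva,
oropharynx, nasal cavity — and to classify subjects into two lung community
types by the intensity of that oral input.  This note records the models,
the parameter choices that matter, what the synthetic cohort does and does
not emulate, and the numerical decisions taken where the design was open.

## Neutral community model

A taxon with mean relative abundance `p` in a source pool is predicted to
occur in a fraction

    F̂(p) = 1 − BetaCDF(d; N_T·m·p, N_T·m·(1−p))

of local (sink) communities, where `m` is the migration (diffusion)
coefficient, `N_T` the local community size and `d` the detection limit.
Neither `N_T` nor `d` is observable from a count table; following the
standard implementation of this model we set `N_T` to the mean sink read
depth and `d = 1/N_T`.  Observed occurrence is presence (`count > 0`) in a
sink sample; source abundance is the mean of per-sample relative abundances
(robust to depth imbalance across source samples, unlike a pooled-count
ratio).

`m` is fitted by bounded least squares on the per-taxon squared frequency
residuals, on `log m` over `[1e-6, 10]` with five log-spaced starts — the
SSE surface is unimodal in practice but flat for tiny `m`, and the
multi-start costs little.  `R² = 1 − SSE/SST` may be negative (worse than a
constant predictor), as it is for nasal-only fits on real lung data.  A 95%
Wilson score band around `F̂` (with `n` = number of sink samples) partitions
taxa into neutrally distributed, over-represented and under-represented
sets.

The multi-source fit pools sources as the mean relative abundance over the
concatenated source samples, so sites are implicitly weighted by their
sample counts.  Each fitted taxon is attributed to the site where its mean
relative abundance is highest; ties break by within-site prevalence, then
lexicographic site name, so attribution is deterministic.  Taxa are
cross-tabulated by site against inclusive quartile groups of their lung
occurrence frequency, with boundary taxa assigned to the more extreme
group.

On cohorts generated by the package's own simulator (matched
`N_T = depth = 1000`, 200 sinks, 300 taxa) the fitted `m` lands within
about 20% of truth.  The residual upward bias is structural: the model
compares `P(abundance > d)` with observed presence `P(count ≥ 1)`, and the
multinomial read layer detects some taxa below `d`.  We keep the standard
presence definition rather than a depth-scaled threshold because it is what
the field fits to real data and its bias is the smaller of the two.

## Gibbs source tracking

Each BAL community is modelled as a mixture over the named source
communities plus an "unknown" source.  A collapsed Gibbs sampler reassigns
each sink read `r` of taxon `t` with conditional probability

    P(z_r = s) ∝ (m_st + α₁)/(m_s + α₁T) · (n_s^{−r} + β)/(n − 1 + βS)

where `m_st` are the source's training counts — for the unknown source, the
sink reads currently assigned to it, smoothed by `α₂` instead of `α₁`.
Defaults mirror the reference implementation of this sampler: `α₁ = 0.001`,
`α₂ = 0.1`, `β = 10`, burn-in 100 sweeps, 10 restarts, 1 retained draw per
restart, rarefaction (without replacement) to 1,000 reads.  Mixing
proportions are fractions of sink reads per source averaged over retained
draws; the saliva proportion of a BAL sink is its ST value.

Correctness is checked against exhaustive enumeration: on a toy with 6 sink
reads and 2 sources the collapsed joint weight of every assignment vector
can be summed exactly, and the sampler's posterior means agree within
Monte-Carlo error.  The inner sweep is JIT-compiled (numba), which makes
cohort-scale runs (60 subjects × 10 restarts × 100 sweeps × 1,000 reads)
take seconds.

Sources are subject-paired when every sink subject has a full set of source
samples, otherwise site-pooled across the cohort; the mode used is logged.

## Pneumo-type calling

Across subjects the ST value is bimodal: a high-oral-input mode and a
low-oral-input mode.  The cutoff is the density minimum strictly between
the two highest modes of a Gaussian KDE (Silverman bandwidth, 512-point
grid on [0, 1]); local maxima below 5% of the global maximum are ignored as
ripple.  Subjects at or above the cutoff are HOIT, below it LOIT (the
boundary is closed on the high side).  Fewer than two qualifying modes is
an error — the distribution is then not bimodal and a manual cutoff must be
supplied deliberately.

### Dirichlet multinomial mixture

The independent typing route fits a mixture of Dirichlet-multinomial
components by EM.  The M-step updates each concentration vector by a damped
fixed-point iteration that includes a weakly informative Gamma(0.1, 0.1)
prior on every concentration, parameterised in log-concentration space
(where the prior mode is well defined; in the raw parameterisation the
density diverges at zero).  The number of components minimises a
Laplace-approximated negative log evidence evaluated at that MAP: per
component the Hessian of the penalised objective has the closed form
`diag(d) + c·11ᵀ`, so its determinant costs O(T); the prior ordinate
supplies the per-parameter Occam penalty.  BIC is available as a config
alternative but under-penalises deep count tables.  EM ascends the
penalised objective monotonically; the data log-likelihood is reported
separately.

Community typing runs on the core taxa (cohort-total reads > 1,000, the
same filter used for networks); on full tables with heavy neutral
overdispersion the evidence sometimes supports a third component that
splits the high-input group along its mixing-weight continuum.

Concordance between trough labels and DMM assignments is a 2×2 table with
a two-sided Fisher exact test.  When the DMM keeps more than two
components, each component is collapsed to high/low by whether its mean ST
exceeds the cutoff before the test.

## Ecology statistics

Shannon index (natural log), Bray-Curtis on relative abundances (rarefied
counts optional upstream), classical PCoA (negative eigenvalue mass is
logged and dropped), PERMANOVA with Anderson's pseudo-F and free label
permutation (`p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1)`; Bonferroni across
pairs in pairwise mode), and Levins' niche breadth `B = 1/Σ P²` where `P`
shares each taxon's cohort-wide abundance across samples.

The normalised stochasticity ratio compares each within-group pair's
observed Bray-Curtis similarity `C` with its expectation `Ē` under a null
that preserves per-sample richness, draws taxa with probability
proportional to cohort occupancy and assigns them cohort-mean relative
abundances (100 randomisations by default).  The per-pair value
`1 − |C − Ē| / max(Ē, 1 − Ē)` is 1 when observed turnover matches the null
and 0 at maximal deviation; the group NST is the clamped mean.  This
normalisation is this package's own; it follows the spirit of the published
NST framework but is not numerically interchangeable with the reference NST
package, so only ordering and threshold properties (neutral > 0.5,
selection-dominated < 0.5, higher-migration ≥ lower-migration) should be
compared across tools.

## Co-occurrence networks

SparCC basis correlations from log-ratio variances with pseudocount-1
fractions: `T_ij = Var(log x_i/x_j)` via one covariance matrix, basis
variances from the sparsity-approximation linear system, correlations
clamped to [−1, 1].  Fraction estimation is deterministic (no Dirichlet
draws) so repeated runs agree exactly; the permutation layer supplies all
uncertainty.  The single strongest pair above 0.1 is excluded and the
system re-solved, up to 10 rounds.  Significance: each taxon's counts are
independently permuted across samples (1,000 iterations; a
resample-with-replacement mode exists for comparison) and two-sided pseudo
p-values computed with the +1 correction.  Edges are retained when
`|ρ| ≥ 0.4` and `p < 0.05`.  The published description of this retention
rule ("correlation coefficient ranges between −0.4 and 0.4") is ambiguous;
retaining only weak edges would be ecologically meaningless, so the
magnitude reading is used.

Attack robustness removes nodes in descending *initial* degree order (ties:
higher mean abundance, then name), recording the largest-connected-
component fraction after each removal; the AUC is the trapezoidal area.
The static order keeps the curve deterministic and matches degree-targeted
attack; adaptive recomputation is a config option.

The neighbor-shift (NESH) score between two networks is the Jaccard
dissimilarity of a common node's neighborhoods (0 for identical, 1 for
disjoint non-empty); "driver" nodes sit in the top NESH quartile and gained
degree in the second network.  This is a deliberately simplified
re-implementation of the neighbor-shift idea — the original tool's exact
formula is not public in the source we follow.

Cross-site networks concatenate site-tagged taxon counts of paired subjects
into one feature vector per subject and proceed as above; per-node total
and cross-site edge counts are reported.

## Synthetic cohort

The generator emulates the study design: three source sites with log-normal
abundance spectra — saliva and oropharynx share a fraction (default 0.6) of
their taxa with identical base abundances, the nasal profile puts 95% of
its mass on a disjoint block — and per-subject lung communities assembled
neutrally.  Each subject's regional pool is `q = Σ w_s p^(s)`; the lung
composition is `Dirichlet(N_T·m_g·q)` and reads a multinomial draw.
Because the Dirichlet marginal is exactly the Beta distribution the neutral
fitter assumes, parameter recovery is a true inverse problem.

Defaults: 300 taxa, 60 subjects, 10,000 reads per sample, `N_T = 10,000`
(equal to depth, so the generative detection limit is the one the fitter
estimates), 70% of subjects in the high-input group.  Saliva mixing weight
is Beta(8, 2) in the HI group and Beta(2, 8) in the LO group; the remaining
mass splits 30/70 between oropharynx and nasal, making low-input lungs
nasal-dominated.  Migration rates default to 0.04 (HI) and 0.012 (LO),
magnitudes in line with fits reported for real high/low-oral-input lung
cohorts.  An optional "unknown" environmental source (off by default) adds
taxa absent from every named source.

What the simulator does **not** emulate: sequencing error, chimeras or
contamination; taxonomic mis-assignment; host covariates; longitudinal
dynamics; within-subject source variability beyond multinomial sampling.
Passing recovery tests therefore demonstrates the estimators are correct
and well-calibrated for neutrally assembled multinomial count data — not
that real BAL cohorts satisfy those assumptions.

A known ceiling: Beta(8, 2) and Beta(2, 8) overlap, so roughly 3% of
subjects per group draw a saliva weight on the far side of 0.5.  Such
subjects genuinely have the other type's lung composition; any classifier
of latent group membership — including a Bayes-optimal one — mislabels
them, which caps composition-based (DMM) agreement with the latent labels
at about 2 errors per 60 subjects on average.  The ST-based trough
classifier is less affected because the Gibbs apportionment non-linearly
compresses low-oral-input subjects toward small ST values.

## Numerical choices and degenerate inputs

- One global integer seed; each stage derives its generator from the seed
  and a CRC-32 of its operation name, so re-running one stage never
  perturbs another.
- Count tables reject negative, non-integer and NaN cells with coordinates
  in the error; zero-total samples are dropped (with a warning) on read.
- Zero-variance ST vectors and unimodal distributions raise rather than
  silently emitting a cutoff.
- SparCC taxa with non-positive basis variance become NaN rows with a
  warning; empty networks are valid objects whose path-length statistics
  are NaN.
- Proportion vectors are validated to sum to 1 within 1e-9.

## Problem sizes

Validation experiments are sized for a desk machine: migration recovery at
200 sinks × 300 taxa (~1 s per fit), apportionment recovery at 2,000-read
sinks, pneumo-typing on the 60-subject default cohort (~6 s end to end),
SparCC recovery at 50 taxa × 500 samples with 1,000 permutations (~2 s),
NST with 100 randomisations.  The full test suite runs in well under a
minute after JIT warm-up.
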