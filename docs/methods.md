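# Methods

## Growth model and VAF normalization

Hematopoietic stem cells are modeled as a fixed wild-type pool of
`N = 100,000` cells plus mutant clones.  A clone with fitness `s`
(per-year net growth advantage) acquired at age `ATMA` grows
deterministically as `x(t) = exp(s·(t − ATMA))` from one cell; the
stochastic counterpart is a linear birth–death process with birth rate
`1 + s` and death rate `1` per cell-year, whose expectation is the same
exponential.  The per-cell rates set only the noise timescale — the
data constrain `s`, not the birth and death rates separately — and are
exposed in the simulator.

A heterozygous mutation in a diploid genome is carried on one of two
alleles, so a clone of size `x` in a compartment of effective size
`N + (competing mutant mass)` is read out at

    VAF_j(t) = x_j(t) / (2 · (N + Σ_i x_i^lead(t))),

the sum running over the host's clones, each contributing the size of
its lead variant (the clone's highest-VAF mutation) once.  The growth
equations themselves carry no diploid factor; the factor 2 in the
denominator is forced by the observable saturation of dominant clones
at VAF 0.5 (a clone that replaces the whole compartment occupies one of
two alleles).  The "isolated" model is the special case with a single
clone in the denominator, `VAF = x / (2(N + x))`.

## Emission model

Observed alt-read counts are Binomial(depth, VAF_model).  Observations
that predate a variant's acquisition are scored at a sequencing-error
floor VAF of 1e-4 (configurable) rather than zero, so spurious reads do
not produce infinite penalties; post-acquisition model VAFs are used
as-is (they are bounded below by the single-cell frequency
`1/(2(N+1)) ≈ 5e-6`).  The full hidden-process machinery of trajectory
emission is deliberately reduced to this binomial model with
deterministic latent growth — the minimal choice consistent with the
data actually available (read counts at a handful of visits); a
beta-binomial overdispersion option would slot into the same interface.

## Clonal-structure inference

For a participant with `k` mutations, candidate clonal structures are
the set partitions of the mutation set, enumerated exhaustively in
restricted-growth-string order for `k ≤ 8` (Bell number B(8) = 4140)
and searched greedily (agglomerative merging from singletons, flagged
non-exhaustive) above that.  Mutations in one clone share one fitness;
each variant has its own acquisition age (a later mutation nested in an
existing clone).

Each structure is scored by its marginal likelihood:

* fitness is integrated over a uniform grid on [0, 1] in steps of 0.005
  (uniform prior on the grid and over structures);
* acquisition ages are profiled on a 1-year grid over [0, age at first
  observation]: the clone's lead variant first, then the other members
  with the lead's size fixed and their acquisition constrained to be no
  earlier than the lead's;
* the VAF denominator for a clone's members contains `N`, the clone's
  own modelled lead size, and the *data-estimated* sizes of the other
  clones' leads.  Given observed lead VAFs `v_i` at an age (linearly
  interpolated between visits, clamped at the ends), the joint inversion
  of the VAF equations gives the total mutant mass
  `S = 2VN/(1 − 2V)` with `V = Σ v_i`, and `x_i = v_i · 2(N + S)`.

Treating competitor masses as data rather than parameters is the key
tractability decision: it factorizes the evidence over clones, so the
cost of scoring a partition is linear in the number of clones instead of
exponential (a joint fitness grid over clones is `201^(#clones)`).  It
also matters statistically: next to a saturating clone, subordinate
clones show flat or declining VAF trajectories, which a
competition-blind likelihood cannot explain — in experiments that bias
selected structures toward spurious merging.  The residual
approximation is that competitor masses carry sampling noise from the
observed VAFs instead of being integrated over.  A fully parametric
cross-clone log-likelihood (`structure_loglik`) is provided for
diagnostics at explicit parameter values.

The winning structure maximizes the evidence; ties break toward more
blocks (independent clones claim less shared information), then
canonical order, and are recorded as warnings.  Per-clone fitness is
reported as the MAP of the grid posterior.  An independent nested-loop
implementation of the same definitions (plain Python loops,
`scipy.stats.binom`) lives in the test suite and must agree with the
vectorized evidence to 1e-8.

## Acquisition-age estimation (ATMA)

After structure selection, each variant's ATMA is re-estimated by
continuous bounded optimization (tolerance 1e-6 years) of the binomial
log-likelihood under the isolated deterministic model at the clone's MAP
fitness — the most probable age at which the clone was a single cell.
The search interval is [0, first observation age]: near-birth
acquisition is allowed, prenatal ages are not emitted; optima at the
interval ends are clamped and flagged `boundary`.  Variants with
fitness at the grid minimum, or with zero alt reads throughout, are
flagged unidentifiable and excluded from timing-dependent metrics.

## MACS120 and forecasts

`MACS120 = exp(s·(120 − ATMA))` is the predicted clone size at age 120;
the log value `s·(120 − ATMA)` is carried alongside because the raw
value spans tens of orders of magnitude.  Isolated and context-aware
VAF forecasts at age 120 are compared per variant; the cohort summary
reports the mean absolute difference and the fraction of participants
whose largest difference exceeds 0.20.  Participant-level metrics (max
observed VAF, max MAP fitness, max MACS120) are z-scored cohort-wide at
the analysis stage; MACS120 is z-scored on the log scale, since
z-scoring the raw value would be dominated by a few enormous clones.

## Variant filtering

A variant passes when any time point simultaneously satisfies:
VAF ≥ 1% (2% selectable), alt reads AO ≥ 5, unique-molecule alt reads
UAO ≥ 3 when available, and gnomAD under-representation p ≤ 0.05 when
available (a precomputed column; no live queries).  Once a variant
passes anywhere, *all* participant-matched observations are kept.
Variants whose VAF stays within ±0.05 of 0.5 or of 1.0 at every wave
are rejected as germline (the band absorbs binomial noise at typical
depths).  Manual-curation outcomes are consumed as allow/deny lists
(one `gene:variant` per line), not re-derived.  Rejections carry reason
codes; filtering is idempotent and never raises (malformed rows are
reason-coded).

## Synthetic cohorts

The generator emulates the three sampling designs: LBC (3 waves near
ages 70/76/82, depth ~2000), SardiNIA (5 waves over ~20 years from a
baseline between 45 and 65, depth ~1000), WHI (all female, baseline
50–79, visits at years 1/3/6/9 plus a late-life visit 14–19 years in,
depth ~1500).  Depth means are placeholders exposed in the design
objects; depths are negative-binomial (size 20) around them.  Per-gene
fitness is log-normal (σ = 0.35) around category means ordered as
observed in CH (splicing factors high, ~0.25; epigenetic regulators
low, ~0.07); DNMT3A and TET2 dominate the gene draw.  Acquisition ages
are drawn conditional on the clone reaching roughly 1% VAF by the last
visit — cohort participants are enrolled *because* CH was detected —
with low-fitness clones clamped to near-birth acquisition, mirroring
the detection limit.  Later variants join the previous clone with
probability 0.35 (nested, acquired ≥ 1 year after the host clone's
youngest member).  Read counts are binomial around the context-aware
VAF; the truth table records partitions, fitness and ATMA per variant.

Birth–death realizations are sampled exactly at the visit ages through
the process's binomial/negative-binomial transition law (number of
surviving lineages, then offspring of each), which is identical in
distribution to event-by-event simulation but vectorizes over
thousands of replicates; conditioning on non-extinction by the first
visit is by rejection.  Both conditioned and unconditioned modes are
exposed.

Markers are generated from the same linear mixed model the analysis
stage fits (fixed effects on age, z-scored max VAF, age×maxVAF, max
fitness and log-MACS120; participant random intercept sd 0.3; residual
sd 1); survival times are exponential proportional-hazards draws on
z-scored covariates with independent exponential censoring.  What the
generator does **not** emulate: sequencing artifacts and UMI behavior,
cohort attrition beyond censoring, marker-specific measurement scales
(markers are generated on the standardized scale), and correlation
between a participant's metrics and their visit schedule.  Passing
tests therefore demonstrate correctness of the estimation machinery
under the stated model, not robustness to the full messiness of real
panels.

## Association stages

Markers are normalized per cohort: values outside
[Q1 − 3·IQR, Q3 + 3·IQR] are removed; the transformation among log,
square root, Box–Cox and Yeo–Johnson (log/sqrt only when domain-valid)
maximizing the Shapiro–Wilk W is applied; the result is z-scored.
Binary markers bypass transformation; series with under 8 values or
zero variance are skipped with a report entry.  Each marker is fit with
`value ~ age * maxVAF_z + maxFitness_z + MACS120_z` plus a participant
random intercept (statsmodels MixedLM, REML); participants contribute
only markers with ≥ 2 visits; singular or non-convergent fits fall back
to OLS, flagged, and are excluded from correction.  The age×maxVAF
coefficient carries the rate-of-change interpretation; age-interactions
with the other two metrics are available behind a flag but off by
default, matching the formula as printed.  P-values are corrected per
predictor across the marker panel with the two-stage adaptive
Benjamini–Hochberg procedure (Benjamini–Krieger–Yekutieli 2006).  Note
the adaptive procedure rescales by the estimated null fraction, so its
q-values can drop below raw p-values; monotonicity in raw p is the
invariant that holds (the plain Benjamini–Yekutieli correction used for
the network contrasts does satisfy q ≥ p).

Survival uses lifelines' Cox proportional-hazards model on z-scored max
VAF, max fitness, log-MACS120, age at first observation, and sex, with
the concordance index reported; constant covariates are dropped with a
warning and convergence failures trigger a penalized (ridge 0.1) refit,
flagged.  Age-stratified refits use half-open bins [50,60), [60,70),
[70,80), [80,∞); per-cohort refits reuse the same model.

The Brunner–Munzel contrasts of log fitness (natural log of MAP s,
floored at half a grid step before logging) between mutations alone in
a clone and co-occurring ones are corrected with Benjamini–Yekutieli;
groups with fewer than 2 observations on either side are reported
descriptively but never tested.  Under complete separation the BM
variance degenerates, and the contrast reports the exact two-sided
permutation floor `2/C(n1+n2, n1)` with a flag.  The correction universe
defaults to all contrasts computed in one call (genes, or categories
plus partner pairings); scope is a parameter.

## Replicate-study designs and problem sizes

The verification studies use sizes chosen to characterize the estimator
while keeping the full suite to a few minutes on one core:

* **Parameter recovery** — 200 single-clone participants per fitness
  level s ∈ {0.1, 0.2, 0.3}, 4 waves at ages 50/60/70/80, depth 2000;
  generating ATMA 0/20/35 so each trajectory spans detectable VAFs.
  MAP fitness is required within 0.03 of truth per level.  Timing is
  required within ±3 years on average per level where the generating
  ATMA is interior (measured ≈ ±0.15 y) and pooled across levels.  At
  s = 0.1, detectability under N = 100,000 forces acquisition at birth:
  the ATMA truth sits on the boundary of its domain, and the signed
  error (+6 y at sd 7.5 y) is the half-normal mean of an unbiased
  estimator truncated at zero — an information limit of the design, not
  estimator bias; the posterior-mean alternative is worse (+11 y).
* **Structure classification** — 200 replicates each of a shared-clone
  design (s = 0.2, ATMA 20 and 30) and a discordant-fitness design
  (s = 0.3/ATMA 35 vs s = 0.05/ATMA 0), same waves and depth; ≥ 80%
  correct required.
* **Oracle equivalence** — every partition of 2- and 3-variant
  participants on a 20-point grid against the nested-loop brute force,
  to 1e-8.
* **Association stages** — mixed-model recovery of an age×maxVAF effect
  of −0.03 at n = 300 participants × 3 visits over 60 replicates (mean
  bias ≤ 0.01, 95% CI coverage ≥ 90%); all-null 43-marker panels at
  n = 150 × 2 visits over 10 replicates (mean adjusted-significant
  fraction ≤ 0.05); Cox recovery of a log hazard of 0.66 on the
  MACS120 covariate at n = 700 over 100 replicates (coverage ≥ 90%).
* **Birth–death check** — 10,000 conditioned realizations against the
  analytic conditional mean `exp(sτ)/(1 − α(τ))`.

## Known limitations

* Fitness is assumed constant over a clone's life; time-varying
  selection is out of scope.
* Within-clone phylogenetic order is represented only through the
  nested-acquisition constraint, not inferred as a tree.
* Competitor masses in the evidence are plug-in estimates from observed
  lead VAFs; their sampling noise is not propagated.
* The structure prior is uniform over partitions; no complexity penalty
  beyond the implicit Occam factor of marginalization.
* Cohort-level analyses treat metrics as fixed covariates; inference
  uncertainty in s and ATMA is not propagated into the Cox/LMM stages.
* Associations are correlational; no causal direction is implied.
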