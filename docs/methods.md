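# Methods

This note documents the statistical model behind `bwsprefs`, the choices
made where the methodology was genuinely open, and what the synthetic
cohorts do and do not establish.

## Study design

Scenarios are blocks of a balanced incomplete block design. The package
constructs BIBDs by cyclic development of perfect difference sets and
ships the families it needs: (7, 3) — the Fano plane, used as a small
test bed — (11, 5), (13, 4) and (21, 5). For 13 outcomes in blocks of 4
the difference set {0, 1, 3, 9} mod 13 yields the symmetric
(13, 13, 4, 4, 1) design: 13 scenarios, every outcome shown 4 times,
every pair exactly once. Any valid (13, 13, 4, 4, 1) design is
statistically equivalent for the analysis; a deterministic canonical
construction was chosen so runs are reproducible down to the block
composition. Blocks are stored as sets — within-block presentation order
is a survey-administration concern outside the likelihood, and would be
randomized per respondent at interview time. Requests for sizes without
a catalogued difference set fail loudly with the admissibility
conditions rather than attempting a search; general BIBD search is out
of scope.

## Choice model and estimation

A best-worst answer on block S is modelled as one draw from the maxdiff
pair logit: the respondent picks the ordered pair (best, worst) = (i, j)
with probability proportional to exp(u_i − u_j) among all k(k−1) ordered
pairs of S. Identification fixes the reference outcome's utility at 0
(no sum-to-zero coding), matching the convention of reporting log-odds
against a reference outcome. A global choice-determinism scale is not
separately identified and is absorbed into the coefficients: data
simulated at scale s recover s·u.

The log-likelihood is concave, so estimation uses damped Newton steps
with the analytic gradient and observed information; convergence is
declared at max |gradient| < 1e-6 (at most 500 iterations, with step
halving as a safeguard). The optimum is start-independent, which the
suite verifies from random starts, and is cross-checked against an
independent conditional-logit implementation and against brute-force
numerical maximization on small Fano-design datasets.

Quasi-complete separation in this model occurs when an outcome is chosen
best on *every* one of its appearances (or worst on every appearance):
the likelihood is then monotone in that outcome's utility and the MLE
diverges. The fit guards exactly that condition and names the outcome.
Note that an outcome merely never being chosen does not make the MLE
diverge here — such an outcome still enters every candidate
denominator — so no stronger precondition is imposed.

Repeated choices by one respondent are correlated; the default standard
errors are one-way cluster-robust (sandwich) on respondent with an
n_c/(n_c−1) small-sample factor. Scenarios are design cells nested in
the candidate-set coding, not a second clustering dimension, so two-way
clustering is not implemented; `cluster_by="none"` exposes the
inverse-information errors. Confidence intervals are Wald with z = 1.96.
Cross-stratum comparisons use min-max normalization of the coefficient
vector to [0, 1], since relative log-odds scales are not directly
comparable.

## Preference weights (SUCRA)

Each respondent's B–W score per outcome (#best − #worst) is divided by
times shown, giving a rate in [−1, 1]. The effect of outcome i is the
standardized mean difference of its rate against the reference outcome,
standardized by the SD of the paired per-respondent differences (a
paired, Cohen's-d_z-type SMD); the reference's SMD is structurally 0.
Respondents are the replication units: the SMD vector's covariance is
the empirical covariance of the paired differences divided by n (scaled
to the SMD metric). An alternative reading of the standardization —
pooling SDs per outcome rather than over paired differences — exists;
the paired-difference version was implemented because it respects the
within-respondent pairing that the design induces.

With a flat prior the posterior of the effect vector is normal at the
frequentist estimates. The sampler draws from that multivariate normal
(singular covariances are handled by eigendecomposition; non-PSD inputs
raise unless a nearest-PSD repair is requested), ranks each draw
descending — larger SMD = more worrisome = rank 1, exact ties broken
uniformly at random within the draw — and accumulates the
rank-probability matrix, which is doubly stochastic by construction.
SUCRA_i = (1/(a−1)) Σ_{k<a} P(rank_i ≤ k); its mean over outcomes is
exactly 0.5. Default 100,000 draws; the seed is a required part of any
pipeline configuration. Three-outcome sampling is validated against
exact quadrature.

Pooled weights come from re-analysis of the merged two-site data, not
from averaging site weights. Interval estimation follows the simulate-
then-bootstrap recipe: per outcome, normal variates centered at the
weight with the between-survey variance (mean squared deviation of the
site weights from the pooled weight — the only dispersion estimate a
two-site design supports; user-supplied variances are accepted),
resampled with replacement, 2.5th/97.5th percentiles of the resample
means, clipped to [0, 1]. By default 1,000 variates and 1,000 resamples.
A point weight at the ceiling 1 is reported one-sided with the upper
bound fixed at 1, since 1 bounds the probability scale. When sites agree
exactly (between-survey variance 0) the interval collapses to the point —
visible for well-separated outcomes whose ranks are essentially certain
at these sample sizes.

## Diagnostics

For a response with best b and worst w on block S, the implied
dominances are b ≻ x for x ∈ S∖{b} and x ≻ w for x ∈ S∖{b, w}; pairs
involving neither b nor w are uninformative for that response. Cell
(i, j) of the win matrix is wins(i over j) divided by the informative
count; unsupported cells are flagged as "no data" (the heat map's white
patches) and the matrix satisfies entry(i,j) + entry(j,i) = 1 wherever
supported. Whether worst-implied losses should count is not dictated by
the heat-map definition alone; they are included by default to match
the implied-paired-comparison framing, with `include_worst_losses=False`
as a sensitivity flag. Heat maps order outcomes by descending pooled
preference, which renders a consistent cohort as a corner-to-corner
gradient.

Agreement uses Lin's concordance correlation coefficient with
population (1/n) moments and the Fisher-z interval with Lin's variance
on n − 2 degrees of freedom; |CCC| ≤ |Pearson r| always, and the point
estimate requires n ≥ 3 and non-degenerate variances. Plots (heat maps,
cumulative ranking curves, agreement scatters) are artifacts only; all
assertions run against the underlying matrices.

## Synthetic cohorts

The generator is the estimator's generative twin: choices are drawn from
the same maxdiff pair logit, which makes parameter recovery well-posed
and turns the analysis into a testable round trip. Defaults emulate the
motivating study: sites "Ethiopia" (n=100) and "Switzerland" (n=120),
all 13 scenarios answered by every respondent, true utilities set to the
published pooled log-odds (6.1, 4.6, 3.9, 3.1, 2.6, 2.3, 1.7, 1.4, 1.0,
0.9, 0.6, 0.2, 0), choice scale 1. A sequential best-then-worst rule is
available behind a flag for robustness experiments but is not the
default, and nothing models fatigue, item-order effects, or erratic
respondents beyond the scale parameter.

VAS ratings are generated as a min-max affine map of the utilities onto
0–100 plus Gaussian noise (SD 10 by default, chosen as a plausible
magnitude for direct severity ratings), clipped to the scale; this
suffices to reproduce the qualitative finding that VAS agrees poorly
with choice-based weights once the noise is material. Covariates (age,
sex, education) follow the published per-site summaries but do not enter
the likelihood; they exist so cohort summary tables are testable.

What passing tests show: the pipeline recovers the utilities, ordering
and cross-site agreement *under its own generative model* at the study's
sample sizes. What they do not show: robustness to real respondents'
unknown decision processes, inattention, or preference heterogeneity —
the original survey's data-generating process is unknowable, and the
published coefficient values themselves are not reproducible without the
undeposited raw responses.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-stage sub-seeds are derived
deterministically (CRC32 of a stage tag mixed with the master seed,
reduced below 2^31). Identical configuration and seeds give byte-
identical CSV outputs, asserted in the suite. Incomplete respondents are
dropped listwise with a warning by default (the motivating study had
none); a flag retains them with their actual times-shown in tallies.
Tabular artifacts are plain CSV with a header row; matrices are written
with outcome labels.

Default problem sizes — 220 simulated respondents, 100,000 rank draws,
1,000 bootstrap resamples, 20-seed replication for stochastic checks —
were chosen to keep every quantity's Monte Carlo error well below the
decision thresholds it is compared against while remaining comfortable
on a single CPU.
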