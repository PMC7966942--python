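# Methods

This note records the models implemented in `rarecohort`, the numerical
and design choices behind them, what the synthetic generators do and do
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Input model and preprocessing

The unit of analysis is an OTU count table: non-negative integers over
(sample, taxon), optionally with ISO-dated samples and semicolon-joined
taxonomic lineages. Samples are rarefied to a common depth by
multivariate hypergeometric subsampling (without replacement), which
preserves the richness-loss behaviour of drawing reads from a finite
sample; samples below the target depth are dropped with a warning.
Singletons are defined on the pooled table-wide total (a taxon with one
read anywhere), not per sample. Per-taxon mean relative abundance p_i is
the mean over samples of per-sample proportions; with equal depths this
equals the pooled proportion.

## Rarity cohorts

A taxon is *rare* when its pooled reads fall below a fraction of the
grand total (default 1%). Among rare taxa, occurrence below the
transient threshold (default < 4 of 12 samples) gives *transient-rare*;
occurrence above the persistence threshold (default > 8) gives
*persistent-rare*; the band in between is kept visible as
*intermediate-rare* and excluded from two-cohort analyses rather than
silently dropped. All inequalities are strict. The sensitivity scan
enumerates 12 abundance thresholds spanning 0.05–4.00% — anchored on the
round percentages that appear in standard presentations of this design
(0.05, 0.075, 0.5, 0.75, 1, 4) — crossed with occurrence thresholds
2–6, i.e. 60 combinations.

Conditional rarity is flagged by Sarle's bimodality coefficient
b = (skewness² + 1)/kurtosis (non-excess, biased moments) on the
per-sample relative abundances, with b > 0.9 and the requirement that
the taxon crosses the rarity threshold in both directions across
samples. Zero-variance taxa are never flagged.

## Species-abundance distributions

Histograms use half-open octaves [2^k, 2^(k+1)), k ≥ 0, with no
Preston boundary-splitting. The log-series is fitted on (S, N) alone —
α solves S = α·ln(1 + N/α) by bracketed root finding (relative
tolerance 1e-15) — and octave expectations are obtained afterwards by
summing α·xⁿ/n over each bin. The log-normal S(k) = S₀·exp(−a²(k−R₀)²)
is fitted by least squares from moment-based starts with two perturbed
restarts. The modal octave is constrained to R₀ ≥ 0: the implemented
curve is the canonical (unveiled) Preston form, and without the
constraint the three-parameter fit degenerates into a pure decay that
mimics the log-series, making model preference meaningless. Veiled-line
truncation is not modelled.

Goodness of fit is Pearson's χ² with bins pooled inward from whichever
tail has the smaller expected count until every pooled bin reaches an
expected count of 1 (switchable to the textbook 5);
dof = bins − 1 − fitted parameters, floored at 1.

Model identifiability at this design size is real but modest: on
communities of ~5,000 individuals sampled from a log-series (α = 20),
the log-series attains the lower χ² in a majority of replicates, but
only a modest one (the three-parameter log-normal is flexible enough to
chase a 6–11-octave histogram); Preston-curve data identify the
log-normal essentially always. For cohort sub-tables spanning only
4–6 octaves the raw-χ² preference is close to uninformative, and the
scan's per-combination `preferred` flag should be read together with
the GOF p-values, which penalize the log-normal's extra parameters.

## Sloan neutral community model

Predicted occurrence frequency for a taxon at metacommunity abundance p
is 1 − I_d(Nm·p, Nm·(1−p)), the beta tail probability beyond the
detection limit d. Nm is estimated by least squares on a log₁₀ grid of
200 points over [10⁻², 10⁷] refined by bounded scalar minimization;
convergence requires an interior minimum. The generalized R² is
1 − SS_err/SS_total about the mean observed frequency; when SS_total is
zero the fit is flagged uninformative. Taxa with p ∈ {0, 1} cannot
enter the beta prediction and are excluded and listed.

**Detection limit.** The default is d = ln(2)/N rather than the naive
one-read limit 1/N. When a sample of N reads is drawn multinomially
from a community at relative abundance x, the detection probability is
1 − (1−x)^N ≈ 1 − e^(−Nx) — the CDF of an exponential threshold with
mean 1/N — so detection behaves like comparison against a random
threshold whose *median* is ln(2)/N. Using the median-matched fixed
threshold makes the beta tail prediction agree with actual multinomial
detection across the abundance range (residual systematic gap < 0.03 in
frequency at the design depth) and removes an upward bias in fitted Nm
that the 1/N limit induces. The naive limit remains available as a
parameter.

The 95% envelope is the Wilson score interval around each predicted
frequency with trial count equal to the number of samples (the
denominator of observed occurrence frequencies); endpoints at predicted
frequency exactly 0 or 1 are forced to exactly 0/1 so boundary
observations compare as *within* (closed interval). Note an intrinsic
small-n property: with 12 samples the Wilson band around any prediction
strictly below 1 excludes an observed frequency of 12/12, so taxa whose
true detection probability is high but not ~1 are structurally prone to
land *above*; the neutrality fraction therefore depends on the
community's abundance profile, not only on whether assembly is neutral.
The binomial comparison model is 1 − BinomCDF(⌈N·d⌉ − 1; N, p), which
at d ≤ 1/N is 1 − (1−p)^N, with no free parameter.

## Beta-null deviation

The ecological-equivalence null redraws each sample's reads (totals
fixed) with replacement from the regional pool with probabilities
proportional to pooled taxon totals; per-sample richness is not
constrained — a deliberate simplification of richness-matching null
schemes, recorded in the run manifest. The deviation of a sample pair is
its observed Bray–Curtis distance minus the mean over null iterations
(default 999), aggregated per sample as the mean over pairs involving
it. The two cohorts are compared by a two-sided Mann–Whitney U
(primary, robust at n = 12) with a Welch t reported alongside. On data
generated by the null process itself the deviations center on zero;
this calibration is recomputed by the test suite.

## Distances, ordination, permutation tests

Bray–Curtis is computed on per-row proportions by default because
cohort sub-tables have unequal totals. Principal coordinates use
double-centering and a symmetric eigendecomposition with negative
eigenvalues retained. PERMANOVA's pseudo-F comes from the distance-based
decomposition of total versus within-group sums of squared
dissimilarities; PERMDISP embeds items in the full PCoA space, computes
distances to group centroids with the imaginary-axis correction
(negative-eigenvalue contributions subtracted under the square root),
and takes the one-way F. Both tests permute group labels — PERMDISP
recomputes centroids per permutation — and report
p = (exceedances + 1)/(permutations + 1); passing `permutations=None`
enumerates all label permutations exhaustively and reports the exact
fraction. Cohort-vs-cohort testing stacks the two cohort sub-tables of
the same samples as 2n items labeled by cohort. Phylogenetic (UniFrac)
distances are out of scope; Bray–Curtis stands in wherever a
phylogeny-weighted distance would otherwise be used, and the run
manifest says so.

## Time decay

Similarity is 1 − Bray–Curtis; the decay exponent is the OLS slope of
log₁₀(similarity) on log₁₀(lag in days). Zero-similarity pairs are
excluded (counted and reported) rather than offset. Because the
n(n−1)/2 pairwise points share samples, significance comes from
permuting the date assignment across samples and comparing |slope|,
not from the naive OLS t-test.

## Synthetic communities

The neutral generator draws a metacommunity of n_taxa abundances from a
log-series with parameter x = M/(M + α) (α = 50, implied metacommunity
size M = 10⁶ by default; parameterizing x from α and the taxon count
would drive x → 1 and underflow). Each sample's relative abundances are
Dirichlet with concentration Nm·p — so each taxon's marginal is exactly
Beta(Nm·p_i, Nm·(1−p_i)), the distribution the Sloan fit assumes — and
counts are multinomial at the target depth. Defaults are the design the
package targets: 12 samples, depth 2,988, 2,000 taxa (paper-scale
richness), Nm = 300, giving roughly one to two thousand observed OTUs
dominated by rare, low-occurrence taxa.

The niche alternative filters the same metacommunity through a Gaussian
response exp(−(e_j − u_i)²/2σ²) to a per-sample environment. The default
environment *alternates* between two conditions (±1, a seasonal-style
fluctuation matching bimonthly sampling) with σ = 0.5. This choice is
deliberate: under a smooth monotone gradient the least-squares Sloan fit
simply collapses Nm until the flattened curve covers the occupancy
cloud, and the Wilson within-fraction fails to distinguish niche from
neutral data even while the generalized R² plummets. A two-condition
environment creates abundant specialists whose occurrence is capped
near half the samples at high mean abundance — a pattern no value of Nm
can reproduce — so the neutrality fraction drops, as it should. A
gradient remains available through the `env` field.

The time-series generator applies AR(1) drift (ρ = 0.85, innovation
s.d. 0.4 by default) to the metacommunity log-abundances between
bimonthly dates, so time-decay structure and Sloan-model structure
coexist.

What the generators do *not* emulate: sequencing error and chimeras,
taxonomic structure of the metacommunity, richness as high as deep
amplicon surveys (tests run at hundreds to a few thousand taxa for
speed), multiple interacting environmental axes, and seasonal
periodicity beyond a two-level alternation. Tests passing on these
communities show that the estimators recover known generating
parameters and calibrate correctly under their own assumptions — not
that any particular real community is neutral.

## Problem sizes in the shipped checks

The test suite and acceptance script run everything at the study's
design scale or modestly below it, chosen once for single-CPU runtimes:
Nm recovery uses 500-taxon tables over 25 seeds per Nm ∈ {30, 300,
3000}; neutrality calibration uses the 2,000-taxon defaults over 20
seeds; beta-null calibration uses 199 null iterations over 20 seeds;
permutation-test calibration uses 1,000 exchangeable replicates at 99
permutations; the acceptance script repeats the same computations at
~10 seeds each.

## Known limitations

- The Sloan fit treats estimated p̂_i as exact; estimating p from the
  same 12 samples that provide the occurrence frequencies correlates
  the axes and biases the rare end of the curve. This is inherent to
  the standard method, not corrected here.
- The χ²-based model preference between log-series and log-normal does
  not account for parameter count; prefer the reported p-values for
  cohort sub-tables with few octaves.
- The beta-null scheme does not constrain per-sample richness.
- PERMDISP permutes raw labels (centroids recomputed), which can
  confound location differences with dispersion; interpret alongside
  the PERMANOVA result.
- Occurrence-based quantities are undefined for taxa never observed;
  all fits operate on the observed sub-table and report exclusions.
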