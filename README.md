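# rarecohort

Community-assembly analysis of rare and common microbial taxa from
temporal OTU count tables.

Microbial communities are dominated numerically by a handful of common
taxa, but most of their *species* are rare. Whether those rare taxa are
maintained by the same ecological processes as the common ones — niche
selection by the environment versus neutral dispersal and drift — is a
central question for the rare biosphere, and it matters practically
wherever community composition is used as an indicator (activated-sludge
bioreactors being the canonical engineered example). `rarecohort`
implements the complete analysis chain for answering it from a taxa ×
samples count table with collection dates:

1. **Rarity cohorts** — taxa are split by pooled relative abundance and
   occurrence into *transient-rare* (rare, seen in few samples),
   *persistent-rare* (rare, seen in most samples), *intermediate-rare*
   and *common*, with a 60-combination threshold-sensitivity scan.
2. **Species-abundance distributions** — octave (power-of-2 abundance
   class) histograms fitted with Fisher's log-series, where
   S = α·ln(1 + N/α) and the expected number of species of abundance n
   is α·xⁿ/n with x = N/(N+α), and with the Preston log-normal
   S(k) = S₀·exp(−a²(k−R₀)²); χ² goodness of fit with tail pooling.
3. **Sloan neutral community model** — a taxon with metacommunity
   relative abundance p has local abundance ~ Beta(Nm·p, Nm·(1−p)); its
   predicted occurrence frequency is 1 − I_d(Nm·p, Nm·(1−p)) at
   detection limit d. Nm (community size × immigration rate) is fitted
   by nonlinear least squares; fit quality is the generalized
   R² = 1 − SS_err/SS_total; a Wilson score envelope partitions taxa
   into above/within/below, and the *neutrality fraction* (share of taxa
   within the envelope) is tracked by abundance bin and cohort. A
   dispersal-unlimited binomial sampling model is the comparison.
4. **Beta-null deviation** — observed Bray–Curtis beta-diversity minus
   its mean under an ecological-equivalence null (sample totals redrawn
   from the regional pool); deviations near zero indicate neutral
   assembly.
5. **Permutation tests** — PERMANOVA (location) and PERMDISP
   (dispersion) between cohort assemblages on Bray–Curtis distances,
   with exact exhaustive enumeration available for small designs.
6. **Time decay** — the slope w of log₁₀(similarity) on log₁₀(lag) with
   a date-permutation significance test.
7. **Synthetic communities** — a Dirichlet-multinomial neutral
   generator that is the exact generative dual of the fitted Sloan
   model, a Gaussian environmental-filtering niche alternative, and an
   AR(1)-drifting time series, so every stage is testable with known
   ground truth.

## Worked example

```python
import rarecohort as rc
from rarecohort import synth

# a drifting neutral community: 12 bimonthly samples, depth 2,988,
# 2,000-taxon log-series metacommunity, migration parameter Nm = 300
table = synth.simulate_timeseries(synth.TimeSeriesSimParams(
    neutral=synth.NeutralSimParams(n_taxa=2000, nm=300.0, depth=2988,
                                   n_samples=12, seed=7)))
table = rc.remove_singletons(table)
summaries = rc.summarize_taxa(table)
part = rc.classify_taxa(summaries, rc.CohortThresholds())
print(part.summary.round(1))

fit = rc.fit_ncm(summaries, n_reads=2988, n_samples=12)
rc.ncm_envelope(fit)
rc.partition_by_envelope(fit)
curve = rc.neutrality_curve(fit, part)
print(f"Nm = {fit.nm:.1f}  m = {fit.m:.3f}  R2 = {fit.r_squared:.3f}")
print(curve.cohort_fractions.round(3).to_string(index=False))
```

prints

```
                   n_otus  pct_otus  pct_reads
cohort
transient_rare       1590      82.8        7.4
persistent_rare       122       6.4       49.4
intermediate_rare     195      10.2       19.5
common                 14       0.7       23.8
Nm = 267.2  m = 0.089  R2 = 0.844
           cohort  n_taxa  frac_within  within_rel_abund_share
           common      14        0.214                   0.320
intermediate_rare     195        0.918                   0.902
  persistent_rare     122        0.713                   0.615
   transient_rare     308        0.961                   0.874
```

Reading this: most OTUs (82.8%) are transient-rare but carry only 7.4%
of the reads. The fitted migration parameter (Nm ≈ 267) recovers the
generating value (300) to within drift-induced error, and the neutrality
fraction is highest for the transient-rare cohort (96% of its observed
taxa sit inside the 95% envelope) and lowest for the common taxa — rare,
sporadic taxa look neutral; abundant taxa deviate. `n_taxa` counts only
taxa that entered the fit (observed at least once).

## Command line

The same pipeline is exposed as `rarecohort` with subcommands
`simulate`, `rarefy`, `classify`, `sad`, `ncm`, `betanull`, `permtest`,
`timedecay`, `scan` and `run-all`; `run-all --config pipeline.yaml`
executes every stage into one run directory with a `manifest.json`
recording versions, seeds and methodological substitutions. Exit codes:
0 ok, 2 config error, 3 data error, 4 numerical failure.

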