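# Methods

This note records the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Time binning

Twelve Phanerozoic periods (ICS 2020 boundaries, Carboniferous kept
undivided to match period-level PBDB binning) nested in three eras.
Boundary ages resolve to the younger interval — a deterministic,
documented tie-break; the oldest bound (541 Ma) belongs to the Cambrian.
Era durations used as per-Myr denominators are pinned to the
conventionally rounded 289 / 185 / 66 Myr rather than the exact boundary
differences (289.098 / 185.902 / 66.0) so that era rates reproduce the
familiar printed precision. Genus occurrences whose [min_ma, max_ma]
range spans a period boundary cannot be binned uniquely; they are
flagged and excluded from bins, and the exclusion count is logged so
totals stay auditable.

## Record filters

Certainty categories grade the evidence that an interaction is
parasitism; category 4 (also consistent with non-parasitic
interactions) is excluded from every analysis. Records without reported
specimen counts remain in occurrence counts but are never
prevalence-eligible: the two parasitism indices have different data
requirements, and conflating them would silently bias prevalence toward
well-sampled faunas. Prevalence eligibility is n ≥ 10 reported
specimens (inclusive); n ≥ 20 is the robustness setting.

## Prevalence statistics

Prevalence is held as an exact fraction k/n and rounded only at report
time. Era medians get percentile bootstrap 95% intervals with
B = 10 000 replicates (B and the method are our choice; the interval is
the 2.5/97.5 empirical percentiles of the median over resamples, seeded
and recorded in the output metadata). Era comparisons use the
two-sided Mann–Whitney U test: exact enumeration when the smaller
sample has ≤ 8 tie-free values, otherwise the tie-corrected normal
approximation with continuity correction (whether any continuity
correction was used in prior analyses of such data is usually unstated;
ours is documented and the two branches agree within 0.02 absolute p on
tie-free samples of 9–12).

Coverage of the bootstrap interval was checked by simulation: for
Beta(2, 20) prevalence samples of n = 50, empirical coverage of the
true median is ≈ 0.95 (computed by `experiments.bootstrap_coverage`).
Percentile intervals for a median are slightly granular at small n;
coverage at much smaller samples can wobble a few points.

## Coverage-standardized richness (SQS)

Raw richness per bin confounds diversity with sampling effort. SQS
fixes the sampled *coverage*: with Good's u = 1 − n₁/N estimating the
covered fraction of the frequency distribution, each genus's corrected
share is u·f_t. A trial shuffles the occurrence list, walks it, adds
u·f_t at each first encounter, counts the genus, and stops once the
running coverage reaches the quorum q — the genus that crosses the
quorum is counted. S̄ is the mean over trials (default q = 0.6, 50
trials; both configurable). Bins below 10 occurrences or 2 genera, or
with u < q, yield flagged missing cells instead of estimates.

Two refinements of the procedure exist in the literature —
excluding the most abundant genus from coverage tallies and
single-publication corrections. There is no basis in a period-level
analysis of this kind for assuming either was applied, so the dominant-
genus exclusion is a config flag (default off) and publication-level
corrections are out of scope; the flag state is written to run
metadata.

The subsampler is validated against exact enumeration: in a uniform
shuffle of a multiset, the first-encounter order of genera follows
successive sampling without replacement (probability proportional to
counts), so the expected trial richness of a small bin can be summed
over all genus orders. `sqs.expected_richness_exact` implements this
brute-force reference; the Monte-Carlo mean agrees within two standard
errors at 10 000 trials.

## Three-timer turnover rates

From the genus × period incidence, for interior bin i: 3t (sampled in
i−1, i, i+1), pt (sampled in i−1 and i+1 but not i), 2t_bottom (i−1 and
i), 2t_top (i and i+1), and the per-bin sampling probability
P_s = 3t/(3t+pt). The sampling-corrected rates are

    μ_i = ln(2t_bottom,i / 3t_i) + ln(P_s,i+1)
    λ_i = ln(2t_top,i    / 3t_i) + ln(P_s,i−1)

with the extinction correction taken from the bin above and the
origination correction from the bin below — the standard structure of
this correction family; P_s is per-bin, not a global constant. Rates
are per-bin (dimensionless) by default, matching dimensionless GLM
predictors; a per-Myr variant sits behind a flag. Cells whose inputs
are undefined (edge bins, 3t = 0, P_s unavailable or 0) are flagged
missing; negative rates are reported as-is with a flag, since the
correction can legitimately produce them.

Consistency: on simulated histories with known per-transition
extinction −ln(survival), 200-replicate means of μ̂ match the
generating values within 3 SE at high (92–99.8%) per-genus-bin sampling
probability, and the no-turnover complete-sampling limit returns
P_s = 1 and λ = μ = 0 exactly.

## Weighted GLMs

"Related via GLM with a Poisson/binomial link function" is read as the
canonical pairs: Poisson family with log link for per-period counts,
binomial with logit for k-of-n prevalence. Fitting is IRLS (relative
tolerance 1e-8, ≤ 100 iterations) on the weighted log-likelihood; the
binomial k-of-n likelihood with an extra weight w is implemented as a
proportion response with variance weights n·w, which reproduces the
pooled weighted logit in the intercept-only case. Predictors enter
unstandardized; inference is Wald z with two-sided normal p and the
significance codes # (<0.10), * (<0.05), ** (<0.01), *** (<0.001);
no multiple-testing correction is applied. Rows (periods or
occurrences) with any missing predictor are dropped and logged —
complete-case fitting is the only interpretable default, and with
12 periods the four edge bins lacking a turnover rate always drop.
Rank-deficient designs and non-convergence produce flagged fits, never
silent output.

**Weighting convention.** Weights are *relative* precision weights: the
named models normalize log₁₀(specimens) to mean 1 before fitting.
Variance weights treat absolute scale as information, so unnormalized
log₁₀ weights (mean ≈ 3) would shrink every reported standard error by
≈ √3 and roughly triple the nominal type-I error without adding any
data. The estimator itself (`fit_glm`) keeps literal weighted-likelihood
semantics — scaling all weights by c leaves coefficients unchanged and
shrinks SEs by √c — so the normalization is a property of the analysis
models, not of the fitting routine. A residual caveat remains: with
*heterogeneous* weights the reported Wald variance A⁻¹ understates the
sandwich A⁻¹BA⁻¹ (B ≈ 1.5·A under the default heavy-tailed specimen
counts for the prevalence model), so weighted binomial p-values are
somewhat anticonservative. This is inherent to specimen-count weighting
of proportion data; it is reported here rather than silently corrected.

When some period with occurrences has no reported specimen counts at
all, the occurrence model falls back to unweighted fitting and the
results table is annotated — the convention the # footnote in
coefficient tables of this kind denotes.

**Classification rule** (explicit and configurable): amplification when
the diversity coefficient is significantly positive, or when
origination is positive and extinction negative with either
significant; dilution when diversity is significantly negative, or
extinction significantly positive; unclear when nothing reaches
p < 0.10. Mechanism notes always list every signed term below the
marginal threshold, so a reader can audit the call against the
coefficients.

## Synthetic data

The generator draws a discrete-bin branching history: each extant genus
survives a bin of duration d with probability exp(−μ·d) (multiplied by
a mass-extinction survival factor at the end-Permian, 0.4, and
end-Cretaceous, 0.55, transitions — these pulses give the richness path
structure that decorrelates diversity from age, as in the real record)
and spawns Poisson(λ·d) new genera that first appear in the next bin.
Defaults: 150 starting genera, λ = 0.009, μ = 0.007 per genus-Myr.
Bin-level truth makes the downstream oracles exact, which is why a
discrete-bin process was chosen over continuous-time birth–death: the
analysis consumes only bin-level data.

Sampling is gamma-Poisson per genus-bin (mean 3 occurrences, shape 1 by
default) with point ages uniform strictly inside the bin, so every
emitted occurrence bins unambiguously. Specimens per parasitism
occurrence are lognormal rounded up, median ≈ 30 with log-sd 2 (mean
≈ 250), mimicking compiled sample-size skew; ~26% of analytical rows
carry a reported n ≥ 10, the rest are missing or small-sample reports,
and roughly a third of all rows carry certainty 4.

Three scenarios share one generating process — analytical row totals
allocated across periods by multinomial weights exp(g·(R_i − R̄)) and
per-bin prevalence logistic(a + b·R_i) on true richness R:
amplification (b = g = +0.02), dilution (−0.02), neutral (0). The
slopes put the standardized effect near one logit/log unit per
predictor SD at paper scale (~12 periods, ~370 eligible records), the
regime in which sign recovery is claimed. The *neutral* scenario is by
construction the null of the fitted models (uniform expected counts,
constant prevalence), so its rejection rate measures test size, not
misspecification. A separate *replica* configuration pins the published
compilation's marginals as inputs: the era record totals (481/492/451
analytical of 2118; 112/144/117 eligible) and era-level true prevalence
fixed by logit shifts at 5% / 4% / 10%, the compiled record's era
medians; it exists to emulate the record's count-derived summaries, not
for power experiments.

What the passing experiments show: the estimators recover the
generating structure under the stated noise model — independent
multinomial/binomial sampling, no spatial or taphonomic structure, no
within-period heterogeneity of prevalence beyond the richness link, no
correlated reporting of specimen counts. Real compilations violate all
of these to unknown degrees (literature-driven reporting, lithification
bias, autocorrelated sampling), so green tests certify the machinery,
not the biology.

## Numerical details

- All randomness descends from one seed through named `SeedSequence`
  substreams (per stage in the pipeline, per bin in the subsampler);
  reruns with the same config are byte-identical.
- Quorum comparisons use a 1e-9 slack so accumulated floating-point
  error cannot drop the crossing genus at q = u or q = 1.
- Exact prevalence fractions are converted to floats only for
  resampling and model matrices.
- Mann–Whitney falls back to the tie-corrected normal approximation
  whenever ties are present, regardless of sample size, because exact
  enumeration assumes continuity.
- Bins failing quorum or size thresholds, undefined turnover cells and
  dropped GLM rows are all carried as flags in the output tables, and
  the pipeline reconciles record counts at every filter
  (input = retained + excluded).

## Known limitations

- Weighted-binomial Wald inference is anticonservative under weight
  heterogeneity (see above); a sandwich or quasi-likelihood option
  would be the natural extension.
- The published per-group coefficient tables cannot be reproduced
  numerically here: they depend on the full unpublished compilation and
  on dated PBDB snapshots. The package instead validates the method
  (closed forms, calibration, sign recovery) and applies it to
  emulated data; supplementary-database values (e.g. era medians
  0.05/0.04/0.10 and the 99 232-specimen total) are documented targets
  for users who obtain that file, not asserted results.
- SQS variants involving publication-level corrections, classical
  rarefaction, squares/TRiPS estimators and range-through counting are
  deliberately out of scope.
- Per-class analyses run through the same code path (`host_groups`),
  but the synthetic class labels are exchangeable — they do not emulate
  clade-specific sampling regimes.
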