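# paleoprev

Macroevolutionary analysis of marine parasitism and host diversity across
the Phanerozoic, for paleobiologists and disease macroecologists who want
to test **amplification** (parasitism rises with host diversity) against
**dilution** (diverse host communities suppress prevalence) on
fossil-occurrence data.

The pipeline takes two delimited-text inputs — a compilation of
parasitized host occurrences (with confidence categories and specimen
counts) and a Paleobiology-Database-style genus occurrence export — and
produces:

1. **Record filters.** Interactions are kept for analysis only when their
   certainty category is 1–3 (category 4 = consistent with parasitism but
   also with other interactions). Prevalence p = k/n (k infested of n
   examined) is computed per occurrence with n ≥ 10 reported specimens.
2. **Era-level prevalence statistics.** Median prevalence per era with
   bootstrapped 95% percentile confidence intervals (B = 10 000),
   two-sided Mann–Whitney comparisons between eras, and observation rates
   per Myr using the era durations 289 / 185 / 66 Myr.
3. **Coverage-standardized diversity.** Per-period shareholder quorum
   subsampling (SQS): occurrences are drawn until the summed
   coverage-corrected genus frequencies u·f_t reach a quorum q (default
   0.6, 50 trials), where u = 1 − n₁/N is Good's coverage estimate. Mean
   sampled richness S̄ is reported per period together with three-timer
   turnover rates

       μ_i = ln(2t_bottom,i / 3t_i) + ln(P_s,i+1)
       λ_i = ln(2t_top,i    / 3t_i) + ln(P_s,i−1)

   built from three-timer (3t), two-timer (2t) and part-timer (pt) genus
   counts, with the sampling correction P_s = 3t/(3t+pt).
4. **Weighted GLMs and hypothesis calls.** A Poisson (log link) model of
   per-period parasitized-occurrence counts and a binomial (logit link)
   model of per-occurrence prevalence, both on the predictors
   (S̄, λ, μ, age) and weighted by log₁₀ specimen counts, with Wald z
   tests (codes: # p<0.10, * p<0.05, ** p<0.01, *** p<0.001) and an
   explicit, configurable classification rule mapping the signed
   significant coefficients to amplification / dilution / unclear.
5. **A synthetic-data generator** (discrete-bin birth–death genus
   histories, overdispersed sampling, logistic prevalence links) whose
   scenarios carry known ground truth, so every stage above is testable
   without any database download.

## Worked example

Generate a paper-scale amplification-scenario dataset and run the whole
pipeline on it:

```bash
paleoprev simulate --scenario amplification --preset paper --seed 11 --out data
paleoprev run --parasitism data/parasitism.csv --occurrences data/occurrences.csv \
              --out results --seed 11
paleoprev report --out results
```

which prints (output of the commands above):

```
== era_summary ==
      era  n_values  median_p  ci_low  ci_high  occurrences_per_myr
Paleozoic        35      0.08    0.05     0.15                 0.12
 Mesozoic        29      0.13    0.10     0.18                 0.16
 Cenozoic       309      0.64    0.61     0.65                 4.68
== hypothesis_calls ==
group      model          call                                                                      mechanism
  all occurrence amplification                                                         (+) S_mean (p=6.4e-06)
  all prevalence amplification (+) S_mean (p=1.49e-08); (+) lambda_3t (p=0.0216); (-) best_age_ma (p=0.00381)
```

In this scenario the generator ties both the number of parasitized
occurrences and prevalence to true standing richness with positive
slopes, so most eligible occurrences and the highest prevalences fall in
the diverse late bins; both fitted models recover a significantly
positive diversity coefficient and the classifier calls amplification
for the pooled data — the generated truth.

The equivalent library calls are:

```python
from paleoprev import (SQSConfig, OccurrenceCountModel, PrevalenceModel,
                       diversity_table, filter_analytical,
                       select_prevalence_eligible, scenario_bundle)

bundle = scenario_bundle("amplification", preset="paper", seed=11)
analytical = filter_analytical(bundle.parasitism)
div = diversity_table(bundle.occurrences, SQSConfig(quorum=0.6, trials=50, seed=1))
fit = OccurrenceCountModel.from_records(analytical, div).fit()
print(fit.summary())          # term, estimate, se, z, p, code
```

`scenario_bundle("replica", ...)` (CLI: `--scenario replica`) instead
pins the marginals of the published compilation — 2118 rows of which
1424 are unambiguous (481/492/451 per era), 373 prevalence-eligible
(112/144/117), and era-level prevalence 5% / 4% / 10% — as generator
inputs, so the summaries come out at the published values: occurrence
rates 1.66 / 2.66 / 6.83 Myr⁻¹, prevalence-observation rates
0.39 / 0.78 / 1.77 Myr⁻¹, era medians ≈ 0.05 / 0.04 / 0.10 and overall
median ≈ 0.06.

## Input formats

Parasitism CSV columns: `record_id, host_taxon, host_phylum, host_class,
parasite_phylum, certainty, n_specimens, n_infested, best_age_ma,
period, era, reference_id` (empty `n_specimens`/`n_infested` = not
reported; such rows count as occurrences but never enter prevalence).
Occurrence CSV columns: `genus, class, collection_no, max_ma, min_ma,
reference_no`; extra columns are ignored, and rows whose age range spans
a period boundary are flagged age-ambiguous and excluded from bins.

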