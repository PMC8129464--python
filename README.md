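# bridgetox

Robust Bayesian bridging for phase I oncology dose-escalation trials.

`bridgetox` implements a hierarchical dose–toxicity model that leverages
*co-data* — completed animal toxicology studies and concurrent human
trials in related patient subgroups — into the analysis of a new phase I
trial. Per human subgroup, the two-parameter logistic curve parameters
follow a prespecified-weight mixture over

* exchangeability with each animal species' study-level parameters
  (after log-normal translation of animal doses onto a human-equivalent
  scale),
* exchangeability with the other human subgroups, and
* a robust, non-exchangeable bivariate-normal prior of the subgroup's
  own,

with a truncated-normal bridging factor rescaling each subgroup's doses.
On top of the model the package provides:

* `model_core` — domain types, the dose–toxicity link and the joint
  log-density (reference implementation used by the test oracles);
* `inference` — a compiled adaptive Metropolis-within-Gibbs sampler,
  posterior mixture-component probabilities, meta-analytic predictive
  (MAP) risk distributions, interval probabilities and summaries;
* `ess` — Beta moment-matching of marginal predictive distributions and
  the resulting effective sample size (a + b);
* `escalation` — starting-dose rule, overdose-controlled interim
  recommendations with a no-skipping cap, safety stopping and MTD
  declaration;
* `trial_sim` — a simulator for paired sequential trials (T1 in region
  R1, then T2 in region R2) under six truth scenarios and five analysis
  presets (A–E), with operating-characteristics aggregation;
* `synthetic_data` — calibrated synthetic rat/monkey study generators
  (the published example's animal datasets are not deposited; the
  default fixture is calibrated so the translated monkey and rat data
  predict ~25% human DLT risk near 5 and 1 mg/kg respectively).

## Command line

```sh
bridgetox fixtures --seed 1999 --out animal.csv
bridgetox fit --data animal.csv --subgroup 1 --out fit/
bridgetox ess --summaries fit/risk_summary.csv --out ess.csv
bridgetox simulate --scenario 1 --model A --reps 100 --seed 7 --out sim/
```

`fit` writes long-format draws, per-dose risk summaries (with interval
probabilities and ESS columns) and convergence diagnostics; `simulate`
writes per-region operating characteristics and per-cohort decision
traces.

## Notes

* Interim fits inside the simulator default to reduced MCMC settings
  (`trial_sim.DEFAULT_INTERIM_MCMC`, one chain of 8000 iterations);
  pass `mcmc=McmcSettings(chains=2, iterations=15000, burnin=5000)` for
  reference-scale analyses.
* A fit whose split-R-hat exceeds 1.05 on any subgroup-level parameter
  is flagged; the simulator then doubles the iterations once and, if
  still flagged, aborts that trial (reported separately in the
  operating characteristics).
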