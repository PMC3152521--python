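# Packaged parameters for the NZ insomnia treatment evaluation.
# All dollar values NZD, GST-exclusive.

model:
  name: NZ insomnia treatment pathways
  currency: NZD 2009, GST-exclusive

population:
  at_risk_millions: 2.317      # population aged 20-59
  prevalence: 0.13             # insomnia symptom prevalence
  p_seek: 0.15                 # proportion of insomniacs seeking treatment

treatment_cost:
  # Published base-case mean treatment cost per person treated. The branch
  # probabilities needed to recompute it were never published, so it enters
  # the population scaling as a parameter.
  base_case_per_person: 145.0

health_costs:
  personal_medical_services_millions: 15313.0   # national spend, $M, 2008
  population_millions: 4.292                    # all-ages population, M
  cost_increase: 0.18          # insomniac vs non-insomniac per-capita cost
  cost_increase_range: [0.05, 0.25]             # literature range

utility:
  # pooled utility-difference dataset (EQ-5D clinician assessments plus
  # literature SF-36 conversions): low assumed 0, base = mean, high = max
  low: 0.0
  base: 0.157
  high: 0.373

transport_derivation:
  rate_per_km: 0.56
  round_trip_km: 29.83   # product 16.7048; the tabulated base case is 16.71

psa:
  n_iterations: 10000
  fraction: 0.25
  seed: 0
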