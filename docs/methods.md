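# Methods

## Model structure

The package implements a one-year, prevalence-based economic evaluation of
insomnia treatment versus no treatment, from a societal perspective
restricted to direct costs (provider fees, medicines, transport). The core
is a decision tree: a person with suspected insomnia either does not seek
treatment or enters care through one of five provider types; each provider
branch continues through no-further-action / treat / refer chance nodes
with at most one level of on-referral. Every node may reference a costed
*event*; an event's cost is the sum over resources of utilisation volume ×
unit cost. Fractional volumes are read as expected utilisation (0.5
prescriptions = half of patients receive one). A pathway's probability is
the product of branch probabilities from root to leaf, its cost the sum of
its event costs, and the per-patient mean treatment cost is the
probability-weighted sum of pathway costs. The wording "sum of all pathway
costs" in the original schematic is implemented as this expectation: only
the probability-weighted form is consistent with the tree cost being an
*average* cost per patient.

Treatment benefit is an avoided-cost offset: the gap between insomniac and
non-insomniac per-capita health spend. Writing TP for the all-population
per-capita cost, Ip for prevalence and R for the insomniac:non-insomniac
cost ratio, the mixture identity TP = Ip·R·Y + (1−Ip)·Y gives the
non-insomniac mean Y = TP/(1 + Ip(R−1)), the insomniac mean X = R·Y and
the offset Δ = X − Y. This closed form is adopted because it is the unique
decomposition reproducing all three published outputs (3,486 / 4,114 /
628) from the published inputs (3,568; 0.13; 1.18).

Success is embedded in the tree: every termination node of the treatment
subtree is assumed a successful outcome, so the full offset Δ accrues to
every treated person and no separate success rate is applied. A
`success_only` switch restricts the benefit to pathways ending at an
explicit "Success" leaf (scaling Δ by that probability mass) for users who
prefer the stricter reading.

With a one-year horizon there is no discounting, and a utility difference
equals QALYs gained. Net benefit per person = Δ − mean treatment cost; net
benefit per QALY divides by the utility gain; national totals multiply by
n = at-risk population × prevalence × proportion seeking treatment.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| Unit resource costs | packaged table | NZD 2009, GST-excl. | published fee/price estimates |
| Transport round trip | 16.71 | NZD | tabulated base case; the published derivation 0.56 $/km × 29.83 km = 16.7048 is exposed by `transport_unit_cost` but the tabulated 16.71 is authoritative because downstream totals match it |
| At-risk population | 2.317 | million persons (20–59) | prevalence estimates only cover this age band |
| Prevalence Ip | 0.13 | proportion | national symptom-survey estimate |
| Proportion seeking care | 0.15 | proportion | US finding that 85% of insomniacs do not seek treatment |
| Cost ratio R | 1.18 | — | literature mean 18% cost increase; plausible range 5–25% kept for sensitivity |
| Utility gain | low 0, base 0.157, high 0.373 | utility (= QALYs/yr) | pooled EQ-5D / rescaled SF-36 dataset: base = mean, high = max, low = 0 (treatment may fail) |
| Base-case mean treatment cost | 145 | NZD per person treated | published model average; used as a *parameter* for population scaling and as the calibration target, because the branch probabilities that generated it were never published |
| PSA ranges | ±25% | of base case | stated design, except R (literature range) and utility (its own low/high) |
| PSA iterations | 10,000 | — | stated design |

Resource columns of the utilisation matrix are mapped positionally to the
unit-cost rows (GP, specialist initial, specialist follow-up, psychologist,
health practitioner, alternative health practitioner, prescription, OTC,
transport) — the unique assignment under which the published pathway
totals ($33 / $434 / $502 / $562 after rounding) are reproduced.

First-contact proportions: raw survey percentages are grouped
(nurse + counsellor → health practitioner, 14.1; herbalist + acupuncturist
+ hypnotist → alternative health practitioner, 21.1), psychiatrist (3.5) is
dropped because the model has no psychiatrist entry branch, and the five
retained categories are renormalised (the survey allowed multiple
consultations). After dropping psychiatrist the retained percentages sum to
exactly 100, so renormalisation is the identity on the base case.

## Synthetic inputs

The success/refer splits and referral-destination probabilities downstream
of first contact were never published. The packaged completion therefore
uses placeholder values — P(no further action) = 0.2 at each provider,
P(refer) = 0.3 at each treat stage, referral destinations uniform — chosen
once as qualitatively plausible (most patients respond to first-line care;
a minority are referred on). Every completion carries a `provenance` field,
`"synthetic"` here, which propagates into the tree name and all CLI
reports. `calibrate_refer_probability` bisects the one shared refer/success
knob until the mean cost per person treated matches a target (the
published $145 in the acceptance pipeline); the result is a consistency
device — a completion compatible with one published average — never an
estimate of real referral behaviour.

Consequently the generator emulates the *structure* of the study inputs
(valid probability assignments over the published topology, entry
proportions from the published survey) but not real referral frequencies:
passing tests demonstrate that the engine computes the published algebra
correctly, not that the placeholder probabilities describe New Zealand
care-seeking. Quantities that depend on those probabilities (the tree
average, per-provider means, PSA intervals) are reproduced only up to the
synthetic completion; quantities that follow from published tables alone
(pathway costs, the cost split, the population scaling) are reproduced
exactly.

`generate_random_tree` supplies property-test fixtures: random topologies
(configurable depth/branching), Dirichlet branch probabilities per chance
node, uniform event costs on [0, 100), ~20% costless structural nodes, all
reproducible under a seed.

## Numerical choices

- Probability-conservation tolerance: 1e-9 for trees built in code, 1e-6
  for hand-entered configurations (rounded probabilities).
- Structural defects (duplicate ids, wrong arity) raise, while probability
  problems are returned as findings — a malformed tree makes probability
  findings meaningless.
- Dirichlet draws are renormalised by their sum to remove last-bit float
  slack, keeping generated trees inside the 1e-9 tolerance.
- Triangular sampling uses the inverse CDF of a uniform deviate; one
  seeded `numpy` Generator stream, parameters sampled in their listed
  order, so identical specs give bitwise-identical results. A zero-width
  range returns its point mass.
- Per iteration, sampled sibling branch probabilities are renormalised to
  sum to one; a sampled set with a non-positive sibling sum raises and is
  counted (`n_invalid`), never silently dropped.
- Quantiles: linear interpolation between order statistics
  (`numpy.quantile` default) — fixed for reproducibility.
- Dollars are carried at full precision and rounded only for reporting
  (half-up to the nearest dollar for per-person values, one decimal for
  $-million totals). The published per-person net benefit (482) and net
  benefit per QALY (3,072) were themselves computed from rounded
  intermediates; this package reports the full-precision equivalents
  (627.52 − 145 = 482.52; 482.52/0.157 = 3,073.4) and treats the published
  figures as rounded reports.
- Zero QALY gain makes cost per QALY undefined and is signalled as an
  error rather than returned as infinity.

## Design choices

- The no-treatment branch is a zero-treatment-cost end node; its
  consequences enter through the avoided-cost offset, not tree costs. The
  seek/no-seek split (0.85/0.15) can sit at the tree root (default) or be
  applied outside a conditional tree (`seek_split_in_tree=False`); both
  give identical per-treated costs.
- All PSA inputs are sampled independently (no correlation structure), and
  unit costs, utilisation volumes, branch probabilities, prevalence,
  care-seeking proportion, cost ratio and utility gain are all varied; the
  three headline outputs are computed per iteration from the same sampled
  set.
- Test problem sizes: oracle-equivalence and conservation properties run
  on 100 random trees (depth ≤ 5, branching ≤ 4); sampler calibration uses
  1e5 draws against the analytic mean (3 SE band); packaged-model PSA
  tests use 2,000–4,000 iterations, the acceptance pipeline 10,000.

## Limitations

- Downstream branch probabilities are synthetic (above); tree averages and
  PSA intervals characterise the packaged completion, not observed care.
- Comorbidity-attributable costs, productivity losses, travel time and
  accident externalities are out of scope, as in the source design.
- The EQ-5D tariff scoring algorithm is not implemented; utilities enter
  as numbers.
- The model is a single-year decision tree: no state transitions,
  discounting, or multi-year horizons, and only one level of on-referral.
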