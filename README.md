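# insomnia-cea

A decision-analytic cost-utility model of insomnia treatment pathways in
New Zealand (all dollars NZD 2009, GST-exclusive). The package is aimed at
health economists and health-services researchers who want a tested,
configurable implementation of a prevalence-based decision-tree evaluation:
micro-costed care pathways, an avoided-cost benefit derived from the
insomniac/non-insomniac health-spend gap, QALY-based cost-utility metrics,
national budget-impact scaling, and Monte Carlo probabilistic sensitivity
analysis.

## The model

A person with insomnia either does not seek treatment (probability 0.85) or
enters care through one of five providers — pharmacist, GP, health
practitioner, psychologist, alternative health practitioner — with entry
proportions derived from a UK treatment-seeking survey. Each provider
branch continues through no-further-action / treat / refer chance nodes,
with one level of on-referral. For a tree with branch probabilities
*p<sub>E</sub>* and per-event costs *c<sub>E</sub>*:

- cost of an event: *c<sub>E</sub> = Σ<sub>r</sub> volume(E, r) ·
  unit_cost(r)* over resources *r* (consultations, medicines, transport);
- probability of a pathway: product of branch probabilities root → leaf;
- cost of a pathway: sum of its event costs;
- expected tree cost: probability-weighted sum over pathways (the mean
  treatment cost per patient).

The benefit of successful treatment is the per-capita health-spend gap
between insomniacs and good sleepers. With population mean *TP*, prevalence
*Ip* and cost ratio *R*, the non-insomniac mean is
*Y = TP / (1 + Ip(R − 1))*, the insomniac mean *X = RY*, and the avoided
cost *Δ = X − Y*. Net benefit per person treated is *Δ* minus the mean
treatment cost; dividing by the utility gain (one-year horizon, so utility
difference = QALYs) gives net benefit per QALY. National totals scale by
*n = at-risk population × prevalence × proportion seeking care*.

Uncertain inputs carry triangular distributions (base case ±25% unless a
published range exists) propagated by Monte Carlo simulation (10,000
iterations by default) with sibling branch probabilities renormalised per
draw.

The downstream branch probabilities (success/refer splits, referral
destinations) were never published numerically; the package ships clearly
flagged **synthetic** placeholder values plus a calibration helper that
pins the one free split to a published mean treatment cost.

## Worked example

```python
import insomnia_cea as ic

costs = ic.load_unit_costs()
matrix = ic.load_utilisation()
event_costs = ic.build_event_costs(matrix, costs)

tree = ic.build_insomnia_tree()            # packaged tree, synthetic splits
paths = {p.leaf: p for p in ic.enumerate_pathways(tree, event_costs)}
print(round(paths["1.2"].cost, 2))         # 32.71  (pharmacist: OTC + travel)
print(round(paths["2.2.2.2"].cost, 2))     # 433.64 (GP -> specialist)
print(round(paths["3.2.2.1"].cost, 2))     # 562.32 (health prac. -> psychologist)

tp = ic.per_capita_cost(15313, 4.292)      # 3567.80 $ per capita
off = ic.split_costs(tp, 0.13, 1.18)
print(round(off.Y), round(off.X), round(off.delta))   # 3486 4114 628

res = ic.evaluate(145.0, off.delta, 0.157,
                  ic.PopulationScaling(2.317, 0.13, 0.15))
print(round(res.n_treated, 3))             # 0.045 million treated
print(round(res.total_cost, 1),            # 6.6  $M incurred
      round(res.total_avoided, 1),         # 28.4 $M avoided
      round(res.total_net_benefit, 1))     # 21.8 $M net benefit
```

The micro-costed pathway totals say a pharmacist-only episode costs about
$33 while a psychologist reached through a health practitioner costs $562;
nationally, treating the 0.045 million insomniacs who seek care costs
$6.6M and avoids $28.4M of downstream health spend.

Or from the shell, against the packaged model:

```text
$ insomnia-cea run --out results
Insomnia treatment evaluation (NZD 2009, GST-exclusive)
Branch probabilities: SYNTHETIC

Mean treatment cost by entry provider ($ per person treated):
  pharmacist                            54.32
  general_practitioner                 155.33
  health_practitioner                  215.44
  psychologist                         156.96
  alternative_health_practitioner      259.91

Mean treatment cost per person treated ($): 169.32
Health cost avoided per person ($): 627.52
Net benefit per person ($): 458.20
...
```

(The provider means and the $169.32 tree average depend on the synthetic
branch probabilities — the header flags that — whereas the pathway costs
and the $627.52 avoided cost follow from published tables alone.)

`insomnia-cea psa --seed 1` runs the sensitivity analysis and prints the
base case with the mean and 5th/95th percentiles for net benefit per
person, national net benefit, and net benefit per QALY.

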