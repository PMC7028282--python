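# rsbr

Single-score aggregation of a quantified Human Health **handprint** and an
environmental **footprint**, and the **Relative Sustainability Benefit Rate
(RSBR)** for comparing two alternatives — with Monte Carlo uncertainty over
the normalization and weighting value choices, and a generic Markov cohort
engine for producing DALY handprints.

## The problem

Endpoint life-cycle impact assessment expresses the environmental burden of a
product system on three Areas of Protection (AoP): Human Health (DALY),
Ecosystems (species.yr) and Resources (USD surplus cost).  Health
interventions also have a *handprint* — a measurable health benefit in the
same DALY metric.  Does the health benefit of, say, a pharmaceutical
treatment outweigh the environmental burden of producing and delivering it?
Answering that requires putting a patient-health DALY burden and a
three-dimensional environmental burden on one dimensionless scale.

The pipeline is the standard single-score route:

1. **External normalization** — divide each AoP burden *F_a* by a global
   reference total *N_a* (the total impact of that category per year), giving
   a dimensionless per-year share.  The handprint is normalized separately
   (against the total global disease burden) because its cause–effect chain
   differs from the footprint's.
2. **Panel weighting** — multiply by weights *w_a* with Σ *w_a* = 1.
3. **Combine** handprint and footprint on Human Health — only after
   normalization and weighting.
4. **Single score** — SiSc = Σ_a *w_a F_a / N_a* (points).
5. **RSBR** — for a treatment T vs a comparator C:

   RSBR = (SiSc_C − SiSc_T) / SiSc_C × 100 (%)

   Positive means treatment carries less burden.  Results tables often print
   the negated value (negative = burden reduced); a `table_sign` flag does
   that.  When footprint and handprint both fall (or both rise) under
   treatment, the combined rate would mostly reflect whichever side dominates
   in magnitude, so the two rates are reported separately
   (`decide_rsbr_mode`).

Normalization and weighting factors are *value choices*, so the package
treats them as distributions: hierarchical Monte Carlo over factor pools,
exact enumeration of all pool combinations, and one-way sensitivity analysis
(fix normalization, vary weighting, or vice versa).

Two published pharmaceutical case studies ship as built-in fixtures:
mass drug administration of mebendazole against soil-transmitted
helminthiases in Vietnam (`sth_vietnam`), and maintenance treatment of
schizophrenia with paliperidone palmitate in Belgium
(`schizophrenia_belgium`).

## Worked example

```python
from rsbr import (builtin_case, derived_reference_factors, evaluate_case,
                  display_rsbr, score_scenario, hh_handprint_share)

case = builtin_case("sth_vietnam")
nf, hnf, wf = derived_reference_factors("sth_vietnam")   # reference sets
for sc in (case.comparator, case.treatment):
    r = score_scenario(sc, nf, hnf, wf)
    print(sc.name, f"{r.score:.2E}", f"{hh_handprint_share(r):.1f}%")
res = evaluate_case(case, nf, hnf, wf)
print(res.mode.value, f"{display_rsbr(res.combined_rsbr, True):.2f}%")
```

prints

```
no_treatment 2.95E-05 100.0%
mebendazole_mda 1.29E-05 99.8%
combined -56.25%
```

The no-treatment arm scores 2.95E-05 points (all of it patient DALY burden);
treatment scores 1.29E-05 points, of which 99.8% of the Human Health
component is handprint.  Treatment reduces the combined single-score burden
by 56.25% — the health benefit outweighs the added environmental footprint.

More narrative scripts live in `examples/` (single-score report, value-choice
Monte Carlo vs exact enumeration, one-way sensitivity, Markov-derived
handprints), and a thin CLI exposes the same operations:

```sh
rsbr score --case sth_vietnam --table-sign
rsbr montecarlo --case sth_vietnam --iterations 10000 --seed 0 --out-json mc.json
rsbr markov run --preset sth_toy
rsbr fixtures export --dest fixtures/
```

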