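# Methods

## Model and assumptions

The package implements the single-score route of endpoint life-cycle impact
assessment extended with a quantified Human Health handprint.  Both handprint
and footprint are stored as non-negative *burdens* (DALY, species.yr, USD
per functional unit); benefit only arises when two scenarios are compared.
A missing burden ("not assessed") is a first-class value, distinct from
zero: it contributes nothing to sums, survives file round-trips as `NA`, and
makes any rate whose comparator is zero or absent `NA` rather than ±inf.

For a scenario with footprint *F_a* on AoP *a*, handprint *H*, footprint
normalization factors *N_a*, handprint normalization factor *N_H* and
weights *w_a* (Σ *w_a* = 1):

    SiSc = w_HH · (F_HH/N_HH + H/N_H) + w_ECO · F_ECO/N_ECO + w_RES · F_RES/N_RES

Handprint and footprint are normalized separately — the handprint against a
total global disease burden, the footprint against environmental reference
totals — and combined on Human Health only after weighting.  The RSBR
between comparator C and treatment T is (SiSc_C − SiSc_T)/SiSc_C × 100 %,
positive when treatment is beneficial; `display_rsbr(..., table_sign=True)`
negates for the results-table convention.  Only external normalization is
supported; internal (min-max or ranking) normalization is out of scope by
design.

**Mode rule.** When the footprint and handprint single-score deltas have the
same sign (both burdens rise or both fall under treatment), the aggregate
rate would mostly reflect the side that dominates in magnitude, so
`decide_rsbr_mode` reports the two rates separately; opposite signs (the
canonical trade-off), a zero delta or an absent side give the combined rate.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| weighting-set sum tolerance | — | 1e-9 | sets violating Σw=1 are rejected, never renormalized: silent rescaling would hide data errors in user-supplied panels |
| Monte Carlo iterations | — | 10,000 | the convention for value-choice resampling of this kind; the pools are small, so the median stabilises well before this |
| one-way sensitivity iterations | — | 2,000 | the convention for the one-axis runs |
| significant digits in reports | — | 3 | matches the precision of published endpoint tables |
| Markov row-sum / initial-distribution tolerance | — | 1e-9 | transition matrices must be row-stochastic to machine precision |
| handprint variants in MC | — | sampled uniformly | the enumeration covers min/base/max exactly, so sampling policy only affects the median, which is robust to it; a `variant` override fixes it |

## Derived reference factors

The reference normalization sets (ReCiPe Hierarchist World 2000 for the
footprint, GBD World 2000 for the handprint) are not published to full
precision.  Each is derived as (raw burden) ÷ (published normalized value)
from an anchor row of the case: the footprint factors from the only row with
both values printed (the STH treatment row; the schizophrenia
treatment-interruption row), the handprint factor from the comparator row.
The two cases imply slightly different Human Health footprint factors
(≈8.29e7 vs ≈8.72e7 DALY/yr), so each case carries its own derived set,
tagged as derived.

One published inconsistency is load-bearing: the two schizophrenia footprint
rows imply Human Health factors differing by ~5% (0.855/9.81e-9 ≈ 8.72e7 vs
0.512/6.18e-9 ≈ 8.28e7), beyond 3-significant-figure round-off, so no single
factor reproduces both printed rows from raw burdens.  The fixtures
therefore also expose the published normalized rows themselves
(`published_normalized_footprint`), and the schizophrenia footprint RSBR is
reproduced by entering the pipeline at the weighting step from those rows.
The published schizophrenia *handprint* normalized values are likewise
mutually inconsistent (3.48e-7 vs 3.16e-7 imply different totals), so the
−9.02% handprint rate printed for that case is not recomputable from raw
inputs; the raw-DALY handprint benefit (7.1%) is.

## Value-choice uncertainty

Pools hold footprint normalization sets, handprint normalization sets, and
weighting sub-sets grouped into main panels.  Per iteration: both
normalization sets uniform over their pools; the weighting draw is
hierarchical — main panel uniform over panels, then sub-set uniform within
the panel — so a panel's probability does not depend on how many sub-sets it
contributes (with panels of 4/19/3 sub-sets each panel has probability 1/3,
an individual 19-panel sub-set 1/57).  The handprint variant (base/min/max)
is drawn uniformly.  All draws are independent; the generator is numpy's
seeded PCG64, and identical seeds give identical output.  Iterations whose
RSBR is undefined (zero comparator) are excluded from statistics and
reported as a count.  Percentiles use linear interpolation between closest
ranks.  Exhaustive enumeration of the Cartesian product gives exact
min/median/max; every sampled value appears in the enumeration.

One-way sensitivity fixes one side at the *reference* sets and re-draws the
other every iteration (the alternative — re-drawing the fixed side once per
run — was a genuinely open choice; the reference interpretation was chosen
because it yields a deterministic baseline against which spread is
attributable to one axis alone).

## Markov cohort engine

Expectation-level propagation: occupancy (persons) times a row-stochastic
matrix per cycle; no microsimulation, no probabilistic transition sampling
(parameter uncertainty is carried upstream as min/base/max handprints).
YLD accrues on the occupancy at the **start** of each cycle (occupancy ×
disability weight × cycle length); an opt-in half-cycle correction averages
start and end occupancy, the common health-economics refinement — it is off
by default as the simplest convention, and neither convention is asserted as
canonical.  YLL credits each new entry into a death state with that state's
remaining life expectancy, which defaults to zero so mortality contributes
nothing unless the user supplies a value (the shipped cases are
morbidity-dominated).  `constant_burden` (cases × weight × years) is the
no-intervention counterfactual and equals an identity-matrix cohort run.

The shipped presets (`sth_toy`, `relapse_toy`) are **synthetic**: they are
structurally analogous to the deworming and relapse models the case studies
cite (which are parameterised in their own publications), not transcriptions
of them.  Real parameters can be supplied through the JSON model schema.

## What the synthetic generators do and do not show

`paper_shaped_pools` reproduces the published pool *structure* exactly
(4 × 4 × 26 × 3 = 1248 combinations; panels of 4/19/3 weighting sub-sets)
but its numeric values are log-uniform perturbations (±exp(0.5)) around the
derived reference factors, with Dirichlet(4,3,2) weights so Human Health
tends to receive the largest weight, as in real panels.  Monte Carlo
summaries computed from these pools therefore validate the machinery —
sampling law, enumeration bracketing, determinism — not the published
uncertainty ranges, which depend on the real supplementary factor tables.
`generate_random_case` draws log-uniform burdens over wide magnitude ranges
purely for property testing.  Neither generator models correlations between
factor sets (real normalization perspectives are correlated across AoPs),
nor inventory-level uncertainty, which the framework deliberately treats
upstream of this package.

## Numerical choices

- Single-score components are summed in the fixed AoP order; the
  score-equals-sum-of-components invariant is enforced at 1e-12 relative.
- Published-table comparisons in tests use 1.5% relative tolerance on cells
  and ±0.15 percentage points on RSBR values, absorbing the 3-significant-
  figure printing of the source tables without masking real errors.
- Weight sets failing Σw=1±1e-9 and matrices failing row-stochasticity
  ±1e-9 are rejected with explicit errors; nothing is renormalized.
- Degenerate inputs: an all-missing scenario cannot be scored (error); a
  zero comparator makes rates `NA`; reports print unassessed rows as the
  zero row, matching the published convention.

## Problem sizes

The test suite and acceptance script run the deterministic pipeline on the
two built-in cases, Monte Carlo runs of 25–10,000 iterations, exhaustive
enumeration of the 1248-combination pools, 100,000 sampling-law draws and a
1,000-case reconstruction sweep — sizes chosen to exercise every code path
and stabilise the sampled statistics while keeping the whole suite fast on a
single CPU.

## Known limitations

- The framework consumes endpoint burdens; it does not compute footprints
  from inventory data (no characterization, no midpoint modelling).
- Panel weighting only: no monetization, distance-to-target or MCDA
  weighting, and no internal normalization.
- Published Monte Carlo medians/ranges for the case studies depend on the
  supplementary factor tables, which are not redistributed here; with
  synthetic pools the package reproduces the deterministic reference results
  and the structure of the uncertainty analysis, not its published bands.
- Handprints are Human Health only; handprints on Ecosystems or Resources
  would need their own normalization route.
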