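"""The deterministic aggregation pipeline: normalize, weight, combine, score.

The chain mirrors the single-score route of endpoint life-cycle impact
assessment:

1. divide each Area-of-Protection burden by an external normalization factor
   (a global reference total for that impact, per year), making it a
   dimensionless per-year share;
2. multiply by a panel weighting factor (weights sum to 1);
3. combine handprint and footprint on Human Health — only after normalization
   and weighting, because the two are normalized against different reference
   totals;
4. sum the weighted components into a single score, in points;
5. compare two scenarios' single scores as a relative difference, the
   Relative Sustainability Benefit Rate (RSBR):

       RSBR = (SiSc_comparator - SiSc_treatment) / SiSc_comparator * 100  (%)

A positive RSBR means the treatment carries less single-score burden than the
comparator.  Results tables conventionally print the negated value (negative
= burden reduced by treatment); :func:`display_rsbr` applies that convention.
"""

from __future__ import annotations

from typing import Optional

from .types import (
    AoP,
    CaseStudy,
    HandprintNormalizationSet,
    ImpactVector,
    NormalizationSet,
    NormalizedVector,
    RSBRMode,
    RSBRResult,
    Scenario,
    SingleScoreResult,
    ValidationError,
    WeightedVector,
    WeightingSet,
)

__all__ = [
    "normalize_footprint",
    "normalize_handprint",
    "apply_weights",
    "combine_hh",
    "single_score",
    "rsbr",
    "display_rsbr",
    "decide_rsbr_mode",
    "handprint_benefit",
    "hh_handprint_share",
    "score_scenario",
    "evaluate_case",
]


def normalize_footprint(fp: ImpactVector, nf: NormalizationSet) -> NormalizedVector:
    """Divide each present burden by its AoP's normalization factor.

    Missing entries stay missing; they are not turned into zeros.
    """
    values = {
        aop.value: (None if fp[aop] is None else fp[aop] / nf[aop]) for aop in AoP
    }
    return NormalizedVector(nf_id=nf.id, **values)


def normalize_handprint(h: float, nf: HandprintNormalizationSet) -> float:
    """Divide a handprint DALY burden by the global disease-burden total."""
    if h < 0:
        raise ValidationError(f"handprint burden must be non-negative, got {h!r}")
    return h / nf.factor


def apply_weights(nv: NormalizedVector, wf: WeightingSet) -> WeightedVector:
    """Multiply each present normalized share by its AoP weight."""
    values = {
        aop.value: (None if nv[aop] is None else nv[aop] * wf[aop]) for aop in AoP
    }
    return WeightedVector(nf_id=nv.nf_id, wf_id=wf.id, **values)


def combine_hh(
    handprint_weighted: Optional[float], footprint_weighted_hh: Optional[float]
) -> Optional[float]:
    """Sum the weighted handprint and footprint Human Health components.

    A missing side contributes nothing; both missing yields missing.
    """
    present = [v for v in (handprint_weighted, footprint_weighted_hh) if v is not None]
    if not present:
        return None
    return sum(present)


def single_score(
    wv: WeightedVector,
    combined_hh: Optional[float] = None,
    *,
    scenario: str = "",
    handprint_included: bool = False,
    handprint_hh: Optional[float] = None,
    footprint_hh: Optional[float] = None,
    handprint_nf_id: str = "",
    handprint_variant: str = "base",
) -> SingleScoreResult:
    """Sum the weighted components into the single score, in points.

    When ``combined_hh`` is supplied it replaces the Human Health component
    (the handprint having been folded in after weighting).
    """
    if combined_hh is not None:
        wv = wv.with_human_health(combined_hh)
    present = [wv[aop] for aop in AoP if wv[aop] is not None]
    if not present:
        raise ValidationError(
            f"scenario {scenario!r} has no assessed components; cannot score"
        )
    return SingleScoreResult(
        scenario=scenario,
        score=sum(present),
        components=wv,
        handprint_included=handprint_included,
        handprint_hh=handprint_hh,
        footprint_hh=footprint_hh,
        handprint_nf_id=handprint_nf_id,
        handprint_variant=handprint_variant,
    )


def rsbr(score_comparator: float, score_treatment: float) -> Optional[float]:
    """Relative difference of two single scores, in percent.

    Positive when the treatment scores lower (is beneficial).  Returns
    ``None`` when the comparator score is zero: the rate is then undefined
    and is reported as NA rather than +/-inf.
    """
    if score_comparator < 0 or score_treatment < 0:
        raise ValidationError("single scores are burdens and cannot be negative")
    if score_comparator == 0:
        return None
    return (score_comparator - score_treatment) / score_comparator * 100.0


def display_rsbr(value: Optional[float], table_sign: bool = False) -> Optional[float]:
    """Apply the results-table sign convention (negative = reduced burden)."""
    if value is None or not table_sign:
        return value
    return -value


def _delta_or_none(
    comparator: Optional[float], treatment: Optional[float]
) -> Optional[float]:
    if comparator is None and treatment is None:
        return None
    return (comparator or 0.0) - (treatment or 0.0)


def decide_rsbr_mode(
    case: CaseStudy,
    nf: NormalizationSet,
    hnf: HandprintNormalizationSet,
    wf: WeightingSet,
    variant: str = "base",
) -> RSBRMode:
    """Choose combined vs separate reporting of the RSBR.

    Separate reporting applies when footprint and handprint single scores
    move in the same direction under treatment (both increase or both
    decrease): an aggregate would mostly reflect whichever side dominates in
    magnitude.  Opposite movements — the canonical trade-off — are combined,
    as is the degenerate situation where one side is absent or unchanged.
    """
    fp_delta = _score_delta(case, nf, wf, side="footprint")
    hp_delta = _score_delta(case, hnf, wf, side="handprint", variant=variant)
    if fp_delta is None or hp_delta is None or fp_delta == 0 or hp_delta == 0:
        return RSBRMode.COMBINED
    if (fp_delta > 0) == (hp_delta > 0):
        return RSBRMode.SEPARATE
    return RSBRMode.COMBINED


def _score_delta(case, factors, wf, side, variant="base"):
    def one(sc: Scenario) -> Optional[float]:
        if side == "footprint":
            if sc.footprint is None:
                return None
            wv = apply_weights(normalize_footprint(sc.footprint, factors), wf)
            vals = [wv[a] for a in AoP if wv[a] is not None]
            return sum(vals) if vals else None
        if sc.handprint is None:
            return None
        return normalize_handprint(sc.handprint[variant], factors) * wf[AoP.HUMAN_HEALTH]

    c, t = one(case.comparator), one(case.treatment)
    return _delta_or_none(c, t)


def handprint_benefit(case: CaseStudy, variant: str = "base") -> Optional[float]:
    """Relative DALY reduction of the treatment arm's handprint, in percent.

    Computed on raw DALYs, before any normalization or weighting.  ``None``
    when the comparator burden is zero.
    """
    if case.comparator.handprint is None or case.treatment.handprint is None:
        raise ValidationError("both scenarios need a handprint estimate")
    c = case.comparator.handprint[variant]
    t = case.treatment.handprint[variant]
    if c == 0:
        return None
    return (c - t) / c * 100.0


def hh_handprint_share(score: SingleScoreResult) -> Optional[float]:
    """Share of the weighted Human Health component due to the handprint, %.

    ``None`` when the Human Health component is zero (share undefined).
    """
    hp = score.handprint_hh
    fp = score.footprint_hh
    if hp is None and fp is None:
        raise ValidationError(
            f"score for {score.scenario!r} has no recorded Human Health split"
        )
    total = (hp or 0.0) + (fp or 0.0)
    if total == 0:
        return None
    return (hp or 0.0) / total * 100.0


def score_scenario(
    scenario: Scenario,
    nf: NormalizationSet,
    hnf: HandprintNormalizationSet,
    wf: WeightingSet,
    variant: str = "base",
    include_handprint: bool = True,
) -> SingleScoreResult:
    """Run one scenario through the full normalize-weight-combine pipeline."""
    if scenario.footprint is not None:
        wv = apply_weights(normalize_footprint(scenario.footprint, nf), wf)
    else:
        wv = WeightedVector(nf_id=nf.id, wf_id=wf.id)
    footprint_hh = wv[AoP.HUMAN_HEALTH]

    handprint_hh = None
    if include_handprint and scenario.handprint is not None:
        handprint_hh = (
            normalize_handprint(scenario.handprint[variant], hnf)
            * wf[AoP.HUMAN_HEALTH]
        )
    combined = combine_hh(handprint_hh, footprint_hh)
    return single_score(
        wv,
        combined_hh=combined,
        scenario=scenario.name,
        handprint_included=handprint_hh is not None,
        handprint_hh=handprint_hh,
        footprint_hh=footprint_hh,
        handprint_nf_id=hnf.id if handprint_hh is not None else "",
        handprint_variant=variant,
    )


def evaluate_case(
    case: CaseStudy,
    nf: NormalizationSet,
    hnf: HandprintNormalizationSet,
    wf: WeightingSet,
    variant: str = "base",
) -> RSBRResult:
    """Score both arms and report the RSBR in the appropriate mode.

    Always computes the footprint-only and handprint-only rates where both
    arms carry the respective burden; the combined rate is computed whenever
    both arms are scorable with everything included.
    """
    mode = decide_rsbr_mode(case, nf, hnf, wf, variant)

    def maybe_score(sc: Scenario, include_handprint: bool, footprint_only: bool):
        try:
            if footprint_only:
                if sc.footprint is None:
                    return None
                return score_scenario(sc, nf, hnf, wf, variant, include_handprint=False)
            return score_scenario(sc, nf, hnf, wf, variant, include_handprint=include_handprint)
        except ValidationError:
            return None

    fp_c = maybe_score(case.comparator, False, footprint_only=True)
    fp_t = maybe_score(case.treatment, False, footprint_only=True)
    footprint_rsbr = (
        rsbr(fp_c.score, fp_t.score) if fp_c is not None and fp_t is not None else None
    )

    hp_c = hp_t = None
    if case.comparator.handprint is not None and case.treatment.handprint is not None:
        hp_c = normalize_handprint(case.comparator.handprint[variant], hnf) * wf[AoP.HUMAN_HEALTH]
        hp_t = normalize_handprint(case.treatment.handprint[variant], hnf) * wf[AoP.HUMAN_HEALTH]
    handprint_rsbr = rsbr(hp_c, hp_t) if hp_c is not None else None

    all_c = maybe_score(case.comparator, True, footprint_only=False)
    all_t = maybe_score(case.treatment, True, footprint_only=False)
    combined_rsbr = (
        rsbr(all_c.score, all_t.score) if all_c is not None and all_t is not None else None
    )

    return RSBRResult(
        mode=mode,
        combined_rsbr=combined_rsbr,
        footprint_rsbr=footprint_rsbr,
        handprint_rsbr=handprint_rsbr,
        nf_id=nf.id,
        handprint_nf_id=hnf.id,
        wf_id=wf.id,
        handprint_variant=variant,
    )
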