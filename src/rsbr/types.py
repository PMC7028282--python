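"""Domain types for handprint-footprint single-score aggregation.

The endpoint level of life-cycle impact assessment expresses damage on three
Areas of Protection (AoP): Human Health in Disability-Adjusted Life Years
(DALY), Ecosystems in species.yr (potential species lost per year), and
Resources in USD surplus extraction cost.  A *footprint* is the environmental
burden of a product system on those areas; a *handprint* is a quantified
beneficial outcome expressed in the same metric — here the patient-health DALY
burden of a treatment arm, whose reduction relative to a comparator is the
benefit.

Burdens are always stored as non-negative numbers; "benefit" only ever arises
from comparing two scenarios.  A missing entry (e.g. an impact that was not
assessed) is represented as ``None``, which is distinct from zero and survives
serialization as the literal ``"NA"``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

__all__ = [
    "AoP",
    "CANONICAL_UNITS",
    "ValidationError",
    "ImpactVector",
    "HandprintEstimate",
    "Scenario",
    "CaseStudy",
    "NormalizationSet",
    "HandprintNormalizationSet",
    "WeightingSet",
    "NormalizedVector",
    "WeightedVector",
    "SingleScoreResult",
    "RSBRMode",
    "RSBRResult",
    "WEIGHT_SUM_TOL",
]

#: Tolerance on the sum-to-one constraint of a weighting set.  Sets failing it
#: are rejected, never silently renormalized.
WEIGHT_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class AoP(str, enum.Enum):
    """The three endpoint Areas of Protection."""

    HUMAN_HEALTH = "human_health"
    ECOSYSTEMS = "ecosystems"
    RESOURCES = "resources"

    @property
    def unit(self) -> str:
        return CANONICAL_UNITS[self]


CANONICAL_UNITS: Mapping[AoP, str] = {
    AoP.HUMAN_HEALTH: "DALY",
    AoP.ECOSYSTEMS: "species.yr",
    AoP.RESOURCES: "USD",
}


def _check_nonneg(name: str, value: Optional[float]) -> None:
    if value is None:
        return
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ImpactVector:
    """Per-AoP burden of one scenario, in the canonical unit of each AoP.

    Entries are per functional unit.  ``None`` marks an impact that was not
    assessed; it is preserved through aggregation (contributing nothing to
    sums) and through file round-trips.
    """

    human_health: Optional[float] = None
    ecosystems: Optional[float] = None
    resources: Optional[float] = None

    def __post_init__(self) -> None:
        for aop in AoP:
            _check_nonneg(f"footprint {aop.value}", self[aop])
        if all(self[aop] is None for aop in AoP):
            # permitted: the 'no treatment' arm of a case may have no
            # assessed footprint at all
            pass

    def __getitem__(self, aop: AoP) -> Optional[float]:
        return getattr(self, aop.value)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {aop.value: self[aop] for aop in AoP}


@dataclass(frozen=True)
class HandprintEstimate:
    """Patient-health DALY burden of one arm, with sensitivity bounds.

    ``base`` is the central estimate; ``min``/``max`` bracket it (obtained in
    practice from sensitivity analysis of the underlying disease model).
    """

    base: float
    min: float
    max: float

    def __post_init__(self) -> None:
        for name in ("base", "min", "max"):
            _check_nonneg(f"handprint {name}", getattr(self, name))
        if not (self.min <= self.base <= self.max):
            raise ValidationError(
                f"handprint bounds must satisfy min <= base <= max, got "
                f"min={self.min}, base={self.base}, max={self.max}"
            )

    def __getitem__(self, variant: str) -> float:
        if variant not in ("base", "min", "max"):
            raise KeyError(variant)
        return getattr(self, variant)


@dataclass(frozen=True)
class Scenario:
    """A named alternative: a footprint, a handprint, or both."""

    name: str
    footprint: Optional[ImpactVector] = None
    handprint: Optional[HandprintEstimate] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("scenario name must be non-empty")
        if self.footprint is None and self.handprint is None:
            raise ValidationError(
                f"scenario {self.name!r} needs a footprint or a handprint"
            )


@dataclass(frozen=True)
class CaseStudy:
    """Two scenarios compared over one functional unit.

    ``treatment`` is the intervention arm, ``comparator`` the reference
    ('no treatment' or treatment-interruption) arm.
    """

    name: str
    treatment: Scenario
    comparator: Scenario
    functional_unit: str = ""

    def __post_init__(self) -> None:
        if self.treatment.name == self.comparator.name:
            raise ValidationError(
                "treatment and comparator scenarios must have distinct names"
            )


@dataclass(frozen=True)
class NormalizationSet:
    """External normalization factors for the footprint.

    One strictly positive reference total per AoP (unit of the AoP, per
    year), e.g. the global Human Health damage attributable to environmental
    factors in the reference year.  Dividing a burden by the factor yields a
    dimensionless per-year share.
    """

    id: str
    source: str = ""
    year: Optional[int] = None
    human_health: float = 1.0
    ecosystems: float = 1.0
    resources: float = 1.0
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("normalization set id must be non-empty")
        for aop in AoP:
            _check_positive(f"normalization factor {aop.value}", self[aop])

    def __getitem__(self, aop: AoP) -> float:
        return getattr(self, aop.value)


@dataclass(frozen=True)
class HandprintNormalizationSet:
    """Normalization factor for the handprint: a global disease-burden total.

    The handprint's cause-effect chain (disease prevalence x health loss)
    differs from the footprint's (emissions x environmental damage), so it is
    normalized separately, against the total global Human Health burden from
    all diseases (DALY per year).
    """

    id: str
    year: Optional[int] = None
    factor: float = 1.0
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("handprint normalization set id must be non-empty")
        _check_positive("handprint normalization factor", self.factor)


@dataclass(frozen=True)
class WeightingSet:
    """Panel weighting factors over the three AoPs, summing to one.

    ``main_set`` groups sub-sets by their source panel study (e.g. the
    Eco-Indicator 99 family, the Itsubo country panels, the EC-JRC
    Environmental Footprint set); the hierarchical Monte Carlo samples the
    main set first, then a sub-set within it.
    """

    id: str
    main_set: str = ""
    human_health: float = 1 / 3
    ecosystems: float = 1 / 3
    resources: float = 1 / 3
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("weighting set id must be non-empty")
        for aop in AoP:
            w = self[aop]
            if w is None or not math.isfinite(w) or not (0.0 <= w <= 1.0):
                raise ValidationError(
                    f"weight {aop.value} must be in [0, 1], got {w!r}"
                )
        total = self.human_health + self.ecosystems + self.resources
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(
                f"weights of set {self.id!r} sum to {total!r}, expected 1"
            )

    def __getitem__(self, aop: AoP) -> float:
        return getattr(self, aop.value)


@dataclass(frozen=True)
class NormalizedVector:
    """Dimensionless per-year footprint shares, with factor-set provenance."""

    human_health: Optional[float] = None
    ecosystems: Optional[float] = None
    resources: Optional[float] = None
    nf_id: str = ""

    def __post_init__(self) -> None:
        for aop in AoP:
            _check_nonneg(f"normalized {aop.value}", self[aop])

    def __getitem__(self, aop: AoP) -> Optional[float]:
        return getattr(self, aop.value)


@dataclass(frozen=True)
class WeightedVector:
    """Dimensionless weighted components, with NF and WF provenance."""

    human_health: Optional[float] = None
    ecosystems: Optional[float] = None
    resources: Optional[float] = None
    nf_id: str = ""
    wf_id: str = ""

    def __post_init__(self) -> None:
        for aop in AoP:
            _check_nonneg(f"weighted {aop.value}", self[aop])

    def __getitem__(self, aop: AoP) -> Optional[float]:
        return getattr(self, aop.value)

    def with_human_health(self, value: Optional[float]) -> "WeightedVector":
        return replace(self, human_health=value)


@dataclass(frozen=True)
class SingleScoreResult:
    """The single score of one scenario: the sum of its weighted components.

    ``handprint_hh``/``footprint_hh`` record the weighted Human Health split
    when a handprint was combined in, so the handprint's share of the Human
    Health component can be reported.
    """

    scenario: str
    score: float
    components: WeightedVector
    handprint_included: bool = False
    handprint_hh: Optional[float] = None
    footprint_hh: Optional[float] = None
    handprint_nf_id: str = ""
    handprint_variant: str = "base"

    def __post_init__(self) -> None:
        _check_nonneg("single score", self.score)
        present = [self.components[aop] for aop in AoP if self.components[aop] is not None]
        if present:
            total = sum(present)
            scale = max(abs(total), 1.0)
            if abs(total - self.score) > 1e-12 * scale:
                raise ValidationError(
                    f"single score {self.score!r} does not equal the sum of its "
                    f"components {total!r}"
                )


class RSBRMode(str, enum.Enum):
    """Whether handprint and footprint are compared combined or separately.

    COMBINED: the treatment trades a worse footprint against a better
    handprint (or only one side is informative), so one aggregate relative
    difference expresses the full benefit.  SEPARATE: both burdens move in the
    same direction under treatment, and the dominant-magnitude side would mask
    the other's relative change, so the two rates are reported side by side.
    """

    COMBINED = "combined"
    SEPARATE = "separate"


@dataclass(frozen=True)
class RSBRResult:
    """Relative Sustainability Benefit Rate between two scenarios, in percent.

    Values follow the defining equation's sign: positive means the treatment
    carries less burden than the comparator.  ``None`` marks a rate that is
    not defined because the comparator score is zero.  Presentation in the
    results-table convention (negative = reduced burden) is a display concern
    handled by :func:`rsbr.pipeline.display_rsbr`.
    """

    mode: RSBRMode
    combined_rsbr: Optional[float] = None
    footprint_rsbr: Optional[float] = None
    handprint_rsbr: Optional[float] = None
    nf_id: str = ""
    handprint_nf_id: str = ""
    wf_id: str = ""
    handprint_variant: str = "base"

    @property
    def is_defined(self) -> bool:
        """True when the mode's headline rate(s) carry a numeric value.

        A zero comparator score makes the corresponding rate NA (None), which
        is a legitimate outcome, not an invariant violation.
        """
        if self.mode is RSBRMode.COMBINED:
            return self.combined_rsbr is not None
        return self.footprint_rsbr is not None and self.handprint_rsbr is not None
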