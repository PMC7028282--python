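"""Uncertainty over value choices: Monte Carlo, enumeration, one-way runs.

Normalization and weighting are value choices, not measurements.  Their
influence on the single score and the RSBR is quantified by resampling
factor *pools*: per iteration a footprint normalization set and a handprint
normalization set are each drawn uniformly from their pools, a weighting set
is drawn hierarchically (main panel first, uniform; then a sub-set within
that panel, uniform), and a handprint variant (base/min/max) is drawn
uniformly over the enabled variants.  With the published pool shape — four
footprint NF sets, four handprint NF sets, 26 weighting sub-sets in three
panels, three variants — there are 4 x 4 x 26 x 3 = 1248 possible
combinations, which can also be enumerated exhaustively for exact extremes.

A one-way sensitivity run attributes output spread to one choice at a time:
fix the normalization sets at a reference and resample only weights, or fix
the weights and resample only normalization sets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import evaluate_case, score_scenario
from .types import (
    CaseStudy,
    HandprintNormalizationSet,
    NormalizationSet,
    RSBRMode,
    ValidationError,
    WeightingSet,
)

__all__ = [
    "FactorPools",
    "MonteCarloConfig",
    "SummaryStats",
    "MonteCarloSummary",
    "SensitivityAxis",
    "SensitivityResult",
    "sample_iteration",
    "run_monte_carlo",
    "enumerate_combinations",
    "one_way_sensitivity",
]

_VARIANTS = ("base", "min", "max")


@dataclass(frozen=True)
class FactorPools:
    """Pools of value-choice sets the Monte Carlo samples over."""

    footprint_nfs: Sequence[NormalizationSet]
    handprint_nfs: Sequence[HandprintNormalizationSet]
    wf_main_sets: dict[str, list[WeightingSet]]
    handprint_variants: Sequence[str] = _VARIANTS

    def __post_init__(self) -> None:
        if not self.footprint_nfs:
            raise ValidationError("footprint NF pool is empty")
        if not self.handprint_nfs:
            raise ValidationError("handprint NF pool is empty")
        if not self.wf_main_sets or any(
            not subsets for subsets in self.wf_main_sets.values()
        ):
            raise ValidationError("every weighting main set needs at least one sub-set")
        if not self.handprint_variants or any(
            v not in _VARIANTS for v in self.handprint_variants
        ):
            raise ValidationError(
                f"handprint variants must be a non-empty subset of {_VARIANTS}"
            )

    @property
    def weighting_sets(self) -> list[WeightingSet]:
        return [wf for subsets in self.wf_main_sets.values() for wf in subsets]

    @property
    def combination_count(self) -> int:
        return (
            len(self.footprint_nfs)
            * len(self.handprint_nfs)
            * len(self.weighting_sets)
            * len(self.handprint_variants)
        )


@dataclass(frozen=True)
class MonteCarloConfig:
    """Iteration count, seed and pools for a Monte Carlo run."""

    pools: FactorPools
    iterations: int = 10_000
    seed: int = 0
    variant: Optional[str] = None  # fix the handprint variant instead of sampling

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.variant is not None and self.variant not in self.pools.handprint_variants:
            raise ValidationError(
                f"variant {self.variant!r} not among enabled variants "
                f"{tuple(self.pools.handprint_variants)}"
            )


@dataclass(frozen=True)
class SummaryStats:
    """Order statistics of one output over the defined iterations."""

    median: float
    min: float
    max: float
    p2_5: float
    p97_5: float
    n: int

    @classmethod
    def from_values(cls, values: Iterable[float]) -> Optional["SummaryStats"]:
        arr = np.asarray([v for v in values if v is not None], dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            return None
        lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5])
        return cls(
            median=float(med),
            min=float(arr.min()),
            max=float(arr.max()),
            p2_5=float(lo),
            p97_5=float(hi),
            n=int(arr.size),
        )


@dataclass(frozen=True)
class MonteCarloSummary:
    """Summary of a Monte Carlo run over value choices.

    ``na_counts`` reports, per output, how many iterations produced an
    undefined (NA) value; those iterations are excluded from the statistics.
    """

    combined_rsbr: Optional[SummaryStats]
    footprint_rsbr: Optional[SummaryStats]
    handprint_rsbr: Optional[SummaryStats]
    single_scores: dict[str, SummaryStats]
    mode: RSBRMode
    iterations: int
    seed: int
    na_counts: dict[str, int] = field(default_factory=dict)
    samples: Optional[pd.DataFrame] = None


class SensitivityAxis(str, enum.Enum):
    """Which value choice is varied in a one-way sensitivity run."""

    FIX_NF_VARY_WF = "fix_nf_vary_wf"
    FIX_WF_VARY_NF = "fix_wf_vary_nf"


@dataclass(frozen=True)
class SensitivityResult:
    """Spread of single scores per scenario under one varying choice."""

    axis: SensitivityAxis
    iterations: int
    seed: int
    single_scores: dict[str, SummaryStats]

    def spread(self, scenario: str) -> float:
        """Min-to-max range of the scenario's single score."""
        s = self.single_scores[scenario]
        return s.max - s.min

    def iqr(self, scenario: str) -> float:
        s = self.single_scores[scenario]
        return s.p97_5 - s.p2_5


def sample_iteration(
    pools: FactorPools, rng: np.random.Generator
) -> tuple[NormalizationSet, HandprintNormalizationSet, WeightingSet, str]:
    """Draw one value-choice combination.

    Footprint and handprint NFs are uniform over their pools.  The weighting
    draw is hierarchical: every main panel is equally likely regardless of
    how many sub-sets it holds, then a sub-set is uniform within the chosen
    panel (so with panels of 4/19/3 sub-sets, each panel has probability 1/3
    and e.g. each of the 19 country sub-sets 1/3 x 1/19).  The handprint
    variant is uniform over the enabled variants.  All draws independent.
    """
    nf = pools.footprint_nfs[rng.integers(len(pools.footprint_nfs))]
    hnf = pools.handprint_nfs[rng.integers(len(pools.handprint_nfs))]
    labels = list(pools.wf_main_sets)
    main = labels[rng.integers(len(labels))]
    subsets = pools.wf_main_sets[main]
    wf = subsets[rng.integers(len(subsets))]
    variant = pools.handprint_variants[rng.integers(len(pools.handprint_variants))]
    return nf, hnf, wf, variant


def _iteration_record(case, nf, hnf, wf, variant):
    res = evaluate_case(case, nf, hnf, wf, variant)
    rec = {
        "nf_id": nf.id,
        "handprint_nf_id": hnf.id,
        "wf_id": wf.id,
        "variant": variant,
        "mode": res.mode.value,
        "combined_rsbr": res.combined_rsbr,
        "footprint_rsbr": res.footprint_rsbr,
        "handprint_rsbr": res.handprint_rsbr,
    }
    for sc in (case.comparator, case.treatment):
        score = score_scenario(sc, nf, hnf, wf, variant)
        rec[f"score_{sc.name}"] = score.score
    return rec


def run_monte_carlo(
    case: CaseStudy, cfg: MonteCarloConfig, keep_samples: bool = False
) -> MonteCarloSummary:
    """Run the full pipeline once per sampled value-choice combination.

    Identical (case, config) including the seed gives identical output.
    Iterations whose RSBR is undefined (zero comparator score) are counted
    in ``na_counts`` and excluded from the percentile statistics.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for _ in range(cfg.iterations):
        nf, hnf, wf, variant = sample_iteration(cfg.pools, rng)
        if cfg.variant is not None:
            variant = cfg.variant
        records.append(_iteration_record(case, nf, hnf, wf, variant))
    return _summarize(case, records, cfg.iterations, cfg.seed, keep_samples)


def _summarize(case, records, iterations, seed, keep_samples) -> MonteCarloSummary:
    df = pd.DataFrame.from_records(records)
    outputs = {}
    na_counts = {}
    for col in ("combined_rsbr", "footprint_rsbr", "handprint_rsbr"):
        values = df[col].tolist()
        na_counts[col] = int(df[col].isna().sum())
        outputs[col] = SummaryStats.from_values(values)
    scores = {}
    for sc in (case.comparator, case.treatment):
        scores[sc.name] = SummaryStats.from_values(df[f"score_{sc.name}"].tolist())
    mode = RSBRMode(df["mode"].mode().iloc[0])
    return MonteCarloSummary(
        combined_rsbr=outputs["combined_rsbr"],
        footprint_rsbr=outputs["footprint_rsbr"],
        handprint_rsbr=outputs["handprint_rsbr"],
        single_scores=scores,
        mode=mode,
        iterations=iterations,
        seed=seed,
        na_counts=na_counts,
        samples=df if keep_samples else None,
    )


def enumerate_combinations(case: CaseStudy, pools: FactorPools) -> pd.DataFrame:
    """Evaluate every value-choice combination exactly.

    Returns one row per element of the Cartesian product (footprint NF x
    handprint NF x weighting sub-set x variant) with full provenance; the
    exact median/min/max of any output follow directly.  Any Monte Carlo
    sample from the same pools takes a value present in this table.
    """
    records = []
    for nf in pools.footprint_nfs:
        for hnf in pools.handprint_nfs:
            for wf in pools.weighting_sets:
                for variant in pools.handprint_variants:
                    records.append(_iteration_record(case, nf, hnf, wf, variant))
    df = pd.DataFrame.from_records(records)
    assert len(df) == pools.combination_count
    return df


def one_way_sensitivity(
    case: CaseStudy,
    axis: SensitivityAxis,
    pools: FactorPools,
    reference: tuple[NormalizationSet, HandprintNormalizationSet, WeightingSet],
    iterations: int = 2_000,
    seed: int = 0,
    variant: str = "base",
) -> SensitivityResult:
    """Vary one value choice while fixing the other at the reference sets.

    FIX_NF_VARY_WF holds both normalization sets at the reference and draws
    the weighting set hierarchically each iteration; FIX_WF_VARY_NF holds the
    weighting set and draws both normalization sets.  The spread of the
    resulting single scores per scenario attributes variability to the
    varying choice.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    ref_nf, ref_hnf, ref_wf = reference
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(iterations):
        nf, hnf, wf, _ = sample_iteration(pools, rng)
        if axis is SensitivityAxis.FIX_NF_VARY_WF:
            nf, hnf = ref_nf, ref_hnf
        else:
            wf = ref_wf
        records.append(_iteration_record(case, nf, hnf, wf, variant))
    df = pd.DataFrame.from_records(records)
    scores = {
        sc.name: SummaryStats.from_values(df[f"score_{sc.name}"].tolist())
        for sc in (case.comparator, case.treatment)
    }
    return SensitivityResult(
        axis=axis, iterations=iterations, seed=seed, single_scores=scores
    )
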