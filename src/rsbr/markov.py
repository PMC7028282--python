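"""Cohort state-transition (Markov) engine for DALY handprint estimates.

A cohort of identical individuals is propagated in expectation through a set
of health states over discrete cycles: the occupancy row vector is multiplied
by a row-stochastic transition matrix each cycle.  Time spent in a state is
converted to years lived with disability (YLD) through that state's
disability weight (a severity coefficient in [0, 1]); entries into death
states contribute years of life lost (YLL) through a remaining life
expectancy.  DALY = YLD + YLL is the handprint burden of an arm, and
comparing a treated model against an untreated one (or against a constant
prevalent burden) yields the treatment's health benefit.

Rewards accrue on the occupancy at the *start* of each cycle by default; an
optional half-cycle correction averages start- and end-of-cycle occupancy
instead, the common refinement in health-economic modelling.

This engine is generic: the disease models it stands in for (an
anthelmintic mass-drug-administration prevalence model, a schizophrenia
relapse model) are published elsewhere with their own transition matrices.
Two structurally analogous SYNTHETIC presets (``sth_toy``, ``relapse_toy``)
ship for demonstration; real parameters can be supplied via the JSON schema
in :mod:`rsbr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .types import HandprintEstimate, ValidationError

__all__ = [
    "MarkovState",
    "MarkovModel",
    "MarkovResult",
    "step",
    "run_cohort",
    "constant_burden",
    "handprint_from_models",
    "sth_toy",
    "relapse_toy",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class MarkovState:
    """One health state: id, disability weight, absorbing/death flags.

    ``life_expectancy`` (years) applies to death states: each person entering
    contributes ``life_expectancy`` years of life lost.  Zero by default, so
    mortality only produces YLL when the user supplies a value.
    """

    id: str
    disability_weight: float = 0.0
    absorbing: bool = False
    death: bool = False
    life_expectancy: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("state id must be non-empty")
        if not 0.0 <= self.disability_weight <= 1.0:
            raise ValidationError(
                f"disability weight of {self.id!r} must be in [0, 1], "
                f"got {self.disability_weight!r}"
            )
        if self.life_expectancy < 0:
            raise ValidationError("remaining life expectancy must be >= 0")
        if self.death and not self.absorbing:
            raise ValidationError(f"death state {self.id!r} must be absorbing")


@dataclass(frozen=True)
class MarkovModel:
    """A cohort model: states, transition matrix, cycles, initial cohort."""

    states: Sequence[MarkovState]
    transition_matrix: np.ndarray
    cycle_length_years: float = 1.0
    horizon_cycles: int = 1
    initial: Optional[np.ndarray] = None  # distribution over states; default all in state 0
    cohort_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("model needs at least one state")
        n = len(self.states)
        m = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", m)
        _validate_matrix(m, n)
        for i, st in enumerate(self.states):
            if st.absorbing and not np.isclose(m[i, i], 1.0, atol=_ROW_TOL):
                raise ValidationError(
                    f"absorbing state {st.id!r} must have self-transition 1"
                )
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle length must be > 0 years")
        if self.horizon_cycles < 1:
            raise ValidationError("horizon must be >= 1 cycle")
        if self.cohort_size <= 0:
            raise ValidationError("cohort size must be > 0")
        init = self.initial
        if init is None:
            init = np.zeros(n)
            init[0] = 1.0
        init = np.asarray(init, dtype=float)
        if init.shape != (n,) or (init < 0).any():
            raise ValidationError("initial distribution must be non-negative, length n")
        if abs(init.sum() - 1.0) > _ROW_TOL:
            raise ValidationError("initial distribution must sum to 1")
        object.__setattr__(self, "initial", init)

    @property
    def disability_weights(self) -> np.ndarray:
        return np.array([s.disability_weight for s in self.states])

    @property
    def state_ids(self) -> list[str]:
        return [s.id for s in self.states]


def _validate_matrix(m: np.ndarray, n: int) -> None:
    if m.shape != (n, n):
        raise ValidationError(f"transition matrix must be {n}x{n}, got {m.shape}")
    if (m < -_ROW_TOL).any() or (m > 1 + _ROW_TOL).any():
        raise ValidationError("transition probabilities must lie in [0, 1]")
    rows = m.sum(axis=1)
    bad = np.where(np.abs(rows - 1.0) > _ROW_TOL)[0]
    if bad.size:
        raise ValidationError(
            f"transition matrix rows {bad.tolist()} sum to {rows[bad].tolist()}, "
            "expected 1"
        )


@dataclass(frozen=True)
class MarkovResult:
    """Occupancy trajectory (persons) and the accrued burden."""

    occupancy: np.ndarray  # (horizon+1, n_states), cycle 0 = initial cohort
    state_ids: list[str]
    yld: float
    yll: float

    @property
    def daly(self) -> float:
        return self.yld + self.yll


def step(distribution: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """One cycle: left-multiply the occupancy vector by the matrix.

    Mass is conserved exactly up to floating point.
    """
    d = np.asarray(distribution, dtype=float)
    if (d < 0).any():
        raise ValidationError("occupancy must be non-negative")
    _validate_matrix(np.asarray(matrix, dtype=float), d.shape[0])
    return d @ matrix


def run_cohort(model: MarkovModel, half_cycle_correction: bool = False) -> MarkovResult:
    """Propagate the cohort over the horizon and accrue YLD and YLL.

    YLD sums, over cycles and states, occupancy x disability weight x cycle
    length; occupancy is taken at the start of each cycle (or the start/end
    average under half-cycle correction).  YLL credits each new entry into a
    death state with that state's remaining life expectancy.
    """
    n = len(model.states)
    occ = np.empty((model.horizon_cycles + 1, n))
    occ[0] = model.initial * model.cohort_size
    for k in range(model.horizon_cycles):
        occ[k + 1] = occ[k] @ model.transition_matrix

    if half_cycle_correction:
        in_state = 0.5 * (occ[:-1] + occ[1:])
    else:
        in_state = occ[:-1]
    yld = float(
        (in_state @ model.disability_weights).sum() * model.cycle_length_years
    )

    yll = 0.0
    for i, st in enumerate(model.states):
        if st.death and st.life_expectancy > 0:
            new_entries = np.diff(occ[:, i]).clip(min=0.0).sum()
            yll += float(new_entries * st.life_expectancy)
    return MarkovResult(occupancy=occ, state_ids=model.state_ids, yld=yld, yll=yll)


def constant_burden(prevalent_cases: float, disability_weight: float, horizon_years: float) -> float:
    """DALY burden of a prevalence held constant over a horizon.

    The no-intervention counterfactual of a control programme: cases x
    disability weight x years.  Equivalent to a one-state identity-matrix
    cohort model with the same weight and horizon.
    """
    if prevalent_cases < 0 or horizon_years < 0:
        raise ValidationError("cases and horizon must be >= 0")
    if not 0.0 <= disability_weight <= 1.0:
        raise ValidationError("disability weight must be in [0, 1]")
    return prevalent_cases * disability_weight * horizon_years


def _perturb_weights(model: MarkovModel, factor: float) -> MarkovModel:
    states = [
        replace(s, disability_weight=min(1.0, s.disability_weight * factor))
        for s in model.states
    ]
    return replace(model, states=states)


def handprint_from_models(
    treated: MarkovModel,
    untreated: MarkovModel,
    dw_perturbation: float = 0.2,
    half_cycle_correction: bool = False,
) -> tuple[HandprintEstimate, HandprintEstimate]:
    """Run both arms and package their DALY burdens as handprint estimates.

    Returns ``(treated, untreated)`` estimates.  Min/max bounds come from
    scaling every disability weight by ``1 -/+ dw_perturbation`` (weights are
    capped at 1), a simple stand-in for a model-specific sensitivity
    analysis.  Arms must share cohort size and total horizon.
    """
    if not np.isclose(treated.cohort_size, untreated.cohort_size):
        raise ValidationError("arms must model the same cohort size")
    if not np.isclose(
        treated.cycle_length_years * treated.horizon_cycles,
        untreated.cycle_length_years * untreated.horizon_cycles,
    ):
        raise ValidationError("arms must cover the same time horizon")
    if not 0.0 <= dw_perturbation < 1.0:
        raise ValidationError("dw perturbation must be in [0, 1)")

    def estimate(model: MarkovModel) -> HandprintEstimate:
        base = run_cohort(model, half_cycle_correction).daly
        lo = run_cohort(_perturb_weights(model, 1 - dw_perturbation), half_cycle_correction).daly
        hi = run_cohort(_perturb_weights(model, 1 + dw_perturbation), half_cycle_correction).daly
        lo, hi = min(lo, base), max(hi, base)
        return HandprintEstimate(base=base, min=lo, max=hi)

    return estimate(treated), estimate(untreated)


def sth_toy(
    cohort: float = 1000.0, horizon_cycles: int = 10, recovery_p: float = 0.3
) -> tuple[MarkovModel, MarkovModel]:
    """SYNTHETIC preset shaped like a deworming programme model.

    Two arms over half-year cycles: infected children either clear the
    infection (treated arm, probability ``recovery_p`` per cycle) or stay
    infected at constant prevalence (untreated arm, identity transitions).
    Returns ``(treated, untreated)``.  Parameters are illustrative, not the
    published programme model.
    """
    states = [
        MarkovState("infected", disability_weight=0.05),
        MarkovState("cleared", disability_weight=0.0, absorbing=True),
    ]
    treated = MarkovModel(
        states=states,
        transition_matrix=np.array([[1 - recovery_p, recovery_p], [0.0, 1.0]]),
        cycle_length_years=0.5,
        horizon_cycles=horizon_cycles,
        cohort_size=cohort,
    )
    untreated = MarkovModel(
        states=states,
        transition_matrix=np.eye(2),
        cycle_length_years=0.5,
        horizon_cycles=horizon_cycles,
        cohort_size=cohort,
    )
    return treated, untreated


def relapse_toy(
    cohort: float = 1000.0, horizon_cycles: int = 12, relapse_p: float = 0.08
) -> tuple[MarkovModel, MarkovModel]:
    """SYNTHETIC preset shaped like a psychiatric relapse model.

    Monthly cycles between a stable state and an acute relapse state with a
    higher disability weight; maintenance treatment lowers the relapse
    probability.  Returns ``(treated, untreated)`` where "untreated" models
    interruption of maintenance therapy (higher relapse probability).
    Parameters are illustrative, not the published disease model.
    """
    states = [
        MarkovState("stable", disability_weight=0.25),
        MarkovState("relapse", disability_weight=0.60),
    ]

    def arm(p_relapse: float) -> MarkovModel:
        recover = 0.5  # per-cycle probability of returning to stable
        return MarkovModel(
            states=states,
            transition_matrix=np.array(
                [[1 - p_relapse, p_relapse], [recover, 1 - recover]]
            ),
            cycle_length_years=1 / 12,
            horizon_cycles=horizon_cycles,
            cohort_size=cohort,
        )

    return arm(relapse_p), arm(relapse_p * 3)
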