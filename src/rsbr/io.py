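"""File formats: scenario tables, factor pools, Markov model specs.

Scenarios travel as a long-format CSV (``scenario,aop,value,unit``) with an
optional companion handprint CSV (``scenario,handprint_base,handprint_min,
handprint_max``), or as a single JSON file mirroring the same field names.
Missing burdens are written as the literal ``NA`` and survive round-trips as
missing (never as zero).  Unit strings must match the canonical Area-of-
Protection units exactly (DALY, species.yr, USD).

Factor pools are JSON: arrays of normalization / weighting set records
grouped as ``footprint_nfs``, ``handprint_nfs``, ``wf_main_sets`` (a mapping
from main-set label to an array of sub-sets) and ``handprint_variants``.
Synthetic built-in pools and user-supplied real pools share this schema.

Markov models are JSON objects with ``states``, ``transition_matrix``,
``cycle_length_years``, ``horizon_cycles``, ``initial`` and ``cohort_size``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Union

from .markov import MarkovModel, MarkovState
from .sampling import FactorPools
from .types import (
    AoP,
    CANONICAL_UNITS,
    CaseStudy,
    HandprintEstimate,
    HandprintNormalizationSet,
    ImpactVector,
    NormalizationSet,
    Scenario,
    ValidationError,
    WeightingSet,
)

__all__ = [
    "format_sci",
    "read_scenarios",
    "write_scenarios",
    "read_case_json",
    "write_case_json",
    "read_factor_pools",
    "write_factor_pools",
    "read_markov_model",
    "write_markov_model",
]

_NA = "NA"
_UNIT_BY_NAME = {unit: aop for aop, unit in CANONICAL_UNITS.items()}


def format_sci(value: Optional[float], digits: int = 3) -> str:
    """Scientific-notation string with ``digits`` significant figures, or NA."""
    if digits < 2:
        raise ValidationError("significant digits must be >= 2")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return _NA
    return f"{value:.{digits - 1}E}"


def _parse_value(raw: str, where: str) -> Optional[float]:
    raw = raw.strip()
    if raw.upper() == _NA or raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        raise ValidationError(f"{where}: cannot parse value {raw!r}") from None
    if value < 0:
        raise ValidationError(f"{where}: negative burden {value!r}")
    return value


def read_scenarios(
    path: Union[str, Path], handprint_path: Union[str, Path, None] = None
) -> list[Scenario]:
    """Read scenarios from the long-format CSV (plus optional handprint CSV)."""
    path = Path(path)
    burdens: dict[str, dict[AoP, Optional[float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"scenario", "aop", "value", "unit"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            where = f"{path}:{i}"
            try:
                aop = AoP(row["aop"].strip())
            except ValueError:
                raise ValidationError(
                    f"{where}: unknown area of protection {row['aop']!r}"
                ) from None
            unit = row["unit"].strip()
            if unit != aop.unit:
                raise ValidationError(
                    f"{where}: unit {unit!r} does not match canonical "
                    f"{aop.unit!r} for {aop.value}"
                )
            name = row["scenario"].strip()
            entry = burdens.setdefault(name, {})
            if aop in entry:
                raise ValidationError(f"{where}: duplicate row for {name}/{aop.value}")
            entry[aop] = _parse_value(row["value"], where)

    handprints: dict[str, HandprintEstimate] = {}
    if handprint_path is not None:
        handprints = _read_handprints(Path(handprint_path))

    scenarios = []
    for name, entry in burdens.items():
        fp = ImpactVector(**{aop.value: entry.get(aop) for aop in AoP})
        scenarios.append(
            Scenario(name=name, footprint=fp, handprint=handprints.get(name))
        )
    for name, hp in handprints.items():
        if name not in burdens:
            scenarios.append(Scenario(name=name, handprint=hp))
    return scenarios


def _read_handprints(path: Path) -> dict[str, HandprintEstimate]:
    out: dict[str, HandprintEstimate] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"scenario", "handprint_base", "handprint_min", "handprint_max"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            where = f"{path}:{i}"
            name = row["scenario"].strip()
            if name in out:
                raise ValidationError(f"{where}: duplicate handprint row for {name}")
            values = {
                key: _parse_value(row[f"handprint_{key}"], where)
                for key in ("base", "min", "max")
            }
            if any(v is None for v in values.values()):
                raise ValidationError(f"{where}: handprint values cannot be NA")
            out[name] = HandprintEstimate(**values)
    return out


def write_scenarios(
    scenarios: list[Scenario],
    path: Union[str, Path],
    handprint_path: Union[str, Path, None] = None,
    digits: int = 6,
) -> None:
    """Write scenarios to the long-format CSV (and handprint companion)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scenario", "aop", "value", "unit"])
        for sc in scenarios:
            fp = sc.footprint if sc.footprint is not None else ImpactVector()
            for aop in AoP:
                writer.writerow(
                    [sc.name, aop.value, format_sci(fp[aop], digits), aop.unit]
                )
    if handprint_path is not None:
        with Path(handprint_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["scenario", "handprint_base", "handprint_min", "handprint_max"]
            )
            for sc in scenarios:
                if sc.handprint is None:
                    continue
                writer.writerow(
                    [sc.name]
                    + [format_sci(sc.handprint[k], digits) for k in ("base", "min", "max")]
                )


def _scenario_to_dict(sc: Scenario) -> dict:
    d: dict = {"scenario": sc.name}
    fp = sc.footprint if sc.footprint is not None else ImpactVector()
    d["footprint"] = {aop.value: fp[aop] for aop in AoP}
    if sc.handprint is not None:
        d["handprint_base"] = sc.handprint.base
        d["handprint_min"] = sc.handprint.min
        d["handprint_max"] = sc.handprint.max
    return d


def _scenario_from_dict(d: dict) -> Scenario:
    fp_raw = d.get("footprint", {})
    for key, value in fp_raw.items():
        if value is not None and value < 0:
            raise ValidationError(f"scenario {d.get('scenario')!r}: negative {key}")
    fp = ImpactVector(**{aop.value: fp_raw.get(aop.value) for aop in AoP})
    hp = None
    if "handprint_base" in d:
        hp = HandprintEstimate(
            base=d["handprint_base"], min=d["handprint_min"], max=d["handprint_max"]
        )
    return Scenario(name=d["scenario"], footprint=fp, handprint=hp)


def write_case_json(case: CaseStudy, path: Union[str, Path]) -> None:
    payload = {
        "name": case.name,
        "functional_unit": case.functional_unit,
        "comparator": _scenario_to_dict(case.comparator),
        "treatment": _scenario_to_dict(case.treatment),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_case_json(path: Union[str, Path]) -> CaseStudy:
    payload = json.loads(Path(path).read_text())
    return CaseStudy(
        name=payload["name"],
        functional_unit=payload.get("functional_unit", ""),
        comparator=_scenario_from_dict(payload["comparator"]),
        treatment=_scenario_from_dict(payload["treatment"]),
    )


def _nf_to_dict(nf: NormalizationSet) -> dict:
    return {
        "id": nf.id,
        "source": nf.source,
        "year": nf.year,
        "human_health": nf.human_health,
        "ecosystems": nf.ecosystems,
        "resources": nf.resources,
        "synthetic": nf.synthetic,
    }


def _wf_to_dict(wf: WeightingSet) -> dict:
    return {
        "id": wf.id,
        "main_set": wf.main_set,
        "human_health": wf.human_health,
        "ecosystems": wf.ecosystems,
        "resources": wf.resources,
        "synthetic": wf.synthetic,
    }


def write_factor_pools(pools: FactorPools, path: Union[str, Path]) -> None:
    payload = {
        "footprint_nfs": [_nf_to_dict(nf) for nf in pools.footprint_nfs],
        "handprint_nfs": [
            {"id": h.id, "year": h.year, "factor": h.factor, "synthetic": h.synthetic}
            for h in pools.handprint_nfs
        ],
        "wf_main_sets": {
            label: [_wf_to_dict(wf) for wf in subsets]
            for label, subsets in pools.wf_main_sets.items()
        },
        "handprint_variants": list(pools.handprint_variants),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_factor_pools(path: Union[str, Path]) -> FactorPools:
    payload = json.loads(Path(path).read_text())
    return FactorPools(
        footprint_nfs=[NormalizationSet(**d) for d in payload["footprint_nfs"]],
        handprint_nfs=[
            HandprintNormalizationSet(**d) for d in payload["handprint_nfs"]
        ],
        wf_main_sets={
            label: [WeightingSet(**d) for d in subsets]
            for label, subsets in payload["wf_main_sets"].items()
        },
        handprint_variants=tuple(payload.get("handprint_variants", ("base", "min", "max"))),
    )


def write_markov_model(model: MarkovModel, path: Union[str, Path]) -> None:
    payload = {
        "states": [
            {
                "id": s.id,
                "disability_weight": s.disability_weight,
                "absorbing": s.absorbing,
                "death": s.death,
                "life_expectancy": s.life_expectancy,
            }
            for s in model.states
        ],
        "transition_matrix": model.transition_matrix.tolist(),
        "cycle_length_years": model.cycle_length_years,
        "horizon_cycles": model.horizon_cycles,
        "initial": model.initial.tolist(),
        "cohort_size": model.cohort_size,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_markov_model(path: Union[str, Path]) -> MarkovModel:
    payload = json.loads(Path(path).read_text())
    return MarkovModel(
        states=[MarkovState(**d) for d in payload["states"]],
        transition_matrix=payload["transition_matrix"],
        cycle_length_years=payload.get("cycle_length_years", 1.0),
        horizon_cycles=payload.get("horizon_cycles", 1),
        initial=payload.get("initial"),
        cohort_size=payload.get("cohort_size", 1.0),
    )
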