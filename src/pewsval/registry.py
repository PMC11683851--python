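"""Declarative definitions and evaluation of paediatric early warning scores.

A score is a list of items; each item awards a fixed number of points when a
predicate over admission findings is true.  Predicates are written in a small
declarative language (stored in YAML) rather than code, so item tables can be
corrected without touching the engine:

* leaf conditions: ``{field, op, value}`` with ``op`` one of
  ``lt, le, gt, ge, eq, in``;
* age-banded thresholds: ``value_by_age: [{age_lt: 12, value: 160},
  {value: 150}]`` picks the threshold from the child's ``age_months``;
* combinators ``all_of`` / ``any_of`` over sub-conditions;
* ``{const: false}`` for items that are retained for documentation but can
  never fire (e.g. a post-operative item in a cohort that excludes surgical
  admissions).

Items that are mutually exclusive alternatives (e.g. the capillary-refill
levels of a behaviour/circulation subscale) share a ``group`` key; a score's
achievable maximum is the sum over groups of the largest item points, and a
definition whose achievable maximum exceeds its declared range is rejected.

Missing inputs are handled per item by ``missing_behavior``:
``score_zero`` (default — an unrecorded sign contributes no points, the
count of affected items is reported) or ``propagate_missing`` (the total
becomes missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from pewsval.records import PATIENT_FIELDS

_OPS = {"lt", "le", "gt", "ge", "eq", "in"}

SCORE_NAMES = (
    "LODS", "FASTER", "TOPRS", "ITAT", "WHO_emergency_signs", "Mpimbaza",
    "Brighton_PEWS", "PEDIA_early", "PEDIA_late", "RISC", "RISC_Malawi",
)


class DefinitionError(ValueError):
    """A score definition violates the schema or its declared invariants."""


# ---------------------------------------------------------------------------
# predicate engine


def _referenced_fields(cond: Mapping) -> set[str]:
    if "const" in cond:
        return set()
    if "all_of" in cond or "any_of" in cond:
        key = "all_of" if "all_of" in cond else "any_of"
        out: set[str] = set()
        for sub in cond[key]:
            out |= _referenced_fields(sub)
        return out
    fields = {cond["field"]}
    if "value_by_age" in cond:
        fields.add("age_months")
    return fields


def _age_banded_value(cond: Mapping, age: pd.Series) -> pd.Series:
    """Resolve a per-child threshold from the item's age bands."""
    bands = cond["value_by_age"]
    out = pd.Series(np.nan, index=age.index, dtype=float)
    assigned = pd.Series(False, index=age.index)
    for band in bands:
        if "age_lt" in band:
            mask = (~assigned) & (age < band["age_lt"])
        elif "age_ge" in band:
            mask = (~assigned) & (age >= band["age_ge"])
        else:  # default band
            mask = ~assigned
        out[mask] = band["value"]
        assigned |= mask
    return out


def _eval_condition(cond: Mapping, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a condition vectorised; returns (truth, missing) bool arrays.

    A record is 'missing' for the condition when any referenced field is
    absent; its truth value is then reported False and handled upstream by
    the item's missing policy.
    """
    if "const" in cond:
        n = len(df)
        return np.full(n, bool(cond["const"])), np.zeros(n, dtype=bool)
    if "all_of" in cond or "any_of" in cond:
        key = "all_of" if "all_of" in cond else "any_of"
        truths, missings = zip(*(_eval_condition(sub, df) for sub in cond[key]))
        truth = np.logical_and.reduce(truths) if key == "all_of" \
            else np.logical_or.reduce(truths)
        missing = np.logical_or.reduce(missings)
        # a determined OR (some branch true) is not missing
        if key == "any_of":
            missing = missing & ~truth
        return truth, missing

    col = df[cond["field"]]
    missing = col.isna().to_numpy()
    op = cond["op"]
    if op == "in":
        truth = col.isin(cond["value"]).to_numpy()
    else:
        value = (_age_banded_value(cond, df["age_months"])
                 if "value_by_age" in cond else cond["value"])
        if PATIENT_FIELDS.get(cond["field"]) == "bool":
            lhs = col.astype("boolean")
        else:
            lhs = col
        if op == "lt":
            truth = (lhs < value)
        elif op == "le":
            truth = (lhs <= value)
        elif op == "gt":
            truth = (lhs > value)
        elif op == "ge":
            truth = (lhs >= value)
        elif op == "eq":
            truth = (lhs == value)
        else:  # pragma: no cover - schema-validated
            raise DefinitionError(f"unknown operator {op!r}")
        truth = pd.Series(truth).fillna(False).to_numpy(dtype=bool)
    return truth & ~missing, missing


def _validate_condition(cond: Mapping, where: str) -> None:
    if not isinstance(cond, Mapping):
        raise DefinitionError(f"{where}: condition must be a mapping")
    if "const" in cond:
        return
    if "all_of" in cond or "any_of" in cond:
        key = "all_of" if "all_of" in cond else "any_of"
        subs = cond[key]
        if not subs:
            raise DefinitionError(f"{where}: empty {key}")
        for i, sub in enumerate(subs):
            _validate_condition(sub, f"{where}.{key}[{i}]")
        return
    if "field" not in cond or "op" not in cond:
        raise DefinitionError(f"{where}: leaf condition needs 'field' and 'op'")
    if cond["field"] not in PATIENT_FIELDS:
        raise DefinitionError(f"{where}: unknown field {cond['field']!r}")
    if cond["op"] not in _OPS:
        raise DefinitionError(f"{where}: unknown op {cond['op']!r}")
    if "value" not in cond and "value_by_age" not in cond:
        raise DefinitionError(f"{where}: needs 'value' or 'value_by_age'")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ScoreItem:
    item_id: str
    predicate: Mapping
    points: int
    group: Optional[str] = None
    missing_behavior: str = "score_zero"

    def __post_init__(self):
        if self.points < 0:
            raise DefinitionError(f"item {self.item_id}: negative points")
        if self.missing_behavior not in ("score_zero", "propagate_missing"):
            raise DefinitionError(
                f"item {self.item_id}: unknown missing_behavior "
                f"{self.missing_behavior!r}")
        _validate_condition(self.predicate, f"item {self.item_id}")


@dataclass(frozen=True)
class ScoreDefinition:
    name: str
    items: tuple[ScoreItem, ...]
    range_min: int
    range_max: int
    label: str = ""
    predefined_cutoff: Optional[int] = None
    applicability: Optional[Mapping] = None
    target_population: Optional[str] = None

    def __post_init__(self):
        if self.range_min != 0:
            raise DefinitionError(f"{self.name}: range_min must be 0")
        if not self.items:
            raise DefinitionError(f"{self.name}: no items")
        if self.applicability is not None:
            _validate_condition(self.applicability, f"{self.name}.applicability")
        amax = self.achievable_max()
        if amax > self.range_max:
            raise DefinitionError(
                f"{self.name}: achievable maximum {amax} exceeds declared "
                f"range_max {self.range_max}")

    def achievable_max(self) -> int:
        """Maximum total respecting mutually exclusive item groups."""
        best: dict[str, int] = {}
        for it in self.items:
            key = it.group or it.item_id
            best[key] = max(best.get(key, 0), it.points)
        return sum(best.values())

    def candidate_cutoffs(self) -> range:
        """All operating points: range_min .. range_max + 1 inclusive."""
        return range(self.range_min, self.range_max + 2)


@dataclass(frozen=True)
class ScoreResult:
    score_name: str
    total_points: Optional[int]
    n_items_missing: int
    applicable: bool


# ---------------------------------------------------------------------------
# loading


def _parse_definition(entry: Mapping) -> ScoreDefinition:
    try:
        name = entry["name"]
        rng = entry["range"]
        raw_items = entry["items"]
    except (KeyError, TypeError) as exc:
        raise DefinitionError(f"malformed score entry: {exc}") from exc
    items = []
    for raw in raw_items:
        try:
            items.append(ScoreItem(
                item_id=raw["id"],
                predicate=raw["when"],
                points=int(raw["points"]),
                group=raw.get("group"),
                missing_behavior=raw.get("missing_behavior", "score_zero"),
            ))
        except KeyError as exc:
            raise DefinitionError(f"{name}: item missing key {exc}") from exc
    return ScoreDefinition(
        name=name,
        label=entry.get("label", name),
        items=tuple(items),
        range_min=int(rng[0]),
        range_max=int(rng[1]),
        predefined_cutoff=entry.get("cutoff"),
        applicability=entry.get("applicability"),
        target_population=entry.get("target_population"),
    )


def load_score_registry(definitions_path) -> Mapping[str, ScoreDefinition]:
    """Load and validate a YAML score-definitions file.

    Returns an immutable mapping name -> :class:`ScoreDefinition`.
    """
    with open(definitions_path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "scores" not in doc or not doc["scores"]:
        raise DefinitionError("definitions file declares no scores")
    registry: dict[str, ScoreDefinition] = {}
    for entry in doc["scores"]:
        definition = _parse_definition(entry)
        if definition.name in registry:
            raise DefinitionError(f"duplicate score name {definition.name!r}")
        registry[definition.name] = definition
    return MappingProxyType(registry)


def default_registry() -> Mapping[str, ScoreDefinition]:
    """The bundled registry of the 11 validated score variants."""
    path = resources.files("pewsval").joinpath("data/score_definitions.yaml")
    with resources.as_file(path) as p:
        return load_score_registry(p)


# ---------------------------------------------------------------------------
# evaluation


def score_frame(definition: ScoreDefinition, df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised evaluation of one score over a cohort table.

    Returns a frame indexed like ``df`` with columns ``total_points``
    (float; NaN when propagated missing), ``n_items_missing`` and
    ``applicable``.
    """
    n = len(df)
    total = np.zeros(n, dtype=float)
    n_missing = np.zeros(n, dtype=int)
    propagate = np.zeros(n, dtype=bool)
    for item in definition.items:
        truth, missing = _eval_condition(item.predicate, df)
        total += item.points * truth
        n_missing += missing
        if item.missing_behavior == "propagate_missing":
            propagate |= missing
    total[propagate] = np.nan
    if definition.applicability is None:
        applicable = np.ones(n, dtype=bool)
    else:
        truth, missing = _eval_condition(definition.applicability, df)
        applicable = truth & ~missing
    return pd.DataFrame(
        {"total_points": total, "n_items_missing": n_missing,
         "applicable": applicable},
        index=df.index,
    )


def evaluate_score(definition: ScoreDefinition, patient: Mapping) -> ScoreResult:
    """Evaluate one score for a single child (mapping of field -> value)."""
    row = {f: patient.get(f, np.nan) for f in PATIENT_FIELDS}
    df = pd.DataFrame([row])
    res = score_frame(definition, df).iloc[0]
    total = None if np.isnan(res["total_points"]) else int(res["total_points"])
    return ScoreResult(
        score_name=definition.name,
        total_points=total,
        n_items_missing=int(res["n_items_missing"]),
        applicable=bool(res["applicable"]),
    )


def score_cohort(registry: Mapping[str, ScoreDefinition],
                 cohort: pd.DataFrame) -> pd.DataFrame:
    """Score every child with every registered score.

    Returns a long table with one row per (child, score):
    ``child_id, score_name, total_points, n_items_missing, applicable``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    frames = []
    for name, definition in registry.items():
        res = score_frame(definition, cohort)
        res.insert(0, "score_name", name)
        res.insert(0, "child_id", cohort["child_id"].to_numpy())
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
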