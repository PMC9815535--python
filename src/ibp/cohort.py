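"""Cohort table schema, domain types, and CSV readers/writers.

The atomic input is one animal at one time point with a map of named
behavioral parameter values (distances, times, freezing, indices).  A cohort
is the collection of such records for a control group and a trauma-exposed
group, at a post-trauma and (optionally) a post-treatment time point.

Canonical on-disk form is a wide CSV: one row per animal x time point, with
columns ``animal_id, group, timepoint, <param1>, ..., <paramM>``.  A long
form with ``parameter, value`` columns is accepted and pivoted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import IntegrityError, ParseError, SchemaError

MANDATORY_COLUMNS = ("animal_id", "group", "timepoint")

#: Group labels used by the built-in pipelines; custom labels are permitted.
CONTROL = "control"
EXPOSED = "exposed"

#: Time-point labels used by the built-in profiles.
POST_TRAUMA = "post_trauma"
POST_TREATMENT = "post_treatment"


class Direction(str, enum.Enum):
    """Pathological direction of a behavioral parameter.

    ``low_is_affected``  — values *below* the cutoff flag the animal
    (e.g. distance traveled, open-arm time: hypo-exploration is pathological).
    ``high_is_affected`` — values *above* the cutoff flag the animal
    (e.g. freezing time, anxiety index).
    ``two_sided``        — either tail flags the animal.
    """

    LOW_IS_AFFECTED = "low_is_affected"
    HIGH_IS_AFFECTED = "high_is_affected"
    TWO_SIDED = "two_sided"


def normalize_name(name: str) -> str:
    """Canonicalize a parameter name: case-fold and map runs of whitespace
    (and hyphens) to single underscores.  Prose labels from behavioral
    exports thereby match the identifiers used by the built-in profiles."""
    out = "_".join(str(name).strip().casefold().replace("-", " ").split())
    return out


@dataclass(frozen=True)
class ParameterSpec:
    """One behavioral parameter of a profile.

    Parameters
    ----------
    name : str
        Canonical identifier (see :func:`normalize_name`).
    source_test : str
        Behavioral test the parameter comes from (WAZM, EPM, OFT, SRT).
    direction : Direction
        Which tail of the control distribution is pathological.
    units : str
        Free-text units (cm, s, %, index).
    """

    name: str
    source_test: str
    direction: Direction
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_name(self.name))
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class ProfileDefinition:
    """An ordered parameter set plus the k-of-m classification threshold.

    ``parameters_by_timepoint`` maps a time-point label to the ordered list of
    :class:`ParameterSpec` active at that time point.  The affected criterion
    is "flagged on at least ``k`` of the ``m`` parameters".
    """

    profile_id: str
    parameters_by_timepoint: Mapping[str, tuple[ParameterSpec, ...]]
    k: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "parameters_by_timepoint",
            {tp: tuple(specs) for tp, specs in self.parameters_by_timepoint.items()},
        )
        for tp, specs in self.parameters_by_timepoint.items():
            names = [s.name for s in specs]
            if len(set(names)) != len(names):
                raise IntegrityError(
                    f"profile {self.profile_id!r}: duplicate parameter names at {tp!r}"
                )
            if not 1 <= self.k <= len(specs):
                raise IntegrityError(
                    f"profile {self.profile_id!r}: k={self.k} outside 1..m={len(specs)} at {tp!r}"
                )

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(self.parameters_by_timepoint)

    def m(self, timepoint: str) -> int:
        return len(self.parameters(timepoint))

    def parameters(self, timepoint: str) -> tuple[ParameterSpec, ...]:
        try:
            return self.parameters_by_timepoint[timepoint]
        except KeyError:
            raise KeyError(
                f"profile {self.profile_id!r} has no parameter list for "
                f"timepoint {timepoint!r}; known: {list(self.parameters_by_timepoint)}"
            ) from None

    def parameter_names(self, timepoint: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.parameters(timepoint))

    def spec(self, name: str, timepoint: str) -> ParameterSpec:
        for s in self.parameters(timepoint):
            if s.name == name:
                return s
        raise KeyError(f"parameter {name!r} not in profile at {timepoint!r}")


@dataclass
class BehavioralRecord:
    """One animal x time point with its parameter-value map."""

    animal_id: str
    group: str
    timepoint: str
    values: dict[str, float] = field(default_factory=dict)

    def is_complete(self, parameter_names: Iterable[str]) -> bool:
        return all(
            p in self.values and pd.notna(self.values[p]) for p in parameter_names
        )

    def missing(self, parameter_names: Iterable[str]) -> list[str]:
        return [
            p
            for p in parameter_names
            if p not in self.values or pd.isna(self.values[p])
        ]


class CohortTable:
    """Validated collection of :class:`BehavioralRecord` with provenance.

    Row order is preserved from the source.  Records missing one or more of
    the active profile parameters are *retained* and flagged incomplete
    rather than dropped: downstream classification labels them
    ``unclassifiable``.
    """

    def __init__(self, records: Sequence[BehavioralRecord], provenance: str = ""):
        self.records: list[BehavioralRecord] = list(records)
        self.provenance = provenance
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.animal_id, r.timepoint)
            if key in seen:
                raise IntegrityError(f"duplicate (animal_id, timepoint): {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # ---- selection -----------------------------------------------------
    def subset(self, *, group: str | None = None, timepoint: str | None = None) -> "CohortTable":
        recs = [
            r
            for r in self.records
            if (group is None or r.group == group)
            and (timepoint is None or r.timepoint == timepoint)
        ]
        new = object.__new__(CohortTable)
        new.records = recs
        new.provenance = self.provenance
        return new

    def groups(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.group not in out:
                out.append(r.group)
        return out

    def animal_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.animal_id not in out:
                out.append(r.animal_id)
        return out

    def record(self, animal_id: str, timepoint: str) -> BehavioralRecord:
        for r in self.records:
            if r.animal_id == animal_id and r.timepoint == timepoint:
                return r
        raise KeyError((animal_id, timepoint))

    def complete_records(self, parameter_names: Iterable[str]) -> list[BehavioralRecord]:
        names = list(parameter_names)
        return [r for r in self.records if r.is_complete(names)]

    # ---- conversion ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Wide DataFrame, one row per record, parameter columns in first-seen order."""
        param_order: list[str] = []
        for r in self.records:
            for p in r.values:
                if p not in param_order:
                    param_order.append(p)
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "animal_id": r.animal_id,
                "group": r.group,
                "timepoint": r.timepoint,
            }
            for p in param_order:
                row[p] = r.values.get(p, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + param_order)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CohortTable":
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        param_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
        records = []
        for idx, row in df.iterrows():
            values: dict[str, float] = {}
            for c in param_cols:
                cell = row[c]
                if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                    continue
                try:
                    values[normalize_name(c)] = float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric value {cell!r} in row {idx}, column {c!r}"
                    ) from None
            records.append(
                BehavioralRecord(
                    animal_id=str(row["animal_id"]),
                    group=str(row["group"]),
                    timepoint=str(row["timepoint"]),
                    values=values,
                )
            )
        return cls(records, provenance=provenance)


def read_cohort(path: str | Path, profile: ProfileDefinition | None = None) -> CohortTable:
    """Read a cohort CSV (wide canonical; long accepted) into a CohortTable.

    The ``profile`` argument is used only to *derive* missing index columns
    from raw columns at ingestion (see :mod:`ibp.measures`); completeness
    against a profile is evaluated lazily by the classifiers so that one file
    can serve several profiles.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names it).
    ParseError
        If a parameter cell is non-numeric (the message names row and column).
    IntegrityError
        If (animal_id, timepoint) is duplicated.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    if {"parameter", "value"}.issubset(df.columns):
        # long format: pivot to wide, preserving animal order of first appearance
        df = (
            df.pivot_table(
                index=list(MANDATORY_COLUMNS),
                columns="parameter",
                values="value",
                aggfunc="first",
                sort=False,
            )
            .reset_index()
        )
        df.columns.name = None
    table = CohortTable.from_dataframe(df, provenance=str(path))
    if profile is not None:
        from .measures import add_derived_columns

        add_derived_columns(table, profile)
    return table


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the wide canonical CSV. Round-trips through :func:`read_cohort`."""
    cohort.to_dataframe().to_csv(path, index=False)
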