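"""Derived behavioral and biochemical measures.

These are the formula-defined quantities that turn raw measurements into
profile parameters or normalized readouts:

* anxiety index   — EPM: percent of session in closed arms + center,
* preference index — social recognition: signed exploration asymmetry,
* densitometry normalization — western blot band relative expression,
* percent of baseline — electrophysiology protocol responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import CohortTable, ProfileDefinition, normalize_name
from .exceptions import DomainError


def anxiety_index(time_closed: float, time_center: float, time_total: float) -> float:
    """EPM anxiety index: ``100 * (closed-arm time + center time) / total time``.

    Higher values mean the animal avoided the anxiogenic open arms.
    Result lies in [0, 100].
    """
    if time_total <= 0:
        raise DomainError(f"time_total must be positive, got {time_total}")
    if min(time_closed, time_center) < 0:
        raise DomainError("times must be non-negative")
    if time_closed + time_center > time_total * (1 + 1e-12):
        raise DomainError(
            f"closed + center time ({time_closed + time_center}) exceeds total ({time_total})"
        )
    return 100.0 * (time_closed + time_center) / time_total


def preference_index(time_unfamiliar: float, time_familiar: float) -> float:
    """Social-recognition preference index:
    ``100 * (t_unfamiliar - t_familiar) / (t_unfamiliar + t_familiar)``.

    Positive values indicate preference for the unfamiliar conspecific
    (intact social recognition memory).  Result lies in [-100, 100].
    Antisymmetric under swapping the two times.
    """
    if min(time_unfamiliar, time_familiar) < 0:
        raise DomainError("exploration times must be non-negative")
    total = time_unfamiliar + time_familiar
    if total <= 0:
        raise DomainError("no exploration: both times are zero")
    return 100.0 * (time_unfamiliar - time_familiar) / total


@dataclass(frozen=True)
class DensitometryInputs:
    """Optical densities for one western-blot lane plus its loading control."""

    band_od: float
    background_od: float
    gapdh_od: float
    gapdh_background_od: float
    control_group_mean: float = 1.0


def normalize_densitometry(inputs: DensitometryInputs) -> float:
    """Relative expression of a band.

    The band OD is background-subtracted, divided by the background-subtracted
    GAPDH (loading control) signal of the same lane, then scaled by the mean
    of the control group so that control-group values average 1 by
    construction.  Background correction is subtractive; see the methods note
    for why.
    """
    if min(inputs.band_od, inputs.background_od, inputs.gapdh_od, inputs.gapdh_background_od) < 0:
        raise DomainError("optical densities must be non-negative")
    net_gapdh = inputs.gapdh_od - inputs.gapdh_background_od
    if net_gapdh <= 0:
        raise DomainError(
            f"non-positive net GAPDH signal ({net_gapdh}); cannot normalize lane"
        )
    if inputs.control_group_mean <= 0:
        raise DomainError("control_group_mean must be positive")
    return ((inputs.band_od - inputs.background_od) / net_gapdh) / inputs.control_group_mean


def percent_of_baseline(responses: Sequence[float], baseline: Sequence[float]) -> float:
    """Protocol response as percent of baseline: ``100 * mean(responses) / mean(baseline)``.

    Used to summarize frequency-dependent and paired-pulse protocols: the
    evoked responses (EPSP slope or population-spike amplitude) during the
    protocol are averaged and expressed relative to the averaged baseline
    pulses.  Values below 100 indicate inhibition, above 100 facilitation.
    """
    responses = np.asarray(responses, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if responses.size == 0 or baseline.size == 0:
        raise DomainError("responses and baseline must be non-empty")
    base_mean = baseline.mean()
    if base_mean == 0:
        raise DomainError("baseline mean is zero")
    return 100.0 * responses.mean() / base_mean


# ---------------------------------------------------------------------------
# ingestion helper: derive index columns from raw columns when present
# ---------------------------------------------------------------------------

#: raw-column recipes: derived name -> (raw names, function)
_DERIVATIONS = {
    "epm_anxiety_index": (
        ("epm_closed_arms_time", "epm_center_time", "epm_total_time"),
        anxiety_index,
    ),
    "srt_preference_index": (
        ("srt_unfamiliar_time", "srt_familiar_time"),
        preference_index,
    ),
}


def add_derived_columns(cohort: CohortTable, profile: ProfileDefinition) -> list[str]:
    """Fill in index parameters computable from raw columns, in place.

    For each record lacking a profile parameter with a known raw-column
    recipe, compute it when all raw inputs are present.  Precomputed index
    values are accepted as-is and never overwritten.  Returns the list of
    derived parameter names that were filled in at least once.
    """
    wanted: set[str] = set()
    for tp in profile.timepoints:
        wanted.update(profile.parameter_names(tp))
    derived: list[str] = []
    for name, (raw_names, func) in _DERIVATIONS.items():
        if name not in wanted:
            continue
        raw_names = tuple(normalize_name(r) for r in raw_names)
        for rec in cohort:
            if name in rec.values:
                continue
            if all(r in rec.values for r in raw_names):
                rec.values[name] = func(*(rec.values[r] for r in raw_names))
                if name not in derived:
                    derived.append(name)
    return derived
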