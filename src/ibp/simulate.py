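"""Synthetic cohort generator.

Emulates the statistical structure the profiling analysis assumes: a control
population whose seven behavioral parameters are correlated Gaussian
readouts of one latent anxiety construct (equicorrelation ``rho``), and a
trauma-exposed population in which a latent *affected* subpopulation is
shifted by ``effect_size_delta`` control-SDs in each parameter's
pathological direction.  At the post-treatment time point a latent
*responder* fraction of the affected animals reverts to the control
distribution while non-responders retain their shift.

Ground-truth labels are returned beside the cohort so that classifier
recovery of the configured fractions can be measured.  The generator works
at the parameter-table level only: it does not simulate trajectories,
freezing bouts, or traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    CONTROL,
    EXPOSED,
    POST_TRAUMA,
    POST_TREATMENT,
    BehavioralRecord,
    CohortTable,
    Direction,
    ProfileDefinition,
)
from .exceptions import ConfigurationError
from .profiles import builtin_profile

#: Default control mean/SD per parameter.  The published study reports no
#: distributional summaries, so these are round numbers on the scale typical
#: of 5-min rodent tests (cm for distances, s for times, % / index points
#: for indices).
DEFAULT_CONTROL_MEANS: dict[str, float] = {
    "wazm_total_distance": 2000.0,
    "wazm_closed_arms_time": 150.0,
    "wazm_closed_arms_distance": 900.0,
    "wazm_open_arms_distance": 600.0,
    "wazm_open_arms_time": 100.0,
    "wazm_total_freezing": 30.0,
    "epm_total_freezing": 20.0,
    "epm_anxiety_index": 65.0,
    "epm_total_distance": 1500.0,
    "oft_total_distance": 2500.0,
    "oft_center_time": 40.0,
    "srt_preference_index": 30.0,
}

DEFAULT_CONTROL_SDS: dict[str, float] = {
    "wazm_total_distance": 400.0,
    "wazm_closed_arms_time": 40.0,
    "wazm_closed_arms_distance": 200.0,
    "wazm_open_arms_distance": 150.0,
    "wazm_open_arms_time": 30.0,
    "wazm_total_freezing": 10.0,
    "epm_total_freezing": 8.0,
    "epm_anxiety_index": 10.0,
    "epm_total_distance": 300.0,
    "oft_total_distance": 500.0,
    "oft_center_time": 15.0,
    "srt_preference_index": 20.0,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of one synthetic two-time-point cohort.

    Defaults mirror the study conditions: 16 controls, 93 trauma-exposed
    animals, about two thirds of the exposed developing the phenotype and
    just under half of those responding to treatment.

    ``affected_param_count`` controls on how many of the m profile
    parameters an affected animal shifts (default 5 of 7, so near-threshold
    4-of-7 cases are exercised); ``"all"`` shifts every parameter.
    ``partial_reversion`` is the fraction of the shift a responder retains
    post-treatment (0 = complete reversion to the control distribution).
    """

    profile_id: str = "IBP1"
    n_control: int = 16
    n_exposed: int = 93
    affected_fraction: float = 0.65
    responder_fraction: float = 0.45
    effect_size_delta: float = 2.0
    affected_param_count: int | str = 5
    rho: float = 0.2
    partial_reversion: float = 0.0
    control_means: Mapping[str, float] = field(default_factory=dict)
    control_sds: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("affected_fraction", "responder_fraction", "partial_reversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError(
                f"rho must lie in [0, 1) for a positive-definite equicorrelation, got {self.rho}"
            )
        if self.n_control < 2 or self.n_exposed < 0:
            raise ConfigurationError("need n_control >= 2 and n_exposed >= 0")


def _equicorrelated(rng: np.random.Generator, n: int, d: int, rho: float) -> np.ndarray:
    """n x d standard-normal draws with pairwise correlation rho (one-factor form)."""
    g = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, d))
    return np.sqrt(rho) * g + np.sqrt(1.0 - rho) * eps


def _shift_sets(
    rng: np.random.Generator,
    profile: ProfileDefinition,
    count: int | str,
) -> dict[str, set[str]]:
    """Choose, once per animal, which parameters its shift touches.

    The subset is drawn from the first (post-trauma) time point's list; for
    time points that swap parameters in, the set is topped back up to the
    same size from the swapped-in parameters so the affected load is
    comparable across time points.
    """
    timepoints = profile.timepoints
    base_names = list(profile.parameter_names(timepoints[0]))
    c = len(base_names) if count == "all" else int(count)
    if not 1 <= c <= len(base_names):
        raise ConfigurationError(
            f"affected_param_count must be in 1..{len(base_names)} or 'all', got {count}"
        )
    base = set(rng.choice(base_names, size=c, replace=False))
    out = {timepoints[0]: base}
    for tp in timepoints[1:]:
        names = list(profile.parameter_names(tp))
        shared = base & set(names)
        extras = [p for p in names if p not in base_names]
        topup = min(c - len(shared), len(extras))
        chosen = set(shared)
        if topup > 0:
            chosen |= set(rng.choice(extras, size=topup, replace=False))
        out[tp] = chosen
    return out


def generate_cohort(
    config: SyntheticCohortConfig,
    profile: ProfileDefinition | None = None,
) -> tuple[CohortTable, pd.DataFrame]:
    """Generate a two-time-point cohort plus its ground-truth label table.

    Returns
    -------
    cohort : CohortTable
        Records for both time points, controls first, in stable animal order.
    truth : pandas.DataFrame
        One row per animal: ``animal_id, group, true_affected,
        true_responder`` (responder is NA for animals not truly affected).

    Fully reproducible: the same config (including seed) yields identical
    tables.
    """
    if profile is None:
        profile = builtin_profile(config.profile_id)
    rng = np.random.default_rng(config.seed)

    union: list[str] = []
    direction_of: dict[str, Direction] = {}
    for tp in profile.timepoints:
        for spec in profile.parameters(tp):
            if spec.name not in union:
                union.append(spec.name)
                direction_of[spec.name] = spec.direction
    means = np.array(
        [
            dict(DEFAULT_CONTROL_MEANS, **config.control_means).get(p, 100.0)
            for p in union
        ]
    )
    sds = np.array(
        [dict(DEFAULT_CONTROL_SDS, **config.control_sds).get(p, 10.0) for p in union]
    )
    if np.any(sds <= 0):
        raise ConfigurationError("control_sds must be positive")

    # pathological sign per parameter; two-sided parameters get a random
    # (per-cohort) sign so both tails are exercised
    signs = np.array(
        [
            -1.0
            if direction_of[p] is Direction.LOW_IS_AFFECTED
            else 1.0
            if direction_of[p] is Direction.HIGH_IS_AFFECTED
            else float(rng.choice([-1.0, 1.0]))
            for p in union
        ]
    )

    n_c, n_e = config.n_control, config.n_exposed
    ids_c = [f"C{i + 1:03d}" for i in range(n_c)]
    ids_e = [f"E{i + 1:03d}" for i in range(n_e)]

    affected = rng.random(n_e) < config.affected_fraction
    responder = np.where(
        affected, rng.random(n_e) < config.responder_fraction, False
    )
    shift_sets = [
        _shift_sets(rng, profile, config.affected_param_count) if a else None
        for a in affected
    ]

    records: list[BehavioralRecord] = []
    timepoints = list(profile.timepoints)
    for tp in timepoints:
        active = set(profile.parameter_names(tp))
        cols = [i for i, p in enumerate(union) if p in active]
        z_c = _equicorrelated(rng, n_c, len(union), config.rho)
        z_e = _equicorrelated(rng, n_e, len(union), config.rho)
        vals_c = means + sds * z_c
        vals_e = means + sds * z_e
        for j in range(n_e):
            if affected[j] is np.False_ or not affected[j]:
                continue
            scale = config.effect_size_delta
            if tp != timepoints[0] and responder[j]:
                scale *= config.partial_reversion
            if scale == 0:
                continue
            tp_set = shift_sets[j][tp]
            for i, p in enumerate(union):
                if p in tp_set:
                    vals_e[j, i] += signs[i] * scale * sds[i]
        for ids, vals, group in ((ids_c, vals_c, CONTROL), (ids_e, vals_e, EXPOSED)):
            for row_id, row in zip(ids, vals):
                records.append(
                    BehavioralRecord(
                        animal_id=row_id,
                        group=group,
                        timepoint=tp,
                        values={union[i]: float(row[i]) for i in cols},
                    )
                )

    truth = pd.DataFrame(
        {
            "animal_id": ids_c + ids_e,
            "group": [CONTROL] * n_c + [EXPOSED] * n_e,
            "true_affected": [False] * n_c + list(map(bool, affected)),
            "true_responder": [pd.NA] * n_c
            + [bool(r) if a else pd.NA for a, r in zip(affected, responder)],
        }
    )
    cohort = CohortTable(records, provenance=f"synthetic:seed={config.seed}")
    return cohort, truth


#: Config of the shipped 12-animal toy cohort (see :func:`worked_example`).
WORKED_EXAMPLE_CONFIG = SyntheticCohortConfig(
    profile_id="IBP1",
    n_control=4,
    n_exposed=8,
    affected_fraction=0.5,
    responder_fraction=0.5,
    effect_size_delta=3.0,
    affected_param_count="all",
    rho=0.0,
    seed=20221222,
)


def worked_example() -> tuple[CohortTable, pd.DataFrame]:
    """The fixed 12-animal toy cohort used in the README walk-through.

    Values are rounded to one decimal so the cutoffs (control mean ± SD)
    and every flag can be checked by hand.  Re-generating with the pinned
    config is byte-identical.
    """
    cohort, truth = generate_cohort(WORKED_EXAMPLE_CONFIG)
    for rec in cohort:
        rec.values = {p: round(v, 1) for p, v in rec.values.items()}
    return cohort, truth
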