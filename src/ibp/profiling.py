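"""The profiling core: control-anchored cutoffs and k-of-m classification.

The procedure flags each animal on each behavioral parameter against a
cutoff placed one control standard deviation from the control mean, in the
parameter's pathological direction, and classifies an animal *affected* when
at least ``k`` of the ``m`` profile parameters are flagged (default 4 of 7).
Previously affected animals are re-profiled after treatment and labelled
*responder* when they no longer meet the affected criterion.

The statsmodels-style surface is :class:`BehavioralProfileModel` /
:class:`ProfileResults`; the underlying operations
(:func:`compute_cutoffs`, :func:`flag_parameters`,
:func:`classify_affectedness`, :func:`classify_response`,
:func:`profile_cohort`) are plain functions usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

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
    read_cohort,
)
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    InvalidStateError,
    MissingInputError,
)

LABEL_AFFECTED = "affected"
LABEL_UNAFFECTED = "unaffected"
LABEL_RESPONDER = "responder"
LABEL_NON_RESPONDER = "non_responder"
LABEL_UNCLASSIFIABLE = "unclassifiable"

ResponderMode = Literal["post_count", "recovered_count"]


class DegenerateCutoffWarning(UserWarning):
    """A parameter's control SD is zero, so its cutoff equals the mean."""


@dataclass
class CutoffTable:
    """Per-parameter cutoffs for one time point, derived from the controls.

    ``table`` is indexed by parameter name with columns ``control_mean``,
    ``control_sd`` (sample SD, denominator n-1), ``lower_cutoff``,
    ``upper_cutoff`` (NaN where the direction does not use that side),
    ``direction``, ``n_control`` and ``degenerate`` — an audit trail of how
    each flag boundary was obtained.
    """

    table: pd.DataFrame
    timepoint: str
    sd_multiplier: float = 1.0

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def direction(self, parameter: str) -> Direction:
        return Direction(self.table.loc[parameter, "direction"])

    def bounds(self) -> dict[str, tuple[float, float, Direction]]:
        """Plain-dict ``{parameter: (lower, upper, direction)}`` view.

        Cached; the table is treated as immutable after construction.
        """
        cached = self.__dict__.get("_bounds")
        if cached is None:
            cached = {
                p: (
                    float(row["lower_cutoff"]),
                    float(row["upper_cutoff"]),
                    Direction(row["direction"]),
                )
                for p, row in self.table.iterrows()
            }
            self.__dict__["_bounds"] = cached
        return cached

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "timepoint", self.timepoint)
        out.insert(1, "sd_multiplier", self.sd_multiplier)
        out.to_csv(path, index_label="parameter")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CutoffTable":
        df = pd.read_csv(path, index_col="parameter")
        timepoint = str(df.pop("timepoint").iloc[0])
        sd_multiplier = float(df.pop("sd_multiplier").iloc[0])
        return cls(df, timepoint=timepoint, sd_multiplier=sd_multiplier)


def compute_cutoffs(
    controls: CohortTable,
    profile: ProfileDefinition,
    timepoint: str,
    sd_multiplier: float = 1.0,
) -> CutoffTable:
    """Derive the cutoff table from the control records at one time point.

    Only records complete for the profile's parameter list at ``timepoint``
    enter the mean/SD.  The SD uses denominator ``n - 1``.  The cutoff is
    ``mean - sd_multiplier * sd`` on the lower side and/or
    ``mean + sd_multiplier * sd`` on the upper side, per the parameter's
    pathological direction.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 complete control records at the time point.

    Warns
    -----
    DegenerateCutoffWarning
        When a parameter's control SD is zero (cutoff collapses to the mean).
    """
    specs = profile.parameters(timepoint)
    names = [s.name for s in specs]
    recs = controls.subset(timepoint=timepoint).complete_records(names)
    n = len(recs)
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 complete control records at {timepoint!r}, got {n}"
        )
    rows = []
    for spec in specs:
        vals = np.array([r.values[spec.name] for r in recs], dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1)
        degenerate = sd == 0
        if degenerate:
            warnings.warn(
                f"parameter {spec.name!r} at {timepoint!r}: control SD is zero; "
                "cutoff equals the control mean",
                DegenerateCutoffWarning,
                stacklevel=2,
            )
        lower = (
            mean - sd_multiplier * sd
            if spec.direction in (Direction.LOW_IS_AFFECTED, Direction.TWO_SIDED)
            else np.nan
        )
        upper = (
            mean + sd_multiplier * sd
            if spec.direction in (Direction.HIGH_IS_AFFECTED, Direction.TWO_SIDED)
            else np.nan
        )
        rows.append(
            {
                "parameter": spec.name,
                "control_mean": mean,
                "control_sd": sd,
                "lower_cutoff": lower,
                "upper_cutoff": upper,
                "direction": spec.direction.value,
                "n_control": n,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return CutoffTable(table, timepoint=timepoint, sd_multiplier=sd_multiplier)


def flag_parameters(record: BehavioralRecord, cutoffs: CutoffTable) -> dict[str, bool]:
    """Flag the record on every parameter of the cutoff table.

    A value is flagged when it is strictly beyond the cutoff in the
    pathological direction; equality with the cutoff is not flagged.

    Raises
    ------
    MissingInputError
        If the record lacks any cutoff parameter — no partial flag vector is
        returned, the animal is unclassifiable at this time point.
    """
    missing = record.missing(cutoffs.parameters)
    if missing:
        raise MissingInputError(
            f"animal {record.animal_id!r} at {record.timepoint!r} missing "
            f"parameter(s): {', '.join(missing)}"
        )
    flags: dict[str, bool] = {}
    for p, (lower, upper, direction) in cutoffs.bounds().items():
        v = record.values[p]
        flagged = False
        if direction in (Direction.LOW_IS_AFFECTED, Direction.TWO_SIDED):
            flagged = flagged or v < lower
        if direction in (Direction.HIGH_IS_AFFECTED, Direction.TWO_SIDED):
            flagged = flagged or v > upper
        flags[p] = bool(flagged)
    return flags


@dataclass
class ClassificationResult:
    """Per-animal outcome of one classification pass."""

    animal_id: str
    group: str
    timepoint: str
    flags: dict[str, bool] | None
    label: str

    @property
    def flag_count(self) -> int | None:
        return None if self.flags is None else sum(self.flags.values())


def classify_affectedness(
    flags: Mapping[str, bool],
    k: int = 4,
    *,
    animal_id: str = "",
    group: str = "",
    timepoint: str = "",
) -> ClassificationResult:
    """Label *affected* when at least ``k`` parameters are flagged, else *unaffected*."""
    flags = dict(flags)
    label = LABEL_AFFECTED if sum(flags.values()) >= k else LABEL_UNAFFECTED
    return ClassificationResult(animal_id, group, timepoint, flags, label)


def classify_response(
    post_flags: Mapping[str, bool],
    pre_flags: Mapping[str, bool] | None = None,
    k: int = 4,
    mode: ResponderMode = "post_count",
    *,
    was_affected: bool = True,
    animal_id: str = "",
    group: str = "",
    timepoint: str = "",
) -> ClassificationResult:
    """Label a previously affected animal *responder* or *non_responder*.

    Two operationalizations of the recovery criterion are available:

    ``post_count`` (default)
        Responder iff fewer than ``k`` parameters are flagged post-treatment
        — i.e. the animal no longer meets the affected criterion.
    ``recovered_count``
        Responder iff at least ``k`` of the m post-treatment parameters are
        *unflagged* ("recovered").  Requires ``pre_flags`` as evidence of the
        pre-treatment state.  For m = 7, k = 4 the two modes coincide.

    Raises
    ------
    InvalidStateError
        If the animal was not previously affected.
    MissingInputError
        ``recovered_count`` without ``pre_flags``.
    """
    if not was_affected:
        raise InvalidStateError(
            f"animal {animal_id!r}: responder classification applies only to "
            "previously affected animals"
        )
    post_flags = dict(post_flags)
    if mode == "post_count":
        responder = sum(post_flags.values()) < k
    elif mode == "recovered_count":
        if pre_flags is None:
            raise MissingInputError("recovered_count mode requires pre_flags")
        unflagged = sum(not f for f in post_flags.values())
        responder = unflagged >= k
    else:
        raise ConfigurationError(f"unknown responder mode {mode!r}")
    label = LABEL_RESPONDER if responder else LABEL_NON_RESPONDER
    return ClassificationResult(animal_id, group, timepoint, post_flags, label)


def profile_cohort(
    cohort: CohortTable,
    profile: ProfileDefinition,
    timepoint: str,
    cutoffs: CutoffTable,
    k: int | None = None,
    *,
    leave_one_out_group: str | None = None,
) -> list[ClassificationResult]:
    """Classify every record of the cohort at one time point.

    All groups are classified, controls included (self-classification of
    controls against their own cutoffs estimates the rule's false-positive
    rate).  Records missing a parameter get label ``unclassifiable`` with no
    flag vector.

    ``leave_one_out_group``, when set to the control group's label, rescores
    each animal of that group against cutoffs recomputed without it,
    removing the animal's own contribution to the mean/SD.

    Raises
    ------
    ConfigurationError
        If the cutoff table was built for a different time point.
    """
    if cutoffs.timepoint != timepoint:
        raise ConfigurationError(
            f"cutoff table is for {cutoffs.timepoint!r}, not {timepoint!r}"
        )
    if k is None:
        k = profile.k
    results: list[ClassificationResult] = []
    for rec in cohort.subset(timepoint=timepoint):
        cuts = cutoffs
        if leave_one_out_group is not None and rec.group == leave_one_out_group:
            others = CohortTable(
                [
                    r
                    for r in cohort.subset(group=rec.group, timepoint=timepoint)
                    if r.animal_id != rec.animal_id
                ]
            )
            cuts = compute_cutoffs(others, profile, timepoint, cutoffs.sd_multiplier)
        try:
            flags = flag_parameters(rec, cuts)
        except MissingInputError:
            results.append(
                ClassificationResult(rec.animal_id, rec.group, timepoint, None, LABEL_UNCLASSIFIABLE)
            )
            continue
        results.append(
            classify_affectedness(
                flags, k, animal_id=rec.animal_id, group=rec.group, timepoint=timepoint
            )
        )
    return results


def classifications_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Flatten classification results to one row per animal with flag columns."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "animal_id": r.animal_id,
            "group": r.group,
            "timepoint": r.timepoint,
            "flag_count": r.flag_count,
            "label": r.label,
        }
        if r.flags:
            for p, f in r.flags.items():
                row[f"flag_{p}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class BehavioralProfileModel:
    """Control-anchored k-of-m profiling model for a two-group cohort.

    Parameters
    ----------
    cohort : CohortTable
        Records for the control and exposed groups at one or two time points.
    profile : ProfileDefinition or str
        A profile definition or the id of a built-in one ("IBP1", "IBP2").
    control_group, exposed_group : str
        Group labels anchoring the cutoffs and receiving the affected
        classification, respectively.
    sd_multiplier : float
        Width of the cutoff band in control-SD units (default 1).
    k : int, optional
        Affected threshold; defaults to the profile's (4 of 7).
    leave_one_out : bool
        Score each control against cutoffs computed without it.

    Examples
    --------
    >>> from ibp import BehavioralProfileModel, simulate
    >>> cohort, truth = simulate.generate_cohort(simulate.SyntheticCohortConfig(seed=7))
    >>> res = BehavioralProfileModel(cohort, "IBP1").fit()
    >>> res.proportions.loc["exposed", "n_affected"]  # doctest: +SKIP
    """

    def __init__(
        self,
        cohort: CohortTable,
        profile: ProfileDefinition | str,
        *,
        control_group: str = CONTROL,
        exposed_group: str = EXPOSED,
        sd_multiplier: float = 1.0,
        k: int | None = None,
        leave_one_out: bool = False,
    ):
        if isinstance(profile, str):
            from .profiles import builtin_profile

            profile = builtin_profile(profile)
        self.cohort = cohort
        self.profile = profile
        self.control_group = control_group
        self.exposed_group = exposed_group
        self.sd_multiplier = sd_multiplier
        self.k = profile.k if k is None else k
        self.leave_one_out = leave_one_out

    @classmethod
    def from_csv(cls, path: str | Path, profile: ProfileDefinition | str = "IBP1", **kwargs):
        if isinstance(profile, str):
            from .profiles import builtin_profile

            profile = builtin_profile(profile)
        return cls(read_cohort(path, profile), profile, **kwargs)

    def _cutoffs(self, timepoint: str) -> CutoffTable:
        controls = self.cohort.subset(group=self.control_group)
        return compute_cutoffs(controls, self.profile, timepoint, self.sd_multiplier)

    def fit(self, timepoint: str = POST_TRAUMA) -> "ProfileResults":
        """Classify every animal at one time point as affected/unaffected."""
        cutoffs = self._cutoffs(timepoint)
        results = profile_cohort(
            self.cohort,
            self.profile,
            timepoint,
            cutoffs,
            self.k,
            leave_one_out_group=self.control_group if self.leave_one_out else None,
        )
        return ProfileResults(self, timepoint, cutoffs, results)

    def fit_response(
        self,
        pre_timepoint: str = POST_TRAUMA,
        post_timepoint: str = POST_TREATMENT,
        mode: ResponderMode = "post_count",
    ) -> "ResponseResults":
        """Run both classification passes and label responders.

        Affected animals are identified at ``pre_timepoint``; each is then
        re-profiled at ``post_timepoint`` against cutoffs recomputed from the
        concurrent controls, and labelled responder/non-responder per
        ``mode``.  Controls are re-profiled affected/unaffected at the
        post-treatment time point as well (false-positive audit).
        """
        pre = self.fit(pre_timepoint)
        post_cutoffs = self._cutoffs(post_timepoint)
        post_pass = profile_cohort(
            self.cohort,
            self.profile,
            post_timepoint,
            post_cutoffs,
            self.k,
            leave_one_out_group=self.control_group if self.leave_one_out else None,
        )
        by_id = {r.animal_id: r for r in post_pass}
        affected_ids = {
            r.animal_id for r in pre.classifications if r.label == LABEL_AFFECTED
        }
        responder_results: list[ClassificationResult] = []
        control_post: list[ClassificationResult] = []
        for r in post_pass:
            if r.group == self.control_group:
                control_post.append(r)
                continue
            if r.animal_id not in affected_ids:
                continue
            if r.flags is None:
                responder_results.append(r)  # unclassifiable post-treatment
                continue
            pre_r = next(
                (c for c in pre.classifications if c.animal_id == r.animal_id), None
            )
            responder_results.append(
                classify_response(
                    r.flags,
                    pre_flags=pre_r.flags if pre_r else None,
                    k=self.k,
                    mode=mode,
                    animal_id=r.animal_id,
                    group=r.group,
                    timepoint=post_timepoint,
                )
            )
        return ResponseResults(
            self, pre, post_cutoffs, responder_results, control_post, mode
        )


def _proportion_block(
    results: Sequence[ClassificationResult], labels: tuple[str, str]
) -> pd.DataFrame:
    from .stats import proportion_summary

    return proportion_summary(results, labels=labels)


@dataclass
class ProfileResults:
    """Results of one affected/unaffected classification pass."""

    model: BehavioralProfileModel
    timepoint: str
    cutoffs: CutoffTable
    classifications: list[ClassificationResult]

    def __post_init__(self) -> None:
        self.frame = classifications_frame(self.classifications)
        self.proportions = _proportion_block(
            self.classifications, (LABEL_AFFECTED, LABEL_UNAFFECTED)
        )

    def counts(self, group: str) -> tuple[int, int]:
        """(affected, unaffected) counts among classifiable animals of a group."""
        row = self.proportions.loc[group]
        return int(row["n_affected"]), int(row["n_unaffected"])

    @property
    def fisher_vs_control(self):
        """Fisher exact test on the exposed-vs-control affectedness table."""
        from .stats import ContingencyTable2x2, fisher_exact_2x2

        a, b = self.counts(self.model.exposed_group)
        c, d = self.counts(self.model.control_group)
        return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))

    def summary(self) -> str:
        lines = [
            f"Behavioral profiling results — profile {self.model.profile.profile_id}, "
            f"timepoint {self.timepoint}",
            f"k-of-m criterion: >= {self.model.k} of "
            f"{self.model.profile.m(self.timepoint)} parameters; "
            f"cutoffs at mean ± {self.cutoffs.sd_multiplier} control SD "
            f"(n_control = {int(self.cutoffs.table['n_control'].iloc[0])})",
            "",
            self.proportions.to_string(float_format=lambda x: f"{x:.1f}"),
        ]
        try:
            fr = self.fisher_vs_control
            lines += [
                "",
                f"Fisher exact ({self.model.exposed_group} vs {self.model.control_group}, "
                f"affected/unaffected): p = {fr.p_value:.4f}, OR = {fr.odds_ratio:.3g}",
            ]
        except KeyError:
            pass
        return "\n".join(lines)


@dataclass
class ResponseResults:
    """Results of the full two-time-point (responder) analysis."""

    model: BehavioralProfileModel
    pre: ProfileResults
    post_cutoffs: CutoffTable
    responder_classifications: list[ClassificationResult]
    control_post: list[ClassificationResult]
    mode: ResponderMode

    def __post_init__(self) -> None:
        self.frame = classifications_frame(self.responder_classifications)
        self.proportions = _proportion_block(
            self.responder_classifications, (LABEL_RESPONDER, LABEL_NON_RESPONDER)
        )
        self.control_post_proportions = _proportion_block(
            self.control_post, (LABEL_AFFECTED, LABEL_UNAFFECTED)
        )

    def counts(self, group: str | None = None) -> tuple[int, int]:
        """(responder, non_responder) counts among classifiable treated animals."""
        if group is None:
            group = self.model.exposed_group
        row = self.proportions.loc[group]
        return int(row["n_responder"]), int(row["n_non_responder"])

    def summary(self) -> str:
        lines = [
            f"Treatment-response profiling — profile {self.model.profile.profile_id}, "
            f"mode {self.mode}",
            "",
            "Post-trauma classification:",
            self.pre.proportions.to_string(float_format=lambda x: f"{x:.1f}"),
            "",
            "Responder classification (previously affected animals):",
            self.proportions.to_string(float_format=lambda x: f"{x:.1f}"),
            "",
            "Controls re-profiled post-treatment:",
            self.control_post_proportions.to_string(float_format=lambda x: f"{x:.1f}"),
        ]
        return "\n".join(lines)
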