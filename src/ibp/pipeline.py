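"""End-to-end pipelines tying classification and statistics together.

:func:`run_pipeline` executes the full analysis of one experiment: cutoffs
from concurrent controls → per-animal flags → affected/unaffected and
responder/non-responder classification → proportion summaries → Fisher
exact comparison of the classification distributions → per-parameter
normality-gated group comparisons.  Every decision (gate outcomes, excluded
animals, cutoffs) is logged and lands in the report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .cohort import CONTROL, EXPOSED, POST_TRAUMA, POST_TREATMENT, CohortTable, read_cohort
from .exceptions import ConfigurationError
from .profiles import builtin_profile
from .profiling import (
    LABEL_AFFECTED,
    LABEL_NON_RESPONDER,
    LABEL_RESPONDER,
    LABEL_UNAFFECTED,
    BehavioralProfileModel,
    ProfileResults,
    ResponseResults,
)
from .simulate import SyntheticCohortConfig, generate_cohort
from .stats import (
    ContingencyTable2x2,
    FisherResult,
    GroupComparisonResult,
    compare_groups,
    fisher_exact_2x2,
)

logger = logging.getLogger("ibp")


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``cohort_path`` (a cohort CSV) or ``simulation`` (a
    synthetic-cohort config) must be supplied.
    """

    profile_id: str = "IBP1"
    cohort_path: str | Path | None = None
    simulation: SyntheticCohortConfig | Mapping[str, Any] | None = None
    responder_mode: str = "post_count"
    alpha: float = 0.05
    alpha_normality: float = 0.05
    sd_multiplier: float = 1.0
    control_group: str = CONTROL
    exposed_group: str = EXPOSED
    out_dir: str | Path | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.simulation is None):
            raise ConfigurationError(
                "supply exactly one of cohort_path or simulation"
            )
        if isinstance(self.simulation, Mapping):
            sim = dict(self.simulation)
            sim.setdefault("profile_id", self.profile_id)
            if self.seed is not None:
                sim["seed"] = self.seed
            self.simulation = SyntheticCohortConfig(**sim)
        elif self.simulation is not None and self.seed is not None:
            from dataclasses import replace

            self.simulation = replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, ready for serialization."""

    config: PipelineConfig
    profile_results: ProfileResults
    response_results: ResponseResults | None
    fisher_affected: FisherResult | None
    group_comparisons: dict[str, dict[str, GroupComparisonResult]] = field(
        default_factory=dict
    )
    truth: pd.DataFrame | None = None

    def summary(self) -> str:
        parts = [self.profile_results.summary()]
        if self.response_results is not None:
            parts.append(self.response_results.summary())
        for tp, by_param in self.group_comparisons.items():
            parts.append(f"\nPer-parameter group comparisons at {tp}:")
            for param, res in by_param.items():
                parts.append(f"[{param}]\n{res.summary()}")
        return "\n\n".join(parts)


def _values_by_label(
    cohort: CohortTable,
    timepoint: str,
    parameter: str,
    label_of: Mapping[str, str],
    wanted_labels: tuple[str, ...],
) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {lab: [] for lab in wanted_labels}
    for rec in cohort.subset(timepoint=timepoint):
        lab = label_of.get(rec.animal_id)
        if lab in out and parameter in rec.values:
            out[lab].append(rec.values[parameter])
    return {k: v for k, v in out.items() if v}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full profiling analysis described by ``config``.

    Stage errors propagate with the stage named in the log; the CLI maps
    them to exit codes.
    """
    profile = builtin_profile(config.profile_id)
    truth = None
    if config.cohort_path is not None:
        logger.info("stage load: reading cohort from %s", config.cohort_path)
        cohort = read_cohort(config.cohort_path, profile)
    else:
        logger.info("stage simulate: generating cohort (seed=%s)", config.simulation.seed)
        cohort, truth = generate_cohort(config.simulation, profile)

    model = BehavioralProfileModel(
        cohort,
        profile,
        control_group=config.control_group,
        exposed_group=config.exposed_group,
        sd_multiplier=config.sd_multiplier,
    )

    timepoints = [tp for tp in profile.timepoints if len(cohort.subset(timepoint=tp))]
    pre_tp = timepoints[0]
    logger.info("stage classify: affected/unaffected at %s", pre_tp)
    profile_results = model.fit(pre_tp)
    for r in profile_results.classifications:
        logger.debug(
            "animal %s (%s): label=%s flags=%s", r.animal_id, r.group, r.label, r.flags
        )
        if r.label == "unclassifiable":
            logger.info("excluded (incomplete record): %s at %s", r.animal_id, pre_tp)

    response_results = None
    if len(timepoints) > 1:
        post_tp = timepoints[1]
        logger.info("stage respond: responder/non-responder at %s", post_tp)
        response_results = model.fit_response(pre_tp, post_tp, mode=config.responder_mode)

    logger.info("stage fisher: exposed vs control affectedness")
    try:
        fisher_affected = profile_results.fisher_vs_control
    except KeyError:
        fisher_affected = None  # one-group cohort

    group_comparisons: dict[str, dict[str, GroupComparisonResult]] = {}

    # {control, affected, unaffected} on each post-trauma parameter
    label_of_pre = {
        r.animal_id: (
            CONTROL
            if r.group == config.control_group
            else r.label
        )
        for r in profile_results.classifications
        if r.label in (LABEL_AFFECTED, LABEL_UNAFFECTED)
        or r.group == config.control_group
    }
    group_comparisons[pre_tp] = {}
    for param in profile.parameter_names(pre_tp):
        vals = _values_by_label(
            cohort, pre_tp, param, label_of_pre, (CONTROL, LABEL_AFFECTED, LABEL_UNAFFECTED)
        )
        if len(vals) >= 2 and all(len(v) >= 3 for v in vals.values()):
            res = compare_groups(vals, config.alpha, config.alpha_normality)
            logger.info(
                "stage stats [%s @ %s]: %s gate=%s p=%.4g",
                param, pre_tp, res.omnibus_test, res.gate_decision, res.p_value,
            )
            group_comparisons[pre_tp][param] = res

    # {control, responder, non_responder} on each post-treatment parameter
    if response_results is not None:
        post_tp = timepoints[1]
        label_of_post = {
            r.animal_id: CONTROL
            for r in response_results.control_post
        }
        label_of_post.update(
            {
                r.animal_id: r.label
                for r in response_results.responder_classifications
                if r.label in (LABEL_RESPONDER, LABEL_NON_RESPONDER)
            }
        )
        group_comparisons[post_tp] = {}
        for param in profile.parameter_names(post_tp):
            vals = _values_by_label(
                cohort, post_tp, param, label_of_post,
                (CONTROL, LABEL_RESPONDER, LABEL_NON_RESPONDER),
            )
            if len(vals) >= 2 and all(len(v) >= 3 for v in vals.values()):
                res = compare_groups(vals, config.alpha, config.alpha_normality)
                logger.info(
                    "stage stats [%s @ %s]: %s gate=%s p=%.4g",
                    param, post_tp, res.omnibus_test, res.gate_decision, res.p_value,
                )
                group_comparisons[post_tp][param] = res

    bundle = ReportBundle(
        config=config,
        profile_results=profile_results,
        response_results=response_results,
        fisher_affected=fisher_affected,
        group_comparisons=group_comparisons,
        truth=truth,
    )
    if config.out_dir is not None:
        from .report import write_report

        write_report(bundle, config.out_dir)
    return bundle


def cross_experiment_comparison(
    counts_a: tuple[int, int], counts_b: tuple[int, int], sided: str = "two_sided"
) -> FisherResult:
    """Fisher exact test comparing a 2-category classification distribution
    between two experiments (rows = experiments, columns = categories).

    ``counts_a``/``counts_b`` are (category1, category2) count pairs, e.g.
    (affected, unaffected) or (responder, non_responder).
    """
    (a, b), (c, d) = counts_a, counts_b
    return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), sided=sided)
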