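"""Statistical layer: exact proportion tests and gated group comparisons.

Two families of analyses accompany the classification:

* Fisher exact tests on 2x2 classification tables (affected/unaffected or
  responder/non-responder counts across cohorts), two-sided by the
  minimum-likelihood rule.
* Normality-gated omnibus comparisons of a continuous measure across groups:
  Shapiro-Wilk on every group decides between one-way ANOVA with
  Bonferroni-adjusted pairwise post-hocs and Kruskal-Wallis with Dunn's
  post-hoc.  Post-hoc tests run only when the omnibus p is significant, and
  the gate decision is part of the returned audit trail.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, DomainError, InsufficientDataError

# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts; rows are cohorts, columns category counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DomainError(f"cell {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise DomainError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    sided: str = "two_sided"


_SIDED_TO_SCIPY = {
    "two_sided": "two-sided",
    "less": "less",
    "greater": "greater",
}


def fisher_exact_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    sided: str = "two_sided",
) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p sums the point probabilities of all tables with the
    observed margins whose hypergeometric probability does not exceed that of
    the observed table (minimum-likelihood rule).  The odds ratio is the
    sample estimate ``ad / bc``; a zero denominator yields ``inf`` (or NaN
    when the numerator is also zero).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    if sided not in _SIDED_TO_SCIPY:
        raise DomainError(f"sided must be one of {sorted(_SIDED_TO_SCIPY)}")
    res = sps.fisher_exact(table.as_array(), alternative=_SIDED_TO_SCIPY[sided])
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        odds = math.nan if num == 0 else math.inf
    else:
        odds = num / den
    return FisherResult(p_value=float(res.pvalue), odds_ratio=odds, sided=sided)


# ---------------------------------------------------------------------------
# normality-gated group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    method: str


@dataclass
class GroupComparisonResult:
    """Full audit trail of one gated comparison."""

    groups: tuple[str, ...]
    normality_p_per_group: dict[str, float]
    gate_decision: str  # "parametric" | "nonparametric"
    omnibus_test: str
    statistic: float
    df: tuple[int, ...] | int
    p_value: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = 0.05
    alpha_normality: float = 0.05
    posthoc_adjustment: str = "bonferroni"

    def to_rows(self) -> pd.DataFrame:
        """Flat per-test rows (omnibus first, then post-hocs) for CSV export."""
        rows = [
            {
                "test": self.omnibus_test,
                "groups": "|".join(self.groups),
                "statistic": self.statistic,
                "p": self.p_value,
                "p_adjusted": np.nan,
                "decision": self.gate_decision,
            }
        ]
        for c in self.posthoc:
            rows.append(
                {
                    "test": c.method,
                    "groups": f"{c.group_a}|{c.group_b}",
                    "statistic": c.statistic,
                    "p": c.p_unadjusted,
                    "p_adjusted": c.p_adjusted,
                    "decision": self.gate_decision,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"{self.omnibus_test}: statistic = {self.statistic:.4g}, "
            f"p = {self.p_value:.4g} (gate: {self.gate_decision})",
            "Shapiro-Wilk per group: "
            + ", ".join(f"{g}: p={p:.3g}" for g, p in self.normality_p_per_group.items()),
        ]
        for c in self.posthoc:
            lines.append(
                f"  {c.group_a} vs {c.group_b}: {c.method}, "
                f"p_adj = {c.p_adjusted:.4g}"
            )
        if not self.posthoc:
            lines.append(f"  no post-hoc (omnibus p >= {self.alpha})")
        return "\n".join(lines)


def _shapiro_p(values: np.ndarray) -> float:
    # constant data has no normal fit; treat as failing the gate
    if np.ptp(values) == 0:
        return 0.0
    return float(sps.shapiro(values).pvalue)


def dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    adjustment: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Dunn's pairwise test from the pooled Kruskal-Wallis ranking.

    Mean ranks come from a single ranking of all observations (mid-ranks for
    ties); the z statistic for a pair uses the tie-corrected variance
    ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t)`` over tie groups.  Two-sided p-values are
    Bonferroni-adjusted over all pairs by default.
    """
    groups = list(values_by_group)
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    pooled = np.concatenate([arrays[g] for g in groups])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in groups:
        n = arrays[g].size
        mean_ranks[g] = float(ranks[start : start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(groups, 2))
    n_pairs = len(pairs)
    out: list[PairwiseComparison] = []
    for ga, gb in pairs:
        se = math.sqrt(base_var * (1.0 / arrays[ga].size + 1.0 / arrays[gb].size))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * float(sps.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p_adj = min(1.0, p * n_pairs)
        elif adjustment == "none":
            p_adj = p
        else:
            raise DomainError(f"unknown adjustment {adjustment!r}")
        out.append(PairwiseComparison(ga, gb, z, p, p_adj, "dunn"))
    return out


def _bonferroni_ttests(
    values_by_group: Mapping[str, np.ndarray],
) -> list[PairwiseComparison]:
    """Pairwise t tests pooling the within-group variance over *all* groups
    (the ANOVA mean-square error), Bonferroni-adjusted — the classic
    Bonferroni post-hoc of one-way ANOVA."""
    groups = list(values_by_group)
    n_total = sum(v.size for v in values_by_group.values())
    df_err = n_total - len(groups)
    sse = sum(
        float(np.sum((v - v.mean()) ** 2)) for v in values_by_group.values()
    )
    mse = sse / df_err
    pairs = list(itertools.combinations(groups, 2))
    n_pairs = len(pairs)
    out: list[PairwiseComparison] = []
    for ga, gb in pairs:
        va, vb = values_by_group[ga], values_by_group[gb]
        se = math.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = (va.mean() - vb.mean()) / se
            p = 2.0 * float(sps.t.sf(abs(t), df_err))
        out.append(
            PairwiseComparison(ga, gb, t, p, min(1.0, p * n_pairs), "bonferroni_t")
        )
    return out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> GroupComparisonResult:
    """Normality-gated omnibus + post-hoc comparison of one measure.

    Shapiro-Wilk runs on every group; if all pass at ``alpha_normality`` the
    parametric branch is taken (one-way ANOVA, Bonferroni pairwise t on a
    significant omnibus), otherwise the nonparametric branch (Kruskal-Wallis,
    Dunn's pairwise test on a significant omnibus).  Post-hoc p-values are
    reported only when the omnibus p is below ``alpha``.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 groups, or any group with fewer than 3 observations
        (the message names it).
    DegenerateDataError
        All observations identical across all groups.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrays: dict[str, np.ndarray] = {}
    for g in groups:
        v = np.asarray(values_by_group[g], dtype=float)
        if v.size < 3:
            raise InsufficientDataError(
                f"group {g!r} has {v.size} observations; need >= 3"
            )
        arrays[g] = v
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations identical in every group")

    normality = {g: _shapiro_p(v) for g, v in arrays.items()}
    parametric = all(p >= alpha_normality for p in normality.values())

    if parametric:
        stat, p = sps.f_oneway(*arrays.values())
        df = (len(groups) - 1, pooled.size - len(groups))
        test = "one_way_anova"
        posthoc = _bonferroni_ttests(arrays) if p < alpha else []
        adjustment = "bonferroni"
    else:
        stat, p = sps.kruskal(*arrays.values())
        df = len(groups) - 1
        test = "kruskal_wallis"
        posthoc = dunn_posthoc(arrays) if p < alpha else []
        adjustment = "bonferroni"

    return GroupComparisonResult(
        groups=tuple(groups),
        normality_p_per_group=normality,
        gate_decision="parametric" if parametric else "nonparametric",
        omnibus_test=test,
        statistic=float(stat),
        df=df,
        p_value=float(p),
        posthoc=posthoc,
        alpha=alpha,
        alpha_normality=alpha_normality,
        posthoc_adjustment=adjustment,
    )


# ---------------------------------------------------------------------------
# proportion summaries
# ---------------------------------------------------------------------------


def proportion_summary(
    classifications: Sequence["ClassificationResult"],
    labels: tuple[str, str] = ("affected", "unaffected"),
) -> pd.DataFrame:
    """Per-group counts and percentages of a binary classification.

    Percentages are computed over *classifiable* animals only; with zero
    classifiable animals the percentage columns are NaN (reported as
    undefined downstream).  ``percent_<label>`` is the raw percentage,
    ``percent_<label>_rounded`` the nearest integer, and a Wilson 95%
    confidence interval accompanies the first label's proportion.

    Raises
    ------
    InsufficientDataError
        On an empty classification list.
    """
    from statsmodels.stats.proportion import proportion_confint

    if len(classifications) == 0:
        raise InsufficientDataError("no classifications to summarize")
    lab1, lab2 = labels
    rows = {}
    for r in classifications:
        rec = rows.setdefault(
            r.group,
            {"n_total": 0, f"n_{lab1}": 0, f"n_{lab2}": 0, "n_unclassifiable": 0},
        )
        rec["n_total"] += 1
        if r.label == lab1:
            rec[f"n_{lab1}"] += 1
        elif r.label == lab2:
            rec[f"n_{lab2}"] += 1
        else:
            rec["n_unclassifiable"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    n_class = df[f"n_{lab1}"] + df[f"n_{lab2}"]
    df["n_classifiable"] = n_class
    for lab in labels:
        pct = 100.0 * df[f"n_{lab}"] / n_class.where(n_class > 0)
        df[f"percent_{lab}"] = pct
        df[f"percent_{lab}_rounded"] = pct.round(0)
    ci_low, ci_high = [], []
    for _, row in df.iterrows():
        if row["n_classifiable"] > 0:
            lo, hi = proportion_confint(
                row[f"n_{lab1}"], row["n_classifiable"], method="wilson"
            )
            ci_low.append(100 * lo)
            ci_high.append(100 * hi)
        else:
            ci_low.append(np.nan)
            ci_high.append(np.nan)
    df[f"percent_{lab1}_ci_low"] = ci_low
    df[f"percent_{lab1}_ci_high"] = ci_high
    return df
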