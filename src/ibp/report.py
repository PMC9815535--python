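"""Report serialization: machine-readable JSON/CSV plus a human summary.

The JSON report nests per-animal labels, per-group proportions and every
test with its inputs; the CSV files are flat per-animal and per-test tables.
Percentages in the report always recompute from its own counts, and raw
fractions are retained beside rounded ones.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import pandas as pd

from .pipeline import ReportBundle
from .profiling import CutoffTable


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None if math.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonable(obj.item())
    return obj


def _proportions_dict(df: pd.DataFrame) -> dict:
    return _jsonable(df.reset_index().to_dict(orient="records"))


def _comparison_dict(res) -> dict:
    return _jsonable(
        {
            "groups": list(res.groups),
            "normality_p_per_group": res.normality_p_per_group,
            "gate_decision": res.gate_decision,
            "omnibus": {
                "test": res.omnibus_test,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
            },
            "posthoc": [
                {
                    "pair": [c.group_a, c.group_b],
                    "statistic": c.statistic,
                    "p": c.p_unadjusted,
                    "p_adjusted": c.p_adjusted,
                    "method": c.method,
                }
                for c in res.posthoc
            ],
        }
    )


def bundle_to_dict(bundle: ReportBundle) -> dict:
    """The full nested JSON form of a report bundle."""
    pr = bundle.profile_results
    out: dict[str, Any] = {
        "profile_id": pr.model.profile.profile_id,
        "k": pr.model.k,
        "sd_multiplier": pr.cutoffs.sd_multiplier,
        "classification": {
            "timepoint": pr.timepoint,
            "per_animal": _jsonable(pr.frame.to_dict(orient="records")),
            "proportions": _proportions_dict(pr.proportions),
        },
        "tests": [],
    }
    if bundle.fisher_affected is not None:
        out["tests"].append(
            _jsonable(
                {
                    "test": "fisher_exact",
                    "comparison": "exposed_vs_control_affectedness",
                    "p": bundle.fisher_affected.p_value,
                    "odds_ratio": bundle.fisher_affected.odds_ratio,
                    "sided": bundle.fisher_affected.sided,
                }
            )
        )
    if bundle.response_results is not None:
        rr = bundle.response_results
        out["response"] = {
            "mode": rr.mode,
            "per_animal": _jsonable(rr.frame.to_dict(orient="records")),
            "proportions": _proportions_dict(rr.proportions),
            "control_post_proportions": _proportions_dict(rr.control_post_proportions),
        }
    out["group_comparisons"] = {
        tp: {param: _comparison_dict(res) for param, res in by_param.items()}
        for tp, by_param in bundle.group_comparisons.items()
    }
    return out


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the report bundle under ``out_dir``; returns the paths written.

    Files: ``report.json`` (nested), ``per_animal.csv``, ``tests.csv``,
    ``cutoffs_<timepoint>.csv``, ``summary.txt``, and ``truth.csv`` when the
    cohort was simulated.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["json"] = out_dir / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(bundle_to_dict(bundle), fh, indent=2)

    pr = bundle.profile_results
    frames = [pr.frame]
    if bundle.response_results is not None:
        frames.append(bundle.response_results.frame)
    paths["per_animal"] = out_dir / "per_animal.csv"
    pd.concat(frames, ignore_index=True).to_csv(paths["per_animal"], index=False)

    test_rows = []
    if bundle.fisher_affected is not None:
        test_rows.append(
            pd.DataFrame(
                [
                    {
                        "test": "fisher_exact",
                        "groups": "exposed|control",
                        "statistic": bundle.fisher_affected.odds_ratio,
                        "p": bundle.fisher_affected.p_value,
                        "p_adjusted": float("nan"),
                        "decision": "exact",
                    }
                ]
            )
        )
    for tp, by_param in bundle.group_comparisons.items():
        for param, res in by_param.items():
            rows = res.to_rows()
            rows.insert(0, "timepoint", tp)
            rows.insert(1, "parameter", param)
            test_rows.append(rows)
    paths["tests"] = out_dir / "tests.csv"
    if test_rows:
        pd.concat(test_rows, ignore_index=True).to_csv(paths["tests"], index=False)
    else:
        pd.DataFrame(
            columns=["timepoint", "parameter", "test", "groups", "statistic", "p", "p_adjusted", "decision"]
        ).to_csv(paths["tests"], index=False)

    cutoff_tables: list[CutoffTable] = [pr.cutoffs]
    if bundle.response_results is not None:
        cutoff_tables.append(bundle.response_results.post_cutoffs)
    for ct in cutoff_tables:
        p = out_dir / f"cutoffs_{ct.timepoint}.csv"
        ct.to_csv(p)
        paths[f"cutoffs_{ct.timepoint}"] = p

    if bundle.truth is not None:
        paths["truth"] = out_dir / "truth.csv"
        bundle.truth.to_csv(paths["truth"], index=False)

    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text(bundle.summary() + "\n")
    return paths


def plot_proportions(bundle: ReportBundle, path: str | Path) -> None:
    """Stacked proportion bars of the classification distributions.

    Purely an output; figures never feed back into any computation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    blocks = [("post-trauma", bundle.profile_results.proportions, ("affected", "unaffected"))]
    if bundle.response_results is not None:
        blocks.append(
            ("post-treatment", bundle.response_results.proportions, ("responder", "non_responder"))
        )
    fig, axes = plt.subplots(1, len(blocks), figsize=(4 * len(blocks), 4), squeeze=False)
    for ax, (title, props, labels) in zip(axes[0], blocks):
        groups = list(props.index)
        bottom = [0.0] * len(groups)
        for lab, color in zip(labels, ("#c0504d", "#4f81bd")):
            pct = props[f"percent_{lab}"].fillna(0.0).tolist()
            ax.bar(groups, pct, bottom=bottom, label=lab, color=color)
            bottom = [b + p for b, p in zip(bottom, pct)]
        ax.set_ylabel("% of classifiable animals")
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
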