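"""End-to-end orchestration: phantoms → simulated observers → metrics → stats."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MVPolicy, build_metrics_table
from .observers import ObserverProfile, default_panel, run_study
from .phantom import PhantomCase, make_scenario_suite
from .stats import (
    ComparisonResult,
    compare_observers,
    compare_strategies,
    global_kruskal,
    select_best_tally,
    summarize_metrics,
)

__all__ = ["StudyConfig", "StudyReport", "run_full_analysis"]


@dataclass
class StudyConfig:
    """Knobs of a full simulated inter-observer study."""

    n_lesions: int = 20
    seed: int = 0
    mv_policy: MVPolicy = MVPolicy.EXPERIENCED_ONLY
    fdr_q: float = 0.10
    observers: list[ObserverProfile] | None = None


@dataclass
class StudyReport:
    """All computed outputs of one study run."""

    config: StudyConfig
    metrics: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: dict[str, list[ComparisonResult]]
    global_tests: dict[str, tuple[float, float]]
    observer_comparisons: dict[str, list[ComparisonResult]]
    tally: pd.DataFrame
    median_jc: dict[str, float] = field(default_factory=dict)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for family, results in self.comparisons.items():
            for r in results:
                rows.append((family, r.group_a, r.group_b, r.statistic, r.p_value,
                             r.significant, r.n_a, r.n_b))
        return pd.DataFrame(
            rows,
            columns=["family", "group_a", "group_b", "H", "p", "significant", "n_a", "n_b"],
        )

    def to_json_dict(self) -> dict:
        pct = {row.algorithm: row.pct for row in self.tally.itertuples()}
        return {
            "n_lesions": self.config.n_lesions,
            "seed": self.config.seed,
            "mv_policy": self.config.mv_policy.value,
            "median_jc": self.median_jc,
            "comparisons": {
                family: [
                    {
                        "pair": f"{r.group_a} vs {r.group_b}",
                        "H": r.statistic,
                        "p": r.p_value,
                        "significant": r.significant,
                    }
                    for r in results
                ]
                for family, results in self.comparisons.items()
            },
            "global_tests": {k: {"H": v[0], "p": v[1]} for k, v in self.global_tests.items()},
            "select_best_pct": pct,
        }

    def write_outputs(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        self.comparisons_frame().to_csv(out / "comparisons.csv", index=False)
        self.tally.to_csv(out / "tally.csv", index=False)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2))


def run_full_analysis(
    config: StudyConfig | None = None,
    suite: list[PhantomCase] | None = None,
    out_dir=None,
) -> StudyReport:
    """Run the whole simulated study and assemble its report.

    Builds (or accepts) a lesion suite, simulates every observer × strategy
    cell, computes the metrics table, the strategy comparison families for
    Jaccard and pairwise %MATV plus PPV/SE vs the majority vote, the
    per-observer Wilcoxon comparisons, and the select-the-best tally.
    """
    if config is None:
        config = StudyConfig()
    observers = config.observers if config.observers is not None else default_panel()
    if suite is None:
        suite = make_scenario_suite(config.n_lesions, seed=config.seed)
    records = run_study(suite, observers, seed=config.seed)
    table = build_metrics_table(records, suite, observers, mv_policy=config.mv_policy)

    comparisons = {
        "jaccard": compare_strategies(table, "jaccard", q=config.fdr_q, kind="pairwise"),
        "pct_matv_diff_pairwise": compare_strategies(
            table, "pct_matv_diff", q=config.fdr_q, kind="pairwise"
        ),
        "ppv_se_vs_mv": compare_strategies(table, "ppv_se", q=config.fdr_q, kind="vs_mv"),
        "pct_matv_diff_vs_mv": compare_strategies(
            table, "pct_matv_diff", q=config.fdr_q, kind="vs_mv"
        ),
    }
    global_tests = {
        "jaccard": global_kruskal(table, "jaccard", kind="pairwise"),
        "pct_matv_diff_pairwise": global_kruskal(table, "pct_matv_diff", kind="pairwise"),
    }
    observer_comparisons = {
        strategy: compare_observers(table, "pct_matv_diff", strategy, q=config.fdr_q)
        for strategy in table["strategy"].unique()
    }
    jc = table[(table["metric"] == "jaccard") & (table["kind"] == "pairwise")]
    median_jc = {s: float(g["value"].median()) for s, g in jc.groupby("strategy")}

    report = StudyReport(
        config=config,
        metrics=table,
        summaries=summarize_metrics(table),
        comparisons=comparisons,
        global_tests=global_tests,
        observer_comparisons=observer_comparisons,
        tally=select_best_tally(records),
        median_jc=median_jc,
    )
    if out_dir is not None:
        report.write_outputs(out_dir)
    return report
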