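"""Univariate statistics: lesion-group ANOVAs and metric regressions.

Per tract, Task Scores are compared across (lesioned, non-lesioned,
control) with a Levene screen choosing classical ANOVA + Sidak or Welch +
Games-Howell.  FA/MD/volume are compared across the six
impairment-by-hemisphere groups, and lesioned-hemisphere metrics are
regressed on Task Scores with Benjamini-Hochberg correction across the
five tracts.  Writes taskscore_anovas.csv, metric_anovas.csv,
regressions.csv under results/study/.
"""

import sys
from pathlib import Path

import pandas as pd

from propriomap.stats import (
    compare_metric_by_impairment, compare_taskscores_by_lesion,
    comparison_to_frame, regression_table,
)
from propriomap.synthetic import TRACTS, demographics_from_csv

OUT = Path("results/study")


def main() -> int:
    demos = demographics_from_csv(OUT / "demographics.csv")
    scores = pd.read_csv(OUT / "scores.csv", index_col="participant")
    groups = pd.read_csv(OUT / "lesion_overlap.csv")
    metrics = pd.read_csv(OUT / "tract_metrics.csv")
    control_ids = [p for p, d in demos.items() if d.group == "control"]
    stroke_ids = [p for p, d in demos.items() if d.group == "stroke"]

    task = scores["task_score"]
    ts_results = [
        compare_taskscores_by_lesion(task, groups, control_ids, tract)
        for tract in TRACTS
    ]
    ts_frame = comparison_to_frame(ts_results)
    ts_frame.to_csv(OUT / "taskscore_anovas.csv", index=False)
    print("Task Score ANOVAs (lesioned vs non-lesioned vs control):")
    for row in ts_frame.itertuples(index=False):
        print(f"  {row.label}: {row.method} F({row.df1:.0f}, {row.df2:.2f}) "
              f"= {row.F:.2f}, p = {row.p:.2e}")

    roles = []
    for row in metrics.itertuples(index=False):
        d = demos[row.participant]
        if d.group == "control":
            roles.append(row.hemisphere)
        else:
            roles.append(
                "lesioned" if row.hemisphere == d.lesioned_hemisphere else "non_lesioned"
            )
    metrics["hemisphere_role"] = roles
    metric_results = [
        compare_metric_by_impairment(metrics, scores["impaired"], control_ids, t, v)
        for v in ("FA", "MD", "volume_mm3")
        for t in TRACTS
    ]
    comparison_to_frame(metric_results).to_csv(OUT / "metric_anovas.csv", index=False)

    lesioned = metrics[
        metrics["participant"].isin(stroke_ids)
        & (metrics["hemisphere_role"] == "lesioned")
    ]
    reg = regression_table(lesioned, task.loc[stroke_ids])
    reg.to_csv(OUT / "regressions.csv", index=False)
    fa = reg[reg["metric"] == "FA"]
    print("FA -> Task Score regressions (lesioned hemisphere):")
    for row in fa.itertuples(index=False):
        star = " *" if row.bh_significant else ""
        print(f"  {row.tract}: intercept {row.intercept:.2f}, "
              f"coefficient {row.coefficient:.2f}, p = {row.p:.4f}{star}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
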