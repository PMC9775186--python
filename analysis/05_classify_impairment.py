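"""Classify impairment from the 38-feature anatomy table.

Seed-volume-normalized, symmetrized lesioned-hemisphere connectivity (28
ROI pairs) plus lesioned-hemisphere FA/MD for the five tracts feed the
three-model logistic cascade: all features, univariate Spearman pruning
(plus premotor/SMA manual exclusions), and recursive feature elimination.
Writes features.csv, classifier_report.json and per-model importance
tables under results/study/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from propriomap.classify import SelectionConfig, run_cascade
from propriomap.connectivity import (
    assemble_features, normalize_streamlines, symmetrize,
)
from propriomap.synthetic import connectomes_from_csv, demographics_from_csv

SEED = 0
OUT = Path("results/study")


def main() -> int:
    demos = demographics_from_csv(OUT / "demographics.csv")
    scores = pd.read_csv(OUT / "scores.csv", index_col="participant")
    metrics = pd.read_csv(OUT / "tract_metrics.csv")
    connectomes, seed_volumes = connectomes_from_csv(OUT / "connectomes.csv")
    stroke_ids = [p for p, d in demos.items() if d.group == "stroke"]

    rows, conn = [], {}
    for pid in stroke_ids:
        hemi = demos[pid].lesioned_hemisphere
        sub = metrics[(metrics["participant"] == pid) & (metrics["hemisphere"] == hemi)]
        rows.append(sub[["participant", "tract", "FA", "MD"]])
        conn[pid] = symmetrize(
            normalize_streamlines(connectomes[(pid, hemi)], seed_volumes[pid])
        )
    features = assemble_features(
        pd.concat(rows), conn, scores["impaired"].loc[stroke_ids]
    )
    features.to_csv(OUT / "features.csv")

    reports = run_cascade(
        features.drop(columns="impaired"), features["impaired"],
        SelectionConfig(seed=SEED),
    )
    payload = {}
    print("classifier cascade (10-fold CV, impaired = positive class):")
    for name, rep in reports.items():
        payload[name] = {
            "n_features": rep.n_features,
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
            "top_features": rep.ranked_importance().head(5).index.tolist(),
        }
        rep.ranked_importance().rename("mean_coefficient").to_csv(
            OUT / f"importance_{name}.csv"
        )
        print(f"  {name}: accuracy {100 * rep.accuracy:.1f}%, "
              f"precision {100 * rep.precision:.1f}%, recall {100 * rep.recall:.1f}%, "
              f"F1 {rep.f1:.3f} ({rep.n_features} features)")
    with open(OUT / "classifier_report.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    top = reports["rfe"].ranked_importance().head(3).index.tolist()
    print(f"most important RFE features: {', '.join(top)}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
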