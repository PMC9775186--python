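"""Univariate group statistics.

One-way comparisons of Task Scores and diffusion metrics across lesion /
impairment groups, switching between classical ANOVA (Sidak-corrected
pairwise t post hocs) and Welch's ANOVA (Games-Howell post hocs) on a
median-centred Levene screen; plus per-tract metric -> Task Score linear
regressions with Benjamini-Hochberg correction across the five tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

HOMOGENEITY_ALPHA = 0.05


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak family-wise adjustment 1 - (1 - p)^m for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


@dataclass
class GroupComparisonResult:
    method: str  # anova_sidak | welch_games_howell
    F: float
    df1: float
    df2: float
    p: float
    levene_p: float
    posthoc: pd.DataFrame  # columns A, B, p_adj
    label: str = ""


@dataclass
class RegressionResult:
    predictor: str
    intercept: float
    slope: float
    p: float
    n: int
    bh_significant: bool | None = None
    degenerate: bool = False


def choose_and_run_anova(
    groups: dict[str, np.ndarray],
    alpha: float = HOMOGENEITY_ALPHA,
    label: str = "",
    method: str = "auto",
) -> GroupComparisonResult:
    """One-way comparison with a variance-homogeneity screen.

    Median-centred Levene (Brown-Forsythe) at ``alpha`` decides the branch:
    heterogeneous variances -> Welch's ANOVA with Games-Howell post hocs;
    otherwise classical ANOVA with Sidak-corrected pairwise t-tests.
    ``method`` can force either branch ("welch" / "classical").
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    df = pd.DataFrame(
        {
            "y": np.concatenate(arrays),
            "g": np.repeat(names, [a.size for a in arrays]),
        }
    )
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: no variance anywhere
        posthoc = pd.DataFrame(
            [(a, b, 1.0) for i, a in enumerate(names) for b in names[i + 1:]],
            columns=["A", "B", "p_adj"],
        )
        return GroupComparisonResult(
            method="anova_sidak", F=0.0, df1=len(names) - 1,
            df2=df.shape[0] - len(names), p=1.0, levene_p=1.0,
            posthoc=posthoc, label=label,
        )
    if method not in ("auto", "welch", "classical"):
        raise ValueError(f"unknown method {method!r}")
    levene_p = float(sps.levene(*arrays, center="median").pvalue)
    if method == "welch" or (method == "auto" and levene_p < alpha):
        aov = pg.welch_anova(data=df, dv="y", between="g")
        gh = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        posthoc = gh.rename(columns={"pval": "p_adj"})[["A", "B", "p_adj"]]
        return GroupComparisonResult(
            method="welch_games_howell",
            F=float(aov["F"].iloc[0]),
            df1=float(aov["ddof1"].iloc[0]),
            df2=float(aov["ddof2"].iloc[0]),
            p=float(aov["p_unc"].iloc[0]),
            levene_p=levene_p,
            posthoc=posthoc,
            label=label,
        )
    aov = pg.anova(data=df, dv="y", between="g", detailed=False)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw_p = [
        sps.ttest_ind(groups[a], groups[b], equal_var=True).pvalue for a, b in pairs
    ]
    posthoc = pd.DataFrame(
        {
            "A": [a for a, _ in pairs],
            "B": [b for _, b in pairs],
            "p_adj": sidak_adjust(np.array(raw_p), len(pairs)),
        }
    )
    return GroupComparisonResult(
        method="anova_sidak",
        F=float(aov["F"].iloc[0]),
        df1=float(aov["ddof1"].iloc[0]),
        df2=float(aov["ddof2"].iloc[0]),
        p=float(aov["p_unc"].iloc[0]),
        levene_p=levene_p,
        posthoc=posthoc,
        label=label,
    )


def compare_taskscores_by_lesion(
    task_scores: pd.Series,
    lesion_groups: pd.DataFrame,
    control_ids: list[str],
    tract: str,
) -> GroupComparisonResult:
    """Task Scores for (tract lesioned) vs (not lesioned) vs controls.

    ``lesion_groups`` is the per-participant x tract table from
    ``assign_lesion_groups``; controls form the third group.
    """
    sub = lesion_groups[lesion_groups["tract"] == tract]
    lesioned = sub.loc[sub["lesioned"], "participant"]
    non_lesioned = sub.loc[~sub["lesioned"], "participant"]
    groups = {
        "lesioned": task_scores.loc[lesioned].to_numpy(),
        "non_lesioned": task_scores.loc[non_lesioned].to_numpy(),
        "control": task_scores.loc[control_ids].to_numpy(),
    }
    for name, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"empty group {name!r} for tract {tract}")
    return choose_and_run_anova(groups, label=tract)


def compare_metric_by_impairment(
    metric: pd.DataFrame,
    impaired: pd.Series,
    control_ids: list[str],
    tract: str,
    value: str = "FA",
) -> GroupComparisonResult:
    """Six-group comparison of a tract metric.

    Groups: {impaired, unimpaired} x {lesioned, non-lesioned hemisphere}
    for stroke participants, plus control left and right hemispheres.
    ``metric`` needs columns participant, tract, hemisphere, ``value`` and
    a ``hemisphere_role`` column in {lesioned, non_lesioned, L, R}.
    """
    sub = metric[metric["tract"] == tract]
    groups: dict[str, np.ndarray] = {}
    stroke_ids = [p for p in impaired.index if p not in control_ids]
    for imp_label, imp_val in (("impaired", True), ("unimpaired", False)):
        ids = [p for p in stroke_ids if bool(impaired.loc[p]) == imp_val]
        for role in ("lesioned", "non_lesioned"):
            sel = sub[sub["participant"].isin(ids) & (sub["hemisphere_role"] == role)]
            groups[f"{imp_label}_{role}"] = sel[value].to_numpy()
    for hemi in ("L", "R"):
        sel = sub[sub["participant"].isin(control_ids) & (sub["hemisphere"] == hemi)]
        groups[f"control_{hemi}"] = sel[value].to_numpy()
    for name, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"missing hemisphere data for group {name!r}")
    return choose_and_run_anova(groups, label=f"{tract}:{value}")


def regress_metric_on_taskscore(
    metric: np.ndarray | pd.Series,
    task_scores: np.ndarray | pd.Series,
    predictor: str = "metric",
) -> RegressionResult:
    """OLS of Task Score on one metric with a two-sided slope p-value.

    Two points interpolate exactly; the p-value is then undefined and the
    result flagged degenerate.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(task_scores, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 complete (metric, task score) pairs")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return RegressionResult(
            predictor=predictor, intercept=float(y[0] - slope * x[0]),
            slope=float(slope), p=float("nan"), n=2, degenerate=True,
        )
    fit = sps.linregress(x, y)
    return RegressionResult(
        predictor=predictor,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        p=float(fit.pvalue),
        n=int(x.size),
    )


def bh_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR ``q``."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def regression_table(
    tract_metrics: pd.DataFrame,
    task_scores: pd.Series,
    metrics: tuple[str, ...] = ("FA", "MD", "volume_mm3"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-tract metric -> Task Score regressions, BH-corrected per metric family.

    ``tract_metrics`` holds lesioned-hemisphere values (columns participant,
    tract, and each metric).  BH runs across the five tracts within each
    metric family, mirroring a per-family false-discovery control.
    """
    rows = []
    for value in metrics:
        fam = []
        for tract, sub in tract_metrics.groupby("tract", sort=False):
            sub = sub.set_index("participant")
            common = sub.index.intersection(task_scores.index)
            res = regress_metric_on_taskscore(
                sub.loc[common, value], task_scores.loc[common],
                predictor=f"{value}_{tract}",
            )
            fam.append((tract, res))
        flags = bh_correct([r.p for _, r in fam], q=q)
        for (tract, res), flag in zip(fam, flags):
            res.bh_significant = bool(flag)
            rows.append(
                {
                    "tract": tract, "metric": value, "intercept": res.intercept,
                    "coefficient": res.slope, "p": res.p,
                    "bh_significant": res.bh_significant, "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def comparison_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label, "method": r.method, "F": r.F, "df1": r.df1,
                "df2": r.df2, "p": r.p, "levene_p": r.levene_p,
            }
        )
    return pd.DataFrame(rows)
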