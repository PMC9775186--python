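"""End-to-end synthetic study orchestration.

``run_all`` generates a normative cohort and a stroke study, scores every
exam, builds tract templates, quantifies lesion overlap, assembles the
anatomy feature table, runs the univariate statistics and the three-model
classifier cascade, and writes every intermediate artifact plus a machine
report (JSON) and a human summary (Markdown).  Given the same config, the
reports are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SelectionConfig, run_cascade
from .connectivity import assemble_features, normalize_streamlines, symmetrize
from .scoring import fit_normative_model, score_cohort
from .stats import (
    compare_metric_by_impairment, compare_taskscores_by_lesion,
    comparison_to_frame, regression_table,
)
from .synthetic import (
    HEMISPHERES, TRACTS, StudyConfig, simulate_normative_cohort, simulate_study,
)
from .tracts import (
    MaskVolume, assign_lesion_groups, build_template, lesion_overlap,
    overlaps_to_frame,
)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    n_stroke: int = 26
    n_control: int = 7
    normative_n: int = 300
    agreement_k: int = 6
    prob_threshold: float = 0.01
    noise_per_damage: float = 5.0
    contract_per_damage: float = 0.8
    shift_per_damage: float = 5.0
    fa_slope: float = 0.10
    md_slope: float = 1.5e-4
    vol_slope: float = 0.35
    streamline_loss: float = 0.6
    cv_folds: int = 10
    spearman_r_threshold: float = 0.7
    spearman_p_threshold: float = 0.05
    out_dir: str = "results/pipeline"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return validate_config(path)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def errors(self) -> list[str]:
        errs = []
        if self.n_control < 2:
            errs.append("n_control must be >= 2")
        if not 1 <= self.agreement_k <= self.n_control:
            errs.append(
                f"agreement_k={self.agreement_k} must lie in [1, n_control={self.n_control}]"
            )
        if not 0 < self.prob_threshold < 1:
            errs.append("prob_threshold must lie in (0, 1)")
        if self.cv_folds < 2:
            errs.append("cv_folds must be >= 2")
        if self.n_stroke < self.cv_folds:
            errs.append(
                f"n_stroke={self.n_stroke} must be >= cv_folds={self.cv_folds}"
            )
        if self.normative_n < 50:
            errs.append("normative_n must be >= 50 for a stable normative fit")
        for name in (
            "noise_per_damage", "contract_per_damage", "shift_per_damage",
            "fa_slope", "md_slope", "vol_slope", "streamline_loss",
        ):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be non-negative")
        if not 0 < self.spearman_r_threshold < 1:
            errs.append("spearman_r_threshold must lie in (0, 1)")
        if not 0 < self.spearman_p_threshold < 1:
            errs.append("spearman_p_threshold must lie in (0, 1)")
        return errs


def validate_config(path) -> RunConfig:
    """Load and validate a JSON config; empty files yield full defaults.

    Every problem (unknown key, out-of-range value) is collected and raised
    as one :class:`ConfigError` so a user sees the whole list at once.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    text = path.read_text().strip()
    payload = json.loads(text) if text else {}
    if not isinstance(payload, dict):
        raise ConfigError(["config must be a JSON object"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config key: {k!r}" for k in payload if k not in known]
    cfg = RunConfig(**{k: v for k, v in payload.items() if k in known})
    errors.extend(cfg.errors())
    if errors:
        raise ConfigError(errors)
    return cfg


@dataclass
class StudyReport:
    config: RunConfig
    lesion_group_sizes: dict[str, int]
    taskscore_anovas: pd.DataFrame
    metric_anovas: pd.DataFrame
    regressions: pd.DataFrame
    classifier: dict
    provenance: dict
    stage_log: list[str] = field(default_factory=list)


def _study_config(cfg: RunConfig) -> StudyConfig:
    return StudyConfig(
        n_stroke=cfg.n_stroke,
        n_control=cfg.n_control,
        agreement_k=cfg.agreement_k,
        noise_per_damage=cfg.noise_per_damage,
        contract_per_damage=cfg.contract_per_damage,
        shift_per_damage=cfg.shift_per_damage,
        fa_slope=cfg.fa_slope,
        md_slope=cfg.md_slope,
        vol_slope=cfg.vol_slope,
        streamline_loss=cfg.streamline_loss,
    )


def run_all(config: RunConfig, write_masks: bool = False) -> StudyReport:
    """Run every stage; artifacts land under ``config.out_dir``.

    NIfTI masks are only written when asked for (they are bulky and fully
    reproducible from the seed).
    """
    if config.errors():
        raise ConfigError(config.errors())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(f"{name}: ok")

    try:
        rng = np.random.default_rng(config.seed)
        norm_exams, _ = simulate_normative_cohort(config.normative_n, rng=rng)
        model = fit_normative_model(norm_exams)
        model.to_json(out / "normative_model.json")
        stage("normative")

        study = simulate_study(_study_config(config), rng=rng)
        from .synthetic import demographics_to_frame, exams_to_csv

        exams_to_csv(study.exams, out / "exams.csv")
        demographics_to_frame(study.demographics).to_csv(out / "demographics.csv")
        stage("simulate")

        scores = score_cohort(study.exams, model)
        scores.to_csv(out / "scores.csv")
        stage("score")

        vox = study.config.grid.voxel_size_mm
        templates = {}
        for (tract, hemi), masks in study.control_tract_masks.items():
            templates[(tract, hemi)] = build_template(
                [MaskVolume(m, vox) for m in masks], config.agreement_k,
                tract=tract, hemisphere=hemi,
            )
            if write_masks:
                templates[(tract, hemi)].mask.to_nifti(
                    out / f"template_{tract}_{hemi}.nii.gz"
                )
        stage("template")

        overlaps = []
        for pid in study.stroke_ids:
            hemi = study.demographics[pid].lesioned_hemisphere
            lesion = MaskVolume(study.lesion_masks[pid], vox)
            if write_masks:
                lesion.to_nifti(out / f"lesion_{pid}.nii.gz")
            for tract in TRACTS:
                overlaps.append(
                    lesion_overlap(templates[(tract, hemi)], lesion, participant=pid)
                )
        overlap_df = overlaps_to_frame(overlaps)
        groups = assign_lesion_groups(overlap_df)
        groups.to_csv(out / "lesion_overlap.csv", index=False)
        group_sizes = {
            t: int(groups[(groups["tract"] == t) & groups["lesioned"]].shape[0])
            for t in TRACTS
        }
        stage("overlap")

        # ---- univariate statistics ------------------------------------
        task = scores["task_score"]
        ts_results = [
            compare_taskscores_by_lesion(task, groups, study.control_ids, tract)
            for tract in TRACTS
        ]
        metric = study.tract_metrics.copy()
        roles = []
        for row in metric.itertuples(index=False):
            demo = study.demographics[row.participant]
            if demo.group == "control":
                roles.append(row.hemisphere)
            elif row.hemisphere == demo.lesioned_hemisphere:
                roles.append("lesioned")
            else:
                roles.append("non_lesioned")
        metric["hemisphere_role"] = roles
        impaired = scores["impaired"]
        metric_results = [
            compare_metric_by_impairment(
                metric, impaired, study.control_ids, tract, value=value
            )
            for value in ("FA", "MD", "volume_mm3")
            for tract in TRACTS
        ]
        ts_frame = comparison_to_frame(ts_results)
        metric_frame = comparison_to_frame(metric_results)
        ts_frame.to_csv(out / "taskscore_anovas.csv", index=False)
        metric_frame.to_csv(out / "metric_anovas.csv", index=False)

        lesioned_metrics = metric[
            metric["participant"].isin(study.stroke_ids)
            & (metric["hemisphere_role"] == "lesioned")
        ]
        regressions = regression_table(lesioned_metrics, task.loc[study.stroke_ids])
        regressions.to_csv(out / "regressions.csv", index=False)
        stage("stats")

        # ---- features and classification ------------------------------
        conn = {}
        for pid in study.stroke_ids:
            hemi = study.demographics[pid].lesioned_hemisphere
            directed = normalize_streamlines(
                study.connectomes[(pid, hemi)], study.seed_volumes[pid]
            )
            conn[pid] = symmetrize(directed)
        features = assemble_features(
            lesioned_metrics[["participant", "tract", "FA", "MD"]],
            conn,
            impaired.loc[study.stroke_ids],
        )
        features.to_csv(out / "features.csv")
        if features["impaired"].nunique() < 2:
            # a null run can leave everyone (un)impaired; classification is
            # then undefined rather than an error
            classifier = {
                "skipped": "single-class outcome: "
                f"{int(features['impaired'].sum())}/{len(features)} impaired"
            }
        else:
            sel = SelectionConfig(
                cv_folds=config.cv_folds,
                spearman_r_threshold=config.spearman_r_threshold,
                spearman_p_threshold=config.spearman_p_threshold,
                seed=config.seed,
            )
            reports = run_cascade(
                features.drop(columns="impaired"), features["impaired"], sel
            )
            classifier = {
                name: {
                    "n_features": r.n_features,
                    "accuracy": r.accuracy,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f1": r.f1,
                    "top_features": r.ranked_importance().head(5).index.tolist(),
                }
                for name, r in reports.items()
            }
            for name, r in reports.items():
                r.ranked_importance().rename("mean_coefficient").to_csv(
                    out / f"importance_{name}.csv"
                )
        stage("classify")
    except ConfigError:
        raise
    except Exception as exc:  # annotate which stage blew up
        failed = ["normative", "simulate", "score", "template", "overlap",
                  "stats", "classify"][len(log)]
        raise RuntimeError(f"stage {failed!r} failed under {out}: {exc}") from exc

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
    }
    report = StudyReport(
        config=config,
        lesion_group_sizes=group_sizes,
        taskscore_anovas=ts_frame,
        metric_anovas=metric_frame,
        regressions=regressions,
        classifier=classifier,
        provenance=provenance,
        stage_log=log,
    )
    _write_report(report, out)
    return report


def _write_report(report: StudyReport, out: Path) -> None:
    payload = {
        "config": report.config.to_dict(),
        "provenance": report.provenance,
        "lesion_group_sizes": report.lesion_group_sizes,
        "taskscore_anovas": report.taskscore_anovas.to_dict(orient="records"),
        "metric_anovas": report.metric_anovas.to_dict(orient="records"),
        "regressions": report.regressions.to_dict(orient="records"),
        "classifier": report.classifier,
        "stages": report.stage_log,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)

    lines = ["# Synthetic study report", ""]
    lines.append(f"seed {report.provenance['seed']}, config {report.provenance['config_hash']}")
    lines.append("")
    lines.append("## Lesion group sizes")
    for t, n in report.lesion_group_sizes.items():
        lines.append(f"- {t}: {n} lesioned")
    lines.append("")
    lines.append("## Task Score ANOVAs (per tract)")
    for row in report.taskscore_anovas.itertuples(index=False):
        lines.append(
            f"- {row.label}: {row.method} F({row.df1:.0f}, {row.df2:.2f}) = "
            f"{row.F:.2f}, p = {row.p:.2e}"
        )
    lines.append("")
    lines.append("## Classifier cascade")
    for name, rec in report.classifier.items():
        lines.append(
            f"- {name}: accuracy {100 * rec['accuracy']:.1f}% "
            f"({rec['n_features']} features)"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")


def demo_config(seed: int = 0, out_dir: str = "results/demo") -> RunConfig:
    """The demo scenario: 26 stroke / 7 controls with the emulated per-tract
    lesion counts and default couplings."""
    return RunConfig(seed=seed, out_dir=out_dir)
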