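"""APM exam scoring: raw parameters, normative z-scores, zeta-scores, Task Score.

The scoring chain follows the Kinarm-style normative pipeline for the arm
position matching task:

1. Eight raw spatial parameters from the 54 trials (absolute error,
   variability, contraction/expansion, shift; each on x and y).
2. Per-parameter z-scores against a normative regression on age, sex and
   handedness (contraction ratios are log-transformed first).
3. Zeta-scores: one-sided rescaling so that best-possible performance maps
   to 0 and the healthy 95th percentile of badness to 1.96.
4. Task Score: root-sum-square of the eight zetas, Box-Cox normalised
   against the normative cohort, and zeta-transformed once more.

A Task Score >= 1.96 flags impairment (95% of healthy controls fall below).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .synthetic import ApmExam, Demographics

PARAMETERS = (
    "abs_err_x", "abs_err_y",
    "var_x", "var_y",
    "contract_x", "contract_y",
    "shift_x", "shift_y",
)

#: one_sided_high: only large values are abnormal (errors, variability).
#: two_sided: deviation in either direction is abnormal (shift; log-ratio
#: contraction, since both shrinkage and enlargement are bad).
DEFAULT_SIDEDNESS = {
    "abs_err_x": "one_sided_high",
    "abs_err_y": "one_sided_high",
    "var_x": "one_sided_high",
    "var_y": "one_sided_high",
    "contract_x": "two_sided",
    "contract_y": "two_sided",
    "shift_x": "two_sided",
    "shift_y": "two_sided",
}

LOG_PARAMETERS = ("contract_x", "contract_y")

IMPAIRMENT_CUTOFF = 1.96

_COVARIATE_COLUMNS = ("intercept", "age", "sex_M", "hand_L", "hand_A")


def _design_row(demo: Demographics) -> np.ndarray:
    return np.array(
        [
            1.0,
            demo.age,
            1.0 if demo.sex == "M" else 0.0,
            1.0 if demo.handedness == "L" else 0.0,
            1.0 if demo.handedness == "A" else 0.0,
        ]
    )


# ---------------------------------------------------------------------------
# raw parameters
# ---------------------------------------------------------------------------

def compute_parameter_scores(exam: ApmExam) -> dict[str, float]:
    """Eight raw APM parameters from one exam.

    Matched positions are first mirrored about the midline so they live in
    the target workspace.  With mirrored matches ``m`` and targets ``t``:

    - abs_err_a: mean over trials of ``|m_a - t_a|`` (cm)
    - var_a: mean over the 9 targets of the per-target SD of ``m_a`` across
      that target's trials (cm)
    - contract_a: range of the 9 per-target mean ``m_a`` divided by the
      range of the 9 target coordinates (unitless)
    - shift_a: mean over trials of ``m_a - t_a`` (signed, cm)
    """
    t = exam.trials
    counts = t.groupby("target_index").size()
    if (counts < 2).any():
        raise ValueError("variability needs at least 2 trials per target")
    m = pd.DataFrame(
        {
            "target_index": t["target_index"],
            "x": 2.0 * exam.midline_x - t["matched_x"],
            "y": t["matched_y"].to_numpy(),
        }
    )
    out: dict[str, float] = {}
    for a in ("x", "y"):
        tgt = t[f"target_{a}"].to_numpy()
        mat = m[a].to_numpy()
        err = mat - tgt
        per_target_sd = m.groupby("target_index")[a].std(ddof=1)
        per_target_mean = m.groupby("target_index")[a].mean()
        tgt_by_index = t.groupby("target_index")[f"target_{a}"].first()
        out[f"abs_err_{a}"] = float(np.mean(np.abs(err)))
        out[f"var_{a}"] = float(per_target_sd.mean())
        out[f"contract_{a}"] = float(
            (per_target_mean.max() - per_target_mean.min())
            / (tgt_by_index.max() - tgt_by_index.min())
        )
        out[f"shift_{a}"] = float(np.mean(err))
    return out


# ---------------------------------------------------------------------------
# normative model
# ---------------------------------------------------------------------------

@dataclass
class ParameterModel:
    transform: str  # identity | log
    coefficients: dict[str, float]  # keyed by _COVARIATE_COLUMNS
    residual_sd: float
    sidedness: str  # one_sided_high | two_sided

    def pre_transform(self, raw: float) -> float:
        if self.transform == "log":
            if raw <= 0:
                raise ValueError("log pre-transform requires a positive raw score")
            return float(np.log(raw))
        return float(raw)

    def predict(self, demo: Demographics) -> float:
        beta = np.array([self.coefficients[c] for c in _COVARIATE_COLUMNS])
        return float(_design_row(demo) @ beta)


@dataclass
class NormativeModel:
    """Per-parameter covariate regressions plus the RSS Box-Cox stage."""

    parameters: dict[str, ParameterModel]
    boxcox_lambda: float
    boxcox_shift: float
    rss_mean: float
    rss_sd: float
    n_fit: int
    sidedness: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SIDEDNESS))

    def to_json(self, path) -> None:
        payload = {
            "parameters": {
                name: {
                    "transform": pm.transform,
                    "coefficients": pm.coefficients,
                    "residual_sd": pm.residual_sd,
                    "sidedness": pm.sidedness,
                }
                for name, pm in self.parameters.items()
            },
            "boxcox_lambda": self.boxcox_lambda,
            "boxcox_shift": self.boxcox_shift,
            "rss_mean": self.rss_mean,
            "rss_sd": self.rss_sd,
            "n_fit": self.n_fit,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormativeModel":
        with open(path) as fh:
            payload = json.load(fh)
        params = {
            name: ParameterModel(
                transform=d["transform"],
                coefficients=d["coefficients"],
                residual_sd=d["residual_sd"],
                sidedness=d["sidedness"],
            )
            for name, d in payload["parameters"].items()
        }
        return cls(
            parameters=params,
            boxcox_lambda=payload["boxcox_lambda"],
            boxcox_shift=payload["boxcox_shift"],
            rss_mean=payload["rss_mean"],
            rss_sd=payload["rss_sd"],
            n_fit=payload["n_fit"],
            sidedness={n: p.sidedness for n, p in params.items()},
        )


def fit_normative_model(
    exams: list[ApmExam],
    min_n: int = 50,
) -> NormativeModel:
    """Fit the normative scoring model on a healthy cohort.

    Per parameter: OLS of the (pre-transformed) raw score on age, sex and
    handedness indicators; the residual SD becomes the z-score denominator.
    Then the cohort's own zeta vectors are collapsed to RSS values, shifted
    strictly positive, Box-Cox transformed with maximum-likelihood lambda,
    and the post-transform mean/SD stored so the fitting sample itself is
    standard normal at the RSS stage.
    """
    n = len(exams)
    if n < min_n:
        raise ValueError(f"normative fit needs n >= {min_n}, got {n}")

    raw = pd.DataFrame([compute_parameter_scores(e) for e in exams])
    X = np.vstack([_design_row(e.demographics) for e in exams])
    rank = np.linalg.matrix_rank(X)

    params: dict[str, ParameterModel] = {}
    zetas = np.empty((n, len(PARAMETERS)))
    for j, name in enumerate(PARAMETERS):
        transform = "log" if name in LOG_PARAMETERS else "identity"
        y = raw[name].to_numpy()
        if transform == "log":
            if (y <= 0).any():
                raise ValueError(f"{name}: log pre-transform requires positive values")
            y = np.log(y)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - rank
        resid_sd = float(np.sqrt(resid @ resid / dof))
        if resid_sd <= 0:
            raise ValueError(f"{name}: non-positive residual variance")
        pm = ParameterModel(
            transform=transform,
            coefficients={c: float(b) for c, b in zip(_COVARIATE_COLUMNS, beta)},
            residual_sd=resid_sd,
            sidedness=DEFAULT_SIDEDNESS[name],
        )
        params[name] = pm
        zetas[:, j] = zeta_transform(resid / resid_sd, pm.sidedness)

    rss = np.sqrt((zetas**2).sum(axis=1))
    shift = 1e-6 + max(0.0, -float(rss.min()))
    transformed, lam = stats.boxcox(rss + shift)
    return NormativeModel(
        parameters=params,
        boxcox_lambda=float(lam),
        boxcox_shift=shift,
        rss_mean=float(transformed.mean()),
        rss_sd=float(transformed.std(ddof=1)),
        n_fit=n,
    )


# ---------------------------------------------------------------------------
# scoring chain
# ---------------------------------------------------------------------------

def z_score_parameters(
    raw: dict[str, float], demographics: Demographics, model: NormativeModel
) -> dict[str, float]:
    """z = (pre-transformed raw - covariate prediction) / residual SD."""
    z = {}
    for name, pm in model.parameters.items():
        z[name] = (pm.pre_transform(raw[name]) - pm.predict(demographics)) / pm.residual_sd
    return z


def zeta_transform(z, sidedness: str):
    """Fold a z-score into non-negative 'badness' units.

    two_sided: zeta = |z| (deviations in either direction count equally).
    one_sided_high: zeta = ndtri((1 + ndtr(z)) / 2), mapping the normative
    median to ~0.674, the 95th percentile to 1.96 and -inf to 0.

    Total function: accepts scalars or arrays, never raises.
    """
    z = np.asarray(z, dtype=float)
    if sidedness == "two_sided":
        out = np.abs(z)
    elif sidedness == "one_sided_high":
        # ndtri((1 + ndtr(z)) / 2) computed via the upper tail for
        # numerical stability; once the tail underflows (z > ~37) switch to
        # the asymptotic isf(p/2)^2 = isf(p)^2 + 2 ln 2.
        with np.errstate(divide="ignore"):
            tail = ndtr(-z) / 2.0
            out = np.where(tail > 0, -ndtri(tail), np.sqrt(z * z + 2.0 * np.log(2.0)))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TaskScoreResult:
    rss: float
    task_score: float
    impaired: bool


def task_score(zetas: dict[str, float] | np.ndarray, model: NormativeModel) -> TaskScoreResult:
    """Collapse the eight zeta scores into the normative Task Score.

    rss = sqrt(sum zeta^2); Box-Cox with the model's lambda/shift and
    standardisation by the normative mean/SD gives an RSS z-score, which is
    folded one-sided so 0 is the best possible score and >= 1.96 flags
    impairment.
    """
    if isinstance(zetas, dict):
        vec = np.array([zetas[p] for p in PARAMETERS], dtype=float)
    else:
        vec = np.asarray(zetas, dtype=float)
    if vec.shape != (len(PARAMETERS),):
        raise ValueError(f"expected {len(PARAMETERS)} zeta scores")
    rss = float(np.sqrt((vec**2).sum()))
    shifted = rss + model.boxcox_shift
    if shifted <= 0:
        raise ValueError("rss + shift must be positive for Box-Cox")
    z_rss = (stats.boxcox(shifted, lmbda=model.boxcox_lambda) - model.rss_mean) / model.rss_sd
    ts = zeta_transform(z_rss, "one_sided_high")
    return TaskScoreResult(rss=rss, task_score=ts, impaired=bool(ts >= IMPAIRMENT_CUTOFF))


def score_exam(exam: ApmExam, model: NormativeModel) -> dict:
    """Full scoring record for one exam: raw, z, zeta, rss, Task Score."""
    raw = compute_parameter_scores(exam)
    z = z_score_parameters(raw, exam.demographics, model)
    zeta = {p: zeta_transform(z[p], model.parameters[p].sidedness) for p in PARAMETERS}
    res = task_score(zeta, model)
    rec = {"participant": exam.participant_id}
    rec.update({f"raw_{p}": raw[p] for p in PARAMETERS})
    rec.update({f"z_{p}": z[p] for p in PARAMETERS})
    rec.update({f"zeta_{p}": zeta[p] for p in PARAMETERS})
    rec.update({"rss": res.rss, "task_score": res.task_score, "impaired": res.impaired})
    return rec


def score_cohort(exams, model: NormativeModel) -> pd.DataFrame:
    """Score many exams; returns one row per participant."""
    if isinstance(exams, dict):
        exams = list(exams.values())
    return pd.DataFrame([score_exam(e, model) for e in exams]).set_index("participant")
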