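"""Subject-level models linking circuit connectivity to diagnosis and
treatment response, plus simple group comparisons from the lesion study.

These are ordinary linear models fit by least squares (statsmodels OLS).
The association model follows the convention of treating within-circuit
connectivity as the response and diagnosis flags as predictors; a logistic
alternative with diagnosis as the response is available for sensitivity.
The trial analysis implements the two-timepoint group x connectivity-change
interaction as a change-score regression, with an optional random-intercept
backend that must agree on the interaction t statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateDataError

logger = logging.getLogger(__name__)

#: BDI score at or above which depression is considered active
BDI_DEPRESSION_THRESHOLD = 20


@dataclass
class ModelResult:
    """One model term: coefficient, t, two-sided p, residual df."""

    term: str
    coef: float
    t: float
    p: float
    df: float
    model: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.model}: {self.term} coef={self.coef:.4g} "
                f"t={self.t:.2f} p={self.p:.3g} (df={self.df:.0f})")


@dataclass
class PrevalenceRecord:
    """Symptom/diagnosis prevalence from ordinal 0/1/2 outcome counts."""

    symptom_pct: float    # fraction with score >= 1 ("PTSD symptoms")
    diagnosis_pct: float  # fraction with score == 2 ("PTSD diagnosis")
    n: int

    @property
    def symptom_pct_rounded(self) -> int:
        return int(round(self.symptom_pct))

    @property
    def diagnosis_pct_rounded(self) -> int:
        return int(round(self.diagnosis_pct))


def prevalence_from_counts(counts: Mapping[int, int]) -> PrevalenceRecord:
    """Prevalence percentages from a {score: count} mapping (scores 0/1/2)."""
    n0 = int(counts.get(0, 0))
    n1 = int(counts.get(1, 0))
    n2 = int(counts.get(2, 0))
    if min(n0, n1, n2) < 0:
        raise ValueError("counts must be non-negative")
    total = n0 + n1 + n2
    if total == 0:
        raise ValueError("total count must be positive")
    return PrevalenceRecord(symptom_pct=100.0 * (n1 + n2) / total,
                            diagnosis_pct=100.0 * n2 / total, n=total)


@dataclass
class GroupTestResult(ModelResult):
    prevalence_a: PrevalenceRecord | None = None
    prevalence_b: PrevalenceRecord | None = None


def group_score_test(scores_a: np.ndarray, scores_b: np.ndarray) -> GroupTestResult:
    """Two-sample pooled-variance t for mean(a) - mean(b) on outcome scores.

    When the scores are ordinal 0/1/2, per-group symptom and diagnosis
    prevalence summaries are reported alongside the test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    ssa = float(((a - a.mean()) ** 2).sum())
    ssb = float(((b - b.mean()) ** 2).sum())
    sp2 = (ssa + ssb) / df
    if sp2 == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    elif sp2 == 0:
        # constant groups with different means: perfect separation,
        # capped like the VLSM rule so p stays in (0, 1]
        t = float(np.sign(a.mean() - b.mean()) * 100.0)
        p = float(2 * sps.t.sf(100.0, df))
    else:
        t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b))))
        p = float(2 * sps.t.sf(abs(t), df))
    def prev(x: np.ndarray) -> PrevalenceRecord | None:
        if set(np.unique(x)) <= {0.0, 1.0, 2.0}:
            vals, cnts = np.unique(x, return_counts=True)
            return prevalence_from_counts({int(v): int(c) for v, c in zip(vals, cnts)})
        return None
    return GroupTestResult(term="group", coef=float(a.mean() - b.mean()), t=t,
                           p=p, df=df, model="unpaired t-test",
                           prevalence_a=prev(a), prevalence_b=prev(b))


# ---------------------------------------------------------------------------
# record handling
# ---------------------------------------------------------------------------

def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r
                           for r in records])
    # the depression flag is always recomputed from BDI when BDI is present
    if "BDI" in df.columns:
        df["depression"] = (df["BDI"] >= BDI_DEPRESSION_THRESHOLD).astype(int)
    return df


def _ols_term(y: np.ndarray, X: pd.DataFrame, term: str, model_name: str) -> ModelResult:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy(dtype=float)) < Xc.shape[1]:
        raise DegenerateDataError(f"collinear design in {model_name}")
    fit = sm.OLS(np.asarray(y, dtype=float), Xc).fit()
    return ModelResult(term=term, coef=float(fit.params[term]),
                       t=float(fit.tvalues[term]), p=float(fit.pvalues[term]),
                       df=float(fit.df_resid), model=model_name)


def circuit_association_model(records, outcome: str = "ptsd",
                              predictor: str = "circuit_z",
                              covariate_flags: Sequence[str] = ("tbi", "depression"),
                              logistic: bool = False) -> ModelResult:
    """Association between within-circuit connectivity and diagnosis.

    Default direction: connectivity as response, diagnosis flags as
    predictors — ``circuit_z ~ 1 + ptsd + covariates`` — returning the
    diagnosis term.  ``logistic=True`` fits the reversed sensitivity model
    ``ptsd ~ 1 + circuit_z + covariates`` by logit and returns the
    connectivity term (z statistic reported in the t slot).
    """
    df = _as_frame(records)
    n = len(df)
    if n < len(covariate_flags) + 3:
        raise ValueError("too few records for the requested covariates")
    if logistic:
        X = sm.add_constant(df[[predictor, *covariate_flags]].astype(float))
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise DegenerateDataError("collinear design in logistic association model")
        fit = sm.Logit(df[outcome].astype(float), X).fit(disp=0)
        return ModelResult(term=predictor, coef=float(fit.params[predictor]),
                           t=float(fit.tvalues[predictor]),
                           p=float(fit.pvalues[predictor]),
                           df=float(n - X.shape[1]), model="logit association")
    X = df[[outcome, *covariate_flags]].astype(float)
    return _ols_term(df[predictor].to_numpy(dtype=float), X, outcome,
                     "rsFC ~ diagnosis + covariates")


def specificity_rank_model(records, outcome: str,
                           target_scalar: str,
                           control_scalars: Sequence[str]) -> pd.DataFrame:
    """Rank-transformed joint and marginal models across connectivity scalars.

    Every connectivity scalar is rank-transformed (average ranks on ties).
    The joint model regresses the diagnosis flag's association on the target
    plus all controls simultaneously; marginal models fit each scalar alone
    for the |t| comparison.  Returns one row per scalar with joint and
    marginal t statistics; the target row is flagged.
    """
    if target_scalar in control_scalars:
        raise DegenerateDataError("target duplicated among controls (collinear)")
    df = _as_frame(records)
    scalars = [target_scalar, *control_scalars]
    if len(scalars) < 2:
        raise ValueError("need at least 2 connectivity scalars")
    if len(df) <= len(scalars) + 3:
        raise ValueError("too few records for the number of predictors")
    ranked = df[scalars].rank(method="average")
    y = df[outcome].astype(float).to_numpy()
    rows = []
    for name in scalars:
        marg = _ols_term(ranked[name].to_numpy(), pd.DataFrame({outcome: y}),
                         outcome, "marginal rank model")
        joint = _ols_term(ranked[name].to_numpy(),
                          pd.DataFrame({outcome: y,
                                        **{c: ranked[c] for c in scalars if c != name}}),
                          outcome, "joint rank model")
        rows.append({"scalar": name, "is_target": name == target_scalar,
                     "marginal_t": marg.t, "marginal_p": marg.p,
                     "joint_t": joint.t, "joint_p": joint.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TMS trial interaction
# ---------------------------------------------------------------------------

def _trial_frame(trial) -> pd.DataFrame:
    df = _as_frame(trial)
    required = {"arm", "pre_circuit_z", "post_circuit_z", "pre_pcl5", "post_pcl5"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial records lack columns: {sorted(missing)}")
    for col in ("pre_pcl5", "post_pcl5"):
        if ((df[col] < 0) | (df[col] > 80)).any():
            raise ValueError("PCL-5 scores must lie in [0, 80]")
    return df


def tms_interaction_model(trial, control_depression: bool = True,
                          extra_covariates: Sequence[str] = (),
                          percent_change: bool = True,
                          backend: str = "ols") -> ModelResult:
    """Group x connectivity-change interaction on PTSD improvement.

    Computes per subject the within-circuit connectivity change
    (post - pre) and the percent PCL-5 improvement 100*(pre - post)/pre,
    then fits ``improvement ~ arm + dconn + arm:dconn [+ dIDS] [+ extras]``
    and returns the interaction term.  ``backend="mixed"`` fits the
    equivalent two-timepoint random-intercept model and reports the same
    interaction; both backends agree on the interaction t.
    """
    df = _trial_frame(trial)
    arms = set(df["arm"])
    if arms != {"active", "sham"}:
        raise ValueError("trial must contain both an active and a sham arm")
    if (df.groupby("arm").size() < 3).any():
        raise ValueError("each arm needs at least 3 subjects")
    if percent_change and (df["pre_pcl5"] == 0).any():
        raise ValueError("pre-treatment PCL-5 of 0: percent change undefined")
    active = (df["arm"] == "active").astype(float)
    dconn = (df["post_circuit_z"] - df["pre_circuit_z"]).astype(float)
    if dconn.groupby(df["arm"]).std(ddof=0).min() == 0:
        raise DegenerateDataError("connectivity change constant within an arm")
    if percent_change:
        dy = 100.0 * (df["pre_pcl5"] - df["post_pcl5"]) / df["pre_pcl5"]
    else:
        dy = df["pre_pcl5"] - df["post_pcl5"]
    X = pd.DataFrame({"arm": active, "dconn": dconn, "arm_x_dconn": active * dconn})
    if control_depression:
        if not {"pre_ids", "post_ids"} <= set(df.columns):
            raise ValueError("control_depression requires pre_ids/post_ids columns")
        X["d_ids"] = (df["post_ids"] - df["pre_ids"]).astype(float)
    for cov in extra_covariates:
        if cov == "STAI":
            X["d_stai"] = (df["post_stai"] - df["pre_stai"]).astype(float)
        else:
            X[cov] = df[cov].astype(float)
    if backend == "ols":
        return _ols_term(dy.to_numpy(dtype=float), X, "arm_x_dconn",
                         "change-score interaction")
    if backend == "mixed":
        # two-timepoint random-intercept model: the subject trajectory is
        # (baseline, post) with every covariate entered both as a main
        # effect (saturating the between-subject space) and interacted with
        # time, so the time x arm x dconn coefficient equals the
        # change-score interaction; t and coef are sign-flipped to the
        # improvement direction used by the OLS backend
        import warnings
        n = len(df)
        if percent_change:
            traj = np.column_stack([np.full(n, 100.0),
                                    100.0 * df["post_pcl5"] / df["pre_pcl5"]])
        else:
            traj = np.column_stack([df["pre_pcl5"], df["post_pcl5"]])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "time": np.tile([0.0, 1.0], n),
            "y": traj.ravel(),
        })
        for name, col in X.items():
            vals = np.repeat(col.to_numpy(dtype=float), 2)
            long[f"{name}_main"] = vals
            long[name] = vals * long["time"]
        fixed = sm.add_constant(long[["time",
                                      *(f"{c}_main" for c in X.columns),
                                      *X.columns]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(long["y"], fixed, groups=long["subject"]).fit(reml=True)
        return ModelResult(term="arm_x_dconn", coef=-float(fit.params["arm_x_dconn"]),
                           t=-float(fit.tvalues["arm_x_dconn"]),
                           p=float(fit.pvalues["arm_x_dconn"]),
                           df=float(n - X.shape[1] - 1),
                           model="mixed interaction")
    raise ValueError("backend must be 'ols' or 'mixed'")
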