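"""Longitudinal progression of composite network scores and prediction of
clinical severity from regional expression.

The longitudinal model is a general linear model with timepoint as a
categorical factor and subject as a blocking factor (so any per-subject
constant is absorbed), followed by paired contrasts of each follow-up against
baseline with Bonferroni correction over the number of contrasts.  Subjects
may miss timepoints: each contrast uses the subjects having both baseline and
that follow-up, while the omnibus fit uses all available rows.

Clinical prediction regresses a severity score (CDRSB) on the selected
regions' local expression scores, trained on half the subjects and evaluated
on the other half; association is summarized by Pearson correlation between
predicted and observed scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "LongitudinalResult",
    "ClinicalPrediction",
    "longitudinal_glm",
    "fit_clinical_regression",
    "correlate",
]

log = logging.getLogger(__name__)


@dataclass
class LongitudinalResult:
    group: str
    f_stat: float
    df_num: float
    df_den: float
    p_omnibus: float
    contrasts: pd.DataFrame = field(repr=False)  # months, n, mean_change, t, p_raw, p_corrected


def longitudinal_glm(scores: pd.DataFrame, group: str = "") -> LongitudinalResult:
    """Blocked GLM of longitudinal composite scores.

    ``scores`` needs columns ``subject_id``, ``months``, ``score`` with months
    0 as baseline.  With exactly two timepoints and complete data the omnibus
    F equals the square of the paired t statistic.
    """
    required = {"subject_id", "months", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    months = np.sort(scores["months"].unique())
    if len(months) < 2:
        raise ValueError("need at least two timepoints")
    if 0 not in months:
        raise ValueError("baseline (months == 0) is required")

    df = scores.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    model = smf.ols("score ~ C(subject_id) + C(months)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc["C(months)"]
    f_stat = float(row["F"])
    df_num = float(row["df"])
    df_den = float(anova.loc["Residual", "df"])
    p_omnibus = float(row["PR(>F)"])

    base = df[df["months"] == 0].set_index("subject_id")["score"]
    contrasts = []
    followups = [m for m in months if m != 0]
    for m in followups:
        at_m = df[df["months"] == m].set_index("subject_id")["score"]
        common = base.index.intersection(at_m.index)
        if len(common) < 2:
            contrasts.append({"months": int(m), "n": len(common), "mean_change": np.nan,
                              "t": np.nan, "p_raw": np.nan, "p_corrected": np.nan})
            continue
        diff = (at_m.loc[common] - base.loc[common]).to_numpy(float)
        t, p = stats.ttest_1samp(diff, 0.0)
        contrasts.append({"months": int(m), "n": int(len(common)),
                          "mean_change": float(diff.mean()), "t": float(t),
                          "p_raw": float(p),
                          "p_corrected": float(min(1.0, p * len(followups)))})
    return LongitudinalResult(group=group, f_stat=f_stat, df_num=df_num,
                              df_den=df_den, p_omnibus=p_omnibus,
                              contrasts=pd.DataFrame(contrasts))


@dataclass
class ClinicalPrediction:
    coefficients: pd.Series = field(repr=False)   # per region, plus "intercept"
    predictions: pd.DataFrame = field(repr=False)  # scan_id, role, predicted, observed
    r_train: float = np.nan
    p_train: float = np.nan
    r_test: float = np.nan
    p_test: float = np.nan
    regularized: bool = False


def fit_clinical_regression(expression: pd.DataFrame, clinical: pd.Series,
                            train_fraction: float = 0.5, seed: int = 0,
                            train_ids: list[str] | None = None,
                            n_components: int = 2) -> ClinicalPrediction:
    """Linear prediction of a clinical score from regional expression.

    Coefficients are estimated on the training rows only (a seeded half split
    unless ``train_ids`` is given).  Plain least squares is used when the
    training rows comfortably outnumber predictors; otherwise — regions
    typically rival subjects in number here — the fit falls back to
    principal-component regression on the leading ``n_components`` training
    components, the classical stabilization in the covariance-pattern
    literature this regression descends from.
    """
    clinical = clinical.loc[expression.index]
    mask_finite = clinical.notna()
    expression, clinical = expression.loc[mask_finite], clinical.loc[mask_finite]
    ids = list(expression.index)
    if train_ids is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC11]))
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        train_ids = [ids[i] for i in perm[:n_train]]
    train_mask = expression.index.isin(train_ids)
    if train_mask.sum() < 3:
        raise ValueError("need at least 3 training rows")

    Xtr = expression.loc[train_mask].to_numpy(float)
    ytr = clinical.loc[train_mask].to_numpy(float)
    n_tr, p = Xtr.shape
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Ztr = (Xtr - mu) / sd

    regularized = p >= int(np.ceil(n_tr / 2)) or np.linalg.matrix_rank(Ztr) < p
    if regularized:
        log.info("clinical regression: %d predictors vs %d training rows; "
                 "principal-component fallback", p, n_tr)
        k = max(1, min(n_components, n_tr - 2, p))
        _, _, vt = np.linalg.svd(Ztr, full_matrices=False)
        v = vt[:k].T
        w = Ztr @ v
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(n_tr), w]), ytr, rcond=None)
        intercept, beta = float(coef[0]), v @ coef[1:]
    else:
        design = np.column_stack([np.ones(n_tr), Ztr])
        coef, *_ = np.linalg.lstsq(design, ytr, rcond=None)
        intercept, beta = float(coef[0]), coef[1:]

    Zall = (expression.to_numpy(float) - mu) / sd
    pred = intercept + Zall @ beta
    out = pd.DataFrame({
        "predicted": pred,
        "observed": clinical.to_numpy(float),
        "role": np.where(train_mask, "train", "test"),
    }, index=expression.index)

    def _corr(role: str) -> tuple[float, float]:
        sub = out[out["role"] == role]
        if len(sub) < 3:
            return np.nan, np.nan
        return correlate(sub["predicted"].to_numpy(), sub["observed"].to_numpy())

    r_tr, p_tr = _corr("train")
    r_te, p_te = _corr("test")
    coefs = pd.Series(np.concatenate([[intercept], beta]),
                      index=["intercept"] + list(expression.columns))
    return ClinicalPrediction(coefficients=coefs, predictions=out,
                              r_train=r_tr, p_train=p_tr, r_test=r_te, p_test=p_te,
                              regularized=bool(regularized))


def correlate(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value (t
    transform on n-2 degrees of freedom)."""
    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
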