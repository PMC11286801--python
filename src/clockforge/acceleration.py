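"""Age acceleration and group comparisons of epigenetic aging.

Age acceleration is the residual from an ordinary least-squares regression
of DNAm age on chronological age; a positive residual means a sample is
epigenetically older than its chronological age predicts. Two designs test
whether a group (e.g. pair-bonded vs sex-naive) ages differently:

* a covariate-adjusted Wald test of the group coefficient in a linear model
  of acceleration on group plus covariates (default sex and tissue), and
* cross-applied group clocks: a clock trained on one group is applied to
  adults of the other, predictions are age-adjusted within the evaluation
  group, and per-tissue one-sample t-tests ask whether the mean deviation
  differs from zero (positive = overestimated, i.e. epigenetically older).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .age_transforms import AgeTransformSpec
from .clock import CrossValidationReport, _accuracy, fit_clock, predict_age
from .datatypes import MethylationDataset, ValidationError
from .io_data import filter_adults


@dataclass
class AccelerationResult:
    """Per-sample age-acceleration residuals (years)."""

    residuals: pd.Series
    strata: pd.Series | None  # stratum label per sample, or None for pooled
    fit_info: pd.DataFrame    # per-stratum slope/intercept of DNAm-age ~ age


@dataclass
class GroupTestResult:
    """One-sample t-test of mean age-adjusted deviation within a stratum."""

    stratum: str
    n: int
    t: float
    df: int
    p: float
    mean_deviation: float
    se: float
    degenerate: bool = False


def compute_acceleration(
    predicted_age,
    true_age,
    strata=None,
) -> AccelerationResult:
    """OLS residuals of predicted on true age, within each stratum.

    Residuals are in years with a positive sign meaning epigenetically
    older; they sum to zero within each regression stratum by construction.
    """
    pred = pd.Series(predicted_age, dtype=float)
    true = pd.Series(true_age, dtype=float)
    true.index = pred.index
    if strata is None:
        groups = pd.Series("all", index=pred.index)
    else:
        groups = pd.Series(strata)
        groups.index = pred.index
    residuals = pd.Series(np.nan, index=pred.index, dtype=float)
    rows = []
    for level, idx in groups.groupby(groups).groups.items():
        y = pred.loc[idx].to_numpy()
        x = true.loc[idx].to_numpy()
        if len(x) < 3:
            raise ValidationError(
                f"stratum {level!r} has fewer than 3 samples for the regression"
            )
        if np.std(x) == 0:
            raise ValidationError(f"zero age variance in stratum {level!r}")
        slope, intercept = np.polyfit(x, y, 1)
        residuals.loc[idx] = y - (intercept + slope * x)
        rows.append((level, len(x), slope, intercept))
    fit_info = pd.DataFrame(rows, columns=["stratum", "n", "slope", "intercept"])
    return AccelerationResult(
        residuals=residuals,
        strata=None if strata is None else groups,
        fit_info=fit_info,
    )


def _one_hot(values: pd.Series, name: str) -> pd.DataFrame:
    """Dummy-code a categorical with the alphabetically first level as reference."""
    levels = sorted(values.astype(str).unique())
    cols = {}
    for level in levels[1:]:
        cols[f"{name}[{level}]"] = (values.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=values.index)


def wald_group_test(
    acceleration: AccelerationResult,
    group,
    covariates: dict | pd.DataFrame | None = None,
) -> dict:
    """Wald test of the group effect on age acceleration.

    Fits ``acceleration ~ group + covariates`` by OLS (categoricals
    dummy-coded with the alphabetically first level as reference) and
    returns the group coefficient, its t statistic, degrees of freedom and
    two-sided p-value.
    """
    resid = acceleration.residuals
    group = pd.Series(group)
    group.index = resid.index
    levels = sorted(group.astype(str).unique())
    if len(levels) != 2:
        raise ValidationError(f"group must have exactly 2 levels, got {levels}")
    design = pd.DataFrame({"(Intercept)": 1.0}, index=resid.index)
    group_col = f"group[{levels[1]}]"
    design[group_col] = (group.astype(str) == levels[1]).astype(float)
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov.index = resid.index
        for name in cov.columns:
            col = cov[name]
            if col.dtype.kind in "fiu" and col.nunique() > 2:
                design[name] = col.astype(float)
            else:
                design = pd.concat([design, _one_hot(col, name)], axis=1)
    D = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        _, R = np.linalg.qr(D)
        bad = [design.columns[i] for i in range(D.shape[1])
               if abs(R[i, i]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValidationError(f"design matrix rank deficient; collinear: {bad}")
    y = resid.to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ beta
    df = len(y) - D.shape[1]
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    sigma2 = float(((y - fitted) ** 2).sum() / df)
    cov_beta = sigma2 * np.linalg.inv(D.T @ D)
    j = list(design.columns).index(group_col)
    coef = float(beta[j])
    se = float(np.sqrt(cov_beta[j, j]))
    t = coef / se if se > 0 else np.inf * np.sign(coef)
    p = float(2 * stats.t.sf(abs(t), df))
    return {
        "coefficient": coef,
        "se": se,
        "t": float(t),
        "df": df,
        "p": p,
        "group_level": levels[1],
        "reference_level": levels[0],
        "terms": list(design.columns),
    }


def one_sample_deviation_test(deviations: np.ndarray, stratum: str) -> GroupTestResult:
    """Two-sided one-sample t-test of mean deviation against 0."""
    dev = np.asarray(deviations, dtype=float)
    n = len(dev)
    mean = float(dev.mean())
    sd = float(dev.std(ddof=1)) if n > 1 else 0.0
    se = sd / np.sqrt(n) if n > 0 else np.nan
    if n < 2 or sd <= 1e-12 * (abs(mean) + 1.0):
        # all deviations identical: t undefined; flag rather than crash
        return GroupTestResult(
            stratum=stratum, n=n, t=np.nan, df=max(n - 1, 0),
            p=np.nan, mean_deviation=mean, se=se, degenerate=True,
        )
    t = mean / se
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return GroupTestResult(
        stratum=stratum, n=n, t=float(t), df=n - 1, p=p,
        mean_deviation=mean, se=float(se),
    )


@dataclass
class CrossClockResult:
    report: CrossValidationReport
    deviations: pd.Series          # age-adjusted deviations (years) in eval group
    tissue_tests: list             # per-tissue GroupTestResult


def cross_clock_test(
    train_ds: MethylationDataset,
    eval_ds: MethylationDataset,
    transform_spec: AgeTransformSpec,
    per_tissue: bool = True,
    min_age: float = 0.3,
    alpha: float = 0.5,
    seed: int = 0,
) -> CrossClockResult:
    """Train a clock on one group, evaluate it on adults of the other.

    Predictions for the evaluation group are age-adjusted by regressing the
    estimate on chronological age within that group and keeping the
    residual, so the per-tissue one-sample t-tests probe a systematic
    over/underestimate rather than the age trend itself.
    """
    shared = set(train_ds.samples.index) & set(eval_ds.samples.index)
    if shared:
        raise ValidationError(f"train and eval groups overlap: {sorted(shared)[:5]}")
    eval_ds = filter_adults(eval_ds, min_age=min_age)
    if eval_ds.n_samples < 3:
        raise ValidationError("fewer than 3 adult evaluation samples")

    model = fit_clock(train_ds, transform_spec, alpha=alpha, seed=seed)
    pred = predict_age(model, eval_ds)
    true_age = eval_ds.ages
    pred_age = pred["predicted_age"].to_numpy()

    # age adjustment within the evaluation group
    slope, intercept = np.polyfit(true_age, pred_age, 1)
    deviations = pd.Series(
        pred_age - (intercept + slope * true_age), index=eval_ds.samples.index
    )

    r, mae = _accuracy(true_age, pred_age)
    predictions = pd.DataFrame(
        {
            "true_age": true_age,
            "predicted_age": pred_age,
            "deviation": deviations,
            "tissue": eval_ds.samples["tissue"],
        },
        index=eval_ds.samples.index,
    )
    rows = []
    for tissue, sub in predictions.groupby("tissue", observed=True):
        sr, smae = _accuracy(sub["true_age"].to_numpy(),
                             sub["predicted_age"].to_numpy())
        rows.append(("tissue", tissue, len(sub), sr, smae))
    report = CrossValidationReport(
        predictions=predictions,
        overall_r=r,
        overall_mae=mae,
        per_stratum=pd.DataFrame(rows, columns=["stratum", "level", "n", "r", "mae"]),
    )

    tests = []
    if per_tissue:
        for tissue, sub in predictions.groupby("tissue", observed=True):
            if len(sub) < 3:
                warnings.warn(f"tissue {tissue!r} has n < 3; skipped")
                continue
            tests.append(
                one_sample_deviation_test(sub["deviation"].to_numpy(), str(tissue))
            )
    else:
        tests.append(one_sample_deviation_test(deviations.to_numpy(), "all"))
    return CrossClockResult(report=report, deviations=deviations, tissue_tests=tests)
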