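"""Elastic-net epigenetic clocks: fitting, prediction, cross-validation.

A clock is a sparse linear model of transformed age on beta values,

    t(age_i) = b0 + sum_j beta_ij * b_j + e_i,

fit by elastic-net regression with mixing parameter alpha (default 0.5, the
midpoint between ridge and lasso). The penalty strength lambda is chosen
automatically by internal k-fold cross-validation on the training set over a
log-spaced grid from lambda_max (the smallest lambda with an all-zero
solution) down to lambda_max * 1e-4, at the minimum mean CV error (a
one-standard-error rule is available). Predictors are standardized
internally; coefficients are returned on the original beta scale.

Accuracy is evaluated by leave-one-out or k-fold cross-validation in which
the whole fitting procedure, penalty selection included, is repeated from
scratch on each training fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .age_transforms import AgeTransformSpec, inverse_transform, transform
from .datatypes import MethylationDataset, ValidationError

#: path coefficients are solved to this tolerance during penalty selection;
#: the final model is refit at the selected penalty to _REFIT_TOL, and
#: fixed-penalty fits (no grid) are solved essentially to convergence.
_PATH_TOL = 1e-3
_REFIT_TOL = 1e-5
_FIXED_TOL = 1e-12
_N_LAMBDAS = 100
_LAMBDA_MIN_RATIO = 1e-4


@dataclass
class ClockModel:
    """Sparse linear age predictor with its age transform attached."""

    transform: AgeTransformSpec
    intercept: float
    coefficients: pd.Series  # nonzero coefficients only, indexed by probe id
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValueError("non-finite intercept")
        if not np.all(np.isfinite(self.coefficients.to_numpy(dtype=float))):
            raise ValueError("non-finite coefficient")

    @property
    def n_cpgs(self) -> int:
        return int((self.coefficients != 0).sum())


@dataclass
class CrossValidationReport:
    """Held-out predictions with overall and per-stratum accuracy."""

    predictions: pd.DataFrame  # true_age, predicted_age (+ strata columns)
    overall_r: float
    overall_mae: float
    per_stratum: pd.DataFrame  # stratum column, level, n, r, mae

    def summary(self) -> str:
        return (
            f"R = {self.overall_r:.3f}, MAE = {self.overall_mae:.3f} y "
            f"(n = {len(self.predictions)})"
        )


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _design_matrix(ds: MethylationDataset) -> np.ndarray:
    """Samples x probes matrix with per-probe mean imputation of missing betas."""
    X = ds.beta.to_numpy(dtype=float).T.copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.5)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    return X


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    # columns constant up to float noise carry no information; zero them out
    constant = sd <= 1e-10 * (np.abs(mean) + 1.0)
    sd_safe = np.where(constant, 1.0, sd)
    Xs = (X - mean) / sd_safe
    Xs[:, constant] = 0.0
    return Xs, mean, sd_safe


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, alpha: float) -> np.ndarray:
    n = len(yc)
    lam_max = np.abs(Xs.T @ yc).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * _LAMBDA_MIN_RATIO), _N_LAMBDAS
    )


def _select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    n_folds: int,
    seed: int,
    rule: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Internal k-fold CV over the lambda grid; returns (lambda, mean mse, se)."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n = len(y)
    sq_err = np.full((n, len(lambdas)), np.nan)
    for train_idx, val_idx in kf.split(X):
        Xs, mean, sd = _standardize(X[train_idx])
        ym = y[train_idx].mean()
        yc = y[train_idx] - ym
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=alpha, alphas=lambdas, tol=_PATH_TOL
        )
        Xv = (X[val_idx] - mean) / sd
        pred = ym + Xv @ coefs  # n_val x n_lambdas
        sq_err[val_idx] = (pred - y[val_idx][:, None]) ** 2
    mse = sq_err.mean(axis=0)
    se = sq_err.std(axis=0, ddof=1) / np.sqrt(n)
    best = int(np.argmin(mse))
    if rule == "1se":
        within = np.where(mse <= mse[best] + se[best])[0]
        best = int(within[0])  # largest lambda within one SE (grid is decreasing)
    return float(lambdas[best]), mse, se


def _fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, alpha: float,
    coef_init: np.ndarray | None = None,
    tol: float = _REFIT_TOL,
) -> tuple[float, np.ndarray]:
    """Elastic-net fit at a fixed penalty; coefficients on the original scale."""
    Xs, mean, sd = _standardize(X)
    ym = y.mean()
    model = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=False, tol=tol,
        max_iter=100000, warm_start=coef_init is not None,
    )
    if coef_init is not None:
        model.coef_ = coef_init.copy()
        model.intercept_ = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y - ym)
    coef_std = model.coef_
    coef = coef_std / sd
    intercept = ym - float(coef @ mean)
    return intercept, coef


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit_clock(
    ds: MethylationDataset,
    transform_spec: AgeTransformSpec,
    alpha: float = 0.5,
    n_folds_internal: int = 10,
    seed: int = 0,
    penalty: float | None = None,
    lambda_rule: str = "min",
) -> ClockModel:
    """Fit an elastic-net clock on a dataset.

    ``penalty`` fixes lambda directly (no internal CV); otherwise lambda is
    selected by ``n_folds_internal``-fold CV at the minimum mean CV error
    (``lambda_rule="1se"`` picks the sparsest model within one standard
    error). Deterministic given ``seed``.
    """
    if penalty is None and ds.n_samples < n_folds_internal:
        raise ValidationError(
            f"{ds.n_samples} samples is fewer than {n_folds_internal} internal folds"
        )
    y = np.asarray(
        transform(transform_spec, ds.ages, ds.samples["species"].to_numpy()),
        dtype=float,
    )
    if np.std(y) == 0:
        raise ValidationError("zero variance in (transformed) age")
    X = _design_matrix(ds)

    meta = {
        "alpha": alpha,
        "n_folds_internal": n_folds_internal,
        "seed": seed,
        "lambda_rule": lambda_rule,
        "n_samples": ds.n_samples,
        "n_probes": ds.n_probes,
        "tissues": sorted(ds.samples["tissue"].unique().tolist()),
        "groups": sorted(ds.samples["group"].unique().tolist()),
        "species": sorted(ds.samples["species"].unique().tolist()),
    }

    if penalty is not None:
        lam = float(penalty)
        meta["lambda"] = lam
        meta["lambda_selection"] = "fixed"
        intercept, coef = _fit_at_lambda(X, y, lam, alpha, tol=_FIXED_TOL)
    else:
        Xs, _, _ = _standardize(X)
        lambdas = _lambda_grid(Xs, y - y.mean(), alpha)
        lam, mse, _ = _select_lambda(
            X, y, lambdas, alpha, n_folds_internal, seed, lambda_rule
        )
        meta["lambda"] = lam
        meta["lambda_selection"] = f"internal {n_folds_internal}-fold CV, {lambda_rule}"
        meta["lambda_max"] = float(lambdas[0])
        # warm start the tight refit from the path solution at lam
        _, path_coefs, _ = enet_path(
            Xs, y - y.mean(), l1_ratio=alpha, alphas=lambdas, tol=_PATH_TOL
        )
        init = path_coefs[:, int(np.argmin(np.abs(lambdas - lam)))]
        intercept, coef = _fit_at_lambda(X, y, lam, alpha, coef_init=init)

    nz = np.flatnonzero(coef)
    coefficients = pd.Series(coef[nz], index=ds.probes.index[nz], dtype=float)
    return ClockModel(
        transform=transform_spec,
        intercept=float(intercept),
        coefficients=coefficients,
        training_meta=meta,
    )


def predict_age(model: ClockModel, ds: MethylationDataset) -> pd.DataFrame:
    """Apply a clock, returning transformed-scale and year-scale predictions."""
    needed = model.coefficients.index
    missing = [p for p in needed if p not in ds.beta.index]
    if missing:
        raise ValidationError(f"dataset missing clock probes: {missing}")
    B = ds.beta.loc[needed].to_numpy(dtype=float) if len(needed) else np.zeros(
        (0, ds.n_samples)
    )
    if not np.all(np.isfinite(B)):
        bad = np.argwhere(~np.isfinite(B))[0]
        raise ValidationError(
            f"non-finite beta for clock probe {needed[bad[0]]!r} in sample "
            f"{ds.beta.columns[bad[1]]!r}"
        )
    pred_t = model.intercept + model.coefficients.to_numpy(dtype=float) @ B
    species = ds.samples["species"].to_numpy()
    years = np.asarray(inverse_transform(model.transform, pred_t, species), dtype=float)
    return pd.DataFrame(
        {
            "predicted_transformed": pred_t,
            "predicted_age": years,
        },
        index=ds.samples.index,
    )


def _accuracy(true_age: np.ndarray, pred_age: np.ndarray) -> tuple[float, float]:
    if len(true_age) < 2 or np.std(true_age) == 0 or np.std(pred_age) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(true_age, pred_age)[0])
    mae = float(np.median(np.abs(pred_age - true_age)))
    return r, mae


def cross_validate(
    ds: MethylationDataset,
    transform_spec: AgeTransformSpec,
    scheme: str = "loo",
    k: int = 10,
    strata_for_report: Sequence[str] = ("tissue", "group", "species"),
    alpha: float = 0.5,
    n_folds_internal: int = 10,
    seed: int = 0,
) -> CrossValidationReport:
    """Cross-validated clock accuracy.

    Each fold refits the clock from scratch on the retained samples
    (internal penalty selection included) and predicts the held-out samples.
    ``scheme`` is ``"loo"`` (leave one sample out) or ``"kfold"``.
    """
    n = ds.n_samples
    if n < 3:
        raise ValidationError("cross_validate needs at least 3 samples")
    if scheme == "loo":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        kf = KFold(n_splits=min(k, n), shuffle=True, random_state=seed)
        folds = list(kf.split(np.arange(n)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    ids = np.asarray(ds.samples.index)
    pred_age = np.full(n, np.nan)
    pred_t = np.full(n, np.nan)
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        sub = ds.subset_samples(ids[train_idx])
        model = fit_clock(
            sub,
            transform_spec,
            alpha=alpha,
            n_folds_internal=min(n_folds_internal, len(train_idx)),
            seed=seed + fold_i,
        )
        out = predict_age(model, ds.subset_samples(ids[test_idx]))
        pred_age[test_idx] = out["predicted_age"].to_numpy()
        pred_t[test_idx] = out["predicted_transformed"].to_numpy()

    predictions = pd.DataFrame(
        {
            "true_age": ds.ages,
            "predicted_age": pred_age,
            "predicted_transformed": pred_t,
        },
        index=ds.samples.index,
    )
    for col in strata_for_report:
        if col in ds.samples.columns:
            predictions[col] = ds.samples[col]

    r, mae = _accuracy(ds.ages, pred_age)
    rows = []
    for col in strata_for_report:
        if col not in ds.samples.columns:
            continue
        for level, sub in predictions.groupby(col, observed=True):
            if len(sub) < 2:
                rows.append((col, level, len(sub), float("nan"), float("nan")))
                continue
            sr, smae = _accuracy(
                sub["true_age"].to_numpy(), sub["predicted_age"].to_numpy()
            )
            rows.append((col, level, len(sub), sr, smae))
    per_stratum = pd.DataFrame(rows, columns=["stratum", "level", "n", "r", "mae"])
    return CrossValidationReport(
        predictions=predictions, overall_r=r, overall_mae=mae, per_stratum=per_stratum
    )


# ---------------------------------------------------------------------------
# clock file format: metadata header lines, then ProbeID,Coefficient rows
# ---------------------------------------------------------------------------

def save_clock(model: ClockModel, path) -> None:
    """Write a clock as self-describing plain text (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("# clockforge clock v1\n")
        fh.write("# transform: " + json.dumps(model.transform.to_dict()) + "\n")
        fh.write("# training_meta: " + json.dumps(model.training_meta) + "\n")
        fh.write("ProbeID,Coefficient\n")
        fh.write(f"(Intercept),{model.intercept:.17g}\n")
        for probe, coef in model.coefficients.items():
            fh.write(f"{probe},{coef:.17g}\n")


def load_clock(path) -> ClockModel:
    transform_spec = None
    meta: dict = {}
    intercept = None
    probes, coefs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# transform:"):
                transform_spec = AgeTransformSpec.from_dict(
                    json.loads(line.split(":", 1)[1])
                )
            elif line.startswith("# training_meta:"):
                meta = json.loads(line.split(":", 1)[1])
            elif line.startswith("#") or line == "ProbeID,Coefficient" or not line:
                continue
            else:
                name, value = line.split(",")
                if name == "(Intercept)":
                    intercept = float(value)
                else:
                    probes.append(name)
                    coefs.append(float(value))
    if transform_spec is None or intercept is None:
        raise ValidationError(f"{path} is not a clockforge clock file")
    return ClockModel(
        transform=transform_spec,
        intercept=intercept,
        coefficients=pd.Series(coefs, index=pd.Index(probes), dtype=float),
        training_meta=meta,
    )
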