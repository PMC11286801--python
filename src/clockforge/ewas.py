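"""Epigenome-wide association screening and Stouffer meta-analysis.

Age EWAS is a per-CpG Pearson correlation screen within each tissue: for
CpG j with n complete pairs, r is the correlation of beta with age,
t = r * sqrt((n-2)/(1-r^2)) gives the two-sided p from a t distribution
with n-2 degrees of freedom, and the Fisher-transformed z-score is
z = atanh(r) * sqrt(n-3). Trait EWAS (e.g. pair-bonding status) fits, per
CpG and per sex-by-tissue stratum, an OLS model

    beta ~ trait + age

restricted to adults, and reports the Wald statistic for the trait
coefficient, with direction "gain" meaning hypermethylated relative to the
reference level. Per-stratum results are combined across tissues with
Stouffer's weighted z-score method, z_meta = sum(w_i z_i) / sqrt(sum w_i^2),
with w_i = sqrt(n_i) by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationDataset, ValidationError
from .io_data import filter_adults

#: |r| is clipped here before atanh so a perfect correlation gives a large
#: finite z instead of infinity
_R_CLIP = 1 - 1e-12

EWAS_COLUMNS = [
    "probe_id", "stratum", "n", "statistic", "estimate", "z", "p", "direction",
    "flag",
]


def _pearson_screen(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorized per-row Pearson screen of X (probes x samples) against y.

    Missing betas are dropped pairwise per CpG.
    """
    mask = np.isfinite(X)
    Xz = np.where(mask, X, 0.0)
    n = mask.sum(axis=1).astype(float)
    Sy = mask @ y
    Syy = mask @ (y * y)
    Sx = Xz.sum(axis=1)
    Sxx = (Xz * Xz).sum(axis=1)
    Sxy = Xz @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sy / n
        varx = Sxx - Sx * Sx / n
        vary = Syy - Sy * Sy / n
        r = cov / np.sqrt(varx * vary)
    flagged = ~np.isfinite(r) | (n < 4)
    r_clipped = np.clip(np.where(flagged, 0.0, r), -_R_CLIP, _R_CLIP)
    df = np.maximum(n - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_clipped * np.sqrt(df / (1 - r_clipped**2))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(flagged, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    z = np.arctanh(r_clipped) * np.sqrt(np.maximum(n - 3, 0))
    z = np.where(flagged, 0.0, z)
    return pd.DataFrame(
        {
            "n": n.astype(int),
            "estimate": np.where(flagged, np.nan, r),
            "z": z,
            "p": p,
            "direction": np.where(flagged, "none",
                                  np.where(r_clipped >= 0, "gain", "loss")),
            "flag": np.where(flagged, "zero_variance", ""),
        }
    )


def ewas_age(
    ds: MethylationDataset, per_stratum: str = "tissue"
) -> pd.DataFrame:
    """Per-CpG Pearson correlation with age, within each stratum.

    Returns one record per CpG per stratum with columns
    ``probe_id, stratum, n, statistic, estimate (r), z, p, direction, flag``.
    """
    frames = []
    for level, sub_ids in ds.samples.groupby(per_stratum, observed=True).groups.items():
        sub = ds.subset_samples(sub_ids)
        if sub.n_samples < 4:
            warnings.warn(f"stratum {level!r} has < 4 samples; skipped")
            continue
        res = _pearson_screen(
            sub.beta.to_numpy(dtype=float), sub.ages
        )
        res.insert(0, "probe_id", ds.probes.index)
        res.insert(1, "stratum", str(level))
        res.insert(3, "statistic", "pearson_r")
        frames.append(res)
    if not frames:
        raise ValidationError("no stratum with enough samples")
    return pd.concat(frames, ignore_index=True)[EWAS_COLUMNS]


def _trait_screen(
    X: np.ndarray, trait: np.ndarray, age: np.ndarray
) -> pd.DataFrame:
    """Per-row OLS of beta on trait + age; Wald test of the trait coefficient."""
    n = len(trait)
    D = np.column_stack([np.ones(n), trait.astype(float), age.astype(float)])
    DtD_inv = np.linalg.inv(D.T @ D)
    H = DtD_inv @ D.T  # 3 x n

    complete = np.all(np.isfinite(X), axis=1)
    est = np.full(X.shape[0], np.nan)
    se = np.full(X.shape[0], np.nan)
    dfree = np.full(X.shape[0], n - 3, dtype=float)
    nn = np.full(X.shape[0], n, dtype=float)

    if complete.any():
        Y = X[complete]  # p x n
        B = H @ Y.T      # 3 x p
        resid = Y.T - D @ B
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / (n - 3)
        est[complete] = B[1]
        se[complete] = np.sqrt(sigma2 * DtD_inv[1, 1])
    for i in np.flatnonzero(~complete):
        ok = np.isfinite(X[i])
        ni = int(ok.sum())
        nn[i] = ni
        if ni < 5 or len(np.unique(trait[ok])) < 2:
            continue
        Di = D[ok]
        try:
            DtD_inv_i = np.linalg.inv(Di.T @ Di)
        except np.linalg.LinAlgError:
            continue
        b = DtD_inv_i @ Di.T @ X[i, ok]
        rss = float(((X[i, ok] - Di @ b) ** 2).sum())
        dfree[i] = ni - 3
        est[i] = b[1]
        se[i] = np.sqrt(rss / (ni - 3) * DtD_inv_i[1, 1])

    with np.errstate(invalid="ignore", divide="ignore"):
        t = est / se
    flagged = ~np.isfinite(t)
    t_safe = np.where(flagged, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t_safe), np.maximum(dfree, 1))
    p = np.where(flagged, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {
            "n": nn.astype(int),
            "estimate": est,
            "z": np.where(flagged, 0.0, t_safe),
            "p": p,
            "direction": np.where(
                flagged, "none", np.where(t_safe >= 0, "gain", "loss")
            ),
            "flag": np.where(flagged, "zero_variance", ""),
        }
    )


def ewas_trait(
    ds: MethylationDataset,
    trait: str = "group",
    reference: str | None = None,
    adjust: str = "age",
    per_stratum: tuple = ("sex", "tissue"),
    adults_only: bool = True,
    min_age: float = 0.3,
) -> pd.DataFrame:
    """Age-adjusted per-CpG association with a binary trait, per stratum.

    Direction "gain" means hypermethylation in the non-reference trait level
    (the reference defaults to the alphabetically first level, e.g.
    pair_bonded vs the sex_naive reference when labels sort that way; pass
    ``reference`` explicitly to be sure).
    """
    if adjust != "age":
        raise ValueError("only age adjustment is supported")
    work = filter_adults(ds, min_age=min_age) if adults_only else ds
    levels = sorted(work.samples[trait].astype(str).unique())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not found in {levels}")
    other = [lv for lv in levels if lv != reference]
    if len(other) != 1:
        raise ValidationError(f"trait must be binary, got levels {levels}")

    frames = []
    grouping = [c for c in per_stratum]
    for key, sub_ids in work.samples.groupby(grouping, observed=True).groups.items():
        label = ".".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        sub = work.subset_samples(sub_ids)
        tvals = sub.samples[trait].astype(str).to_numpy()
        if len(np.unique(tvals)) < 2:
            warnings.warn(f"stratum {label!r} has a single trait level; skipped")
            continue
        if sub.n_samples < 5:
            warnings.warn(f"stratum {label!r} has < 5 samples; skipped")
            continue
        indicator = (tvals != reference).astype(float)
        res = _trait_screen(
            sub.beta.to_numpy(dtype=float), indicator, sub.ages
        )
        res.insert(0, "probe_id", ds.probes.index)
        res.insert(1, "stratum", label)
        res.insert(3, "statistic", "group_coefficient")
        frames.append(res)
    if not frames:
        raise ValidationError("no stratum with both trait levels")
    return pd.concat(frames, ignore_index=True)[EWAS_COLUMNS]


def stouffer_meta(records: pd.DataFrame, weights: str = "sqrt_n") -> pd.DataFrame:
    """Combine per-stratum z-scores per probe with Stouffer's method.

    z_meta = sum(w_i z_i) / sqrt(sum w_i^2) with w_i = sqrt(n_i)
    (``weights="unit"`` gives the unweighted combination). Records with a
    missing z are excluded; a single-stratum probe returns its z unchanged.
    """
    if weights not in ("sqrt_n", "unit"):
        raise ValueError(f"unknown weights {weights!r}")
    rec = records.copy()
    usable = np.isfinite(rec["z"].to_numpy(dtype=float))
    n_excluded = int((~usable).sum())
    rec = rec[usable]
    w = np.sqrt(rec["n"].to_numpy(dtype=float)) if weights == "sqrt_n" else np.ones(
        len(rec)
    )
    rec = rec.assign(_w=w)
    grouped = rec.groupby("probe_id", sort=False)
    num = grouped.apply(
        lambda g: float((g["_w"] * g["z"]).sum()), include_groups=False
    )
    den = grouped.apply(
        lambda g: float(np.sqrt((g["_w"] ** 2).sum())), include_groups=False
    )
    z_meta = num / den
    p = 2 * stats.norm.sf(np.abs(z_meta))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "probe_id": z_meta.index,
            "z": z_meta.to_numpy(),
            "p": p,
            "n_strata": grouped.size().to_numpy(),
            "n_total": grouped["n"].sum().to_numpy(),
            "direction": np.where(z_meta.to_numpy() >= 0, "gain", "loss"),
        }
    ).reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["weights"] = weights
    return out


def select_significant(records: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Records with p strictly below ``alpha``, with a direction partition."""
    if len(records) == 0:
        return records.copy()
    out = records[records["p"] < alpha].copy()
    out.attrs["n_gain"] = int((out["direction"] == "gain").sum())
    out.attrs["n_loss"] = int((out["direction"] == "loss").sum())
    out.attrs["alpha"] = alpha
    return out


def cross_stratum_overlap(
    significant: pd.DataFrame,
    min_strata: int = 3,
    require_consistent_direction: bool = True,
) -> tuple[list, pd.DataFrame]:
    """Probes significant in at least ``min_strata`` strata.

    With ``require_consistent_direction`` the direction of effect must be
    identical in every stratum where the probe is significant. Returns the
    probe list plus a probe x stratum membership matrix (+1 gain, -1 loss,
    0 not significant) suitable for upset-style tabulation.
    """
    strata = sorted(significant["stratum"].unique())
    if len(strata) < min_strata:
        raise ValidationError(
            f"{len(strata)} strata supplied but min_strata={min_strata}"
        )
    signed = significant["direction"].map({"gain": 1, "loss": -1}).fillna(0)
    matrix = (
        significant.assign(_sign=signed)
        .pivot_table(index="probe_id", columns="stratum", values="_sign",
                     aggfunc="first", fill_value=0)
        .reindex(columns=strata, fill_value=0)
    )
    counts = (matrix != 0).sum(axis=1)
    hits = counts >= min_strata
    if require_consistent_direction:
        consistent = (matrix >= 0).all(axis=1) | (matrix <= 0).all(axis=1)
        hits = hits & consistent
    probes = matrix.index[hits].tolist()
    return probes, matrix


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional output column, never the headline filter)."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out
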