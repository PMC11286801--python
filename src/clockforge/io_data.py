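"""Reading, validation and QC of methylation datasets.

File conventions follow the GEO series-matrix layout: beta matrices are
stored probes-as-rows, samples-as-columns, with an id column first. Sample
sheets and probe annotation are plain CSV with fixed required headers.
Genomic coordinates in annotation are 1-based inclusive; BED export converts
to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import (
    PROBE_ANNOTATION_COLUMNS,
    SAMPLE_SHEET_COLUMNS,
    BETA_BOUND_TOL,
    DropReport,
    MethylationDataset,
    ValidationError,
)

SAMPLE_SHEET_HEADERS = {
    "SampleID": "sample_id",
    "Age": "age",
    "Sex": "sex",
    "Tissue": "tissue",
    "Group": "group",
    "Species": "species",
}
PROBE_ANNOTATION_HEADERS = {
    "ProbeID": "probe_id",
    "Chromosome": "chromosome",
    "Position": "position",
    "Gene": "gene",
    "TSSDistance": "tss_distance",
    "Island": "island",
    "ChromatinState": "chromatin_state",
}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_beta_matrix(path, orientation: str = "probes_as_rows") -> pd.DataFrame:
    """Read a delimited beta matrix, returning it oriented probes x samples.

    Missing cells stay NaN (they are never coerced to 0). Non-numeric cells
    and values outside [0, 1] raise a :class:`ValidationError` naming the
    offending probe/sample.
    """
    if orientation not in ("probes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    beta = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ValidationError(
                f"non-numeric beta value {raw.loc[row, col]!r} at row {row!r}, "
                f"column {col!r}"
            )
        beta[col] = converted
    if orientation == "samples_as_rows":
        beta = beta.T
    values = beta.to_numpy()
    out = (values < -BETA_BOUND_TOL) | (values > 1 + BETA_BOUND_TOL)
    if np.any(out & np.isfinite(values)):
        i, j = np.argwhere(out & np.isfinite(values))[0]
        raise ValidationError(
            f"beta value {values[i, j]} outside [0, 1] for probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)
    beta.index.name = "ProbeID"
    return beta


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    """Write probes-as-rows beta matrix with full float precision."""
    beta.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV with headers SampleID,Age,Sex,Tissue,Group,Species."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [h for h in SAMPLE_SHEET_HEADERS if h not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing headers: {missing}")
    df = df.rename(columns=SAMPLE_SHEET_HEADERS)
    df["age"] = df["age"].astype(float)
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return df[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.reset_index(names="sample_id")
    inv = {v: k for k, v in SAMPLE_SHEET_HEADERS.items()}
    out.rename(columns=inv).to_csv(path, sep=_sep_for(path), index=False,
                                   float_format="%.17g")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation CSV with headers ProbeID,...,ChromatinState."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [h for h in PROBE_ANNOTATION_HEADERS if h not in df.columns]
    if missing:
        raise ValidationError(f"probe annotation missing headers: {missing}")
    df = df.rename(columns=PROBE_ANNOTATION_HEADERS)
    df["position"] = df["position"].astype(int)
    df["tss_distance"] = df["tss_distance"].astype(int)
    df["island"] = df["island"].map(
        {"True": True, "False": False, "1": True, "0": False, "TRUE": True,
         "FALSE": False}
    )
    if df["island"].isna().any():
        raise ValidationError("island flag must be boolean (True/False or 1/0)")
    df["gene"] = df["gene"].fillna("")
    df["chromatin_state"] = df["chromatin_state"].fillna("NA")
    df = df.set_index("probe_id")
    df.index = df.index.astype(str)
    if (df["position"] < 1).any():
        bad = df.index[df["position"] < 1][0]
        raise ValidationError(f"probe {bad!r}: position must be >= 1")
    return df[PROBE_ANNOTATION_COLUMNS]


def write_probe_annotation(probes: pd.DataFrame, path) -> None:
    out = probes.reset_index(names="probe_id")
    inv = {v: k for k, v in PROBE_ANNOTATION_HEADERS.items()}
    out.rename(columns=inv).to_csv(path, sep=_sep_for(path), index=False)


def assemble_dataset(
    beta: pd.DataFrame, sample_sheet: pd.DataFrame, probe_annotation: pd.DataFrame
) -> tuple[MethylationDataset, DropReport]:
    """Intersect beta matrix, sample sheet and annotation into one dataset.

    The dataset is restricted to ids present in all relevant inputs, kept in
    sample-sheet / annotation order; everything discarded is listed in the
    returned :class:`DropReport`.
    """
    if beta.columns.duplicated().any() or beta.index.duplicated().any():
        raise ValidationError("duplicate ids in beta matrix")
    if sample_sheet.index.duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    if probe_annotation.index.duplicated().any():
        raise ValidationError("duplicate probe ids in annotation")

    sample_ids = [s for s in sample_sheet.index if s in set(beta.columns)]
    probe_ids = [p for p in probe_annotation.index if p in set(beta.index)]
    if not sample_ids:
        raise ValidationError("no sample ids shared between beta matrix and sheet")
    if not probe_ids:
        raise ValidationError("no probe ids shared between beta matrix and annotation")

    report = DropReport(
        dropped_samples=sorted(
            set(beta.columns).symmetric_difference(sample_sheet.index)
        ),
        dropped_probes=sorted(
            set(beta.index).symmetric_difference(probe_annotation.index)
        ),
    )
    ds = MethylationDataset(
        beta=beta.loc[probe_ids, sample_ids].copy(),
        samples=sample_sheet.loc[sample_ids].copy(),
        probes=probe_annotation.loc[probe_ids].copy(),
    )
    return ds, report


def filter_adults(ds: MethylationDataset, min_age: float = 0.3) -> MethylationDataset:
    """Keep samples strictly older than ``min_age`` years.

    The threshold is strict because sexual maturity is defined as being
    older than 0.3 years, not 0.3 years exactly.
    """
    keep = ds.ages > min_age
    if not keep.any():
        warnings.warn(f"no samples older than {min_age} years; empty dataset")
    return ds.where_samples(keep)


# ---------------------------------------------------------------------------
# QC: hierarchical clustering and sex check
# ---------------------------------------------------------------------------

@dataclass
class ClusterQC:
    """Dendrogram over samples plus label-purity summary."""

    linkage_matrix: np.ndarray
    sample_ids: list
    purity: dict          # label column -> purity in [0, 1]
    assignments: pd.DataFrame  # per-sample cluster index per label column


def cluster_qc(
    ds: MethylationDataset,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
    label_columns: Sequence[str] = ("tissue", "sex", "group"),
) -> ClusterQC:
    """Hierarchically cluster samples and score how well clusters match labels.

    Distance is 1 - Pearson correlation between sample beta profiles. For
    each label column the tree is cut into as many clusters as there are
    distinct labels; purity is the fraction of samples whose cluster's
    majority label equals their own label.
    """
    if ds.n_samples < 2:
        raise ValidationError("cluster_qc needs at least 2 samples")
    if distance != "one_minus_pearson":
        raise ValueError(f"unsupported distance {distance!r}")
    X = ds.beta.to_numpy(dtype=float)
    if np.all(np.isnan(X), axis=0).any():
        raise ValidationError("all-missing sample column")
    sd = np.nanstd(X, axis=0)
    if (sd == 0).any():
        warnings.warn("constant sample profile; correlations involving it set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2, 0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)

    purity: dict = {}
    assign = {}
    labels_df = ds.samples
    for col in label_columns:
        if col not in labels_df.columns:
            continue
        labels = labels_df[col].to_numpy()
        k = len(np.unique(labels))
        if k < 2:
            purity[col] = 1.0
            assign[col] = np.ones(len(labels), dtype=int)
            continue
        clusters = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        assign[col] = clusters
        correct = 0
        for c in np.unique(clusters):
            in_c = labels[clusters == c]
            vals, counts = np.unique(in_c, return_counts=True)
            majority = vals[np.argmax(counts)]
            correct += int((in_c == majority).sum())
        purity[col] = correct / len(labels)
    return ClusterQC(
        linkage_matrix=Z,
        sample_ids=list(ds.samples.index),
        purity=purity,
        assignments=pd.DataFrame(assign, index=ds.samples.index),
    )


@dataclass
class SexCheckResult:
    predicted: pd.Series   # per-sample predicted sex
    mismatch: pd.Series    # per-sample bool flag
    marker_probes: list


def sex_check(ds: MethylationDataset, n_markers: int = 50) -> SexCheckResult:
    """Predict sex from methylation and flag disagreements with the sheet.

    A nearest-centroid classifier is built on the ``n_markers`` CpGs with the
    largest absolute point-biserial correlation with annotated sex. Each
    training sample is predicted leave-one-out (its own profile is excluded
    from the centroids), so a single mislabelled sample still stands out.
    """
    sexes = ds.samples["sex"].to_numpy()
    if len(np.unique(sexes)) < 2:
        raise ValidationError("sex_check needs both sexes present")
    if n_markers > ds.n_probes:
        warnings.warn(
            f"n_markers={n_markers} exceeds probe count {ds.n_probes}; using all probes"
        )
        n_markers = ds.n_probes
    X = ds.beta.to_numpy(dtype=float)
    y = (sexes == "M").astype(float)
    Xc = X - np.nanmean(X, axis=1, keepdims=True)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.nansum(Xc * yc, axis=1) / (
            np.sqrt(np.nansum(Xc**2, axis=1)) * np.sqrt(np.sum(yc**2))
        )
    r[~np.isfinite(r)] = 0.0
    order = np.argsort(-np.abs(r), kind="stable")[:n_markers]
    markers = X[order]  # n_markers x n_samples

    is_m = y == 1
    sum_m = np.nansum(markers[:, is_m], axis=1)
    sum_f = np.nansum(markers[:, ~is_m], axis=1)
    n_m, n_f = int(is_m.sum()), int((~is_m).sum())

    predicted = []
    for j in range(ds.n_samples):
        prof = markers[:, j]
        if is_m[j]:
            cen_m = (sum_m - prof) / max(n_m - 1, 1)
            cen_f = sum_f / n_f
        else:
            cen_m = sum_m / n_m
            cen_f = (sum_f - prof) / max(n_f - 1, 1)
        d_m = np.nansum((prof - cen_m) ** 2)
        d_f = np.nansum((prof - cen_f) ** 2)
        predicted.append("M" if d_m <= d_f else "F")
    predicted = pd.Series(predicted, index=ds.samples.index, name="predicted_sex")
    mismatch = pd.Series(
        predicted.to_numpy() != sexes, index=ds.samples.index, name="sex_mismatch"
    )
    return SexCheckResult(
        predicted=predicted,
        mismatch=mismatch,
        marker_probes=[ds.probes.index[i] for i in order],
    )


def export_bed(probes: pd.DataFrame, scores: pd.Series, path) -> None:
    """Export probes as BED (0-based half-open), score = -log10 p."""
    sub = probes.loc[scores.index]
    bed = pd.DataFrame(
        {
            "chrom": sub["chromosome"],
            "start": sub["position"] - 1,
            "end": sub["position"],
            "name": sub.index,
            "score": -np.log10(np.clip(scores.to_numpy(dtype=float), 1e-300, None)),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
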