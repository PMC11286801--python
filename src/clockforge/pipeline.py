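"""End-to-end pipeline: QC -> clocks -> acceleration -> EWAS -> meta ->
overlap -> enrichment, driven by a YAML config, with a reproducibility
manifest of seeds, versions and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .acceleration import compute_acceleration, cross_clock_test, wald_group_test
from .age_transforms import AgeTransformSpec
from .clock import cross_validate, fit_clock, save_clock
from .datatypes import ValidationError
from .enrichment import (
    chromatin_state_enrichment,
    island_zscore_contrast,
    tss_location_breakdown,
)
from .ewas import (
    cross_stratum_overlap,
    ewas_age,
    ewas_trait,
    select_significant,
    stouffer_meta,
)
from .io_data import (
    assemble_dataset,
    cluster_qc,
    filter_adults,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    sex_check,
)
from .synthetic import SimulationConfig, generate_dataset

log = logging.getLogger("clockforge")

# each stage reruns identically in isolation because child seeds are fixed
# offsets from the config seed
STAGE_SEED_OFFSETS = {
    "clock": 100,
    "cross_clock": 200,
    "simulate": 300,
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run."""

    beta_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    simulate: dict | None = None      # SimulationConfig fields, used if no paths
    out_dir: str = "clockforge_out"
    seed: int = 0
    adult_age: float = 0.3
    age_ewas_threshold: float = 1e-5
    trait_ewas_threshold: float = 0.005
    min_strata: int = 3
    trait: str = "group"
    trait_reference: str = "sex_naive"
    clocks: dict = field(default_factory=lambda: {"pan_tissue": {"kind": "identity"}})
    cv_scheme: str = "loo"
    run_cv: bool = False              # LOOCV of every clock is expensive; opt in
    wald_covariates: tuple = ("sex", "tissue")
    cross_group: tuple | None = ("pair_bonded", "sex_naive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("age_ewas_threshold", "trait_ewas_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.simulate is None:
            for name in ("beta_path", "sample_sheet_path", "annotation_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"config field {name} is required")
                if not Path(p).exists():
                    raise ValidationError(f"config field {name}: no such file {p!r}")


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
    manifest["outputs"].append(str(path))


def _with_coordinates(records: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Attach chromosome/position and sort for Manhattan-style plotting."""
    out = records.merge(
        probes[["chromosome", "position"]], left_on="probe_id", right_index=True,
        how="left",
    )
    return out.sort_values(["chromosome", "position"], kind="stable")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis sequence; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seed_offsets": STAGE_SEED_OFFSETS,
        "inputs": {},
        "outputs": [],
        "stages": [],
    }

    def stage(name):
        t0 = time.time()
        log.info("stage %s ...", name)
        manifest["stages"].append({"name": name, "started": t0})

        def done():
            manifest["stages"][-1]["seconds"] = round(time.time() - t0, 3)
            log.info("stage %s done (%.1fs)", name, time.time() - t0)

        return done

    # ---- load or simulate -------------------------------------------------
    done = stage("load")
    try:
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed + STAGE_SEED_OFFSETS["simulate"])
            sim_cfg = SimulationConfig.from_dict(sim)
            ds, truth = generate_dataset(sim_cfg)
            truth.effects.to_csv(out / "truth.tsv", sep="\t", index=False)
            manifest["outputs"].append(str(out / "truth.tsv"))
            manifest["inputs"]["simulated"] = sim_cfg.to_dict()
        else:
            beta = read_beta_matrix(config.beta_path)
            sheet = read_sample_sheet(config.sample_sheet_path)
            ann = read_probe_annotation(config.annotation_path)
            for key in ("beta_path", "sample_sheet_path", "annotation_path"):
                manifest["inputs"][key] = {
                    "path": getattr(config, key),
                    "sha256": _checksum(getattr(config, key)),
                }
            ds, drop = assemble_dataset(beta, sheet, ann)
            _write(drop.to_frame(), out / "drop_report.tsv", manifest, index=False)
    except Exception as exc:
        raise ValidationError(f"stage 'load' failed: {exc}") from exc
    done()

    # ---- QC ---------------------------------------------------------------
    done = stage("qc")
    qc = cluster_qc(ds)
    _write(
        pd.DataFrame(
            [(k, v) for k, v in qc.purity.items()], columns=["label", "purity"]
        ),
        out / "qc_cluster_purity.tsv", manifest, index=False,
    )
    sc = sex_check(ds)
    _write(
        pd.DataFrame({"predicted_sex": sc.predicted, "mismatch": sc.mismatch}),
        out / "qc_sex_check.tsv", manifest,
    )
    done()

    # ---- clocks -----------------------------------------------------------
    done = stage("clocks")
    clock_seed = config.seed + STAGE_SEED_OFFSETS["clock"]
    cv_rows = []
    for name, spec_dict in config.clocks.items():
        spec = AgeTransformSpec.from_dict(spec_dict)
        model = fit_clock(ds, spec, seed=clock_seed)
        save_clock(model, out / f"clock_{name}.csv")
        manifest["outputs"].append(str(out / f"clock_{name}.csv"))
        if config.run_cv:
            report = cross_validate(
                ds, spec, scheme=config.cv_scheme, seed=clock_seed
            )
            _write(report.predictions, out / f"cv_{name}.tsv", manifest)
            cv_rows.append((name, report.overall_r, report.overall_mae))
    if cv_rows:
        _write(
            pd.DataFrame(cv_rows, columns=["clock", "r", "mae"]),
            out / "cv_summary.tsv", manifest, index=False,
        )
    done()

    # ---- acceleration + group tests --------------------------------------
    done = stage("acceleration")
    pan_spec = AgeTransformSpec.from_dict(
        next(iter(config.clocks.values()))
    )
    adults = filter_adults(ds, min_age=config.adult_age)
    wald = None
    if adults.n_samples >= 10 and adults.samples[config.trait].nunique() == 2:
        model = fit_clock(adults, pan_spec, seed=clock_seed)
        from .clock import predict_age  # local import to avoid cycle at top

        pred = predict_age(model, adults)
        accel = compute_acceleration(pred["predicted_age"], adults.ages)
        _write(
            pd.DataFrame({"acceleration": accel.residuals}),
            out / "acceleration.tsv", manifest,
        )
        covs = {c: adults.samples[c] for c in config.wald_covariates
                if adults.samples[c].nunique() > 1}
        wald = wald_group_test(accel, adults.samples[config.trait], covs)
        with open(out / "wald_group_test.json", "w") as fh:
            json.dump(wald, fh, indent=2)
        manifest["outputs"].append(str(out / "wald_group_test.json"))
    done()

    # ---- cross-applied group clocks ---------------------------------------
    if config.cross_group is not None:
        done = stage("cross_clock")
        ga, gb = config.cross_group
        rows = []
        for train_g, eval_g in ((ga, gb), (gb, ga)):
            tr = ds.where_samples(ds.samples[config.trait] == train_g)
            ev = ds.where_samples(ds.samples[config.trait] == eval_g)
            if tr.n_samples < 20 or ev.n_samples < 10:
                continue
            res = cross_clock_test(
                tr, ev, pan_spec, min_age=config.adult_age,
                seed=config.seed + STAGE_SEED_OFFSETS["cross_clock"],
            )
            for t in res.tissue_tests:
                rows.append((train_g, eval_g, t.stratum, t.n, t.t, t.df, t.p,
                             t.mean_deviation, t.se))
        if rows:
            _write(
                pd.DataFrame(rows, columns=[
                    "train_group", "eval_group", "tissue", "n", "t", "df", "p",
                    "mean_deviation", "se"]),
                out / "cross_clock_tests.tsv", manifest, index=False,
            )
        done()

    # ---- EWAS of age ------------------------------------------------------
    done = stage("ewas_age")
    age_records = ewas_age(ds.where_samples(
        ds.samples["species"] == ds.samples["species"].iloc[0]))
    _write(_with_coordinates(age_records, ds.probes), out / "ewas_age.tsv",
           manifest, index=False)
    meta = stouffer_meta(age_records)
    _write(meta, out / "ewas_age_meta.tsv", manifest, index=False)
    top_age = select_significant(meta, config.age_ewas_threshold)
    _write(top_age, out / "ewas_age_meta_significant.tsv", manifest, index=False)
    if len(top_age):
        from .io_data import export_bed

        scores = top_age.set_index("probe_id")["p"]
        export_bed(ds.probes, scores, out / "ewas_age_significant.bed")
        manifest["outputs"].append(str(out / "ewas_age_significant.bed"))
    done()

    # ---- EWAS of the trait ------------------------------------------------
    done = stage("ewas_trait")
    overlap_probes: list = []
    trait_records = None
    if adults.samples[config.trait].nunique() == 2:
        trait_records = ewas_trait(
            ds, trait=config.trait, reference=config.trait_reference,
            min_age=config.adult_age,
        )
        _write(_with_coordinates(trait_records, ds.probes),
               out / "ewas_trait.tsv", manifest, index=False)
        top_trait = select_significant(trait_records, config.trait_ewas_threshold)
        _write(top_trait, out / "ewas_trait_significant.tsv", manifest, index=False)
        if top_trait["stratum"].nunique() >= config.min_strata:
            overlap_probes, membership = cross_stratum_overlap(
                top_trait, min_strata=config.min_strata
            )
            _write(membership, out / "overlap_membership.tsv", manifest)
            _write(
                pd.DataFrame({"probe_id": overlap_probes}),
                out / "overlap_probes.tsv", manifest, index=False,
            )
    done()

    # ---- enrichment -------------------------------------------------------
    done = stage("enrichment")
    background = list(ds.probes.index)
    fg_age = top_age["probe_id"].tolist()
    if fg_age:
        _write(
            tss_location_breakdown(fg_age, background, ds.probes),
            out / "enrichment_age_tss.tsv", manifest, index=False,
        )
        _write(
            chromatin_state_enrichment(fg_age, background, ds.probes),
            out / "enrichment_age_chromatin.tsv", manifest, index=False,
        )
    contrast = island_zscore_contrast(meta.rename(columns={"z": "z"}),
                                      ds.probes["island"])
    with open(out / "island_contrast.json", "w") as fh:
        json.dump(contrast.__dict__, fh, indent=2)
    manifest["outputs"].append(str(out / "island_contrast.json"))
    if trait_records is not None:
        fg_trait = sorted(
            set(select_significant(trait_records,
                                   config.trait_ewas_threshold)["probe_id"])
        )
        if fg_trait:
            _write(
                chromatin_state_enrichment(fg_trait, background, ds.probes),
                out / "enrichment_trait_chromatin.tsv", manifest, index=False,
            )
    done()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
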