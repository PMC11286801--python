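# clockforge

Epigenetic clocks, epigenome-wide association screening and
genomic-context enrichment for DNA methylation array data — built around
the prairie vole (*Microtus ochrogaster*) study design of multi-tissue,
multi-sex, pair-bonded vs sex-naive cohorts, and exercised end-to-end on
synthetic methylation data with known ground truth.

## Who this is for

Researchers building DNA methylation age estimators ("epigenetic clocks")
for a new species or cohort, and anyone who wants the downstream analyses
that usually accompany them — age acceleration group tests, per-tissue
EWAS with meta-analysis, CpG-island / chromatin-state enrichment — as
plain, tested, scriptable Python instead of a pile of one-off R scripts.

## The model

An epigenetic clock is a sparse linear model of (transformed) age on CpG
methylation beta values,

    t(age_i) = b0 + Σ_j β_ij b_j,

fit by elastic-net regression (mixing parameter α = 0.5, penalty chosen
by internal 10-fold cross-validation) and evaluated by leave-one-sample-out
cross-validation: R is the Pearson correlation of DNAm age with
chronological age, MAE the median absolute error in years. Three
regression scales are supported: identity, a piecewise log-linear
transform for dual-species absolute-age clocks, and relative age
(age / maximum lifespan: vole 5.3 y, human 122.5 y), which lies in [0, 1]
for every species.

Around the clock sit the standard companion analyses:

* **age acceleration** — residual of DNAm age on chronological age;
  group contrasts via covariate-adjusted Wald tests and cross-applied
  group clocks with per-tissue one-sample t-tests;
* **EWAS of age** — per-tissue Pearson screen per CpG
  (t = r·√((n−2)/(1−r²)), Fisher z = atanh(r)·√(n−3)), combined across
  tissues by Stouffer's weighted-z meta-analysis;
* **EWAS of a binary trait** — per sex-by-tissue OLS of beta on
  trait + age in adults, with a cross-stratum overlap rule
  (significant with consistent direction in ≥ 3 strata);
* **enrichment** — Fisher exact tests of selected CpGs against TSS-distance
  bins, CpG-island status and chromatin states (BivProm, EnhA, Quies,
  ReprPC, TSS, Tx, PRC2, ...).

A synthetic-data module generates logit-normal methylation datasets with
spiked age / sex / tissue / group CpGs and a ground-truth registry, so
every stage of the pipeline is testable without any download. See
`docs/methods.md` for the full model description, assumptions and
numerical choices.

## Worked example

Simulate a benchmark-sized cohort (200 samples across blood, brain, ear
and liver; 2000 CpGs of which 100 track age), fit and cross-validate the
pan-tissue clock (10-fold here to keep the example fast; `scheme="loo"`
runs the leave-one-sample-out protocol), and screen for age-associated
CpGs:

```python
from clockforge import (AgeTransformSpec, SimulationConfig, generate_dataset,
                        cross_validate, ewas_age, stouffer_meta,
                        select_significant, truth_report)

ds, truth = generate_dataset(SimulationConfig(seed=5))
report = cross_validate(ds, AgeTransformSpec(kind="identity"),
                        scheme="kfold", seed=5)
print(report.summary())

meta = stouffer_meta(ewas_age(ds))
hits = select_significant(meta, 1e-5)
print(truth_report(truth, hits["probe_id"], "age"))
```

Output:

```
R = 0.998, MAE = 0.014 y (n = 200)
{'effect_type': 'age', 'n_spiked': 100, 'n_selected': 100, 'n_recovered': 100,
 'sensitivity': 1.0, 'false_discovery_proportion': 0.0}
```

The clock tracks the spiked age signal almost perfectly (R = 0.998, with a
median error of ~5 days on a 1.25-year age range), and the meta-analysis at
p < 1e-5 recovers exactly the 100 spiked age CpGs with no false positive
among the 1900 null CpGs.

The same analyses are available from the shell:

```bash
clockforge simulate --seed 5 --out sim/
clockforge cv    --beta sim/beta.csv --sheet sim/samples.csv \
                 --annotation sim/annotation.csv --scheme loo --seed 5
clockforge ewas-age --beta sim/beta.csv --sheet sim/samples.csv \
                 --annotation sim/annotation.csv --out ewas.tsv
clockforge run --config pipeline.yaml   # full QC→clock→EWAS→enrichment run
```

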