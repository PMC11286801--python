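"""Synthetic methylation data with known ground truth.

The generator produces beta matrices with the statistical structure the
analyses assume. For probe j and sample i it draws

    logit(beta_ij) ~ Normal(mu_j + a_j * F_i + s_j * [male_i]
                            + d_{j, tissue_i} + g_j * [bonded_i, affected tissue],
                            sigma)

and squashes through the logistic, so every beta is strictly in (0, 1).
Effects are additive on the logit scale — a deliberate mild mismatch with
beta-scale linear screens, mirroring real data. Baselines mu_j come from a
bimodal mixture (modes at logit +/-2) to imitate the genome-wide U-shaped
beta distribution. The age regressor F_i is age scaled to the primary
species' lifespan (F = age / lifespan * primary lifespan), so aging effects
are conserved on the relative-age scale when a second species with a
different lifespan is simulated — for voles alone F is simply age in years.

Study-design defaults mirror the reference design: four tissues (blood,
brain, ear, liver), two sexes, pair-bonded vs sex-naive groups, ages
uniform on [0.063, 1.31] years with pair-bonded animals restricted to
sexual maturity (> 0.3 y), prairie-vole lifespan 5.3 y.

Every spiked CpG (age / sex / tissue / group) is recorded in a
:class:`SyntheticTruth` registry so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import MethylationDataset


DEFAULT_STATE_FREQS = {
    "TSS1": 0.05,
    "BivProm2": 0.05,
    "PRC2": 0.05,
    "EnhA6": 0.10,
    "EnhWk4": 0.10,
    "ReprPC4": 0.10,
    "Tx2": 0.15,
    "Quies1": 0.30,
    "NA": 0.10,
}


@dataclass
class SpeciesBlock:
    """Optional second-species stratum for dual-species clocks."""

    name: str = "human"
    lifespan: float = 122.5
    age_min: float = 0.0
    age_max: float = 93.0
    n_samples: int = 100
    tissues: tuple = ("blood",)


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the benchmark conditions."""

    n_samples: int = 200
    tissues: tuple = ("blood", "brain", "ear", "liver")
    sexes: tuple = ("F", "M")
    groups: tuple = ("pair_bonded", "sex_naive")
    age_min: float = 0.063
    age_max: float = 1.31
    maturity_age: float = 0.3       # pair-bonded ages are > this
    species: str = "vole"
    lifespan: float = 5.3

    n_probes: int = 2000
    n_age_cpgs: int = 100
    age_effect: float = 2.0         # logits per year of primary-species age
    n_sex_cpgs: int = 30
    sex_effect: float = 1.0         # logit shift in males
    n_tissue_cpgs: int = 100
    tissue_effect: float = 1.0      # logit offset in the probe's assigned tissue
    n_group_multi_cpgs: int = 5     # group effect in every tissue
    n_group_single_cpgs: int = 50   # group effect in one tissue only
    group_effect: float = 1.0       # logit shift in pair-bonded animals
    noise_sd: float = 0.3           # residual sd on the logit scale
    group_slope_multiplier: float = 1.0  # aging-rate multiplier in pair-bonded

    island_prob: float = 0.3
    state_freqs: dict = field(default_factory=lambda: dict(DEFAULT_STATE_FREQS))
    age_cpg_placement: str | None = None  # None | "promoter" | "island"
    n_chromosomes: int = 20

    second_species: SpeciesBlock | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_probes, self.n_age_cpgs, self.n_sex_cpgs, self.n_tissue_cpgs,
            self.n_group_multi_cpgs, self.n_group_single_cpgs,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("probe counts must be >= 0")
        spiked = sum(counts[1:])
        if spiked > self.n_probes:
            raise ValueError(
                f"{spiked} spiked CpGs exceed {self.n_probes} probes"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.second_species is not None:
            d["second_species"] = asdict(self.second_species)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("tissues", "sexes", "groups"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("second_species"):
            sb = dict(d["second_species"])
            if "tissues" in sb:
                sb["tissues"] = tuple(sb["tissues"])
            d["second_species"] = SpeciesBlock(**sb)
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Registry of spiked CpGs and the true sample labels."""

    effects: pd.DataFrame    # probe_id, effect_type, effect_size, affected
    samples: pd.DataFrame    # the generated sample sheet
    config: SimulationConfig

    def spiked(self, effect_type: str) -> list:
        sel = self.effects["effect_type"] == effect_type
        return self.effects.loc[sel, "probe_id"].tolist()

    @property
    def all_spiked(self) -> set:
        return set(self.effects["probe_id"])


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    cells = [
        (t, s, g)
        for t in config.tissues
        for s in config.sexes
        for g in config.groups
    ]
    rows = []
    for i in range(config.n_samples):
        tissue, sex, group = cells[i % len(cells)]
        if group == "pair_bonded":
            # bonded animals are sexually mature by definition
            age = rng.uniform(config.maturity_age, config.age_max)
            age = np.nextafter(age, config.age_max) if age == config.maturity_age else age
        else:
            age = rng.uniform(config.age_min, config.age_max)
        rows.append((f"V{i + 1:04d}", age, sex, tissue, group, config.species))
    if config.second_species is not None:
        sp = config.second_species
        for i in range(sp.n_samples):
            rows.append(
                (
                    f"H{i + 1:04d}",
                    rng.uniform(sp.age_min, sp.age_max),
                    config.sexes[i % len(config.sexes)],
                    sp.tissues[i % len(sp.tissues)],
                    "sex_naive",
                    sp.name,
                )
            )
    df = pd.DataFrame(
        rows, columns=["sample_id", "age", "sex", "tissue", "group", "species"]
    ).set_index("sample_id")
    return df


def _annotation(
    config: SimulationConfig,
    rng: np.random.Generator,
    age_idx: np.ndarray,
) -> pd.DataFrame:
    p = config.n_probes
    probe_ids = [f"cg{j + 1:06d}" for j in range(p)]
    chrom = rng.integers(1, config.n_chromosomes + 1, size=p)
    position = rng.integers(1, 200_000_000, size=p)
    island = rng.random(p) < config.island_prob
    states = list(config.state_freqs)
    freqs = np.array([config.state_freqs[s] for s in states], dtype=float)
    freqs = freqs / freqs.sum()
    chromatin = rng.choice(states, size=p, p=freqs)
    # TSS distance: a promoter-proximal mode plus a broad distal component
    near = rng.random(p) < 0.4
    tss = np.where(
        near,
        np.clip(np.round(rng.normal(0, 800, size=p)), -2000, 2000),
        np.round(rng.uniform(-50_000, 50_000, size=p)),
    ).astype(int)
    if config.age_cpg_placement == "promoter":
        tss[age_idx] = rng.integers(-2000, 501, size=len(age_idx))
    elif config.age_cpg_placement == "island":
        island[age_idx] = True
    genes = np.array([f"Gene{c}_{j % 500}" for j, c in enumerate(chrom)])
    return pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "position": position,
            "gene": genes,
            "tss_distance": tss,
            "island": island,
            "chromatin_state": chromatin,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[MethylationDataset, SyntheticTruth]:
    """Generate a dataset plus its ground-truth registry.

    Bit-identical output for identical config (the seed lives in the
    config).
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config, rng)
    n, p = len(samples), config.n_probes

    # disjoint spiked index blocks
    cursor = 0
    def take(k):
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        cursor += k
        return idx

    age_idx = take(config.n_age_cpgs)
    sex_idx = take(config.n_sex_cpgs)
    tissue_idx = take(config.n_tissue_cpgs)
    gmulti_idx = take(config.n_group_multi_cpgs)
    gsingle_idx = take(config.n_group_single_cpgs)

    probes = _annotation(config, rng, age_idx)
    probe_ids = probes.index

    mu = rng.choice([-2.0, 2.0], size=p) + rng.normal(0, 0.5, size=p)

    a = np.zeros(p)
    a[age_idx] = rng.choice([-1.0, 1.0], size=len(age_idx)) * config.age_effect
    s = np.zeros(p)
    s[sex_idx] = rng.choice([-1.0, 1.0], size=len(sex_idx)) * config.sex_effect

    tissues = list(config.tissues)
    d = np.zeros((p, len(tissues)))
    tissue_assign = {}
    for k, j in enumerate(tissue_idx):
        t = k % len(tissues)
        d[j, t] = config.tissue_effect
        tissue_assign[j] = tissues[t]

    g = np.zeros(p)
    g_affected = {}
    g[gmulti_idx] = rng.choice([-1.0, 1.0], size=len(gmulti_idx)) * config.group_effect
    for j in gmulti_idx:
        g_affected[j] = "all"
    g[gsingle_idx] = rng.choice([-1.0, 1.0], size=len(gsingle_idx)) * config.group_effect
    for k, j in enumerate(gsingle_idx):
        g_affected[j] = tissues[k % len(tissues)]

    age = samples["age"].to_numpy(dtype=float)
    lifespans = np.where(
        samples["species"].to_numpy() == config.species,
        config.lifespan,
        config.second_species.lifespan if config.second_species else config.lifespan,
    )
    F = age / lifespans * config.lifespan
    male = (samples["sex"].to_numpy() == "M").astype(float)
    bonded = (samples["group"].to_numpy() == "pair_bonded").astype(float)
    tissue_of = samples["tissue"].to_numpy()
    tissue_col = np.array(
        [tissues.index(t) if t in tissues else -1 for t in tissue_of]
    )

    logit = np.tile(mu[:, None], (1, n))
    # bonded animals may age at a different rate on the spiked age CpGs
    rate = 1.0 + (config.group_slope_multiplier - 1.0) * bonded
    logit += a[:, None] * (F * rate)[None, :]
    logit += s[:, None] * male[None, :]
    valid_t = tissue_col >= 0
    logit[:, valid_t] += d[:, tissue_col[valid_t]]
    group_mask = np.zeros((p, n))
    for j, affected in g_affected.items():
        if affected == "all":
            group_mask[j] = bonded
        else:
            group_mask[j] = bonded * (tissue_of == affected)
    logit += g[:, None] * group_mask
    if config.noise_sd > 0:
        logit += rng.normal(0, config.noise_sd, size=(p, n))

    beta = pd.DataFrame(_logistic(logit), index=probe_ids, columns=samples.index)

    effects = []
    for j in age_idx:
        effects.append((probe_ids[j], "age", a[j], "all"))
    for j in sex_idx:
        effects.append((probe_ids[j], "sex", s[j], "all"))
    for j in tissue_idx:
        effects.append((probe_ids[j], "tissue", config.tissue_effect, tissue_assign[j]))
    for j in gmulti_idx:
        effects.append((probe_ids[j], "group_multi", g[j], "all"))
    for j in gsingle_idx:
        effects.append((probe_ids[j], "group_single", g[j], g_affected[j]))
    truth = SyntheticTruth(
        effects=pd.DataFrame(
            effects, columns=["probe_id", "effect_type", "effect_size", "affected"]
        ),
        samples=samples.copy(),
        config=config,
    )
    ds = MethylationDataset(beta=beta, samples=samples, probes=probes)
    return ds, truth


def truth_report(
    truth: SyntheticTruth,
    selected,
    effect_type: str,
) -> dict:
    """Recovery metrics for a selection against the spiked CpGs of one type.

    Sensitivity is the fraction of spiked CpGs selected; the false-discovery
    proportion is the fraction of selections that are not spiked with that
    effect type (undefined for an empty selection).
    """
    spiked = set(truth.spiked(effect_type))
    sel = set(selected)
    recovered = len(sel & spiked)
    sensitivity = recovered / len(spiked) if spiked else float("nan")
    fdp = None if not sel else 1.0 - recovered / len(sel)
    return {
        "effect_type": effect_type,
        "n_spiked": len(spiked),
        "n_selected": len(sel),
        "n_recovered": recovered,
        "sensitivity": sensitivity,
        "false_discovery_proportion": fdp,
    }
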