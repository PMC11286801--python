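"""Core containers for methylation data.

A :class:`MethylationDataset` bundles a probes x samples beta matrix with
aligned sample and probe metadata. Beta values are methylation fractions in
[0, 1]; missing measurements are stored as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ["age", "sex", "tissue", "group", "species"]
PROBE_ANNOTATION_COLUMNS = [
    "chromosome",
    "position",
    "gene",
    "tss_distance",
    "island",
    "chromatin_state",
]

#: tolerance beyond which a beta value is rejected as out of [0, 1]
BETA_BOUND_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a dataset invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sample (one tissue from one animal)."""

    sample_id: str
    age: float
    sex: str
    tissue: str
    group: str
    species: str = "vole"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"sample {self.sample_id!r}: age must be >= 0")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sample {self.sample_id!r}: sex must be F or M")


@dataclass(frozen=True)
class ProbeRecord:
    """Annotation for one array probe (one CpG)."""

    probe_id: str
    chromosome: str
    position: int
    gene: str = ""
    tss_distance: int = 0
    island: bool = False
    chromatin_state: str = "NA"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"probe {self.probe_id!r}: position must be >= 1 (1-based)"
            )


@dataclass
class MethylationDataset:
    """Beta matrix plus aligned sample and probe metadata.

    Parameters
    ----------
    beta
        DataFrame of beta values, index = probe ids, columns = sample ids.
    samples
        DataFrame indexed by sample id with columns
        ``age, sex, tissue, group, species``.
    probes
        DataFrame indexed by probe id with columns
        ``chromosome, position, gene, tss_distance, island, chromatin_state``.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if list(self.beta.index) != list(self.probes.index):
            raise ValidationError("beta rows do not match probe annotation order")
        if list(self.beta.columns) != list(self.samples.index):
            raise ValidationError("beta columns do not match sample sheet order")
        if self.samples.index.duplicated().any():
            dupes = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.probes.index.duplicated().any():
            dupes = self.probes.index[self.probes.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dupes}")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        missing = [c for c in PROBE_ANNOTATION_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValidationError(f"probe annotation missing columns: {missing}")
        values = self.beta.to_numpy(dtype=float)
        bad = (values < -BETA_BOUND_TOL) | (values > 1 + BETA_BOUND_TOL)
        if np.any(bad & np.isfinite(values)):
            i, j = np.argwhere(bad & np.isfinite(values))[0]
            raise ValidationError(
                f"beta value {values[i, j]} outside [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if (self.samples["age"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative age in sample sheet")
        bad_sex = set(self.samples["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"invalid sex labels: {sorted(bad_sex)}")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationDataset":
        ids = [s for s in self.samples.index if s in set(sample_ids)]
        return MethylationDataset(
            beta=self.beta[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            probes=self.probes.copy(),
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationDataset":
        ids = [p for p in self.probes.index if p in set(probe_ids)]
        return MethylationDataset(
            beta=self.beta.loc[ids].copy(),
            samples=self.samples.copy(),
            probes=self.probes.loc[ids].copy(),
        )

    def where_samples(self, mask: Iterable[bool]) -> "MethylationDataset":
        mask = np.asarray(list(mask), dtype=bool)
        ids = self.samples.index[mask]
        return self.subset_samples(ids)

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            beta=self.beta.copy(), samples=self.samples.copy(), probes=self.probes.copy()
        )


@dataclass
class DropReport:
    """Ids discarded while intersecting beta matrix, sample sheet and annotation."""

    dropped_samples: list = field(default_factory=list)
    dropped_probes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", s) for s in self.dropped_samples] + [
            ("probe", p) for p in self.dropped_probes
        ]
        return pd.DataFrame(rows, columns=["kind", "id"])
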