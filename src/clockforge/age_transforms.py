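"""Age transforms used as the regression scale for epigenetic clocks.

Three bijective mappings from chronological age to the scale on which the
penalized regression is fit:

``identity``
    No transformation; used for single-species pan-tissue clocks.
``loglinear``
    Piecewise map, logarithmic below a maturity age and linear above::

        f(age) = log(age + offset) - log(adult_age + offset)   if age < adult_age
        f(age) = (age - adult_age) / (adult_age + offset)      otherwise

    Continuous (both branches are 0 at ``adult_age``) and strictly
    increasing; compresses the fast juvenile methylation change so that a
    dual-species absolute-age clock is not dominated by it.
``relative``
    Age divided by the species' maximum recorded lifespan, so values lie in
    [0, 1] for any species and are comparable across species.

Default lifespans: prairie vole 5.3 years, human 122.5 years (maximum
recorded ages from the AnAge database).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_LIFESPANS = {"vole": 5.3, "human": 122.5}

#: default maturity ages for the loglinear transform, per species
DEFAULT_ADULT_AGE = {"vole": 0.3, "human": 20.0}


@dataclass(frozen=True)
class AgeTransformSpec:
    """Declarative description of an age transform.

    Parameters
    ----------
    kind
        One of ``identity``, ``loglinear``, ``relative``.
    adult_age
        Maturity age in years (loglinear only). Default 0.3 y, the age of
        sexual maturity in prairie voles.
    offset
        Additive offset in years inside the logarithm (loglinear only),
        keeping the transform finite at age 0. Default 0.06 y, just below
        the youngest animal in the reference design.
    lifespans
        Mapping species -> maximum lifespan in years (relative only).
    """

    kind: str
    adult_age: float = 0.3
    offset: float = 0.06
    lifespans: dict = field(default_factory=lambda: dict(DEFAULT_LIFESPANS))

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "loglinear", "relative"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if any(v <= 0 for v in self.lifespans.values()):
            raise ValueError("all lifespans must be > 0")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "adult_age": self.adult_age,
            "offset": self.offset,
            "lifespans": dict(self.lifespans),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeTransformSpec":
        return cls(
            kind=d["kind"],
            adult_age=float(d.get("adult_age", 0.3)),
            offset=float(d.get("offset", 0.06)),
            lifespans={k: float(v) for k, v in d.get(
                "lifespans", DEFAULT_LIFESPANS).items()},
        )

    def _lifespan_for(self, species) -> np.ndarray:
        species = np.asarray(species, dtype=object)
        out = np.empty(species.shape, dtype=float)
        for sp in np.unique(species):
            if sp not in self.lifespans:
                raise KeyError(f"no lifespan configured for species {sp!r}")
            out[species == sp] = self.lifespans[sp]
        return out


def transform(spec: AgeTransformSpec, age, species="vole") -> np.ndarray:
    """Map chronological age (years) onto the regression scale."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("age must be >= 0")
    scalar = age_arr.ndim == 0
    age_arr = np.atleast_1d(age_arr)
    if spec.kind == "identity":
        out = age_arr.copy()
    elif spec.kind == "relative":
        sp = np.atleast_1d(np.asarray(species, dtype=object))
        if sp.shape != age_arr.shape:
            sp = np.full(age_arr.shape, sp.item() if sp.size == 1 else None,
                         dtype=object)
        out = age_arr / spec._lifespan_for(sp)
    else:  # loglinear
        a, off = spec.adult_age, spec.offset
        below = age_arr < a
        out = np.where(
            below,
            np.log(age_arr + off) - np.log(a + off),
            (age_arr - a) / (a + off),
        )
    return out.item() if scalar else out


def inverse_transform(spec: AgeTransformSpec, value, species="vole") -> np.ndarray:
    """Map a regression-scale value back to age in years.

    Exact inverse of :func:`transform`; relative-scale values that would map
    to a negative age are clamped to 0 with a warning.
    """
    val = np.asarray(value, dtype=float)
    scalar = val.ndim == 0
    val = np.atleast_1d(val)
    if spec.kind == "identity":
        out = val.copy()
    elif spec.kind == "relative":
        sp = np.atleast_1d(np.asarray(species, dtype=object))
        if sp.shape != val.shape:
            sp = np.full(val.shape, sp.item() if sp.size == 1 else None, dtype=object)
        out = val * spec._lifespan_for(sp)
        if np.any(out < 0):
            warnings.warn("relative value maps to negative age; clamped to 0")
            out = np.clip(out, 0, None)
    else:  # loglinear
        a, off = spec.adult_age, spec.offset
        below = val < 0
        out = np.where(
            below,
            np.exp(val + np.log(a + off)) - off,
            val * (a + off) + a,
        )
    return out.item() if scalar else out
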