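"""Genomic-context enrichment of selected CpGs.

Top CpGs from a screen (the foreground) are contrasted with a background
set — by default every annotated probe — in three ways:

* Fisher's exact (hypergeometric) test per category label, e.g. chromatin
  state or PRC2 binding, on the 2x2 table foreground/background x in/out of
  category, with the sample odds ratio (a*d)/(b*c);
* a TSS-location breakdown, binning probes by signed distance to the
  nearest transcription start site and testing each bin the same way;
* a CpG-island contrast of aging effects, a Welch two-sample t-test of the
  Fisher z-scores of island vs non-island CpGs.

Two-sided Fisher p-values follow the standard exact convention: the sum of
probabilities of all tables (with the observed margins) no more likely than
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Fig-style significance stars; strict inequalities, so p = 0.05 gets none
STAR_THRESHOLDS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]

#: default signed TSS-distance bins (bp); negative = upstream of the TSS
DEFAULT_TSS_BINS = {
    "promoter": (-2000, 500),
    "proximal": (-5000, 5000),   # excluding the promoter window
    "distal": None,              # everything else
}

CHROMATIN_STATE_GROUPS = [
    "BivProm", "EnhA", "EnhW", "Quies", "ReprPC", "TSS", "Tx", "PRC2",
]


def stars(p: float) -> str:
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


def _fisher_table(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    if c == 0 and d == 0:
        # foreground covers the whole background: no contrast to test
        return 1.0, 1.0
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else np.nan)
    return float(odds), float(p)


def fisher_enrichment(
    foreground, background, category: pd.Series
) -> pd.DataFrame:
    """Per-label Fisher exact enrichment of foreground within background.

    ``category`` maps probe id -> label. For each label the 2x2 table is
    (foreground, background-minus-foreground) x (in label, not in label);
    the odds ratio is (a*d)/(b*c) with infinity encoded explicitly when a
    background cell is empty.
    """
    fg = list(dict.fromkeys(foreground))
    bg = list(dict.fromkeys(background))
    fg_set, bg_set = set(fg), set(bg)
    if not fg_set:
        raise ValueError("foreground is empty")
    if not fg_set <= bg_set:
        raise ValueError("foreground is not a subset of background")
    cat = category.reindex(bg)
    labels = sorted(cat.dropna().unique())
    in_fg = cat.index.isin(fg_set)
    rows = []
    for label in labels:
        in_label = (cat == label).to_numpy()
        a = int((in_label & in_fg).sum())
        b = int((~in_label & in_fg).sum())
        c = int((in_label & ~in_fg).sum())
        d = int((~in_label & ~in_fg).sum())
        odds, p = _fisher_table(a, b, c, d)
        rows.append(
            {
                "category": label,
                "foreground_count": a,
                "foreground_total": len(fg),
                "background_count": a + c,
                "background_total": len(bg),
                "odds_ratio": odds,
                "p": p,
                "stars": stars(p),
                "direction": "enriched" if odds > 1 else (
                    "depleted" if odds < 1 else "none"),
            }
        )
    return pd.DataFrame(rows)


def assign_tss_bins(
    tss_distance: pd.Series, bins: dict | None = None
) -> pd.Series:
    """Assign each probe to a TSS-distance bin by signed distance."""
    bins = dict(DEFAULT_TSS_BINS) if bins is None else bins
    dist = tss_distance.astype(float)
    out = pd.Series(index=dist.index, dtype=object)
    bounded = [(name, rng) for name, rng in bins.items() if rng is not None]
    catchall = [name for name, rng in bins.items() if rng is None]
    assigned = pd.Series(False, index=dist.index)
    for name, (lo, hi) in bounded:
        sel = (~assigned) & (dist >= lo) & (dist <= hi)
        out[sel] = name
        assigned |= sel
    if catchall:
        out[~assigned] = catchall[0]
    return out


def tss_location_breakdown(
    foreground, background, probes: pd.DataFrame, bins: dict | None = None
) -> pd.DataFrame:
    """Fisher enrichment of the foreground over TSS-distance bins."""
    usable = probes["tss_distance"].dropna()
    n_dropped = len(probes) - len(usable)
    binned = assign_tss_bins(usable, bins)
    out = fisher_enrichment(
        [p for p in foreground if p in binned.index],
        [p for p in background if p in binned.index],
        binned,
    )
    out.attrs["n_dropped"] = n_dropped
    return out


@dataclass
class IslandContrast:
    t: float
    df: float
    p: float
    island_mean: float
    non_island_mean: float
    island_median: float
    non_island_median: float
    n_island: int
    n_non_island: int


def island_zscore_contrast(
    records: pd.DataFrame, island: pd.Series
) -> IslandContrast:
    """Welch t-test of aging Fisher z-scores, island vs non-island CpGs."""
    flags = island.reindex(records["probe_id"]).to_numpy(dtype=bool)
    z = records["z"].to_numpy(dtype=float)
    z_isl = z[flags & np.isfinite(z)]
    z_non = z[~flags & np.isfinite(z)]
    if len(z_isl) < 2 or len(z_non) < 2:
        raise ValueError("need at least 2 CpGs in each island group")
    res = stats.ttest_ind(z_isl, z_non, equal_var=False)
    return IslandContrast(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        island_mean=float(z_isl.mean()),
        non_island_mean=float(z_non.mean()),
        island_median=float(np.median(z_isl)),
        non_island_median=float(np.median(z_non)),
        n_island=len(z_isl),
        n_non_island=len(z_non),
    )


def chromatin_state_enrichment(
    foreground, background, probes: pd.DataFrame
) -> pd.DataFrame:
    """Fisher enrichment over chromatin-state labels (NA states excluded)."""
    state = probes["chromatin_state"].astype(str)
    annotated = state[state != "NA"]
    fg = [p for p in foreground if p in annotated.index]
    bg = [p for p in background if p in annotated.index]
    return fisher_enrichment(fg, bg, annotated)
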