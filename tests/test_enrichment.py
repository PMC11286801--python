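import numpy as np
import pandas as pd
import pytest

from clockforge.enrichment import (
    assign_tss_bins,
    chromatin_state_enrichment,
    fisher_enrichment,
    island_zscore_contrast,
    stars,
    tss_location_breakdown,
)
from clockforge.synthetic import SimulationConfig, generate_dataset
from clockforge.ewas import ewas_age, select_significant, stouffer_meta

from oracles import fisher_two_sided_oracle


def _category(labels):
    return pd.Series(labels)


class TestFisherEnrichment:
    def test_worked_example_odds_ratio(self):
        # foreground 10/20 in islands, background 100/1000
        bg = [f"p{i}" for i in range(1000)]
        labels = ["island" if i < 100 else "open_sea" for i in range(1000)]
        # foreground: 10 island probes, 10 non-island probes
        fg = bg[:10] + bg[100:110]
        table = fisher_enrichment(fg, bg, _category(pd.Series(labels, index=bg)))
        row = table.set_index("category").loc["island"]
        assert row["odds_ratio"] == pytest.approx((10 * 890) / (10 * 90), rel=1e-12)
        assert row["p"] == pytest.approx(
            fisher_two_sided_oracle(10, 10, 90, 890), rel=1e-8
        )

    def test_null_draws_calibrated(self):
        rng = np.random.default_rng(40)
        bg = [f"p{i}" for i in range(400)]
        labels = pd.Series(rng.choice(["a", "b"], size=400), index=bg)
        pvals, ors = [], []
        for _ in range(200):
            fg = list(rng.choice(bg, size=40, replace=False))
            table = fisher_enrichment(fg, bg, labels).set_index("category")
            pvals.append(table.loc["a", "p"])
            ors.append(table.loc["a", "odds_ratio"])
        assert np.median(ors) == pytest.approx(1.0, abs=0.3)
        # discrete p-values are super-uniform; check no excess of small p
        assert np.mean(np.array(pvals) < 0.05) <= 0.08

    def test_zero_foreground_cell(self):
        bg = [f"p{i}" for i in range(50)]
        labels = pd.Series(["rare"] * 5 + ["common"] * 45, index=bg)
        fg = bg[10:20]  # all "common"
        table = fisher_enrichment(fg, bg, labels).set_index("category")
        assert table.loc["rare", "odds_ratio"] == 0.0
        assert 0 < table.loc["rare", "p"] <= 1

    def test_foreground_not_subset_errors(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment(["x"], ["a", "b"], _category(pd.Series()))

    def test_exhaustive_small_tables_match_enumeration(self):
        # every 2x2 split of small backgrounds against the hypergeometric oracle
        rng = np.random.default_rng(41)
        for _ in range(60):
            n_bg = int(rng.integers(6, 30))
            n_lab = int(rng.integers(1, n_bg))
            n_fg = int(rng.integers(1, n_bg))
            bg = [f"p{i}" for i in range(n_bg)]
            labels = pd.Series(
                ["in"] * n_lab + ["out"] * (n_bg - n_lab), index=bg)
            fg = list(rng.choice(bg, size=n_fg, replace=False))
            table = fisher_enrichment(fg, bg, labels).set_index("category")
            a = sum(1 for p in fg if labels[p] == "in")
            b = len(fg) - a
            c = n_lab - a
            d = (n_bg - n_lab) - b
            if "in" in table.index:
                assert table.loc["in", "p"] == pytest.approx(
                    fisher_two_sided_oracle(a, b, c, d), rel=1e-8, abs=1e-12
                )

    def test_label_permutation_equivariance(self):
        bg = [f"p{i}" for i in range(100)]
        labels = pd.Series((["x"] * 30 + ["y"] * 30 + ["z"] * 40), index=bg)
        fg = bg[:25]
        t1 = fisher_enrichment(fg, bg, labels).set_index("category")
        renamed = labels.map({"x": "z", "y": "x", "z": "y"})
        t2 = fisher_enrichment(fg, bg, renamed).set_index("category")
        for old, new in (("x", "z"), ("y", "x"), ("z", "y")):
            assert t1.loc[old, "p"] == pytest.approx(t2.loc[new, "p"])
            assert t1.loc[old, "odds_ratio"] == pytest.approx(
                t2.loc[new, "odds_ratio"], nan_ok=True
            )


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.05, ""),       # boundary: strict inequality
            (0.049, "*"),
            (0.01, "*"),
            (0.009, "**"),
            (0.001, "**"),
            (0.0009, "***"),
            (0.0001, "***"),
            (0.00009, "****"),
        ],
    )
    def test_thresholds_strict(self, p, expected):
        assert stars(p) == expected


class TestTssBreakdown:
    def test_binning_rule(self):
        dist = pd.Series([-200, -2000, 500, -2001, 4999, 5001, 0],
                         index=list("abcdefg"))
        bins = assign_tss_bins(dist)
        assert bins["a"] == "promoter"
        assert bins["b"] == "promoter"
        assert bins["c"] == "promoter"
        assert bins["d"] == "proximal"
        assert bins["e"] == "proximal"
        assert bins["f"] == "distal"
        assert bins["g"] == "promoter"

    def test_foreground_equals_background(self):
        rng = np.random.default_rng(42)
        probes = pd.DataFrame(
            {"tss_distance": rng.integers(-40000, 40000, 60)},
            index=[f"p{i}" for i in range(60)],
        )
        table = tss_location_breakdown(
            list(probes.index), list(probes.index), probes
        )
        assert np.allclose(table["odds_ratio"], 1.0)
        assert np.allclose(table["p"], 1.0)

    def test_promoter_placed_age_cpgs_enriched(self):
        cfg = SimulationConfig(seed=10, n_samples=100, tissues=("blood",),
                               n_probes=1000, n_age_cpgs=50, n_sex_cpgs=0,
                               n_tissue_cpgs=0, n_group_multi_cpgs=0,
                               n_group_single_cpgs=0, noise_sd=0.2,
                               age_cpg_placement="promoter")
        ds, truth = generate_dataset(cfg)
        records = ewas_age(ds)
        meta = stouffer_meta(records)
        fg = select_significant(meta, 1e-5)["probe_id"].tolist()
        assert len(fg) > 10
        table = tss_location_breakdown(fg, list(ds.probes.index), ds.probes)
        row = table.set_index("category").loc["promoter"]
        assert row["p"] < 0.001
        assert row["odds_ratio"] > 1


class TestIslandContrast:
    def test_tied_hand_instance(self):
        rec = pd.DataFrame(
            {"probe_id": list("abcdef"), "z": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
        )
        island = pd.Series([True, True, True, False, False, False],
                           index=list("abcdef"))
        res = island_zscore_contrast(rec, island)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_shifted_islands_detected(self):
        rng = np.random.default_rng(43)
        n = 500
        z = np.concatenate([rng.normal(1.0, 1, n), rng.normal(0, 1, n)])
        ids = [f"p{i}" for i in range(2 * n)]
        rec = pd.DataFrame({"probe_id": ids, "z": z})
        island = pd.Series([True] * n + [False] * n, index=ids)
        res = island_zscore_contrast(rec, island)
        assert res.p < 1e-10
        assert res.island_mean > res.non_island_mean

    def test_permuted_flags_calibrated(self):
        rng = np.random.default_rng(44)
        ids = [f"p{i}" for i in range(200)]
        rec = pd.DataFrame({"probe_id": ids, "z": rng.normal(0, 1, 200)})
        pvals = []
        for _ in range(200):
            flags = pd.Series(rng.permutation([True] * 100 + [False] * 100),
                              index=ids)
            pvals.append(island_zscore_contrast(rec, flags).p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_tiny_group_errors(self):
        rec = pd.DataFrame({"probe_id": ["a", "b", "c"], "z": [1.0, 2.0, 3.0]})
        island = pd.Series([True, False, False], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            island_zscore_contrast(rec, island)


class TestChromatinStates:
    def test_na_states_excluded_from_background(self):
        rng = np.random.default_rng(45)
        probes = pd.DataFrame(
            {
                "chromatin_state": ["PRC2"] * 20 + ["Quies1"] * 60 + ["NA"] * 20,
            },
            index=[f"p{i}" for i in range(100)],
        )
        fg = [f"p{i}" for i in range(15)]  # all PRC2
        table = chromatin_state_enrichment(fg, list(probes.index), probes)
        assert "NA" not in set(table["category"])
        row = table.set_index("category").loc["PRC2"]
        assert row["background_total"] == 80
        assert row["odds_ratio"] > 1
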