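import numpy as np
import pandas as pd
import pytest

from clockforge.ewas import (
    benjamini_hochberg,
    cross_stratum_overlap,
    ewas_age,
    ewas_trait,
    select_significant,
    stouffer_meta,
)
from clockforge.synthetic import SimulationConfig, generate_dataset

from conftest import make_dataset
from oracles import ols_oracle, pearson_oracle, stouffer_oracle


class TestEwasAge:
    def test_orthogonal_vectors_give_null_record(self):
        n = 50
        age = np.linspace(0.1, 1.3, n)
        centered = age - age.mean()
        # construct beta exactly orthogonal to age
        v = np.tile([1.0, -1.0], n // 2)
        v = v - v.mean()
        v = v - (v @ centered) / (centered @ centered) * centered
        beta = 0.5 + 0.1 * v / np.abs(v).max()
        ds = make_dataset(beta[None, :], ages=age)
        rec = ewas_age(ds).iloc[0]
        assert rec["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert rec["p"] == pytest.approx(1.0)
        assert rec["z"] == pytest.approx(0.0, abs=1e-10)

    def test_perfect_linear_cpg(self):
        age = np.linspace(0.1, 1.3, 30)
        beta = 0.1 + 0.5 * age / 1.31
        ds = make_dataset(beta[None, :], ages=age)
        rec = ewas_age(ds).iloc[0]
        assert rec["p"] < 1e-10
        assert rec["direction"] == "gain"
        assert np.isfinite(rec["z"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(30)
        beta = rng.uniform(0.1, 0.9, size=(20, 30))
        ages = rng.uniform(0.1, 1.3, 30)
        ds = make_dataset(beta, ages=ages)
        records = ewas_age(ds)
        for i, rec in records.iterrows():
            r, t, p, z = pearson_oracle(beta[i], ages)
            assert rec["estimate"] == pytest.approx(r, abs=1e-10)
            assert rec["p"] == pytest.approx(p, abs=1e-10)
            assert rec["z"] == pytest.approx(z, abs=1e-10)

    def test_fisher_z_identity(self):
        rng = np.random.default_rng(31)
        beta = rng.uniform(0.1, 0.9, size=(5, 25))
        ds = make_dataset(beta, ages=rng.uniform(0.1, 1.3, 25))
        records = ewas_age(ds)
        z_expected = np.arctanh(records["estimate"]) * np.sqrt(records["n"] - 3)
        assert np.allclose(records["z"], z_expected, atol=1e-10)

    def test_zero_variance_probe_flagged(self):
        beta = np.vstack([np.full(20, 0.5),
                          np.random.default_rng(0).uniform(0.2, 0.8, 20)])
        ds = make_dataset(beta, ages=np.linspace(0.1, 1.3, 20))
        records = ewas_age(ds)
        rec = records.iloc[0]
        assert rec["flag"] == "zero_variance"
        assert rec["p"] == 1.0

    def test_pairwise_deletion_of_missing(self):
        rng = np.random.default_rng(32)
        ages = rng.uniform(0.1, 1.3, 20)
        beta = rng.uniform(0.1, 0.9, size=(1, 20))
        beta_missing = beta.copy()
        beta_missing[0, 3] = np.nan
        ds = make_dataset(beta_missing, ages=ages)
        rec = ewas_age(ds).iloc[0]
        keep = np.ones(20, bool)
        keep[3] = False
        r, t, p, z = pearson_oracle(beta[0, keep], ages[keep])
        assert rec["n"] == 19
        assert rec["estimate"] == pytest.approx(r, abs=1e-10)
        assert rec["p"] == pytest.approx(p, abs=1e-10)


class TestEwasTrait:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(33)
        n = 10
        beta = rng.uniform(0.1, 0.9, size=(6, n))
        ages = rng.uniform(0.4, 1.3, n)
        groups = ["pair_bonded", "sex_naive"] * 5
        ds = make_dataset(beta, ages=ages, groups=groups, sexes=["F"] * n)
        records = ewas_trait(ds, reference="sex_naive", adults_only=False,
                             per_stratum=("sex",))
        ind = (np.array(groups) != "sex_naive").astype(float)
        D = np.column_stack([np.ones(n), ind, ages])
        for i, rec in records.iterrows():
            b, se, t, p, _ = ols_oracle(D, beta[i])
            assert rec["estimate"] == pytest.approx(b[1], abs=1e-8)
            assert rec["z"] == pytest.approx(t[1], abs=1e-8)
            assert rec["p"] == pytest.approx(p[1], abs=1e-8)

    def test_permuted_labels_calibrated(self):
        # null data, permuted trait: fraction of p < 0.005 within the
        # binomial 99% interval over 2000 CpG-tests
        cfg = SimulationConfig(seed=8, n_samples=70, n_probes=2000,
                               tissues=("blood",), n_age_cpgs=0, n_sex_cpgs=0,
                               n_tissue_cpgs=0, n_group_multi_cpgs=0,
                               n_group_single_cpgs=0, noise_sd=0.3)
        ds, _ = generate_dataset(cfg)
        rng = np.random.default_rng(8)
        sheet = ds.samples.copy()
        sheet["group"] = rng.permutation(sheet["group"].to_numpy())
        sheet["sex"] = "F"
        from clockforge.datatypes import MethylationDataset

        dsp = MethylationDataset(beta=ds.beta, samples=sheet, probes=ds.probes)
        records = ewas_trait(dsp, reference="sex_naive")
        rate = float((records["p"] < 0.005).mean())
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], len(records), 0.005) / len(records)
        assert lo <= rate <= hi

    def test_spiked_group_shift_detected(self):
        rng = np.random.default_rng(34)
        n = 70
        groups = (["pair_bonded"] * 35 + ["sex_naive"] * 35)
        ages = rng.uniform(0.4, 1.3, n)
        beta = np.clip(rng.normal(0.5, 0.05, size=(1, n)), 0.01, 0.99)
        beta[0, :35] += 0.15
        ds = make_dataset(np.clip(beta, 0, 1), ages=ages, groups=groups,
                          sexes=["F"] * n)
        rec = ewas_trait(ds, reference="sex_naive", per_stratum=("sex",)).iloc[0]
        assert rec["p"] < 0.005
        assert rec["direction"] == "gain"

    def test_single_level_stratum_skipped_with_warning(self):
        rng = np.random.default_rng(35)
        n = 20
        ds = make_dataset(
            rng.uniform(0.2, 0.8, (3, n)),
            ages=rng.uniform(0.4, 1.3, n),
            groups=["pair_bonded"] * 10 + ["sex_naive"] * 10,
            sexes=["F"] * 15 + ["M"] * 5,
        )
        with pytest.warns(UserWarning, match="single trait level"):
            records = ewas_trait(ds, reference="sex_naive", per_stratum=("sex",),
                                 adults_only=False)
        assert set(records["stratum"]) == {"F"}


class TestStoufferMeta:
    @staticmethod
    def _records(zs, ns, probe="cg1"):
        return pd.DataFrame(
            {
                "probe_id": [probe] * len(zs),
                "stratum": [f"t{i}" for i in range(len(zs))],
                "n": ns,
                "statistic": "pearson_r",
                "estimate": 0.1,
                "z": zs,
                "p": 0.5,
                "direction": "gain",
                "flag": "",
            }
        )

    def test_single_stratum_identity(self):
        out = stouffer_meta(self._records([2.5], [30]))
        assert out["z"].iloc[0] == pytest.approx(2.5)

    def test_equal_weights_closed_form(self):
        out = stouffer_meta(self._records([2.0, 2.0, 2.0], [30, 30, 30]))
        assert out["z"].iloc[0] == pytest.approx(2 * np.sqrt(3))

    def test_antisymmetric_pair_cancels(self):
        out = stouffer_meta(self._records([3.0, -3.0], [30, 30]))
        assert out["z"].iloc[0] == pytest.approx(0.0)

    def test_matches_weighted_oracle(self):
        rng = np.random.default_rng(36)
        zs = rng.normal(0, 2, 4)
        ns = rng.integers(10, 100, 4)
        out = stouffer_meta(self._records(list(zs), list(ns)))
        assert out["z"].iloc[0] == pytest.approx(
            stouffer_oracle(zs, np.sqrt(ns)), abs=1e-12
        )

    def test_order_invariance(self):
        rec = self._records([1.0, -2.0, 0.5], [10, 20, 30])
        out1 = stouffer_meta(rec)
        out2 = stouffer_meta(rec.iloc[::-1].reset_index(drop=True))
        assert out1["z"].iloc[0] == pytest.approx(out2["z"].iloc[0])

    def test_duplicating_stratum_scales_by_sqrt2(self):
        rec1 = self._records([2.0], [30])
        rec2 = self._records([2.0, 2.0], [30, 30])
        z1 = stouffer_meta(rec1, weights="unit")["z"].iloc[0]
        z2 = stouffer_meta(rec2, weights="unit")["z"].iloc[0]
        assert z2 == pytest.approx(z1 * np.sqrt(2))

    def test_missing_z_excluded(self):
        rec = self._records([2.0, np.nan], [30, 30])
        out = stouffer_meta(rec)
        assert out["z"].iloc[0] == pytest.approx(2.0)
        assert out.attrs["n_excluded"] == 1


class TestSelectSignificant:
    def test_strict_inequality(self):
        rec = pd.DataFrame({"p": [1e-6, 1e-5, 2e-5], "direction": ["gain"] * 3})
        out = select_significant(rec, 1e-5)
        assert len(out) == 1

    def test_empty_input(self):
        rec = pd.DataFrame({"p": [], "direction": []})
        assert len(select_significant(rec, 0.05)) == 0


class TestCrossStratumOverlap:
    @staticmethod
    def _sig(entries):
        return pd.DataFrame(
            [
                {"probe_id": p, "stratum": s, "p": 1e-4, "direction": d}
                for p, s, d in entries
            ]
        )

    def test_direction_consistency_rule(self):
        strata = [f"t{i}" for i in range(8)]
        sig = self._sig(
            [("cgA", s, "gain") for s in strata[:3]]
            + [("cgB", "t0", "gain"), ("cgB", "t1", "gain"), ("cgB", "t2", "loss")]
            + [("cgC", s, "gain") for s in strata]
        )
        probes, matrix = cross_stratum_overlap(sig, min_strata=3)
        assert "cgA" in probes and "cgC" in probes
        assert "cgB" not in probes
        probes2, _ = cross_stratum_overlap(
            sig, min_strata=3, require_consistent_direction=False
        )
        assert "cgB" in probes2

    def test_min_strata_one_gives_union(self):
        sig = self._sig([("cgA", "t0", "gain"), ("cgB", "t1", "loss")])
        probes, _ = cross_stratum_overlap(sig, min_strata=1)
        assert set(probes) == {"cgA", "cgB"}

    def test_recovers_multi_tissue_group_cpgs(self):
        cfg = SimulationConfig(seed=9)
        ds, truth = generate_dataset(cfg)
        records = ewas_trait(ds, reference="sex_naive")
        sig = select_significant(records, 0.005)
        probes, _ = cross_stratum_overlap(sig, min_strata=3)
        multi = set(truth.spiked("group_multi"))
        single = set(truth.spiked("group_single"))
        assert len(multi & set(probes)) >= 4
        # a single-tissue CpG is truly significant in only 2 sex-strata and
        # needs one chance hit elsewhere to leak in (expected ~0.4 per run)
        assert len(single & set(probes)) <= 2


class TestBH:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(37)
        p = rng.uniform(0, 1, 50)
        q = benjamini_hochberg(p)
        assert np.all((q >= p - 1e-12) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
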