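"""Cis scan statistics, q-values, lead-SNP calling, candidate-causal filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methqtl.core import GenotypeTable
from methqtl.mapping import (
    call_meqtls,
    cis_scan,
    estimate_qvalues,
    find_candidate_causal,
    probe_pair_correlation,
)


def _one_to_one_dataset(n_pairs=50, n=64, seed=0):
    """Each probe has exactly one SNP in its window: isolated regressions."""
    rng = np.random.default_rng(seed)
    spacing = 10_000
    pos = np.arange(n_pairs) * spacing
    snp_ids = [f"s{i}" for i in range(n_pairs)]
    probe_ids = [f"p{i}" for i in range(n_pairs)]
    dosages = pd.DataFrame(
        rng.integers(0, 3, size=(n, n_pairs)).astype(float),
        index=[f"ind{i}" for i in range(n)], columns=snp_ids,
    )
    snps = pd.DataFrame({"chrom": "chr1", "pos": pos}, index=pd.Index(snp_ids, name="snp_id"))
    geno = GenotypeTable(dosages, snps)
    meth = pd.DataFrame(
        rng.normal(size=(n, n_pairs)), index=dosages.index, columns=probe_ids
    )
    manifest = pd.DataFrame({"chrom": "chr1", "pos": pos + 100},
                            index=pd.Index(probe_ids, name="probe_id"))
    return meth, geno, manifest


class TestCisScan:
    def test_matches_closed_form_t_test(self):
        meth, geno, manifest = _one_to_one_dataset(n_pairs=100, seed=1)
        assoc = cis_scan(meth, geno, manifest, maf_min=0.0).set_index("probe_id")
        assert len(assoc) == 100
        for i in range(100):
            res = stats.linregress(geno.dosages[f"s{i}"], meth[f"p{i}"])
            row = assoc.loc[f"p{i}"]
            assert abs(row["p_value"] - res.pvalue) < 1e-10
            assert abs(row["effect"] - res.slope) < 1e-10

    def test_constant_dosage_skipped(self):
        meth, geno, manifest = _one_to_one_dataset(n_pairs=3, n=10, seed=2)
        geno.dosages["s1"] = 1.0
        geno = GenotypeTable(geno.dosages, geno.snps.drop(columns="maf"))
        assoc = cis_scan(meth, geno, manifest, maf_min=0.0)
        assert set(assoc["snp_id"]) == {"s0", "s2"}

    def test_maf_threshold_is_strict(self):
        n = 50
        meth = pd.DataFrame(
            np.random.default_rng(3).normal(size=(n, 1)),
            index=[f"i{k}" for k in range(n)], columns=["p0"],
        )
        # 4/100 alleles -> maf 0.04 (excluded); 6/100 -> 0.06 (included)
        d04 = np.zeros(n); d04[:4] = 1
        d06 = np.zeros(n); d06[:6] = 1
        dosages = pd.DataFrame({"rare": d04, "common": d06}, index=meth.index)
        snps = pd.DataFrame({"chrom": "chr1", "pos": [100, 200]},
                            index=pd.Index(["rare", "common"], name="snp_id"))
        geno = GenotypeTable(dosages, snps)
        manifest = pd.DataFrame({"chrom": ["chr1"], "pos": [150]}, index=pd.Index(["p0"]))
        assoc = cis_scan(meth, geno, manifest, maf_min=0.05)
        assert set(assoc["snp_id"]) == {"common"}

    def test_window_boundary_inclusive(self):
        meth, geno, manifest = _one_to_one_dataset(n_pairs=2, n=20, seed=4)
        manifest.loc["p0", "pos"] = geno.snps.loc["s0", "pos"] + 3000
        manifest.loc["p1", "pos"] = geno.snps.loc["s1", "pos"] + 3001
        assoc = cis_scan(meth, geno, manifest, window=3000, maf_min=0.0)
        assert set(assoc["probe_id"]) == {"p0"}

    def test_too_few_samples_rejected(self):
        meth, geno, manifest = _one_to_one_dataset(n_pairs=2, n=3, seed=5)
        with pytest.raises(ValueError, match="at least 4"):
            cis_scan(meth, geno, manifest)

    def test_all_snps_failing_maf_warns_and_returns_empty(self, caplog):
        meth, geno, manifest = _one_to_one_dataset(n_pairs=2, n=20, seed=6)
        with caplog.at_level("WARNING"):
            assoc = cis_scan(meth, geno, manifest, maf_min=0.5)
        assert assoc.empty

    def test_permuted_genotypes_yield_uniform_p(self):
        meth, geno, manifest = _one_to_one_dataset(n_pairs=600, seed=7)
        assoc = cis_scan(meth, geno, manifest, maf_min=0.0)
        _, p = stats.kstest(assoc["p_value"], "uniform")
        assert p > 0.01


class TestQValues:
    def test_all_ones(self):
        q, _ = estimate_qvalues([1.0, 1.0, 1.0])
        np.testing.assert_array_equal(q, 1.0)

    def test_bh_worked_example(self):
        q, pi0 = estimate_qvalues([0.01, 0.02, 0.04, 0.5], pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5], rtol=1e-12)
        assert pi0 == 1.0

    def test_bh_equivalence_against_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.random(500) ** 2
        q, _ = estimate_qvalues(p, pi0=1.0)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, rtol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_q_monotone_in_p(self, ps):
        q, _ = estimate_qvalues(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            estimate_qvalues([0.5, 1.5])

    def test_empty_input(self):
        q, pi0 = estimate_qvalues([])
        assert q.size == 0

    def test_pi0_estimate_near_one_under_null(self):
        rng = np.random.default_rng(9)
        _, pi0 = estimate_qvalues(rng.random(5000))
        assert 0.8 <= pi0 <= 1.0


class TestCallMeqtls:
    def _assoc(self, rows):
        df = pd.DataFrame(rows, columns=["probe_id", "snp_id", "snp_pos", "distance", "p_value"])
        df["effect"] = 1.0
        df["se"] = 1.0
        df["t_stat"] = 1.0
        df["q_value"], _ = estimate_qvalues(df["p_value"].to_numpy(), pi0=1.0)
        df["direction"] = 1
        return df

    def test_no_significant_probes(self):
        assoc = self._assoc([("p1", "s1", 100, 50, 0.9)])
        assert call_meqtls(assoc, fdr=0.10).empty

    def test_single_lead_per_probe(self):
        assoc = self._assoc([("p1", "s1", 100, 50, 1e-8), ("p1", "s2", 200, 150, 1e-3)])
        out = call_meqtls(assoc, fdr=0.10)
        assert len(out) == 1
        assert out.iloc[0]["lead_snp"] == "s1"

    def test_tie_breaks_by_distance_then_position(self):
        assoc = self._assoc(
            [("p1", "far", 900, 800, 1e-6), ("p1", "near", 400, 300, 1e-6),
             ("p1", "near2", 500, 300, 1e-6)]
        )
        out = call_meqtls(assoc, fdr=0.10)
        assert out.iloc[0]["lead_snp"] == "near"

    def test_planted_fixture_recovery(self, planted_dataset):
        d = planted_dataset
        assoc = cis_scan(d["norm"], d["geno"], d["manifest"])
        called = set(call_meqtls(assoc, fdr=0.10)["probe_id"])
        causal = set(d["truth"].causal_pairs)
        # a regionally-shifted probe can sit > 3 kb from its driving SNP and
        # is then undetectable by construction; recall is over detectable ones
        snp_pos = d["geno"].snps["pos"]
        detectable = {
            p for p, (snp, _) in d["truth"].causal_pairs.items()
            if abs(snp_pos.loc[snp] - d["manifest"].loc[p, "pos"]) <= 3000
        }
        recall = len(called & detectable) / len(detectable)
        false_rate = len(called - causal) / max(len(called), 1)
        assert recall >= 0.95
        assert false_rate <= 0.15


class TestCandidateCausal:
    def _assoc(self, pairs):
        rows = []
        for probe, snp, p in pairs:
            rows.append({"probe_id": probe, "snp_id": snp, "snp_pos": 100,
                         "distance": 10, "p_value": p, "effect": 1.0})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "p_second,is_candidate",
        [(1e-5, True), (1e-6, True), (1e-7, False)],  # 3, 2 (boundary), 1 orders
    )
    def test_gap_boundary_inclusive(self, p_second, is_candidate):
        assoc = self._assoc([("p1", "best", 1e-8), ("p1", "second", p_second)])
        cands, _ = find_candidate_causal(assoc, gap_orders=2)
        assert (len(cands) == 1) == is_candidate

    def test_single_snp_probe_excluded(self, caplog):
        assoc = self._assoc([("p1", "only", 1e-10)])
        with caplog.at_level("INFO"):
            cands, summary = find_candidate_causal(assoc)
        assert cands.empty
        assert summary["n_candidates"] == 0

    def test_ld_fixture_recovers_true_causal_snp(self, planted_dataset):
        d = planted_dataset
        wide = cis_scan(d["norm"], d["geno"], d["manifest"], window=5000)
        cands, summary = find_candidate_causal(wide)
        truth = d["truth"].causal_pairs
        hits = sum(
            probe in truth and truth[probe][0] == snp
            for probe, snp in zip(cands["probe_id"], cands["snp_id"])
        )
        assert len(cands) >= 20
        assert hits / len(cands) >= 0.8


class TestProbePairCorrelation:
    def _setup(self, n_pairs=20, rho=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 64
        probes, positions, cols = [], [], []
        for i in range(n_pairs):
            base = rng.normal(size=n)
            a = base if rho == 1.0 else rng.normal(size=n)
            b = base if rho == 1.0 else rng.normal(size=n)
            cols += [a, b]
            probes += [f"pair{i}_a", f"pair{i}_b"]
            positions += [i * 100_000, i * 100_000 + 1000]
        meth = pd.DataFrame(np.column_stack(cols), columns=probes)
        manifest = pd.DataFrame({"chrom": "chr1", "pos": positions},
                                index=pd.Index(probes, name="probe_id"))
        meqtls = pd.DataFrame({"probe_id": probes})
        return meth, manifest, meqtls

    def test_duplicate_probes_are_perfectly_correlated(self):
        meth, manifest, meqtls = self._setup(n_pairs=3, rho=1.0)
        out = probe_pair_correlation(meth, None, meqtls, manifest)
        assert out["normalized"]["n_significant_pairs"] == 3
        assert out["normalized"]["n_probes_in_significant_pair"] == 6

    def test_null_pairs_hit_nominal_alpha(self):
        meth, manifest, meqtls = self._setup(n_pairs=1000, rho=0.0, seed=1)
        out = probe_pair_correlation(meth, None, meqtls, manifest)
        frac = out["normalized"]["n_significant_pairs"] / out["n_pairs"]
        assert abs(frac - 0.05) < 0.02

    def test_distant_pairs_not_tested(self):
        meth, manifest, meqtls = self._setup(n_pairs=2)
        manifest.loc["pair0_b", "pos"] = manifest.loc["pair0_a", "pos"] + 6000
        out = probe_pair_correlation(meth, None, meqtls, manifest)
        assert out["n_pairs"] == 1
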