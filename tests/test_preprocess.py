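"""Probe filtering, rank-normalization and PC-removal behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methqtl.core import NormalizedMethylation
from methqtl.preprocess import (
    filter_probes,
    pc_confounder_report,
    quantile_normalize,
    remove_pcs,
    select_num_pcs,
)
from methqtl.simulate import SimConfig, simulate_genotypes, simulate_methylation


def _toy_manifest():
    # 10 probes: 2 on chrX, 3 autosomal with a SNP in the target interval,
    # 1 flagged non-unique; 4 survive
    manifest = pd.DataFrame(
        {
            "chrom": ["chr1"] * 8 + ["chrX", "chrX"],
            "pos": [1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000, 500, 600],
        },
        index=pd.Index([f"cg{i}" for i in range(10)], name="probe_id"),
    )
    snp_positions = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1990, 2995, 4999]})
    return manifest, snp_positions, {"cg0"}


class TestFilterProbes:
    def test_three_rules_first_wins(self):
        manifest, snps, nonunique = _toy_manifest()
        out = filter_probes(manifest, snps, mappability_flags=nonunique)
        assert len(out) == 4
        assert out.attrs["removed"] == {"non_unique": 1, "sex_chrom": 2, "snp_overlap": 3}

    def test_sex_chromosome_rule(self):
        manifest, *_ = _toy_manifest()
        out = filter_probes(manifest)
        assert not out["chrom"].isin(["chrX", "chrY"]).any()

    def test_snp_overlap_interval_is_half_open_at_upstream_end(self):
        manifest = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "pos": [100, 300, 500]},
            index=pd.Index(["a", "b", "c"]),
        )
        # SNP exactly at the CpG removes; SNP 50 bp upstream (pos - 50) is
        # outside the (pos-50, pos] interval and does not
        snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 250]})
        out = filter_probes(manifest, snps)
        assert list(out.index) == ["b", "c"]

    def test_unknown_chrom_passes_with_warning(self, caplog):
        manifest = pd.DataFrame(
            {"chrom": ["chrUn_gl000220"], "pos": [10]}, index=pd.Index(["weird"])
        )
        with caplog.at_level("WARNING"):
            out = filter_probes(manifest)
        assert "weird" in out.index
        assert any("unknown chromosome" in r.message for r in caplog.records)

    def test_idempotent(self):
        manifest, snps, nonunique = _toy_manifest()
        once = filter_probes(manifest, snps, mappability_flags=nonunique)
        twice = filter_probes(once, snps, mappability_flags=nonunique)
        pd.testing.assert_frame_equal(once, twice)


class TestQuantileNormalize:
    def test_by_probe_matches_inverse_normal_oracle(self):
        beta = pd.DataFrame({"p1": [0.2, 0.9, 0.5]}, index=list("abc"))
        out = quantile_normalize(beta, strategy="by_probe")
        expected = stats.norm.ppf([(1 - 0.5) / 3, (3 - 0.5) / 3, (2 - 0.5) / 3])
        np.testing.assert_allclose(out.values["p1"], expected, atol=1e-12)

    def test_rank_preservation_within_each_normalized_axis(self):
        rng = np.random.default_rng(1)
        beta = pd.DataFrame(rng.random((20, 200)))
        by_probe = quantile_normalize(beta, strategy="by_probe")
        for col in beta.columns[:10]:
            assert (
                np.argsort(by_probe.values[col].to_numpy(), kind="stable")
                == np.argsort(beta[col].to_numpy(), kind="stable")
            ).all()
        # the second stage of two_stage preserves the order of the
        # first-stage (within-individual) scores within each probe
        stage1 = quantile_normalize(beta, strategy="by_individual")
        two = quantile_normalize(beta, strategy="two_stage")
        for col in beta.columns[:10]:
            assert (
                np.argsort(two.values[col].to_numpy(), kind="stable")
                == np.argsort(stage1.values[col].to_numpy(), kind="stable")
            ).all()

    def test_none_is_identity(self):
        beta = pd.DataFrame(np.random.default_rng(2).random((5, 4)))
        out = quantile_normalize(beta, strategy="none")
        pd.testing.assert_frame_equal(out.values, beta)

    def test_two_stage_probe_columns_are_exact_rank_normal_scores(self):
        # the exact (rank - 0.5)/n shape holds for probe columns whose
        # first-stage scores are tie-free (ties get averaged ranks instead)
        rng = np.random.default_rng(3)
        beta = pd.DataFrame(rng.random((30, 2000)))
        stage1 = quantile_normalize(beta, strategy="by_individual")
        out = quantile_normalize(beta, strategy="two_stage")
        n = beta.shape[0]
        expected_sorted = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        checked = 0
        for col in out.values.columns:
            if stage1.values[col].nunique() < n:
                continue
            np.testing.assert_allclose(np.sort(out.values[col]), expected_sorted, atol=1e-12)
            assert abs(out.values[col].mean()) < 1e-6
            checked += 1
            if checked >= 50:
                break
        assert checked >= 50

    def test_constant_vector_maps_to_zero_with_warning(self, caplog):
        beta = pd.DataFrame({"p1": [0.3, 0.3, 0.3, 0.3]})
        with caplog.at_level("WARNING"):
            out = quantile_normalize(beta, strategy="by_probe")
        np.testing.assert_array_equal(out.values["p1"], 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_missing_values_rejected(self):
        beta = pd.DataFrame({"p1": [0.1, np.nan, 0.7]})
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(beta)


class TestRemovePCs:
    def _norm(self, n=30, m=50, seed=4):
        rng = np.random.default_rng(seed)
        return NormalizedMethylation(pd.DataFrame(rng.normal(size=(n, m))))

    def test_zero_components_is_identity(self):
        norm = self._norm()
        out = remove_pcs(norm, 0)
        pd.testing.assert_frame_equal(out.values, norm.values)

    def test_residuals_orthogonal_to_removed_pcs(self):
        norm = self._norm()
        k = 3
        out = remove_pcs(norm, k)
        x = norm.values.to_numpy()
        xc = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        # oracle: explicit projection of each column onto the PC basis
        proj = u[:, :k].T @ out.values.to_numpy()
        assert np.abs(proj).max() < 1e-8

    def test_total_variance_non_increasing(self):
        norm = self._norm()
        prev = np.inf
        for k in (0, 1, 3, 5):
            var = remove_pcs(norm, k).values.to_numpy().var()
            assert var <= prev + 1e-12
            prev = var

    def test_removing_zero_after_k_is_stable(self):
        norm = self._norm()
        once = remove_pcs(norm, 4)
        again = remove_pcs(once, 0)
        pd.testing.assert_frame_equal(once.values, again.values)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            remove_pcs(self._norm(n=10), 10)


class TestSelectNumPCs:
    def test_singleton_grid(self, planted_dataset):
        d = planted_dataset
        k, table = select_num_pcs(d["norm"], d["geno"], d["manifest"], k_grid=[3])
        assert k == 3 and list(table["k"]) == [3]

    def test_confounded_fixture_prefers_removal(self):
        cfg = SimConfig(
            n_samples=64, n_probes=300, n_snps=400, region_length=300_000,
            causal_fraction=0.3, effect_size=1.0, regional_effect_span=0,
            n_confounders=1, confounder_sd=2.0, seed=13,
        )
        g = simulate_genotypes(cfg)
        beta, man, _ = simulate_methylation(g, cfg)
        norm = quantile_normalize(beta)
        k, table = select_num_pcs(norm, g, man, k_grid=[0, 1, 2])
        counts = table.set_index("k")["n_meqtl_probes"]
        assert counts[1] > counts[0]
        assert k >= 1


class TestPCConfounderReport:
    def test_known_factor_equal_to_pc1_detected(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(40, 60))
        base[:, :30] += rng.normal(size=40)[:, None] * 3  # dominant component
        norm = NormalizedMethylation(pd.DataFrame(base))
        x = base - base.mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        cov = pd.DataFrame({"factor": u[:, 0] * s[0]}, index=norm.values.index)
        rep = pc_confounder_report(norm, cov, n_pcs=3)
        row = rep[(rep["pc"] == 1) & (rep["covariate"] == "factor")].iloc[0]
        assert abs(abs(row["stat"]) - 1.0) < 1e-8
        assert row["p_value"] < 1e-12

    def test_independent_covariates_give_uniform_p(self):
        rng = np.random.default_rng(6)
        norm = NormalizedMethylation(pd.DataFrame(rng.normal(size=(50, 80))))
        cov = pd.DataFrame(
            rng.normal(size=(50, 50)), index=norm.values.index,
            columns=[f"c{i}" for i in range(50)],
        )
        rep = pc_confounder_report(norm, cov, n_pcs=1)
        d, p = stats.kstest(rep["p_value"], "uniform")
        assert p > 0.05

    def test_variance_explained_sums_to_at_most_one(self):
        rng = np.random.default_rng(7)
        norm = NormalizedMethylation(pd.DataFrame(rng.normal(size=(20, 30))))
        cov = pd.DataFrame({"c": rng.normal(size=20)}, index=norm.values.index)
        rep = pc_confounder_report(norm, cov, n_pcs=19)
        assert rep.drop_duplicates("pc")["var_explained"].sum() <= 1 + 1e-9

    def test_single_level_covariate_skipped(self, caplog):
        rng = np.random.default_rng(8)
        norm = NormalizedMethylation(pd.DataFrame(rng.normal(size=(10, 12))))
        cov = pd.DataFrame({"batch": ["a"] * 10}, index=norm.values.index)
        with caplog.at_level("WARNING"):
            rep = pc_confounder_report(norm, cov)
        assert rep.empty
        assert any("single level" in r.message for r in caplog.records)

    def test_categorical_covariate_uses_anova(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(40, 30))
        group = np.repeat(["a", "b"], 20)
        vals[group == "b"] += 2.0  # group difference drives PC1
        norm = NormalizedMethylation(pd.DataFrame(vals))
        cov = pd.DataFrame({"batch": group}, index=norm.values.index)
        rep = pc_confounder_report(norm, cov, n_pcs=2)
        assert rep[(rep["pc"] == 1)].iloc[0]["p_value"] < 1e-6
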