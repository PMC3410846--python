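"""Marker QC, phenotype assignment, OLS and mixed-model association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cranioscan.association import (AssociationError, GenotypeMatrix,
                                    assign_phenotypes, bonferroni_threshold,
                                    kinship, linear_assoc, lmm_assoc, snp_qc,
                                    stratify)
from cranioscan.simulate import SimConfig, simulate_genotypes_and_trait


def make_G(calls, breeds=None, sexes=None, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    individuals = pd.DataFrame({
        "iid": [f"d{i}" for i in range(n)],
        "breed": breeds or ["B1"] * n,
        "sex": sexes or ["M"] * n,
    })
    markers = pd.DataFrame({
        "chrom": chrom or ["chr1"] * m,
        "pos": np.arange(1, m + 1) * 1000,
        "a1": ["A"] * m, "a2": ["G"] * m,
    })
    return GenotypeMatrix(calls, individuals, markers)


class TestGenotypeMatrix:
    def test_rejects_bad_dosage_and_unsorted_positions(self):
        with pytest.raises(AssociationError):
            make_G([[0, 3]])
        G = make_G([[0, 1]])
        bad = G.markers.copy()
        bad.loc[1, "pos"] = bad.loc[0, "pos"]
        with pytest.raises(AssociationError):
            GenotypeMatrix(G.calls, G.individuals, bad)

    def test_maf_and_missing(self):
        G = make_G([[0, 2, -1], [1, 2, 0], [2, 2, 0], [1, 2, 0]])
        np.testing.assert_allclose(G.maf(), [0.5, 0.0, 0.0])
        np.testing.assert_allclose(G.missing_fraction(), [0, 0, 0.25])


class TestSnpQC:
    def test_monomorphic_removed(self):
        G = make_G([[0, 1], [0, 1], [0, 0], [0, 2]])
        out = snp_qc(G)
        assert out.n_markers == 1

    def test_strict_missingness_boundary(self):
        # 10 individuals, exactly one missing call = 0.1, removed under < 0.10
        calls = np.ones((10, 1), dtype=np.int8)
        calls[::2, 0] = 0
        calls[0, 0] = -1
        out = snp_qc(make_G(calls), max_missing=0.10, min_maf=0.01)
        assert out.n_markers == 0


class TestAssignPhenotypes:
    def _pheno(self):
        return pd.DataFrame({
            "breed": ["B1", "B1", "B2"], "sex": ["M", "F", "M"],
            "pc1": [0.1, 0.2, -0.3],
            "log_neurocranium_centroid": [4.0, 4.1, 4.5],
        })

    def test_same_cell_dogs_share_value_and_missing_dropped(self):
        G = make_G([[0], [1], [2]], breeds=["B1", "B1", "B3"],
                   sexes=["M", "M", "M"])
        Gp, y, size = assign_phenotypes(G, self._pheno())
        assert Gp.n_individuals == 2
        np.testing.assert_allclose(y, [0.1, 0.1])
        np.testing.assert_allclose(size, [4.0, 4.0])

    def test_sex_fallback_off_by_default(self):
        G = make_G([[0]], breeds=["B2"], sexes=["F"])
        Gp, y, _ = assign_phenotypes(G, self._pheno())
        assert Gp.n_individuals == 0
        Gp, y, _ = assign_phenotypes(G, self._pheno(), sex_fallback=True)
        assert Gp.n_individuals == 1 and y[0] == pytest.approx(-0.3)


class TestLinearAssoc:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8).reshape(-1, 1)
        y = rng.normal(size=6)
        res = linear_assoc(make_G(x), y)
        X = np.column_stack([np.ones(6), x.ravel()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        s2 = r @ r / 4
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p = 2 * stats.t.sf(abs(beta[1] / se), 4)
        row = res.markers.iloc[0]
        assert row["beta"] == pytest.approx(beta[1], abs=1e-10)
        assert row["se"] == pytest.approx(se, abs=1e-10)
        assert row["p_value"] == pytest.approx(p, abs=1e-10)

    def test_constant_phenotype_p_one(self):
        res = linear_assoc(make_G([[0], [1], [2], [1], [0], [2]]),
                           np.full(6, 3.3))
        assert res.markers["p_value"].iloc[0] == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        n, m = 120, 800
        G = make_G(rng.binomial(2, 0.4, size=(n, m)).astype(np.int8))
        y = rng.normal(size=n)
        res = linear_assoc(G, y)
        ks = stats.kstest(res.p_values, "uniform")
        assert ks.pvalue > 0.01

    def test_collinear_covariates_fail(self):
        G = make_G(np.zeros((6, 1), dtype=np.int8))
        C = np.ones((6, 2))
        with pytest.raises(AssociationError, match="collinear"):
            linear_assoc(G, np.arange(6.0), covariates=C,
                         covariate_names=["c1", "c2"])


class TestKinship:
    def test_duplicate_individual_rows_identical(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.5, size=(5, 200)).astype(np.int8)
        calls[1] = calls[0]
        K = kinship(make_G(calls))
        np.testing.assert_allclose(K[0], K[1], atol=1e-12)
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_unstructured_panel_near_zero_off_diagonal_and_psd(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.5, size=(40, 5000)).astype(np.int8)
        K = kinship(make_G(calls))
        np.testing.assert_allclose(K, K.T)
        off = K[~np.eye(40, dtype=bool)]
        # column-centered Z makes K's row sums exactly zero, so the
        # off-diagonal mean equals -tr(K)/(n(n-1)) -> 0 with panel size
        assert off.mean() == pytest.approx(-np.trace(K) / (40 * 39), abs=1e-12)
        assert abs(off.mean()) < 2.0 / 39
        assert np.linalg.eigvalsh(K).min() > -1e-8


class TestLmmAssoc:
    def _toy(self, seed=4, n=40, m=25):
        rng = np.random.default_rng(seed)
        G = make_G(rng.binomial(2, 0.4, size=(n, m)).astype(np.int8))
        y = rng.normal(size=n)
        C = rng.normal(size=(n, 1))
        return G, y, C

    def test_identity_kinship_collapses_to_ols(self):
        G, y, C = self._toy()
        lin = linear_assoc(G, y, covariates=C)
        mix = lmm_assoc(G, y, np.eye(G.n_individuals), covariates=C)
        np.testing.assert_allclose(mix.markers["p_value"],
                                   lin.markers["p_value"], atol=1e-6)
        np.testing.assert_allclose(mix.markers["beta"], lin.markers["beta"],
                                   atol=1e-6)

    def test_scaled_identity_kinship_also_collapses(self):
        G, y, C = self._toy(seed=5)
        lin = linear_assoc(G, y, covariates=C)
        mix = lmm_assoc(G, y, 3.7 * np.eye(G.n_individuals), covariates=C)
        np.testing.assert_allclose(mix.markers["p_value"],
                                   lin.markers["p_value"], atol=1e-6)

    def test_invariance_to_marker_order_and_phenotype_shift(self):
        G, y, _ = self._toy(seed=6)
        K = kinship(G)
        a = lmm_assoc(G, y, K)
        b = lmm_assoc(G, y + 100.0, K)
        np.testing.assert_allclose(a.markers["p_value"], b.markers["p_value"],
                                   atol=1e-8)
        perm = np.random.default_rng(0).permutation(G.n_markers)
        order = np.argsort(perm)
        # reorder columns but keep a valid marker map by re-sorting positions
        Gp = GenotypeMatrix(G.calls[:, perm][:, order], G.individuals, G.markers)
        c = lmm_assoc(Gp, y, K)
        np.testing.assert_allclose(a.markers["p_value"], c.markers["p_value"],
                                   atol=1e-12)

    def test_structured_null_inflation_reduced(self):
        rng = np.random.default_rng(7)
        n_per, m = 30, 600
        f1 = rng.beta(2, 2, m)
        f2 = np.clip(f1 + rng.normal(0, 0.25, m), 0.02, 0.98)
        calls = np.vstack([
            rng.binomial(2, f1, size=(n_per, m)),
            rng.binomial(2, f2, size=(n_per, m)),
        ]).astype(np.int8)
        G = make_G(calls, breeds=["c1"] * n_per + ["c2"] * n_per)
        y = np.r_[np.zeros(n_per), np.ones(n_per)] + rng.normal(0, 0.3, 2 * n_per)
        lin = linear_assoc(G, y)
        mix = lmm_assoc(G, y, kinship(G))
        assert mix.genomic_inflation() <= lin.genomic_inflation()
        assert mix.genomic_inflation() < 1.5

    def test_non_psd_kinship_fails(self):
        G, y, _ = self._toy(seed=8)
        K = -np.eye(G.n_individuals)
        with pytest.raises(AssociationError, match="PSD"):
            lmm_assoc(G, y, K)


def test_single_planted_qtl_tops_mixed_model_scan():
    """With one strong QTL the planted marker ranks first genome-wide."""
    hits = 0
    n_rep = 12
    for seed in range(100, 100 + n_rep):
        cfg = SimConfig(seed=seed, n_qtls=1, qtl_effects=(1.0,))
        study = simulate_genotypes_and_trait(cfg)
        G = snp_qc(study.genotypes)
        Gp, y, size = assign_phenotypes(G, study.phenotypes)
        res = lmm_assoc(Gp, y, kinship(Gp), covariates=size.reshape(-1, 1))
        top = res.markers["p_value"].idxmin()
        qtl = study.genotypes.markers.iloc[study.qtl_indices[0]]
        row = res.markers.iloc[top]
        hits += (row["chrom"] == qtl["chrom"] and row["pos"] == qtl["pos"])
    assert hits >= 0.9 * n_rep


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(0.05, 36685) == pytest.approx(5.8655,
                                                                  abs=1e-3)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.301, abs=1e-3)
        assert bonferroni_threshold(0.05, 61270) == pytest.approx(6.0883,
                                                                  abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(AssociationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(AssociationError):
            bonferroni_threshold(1.5, 10)


class TestStratify:
    def _pheno(self):
        return pd.DataFrame({
            "breed": ["a", "a", "b", "b", "c", "c", "d", "d"],
            "sex": ["M", "F"] * 4,
            "pc1": [0.2, 0.3, 0.05, 0.25, -0.1, -0.2, 0.16, 0.18],
            "log_neurocranium_centroid": [4.0, 4.0, 4.6, 4.6, 4.2, 4.2,
                                          4.9, 4.9],
        })

    def test_size_below_median(self):
        assert sorted(stratify(self._pheno(), "size_below_median")) == ["a", "c"]
        equal = self._pheno().assign(log_neurocranium_centroid=4.0)
        assert stratify(equal, "size_below_median") == []

    def test_drop_listed(self):
        out = stratify(self._pheno(), "drop_listed_breeds", drop_breeds=["a"])
        assert sorted(out) == ["b", "c", "d"]

    def test_pc_cutoff_both_sexes_rule(self):
        # extreme brachycephalic only when BOTH sex averages exceed 0.15
        out = stratify(self._pheno(), "pc_cutoff")
        assert sorted(out) == ["b", "c"]  # a (.2/.3) and d (.16/.18) dropped
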