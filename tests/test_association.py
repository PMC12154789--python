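"""Association statistics: filters, structure PCs, GWAS, stepwise GLM,
collinearity, deviance partitioning, and the IRLS oracle."""

import numpy as np
import pandas as pd
import pytest

from cdhscan import association as assoc
from cdhscan.simulate import (
    simulate_association_dataset,
    simulate_genotype_qc,
)


def small_genotypes(n=6, m=4, seed=0):
    rng = np.random.default_rng(seed)
    dosage = pd.DataFrame(
        rng.integers(0, 3, size=(n, m)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"v{j}" for j in range(m)],
    )
    return dosage


class TestFilterGenotypes:
    def _matrix(self, dosage, depth=None, gq=None):
        return assoc.GenotypeMatrix(dosage, depth=depth, gq=gq)

    @pytest.mark.parametrize(
        "depth,kept", [(3, False), (4, True), (19, True), (20, False)]
    )
    def test_depth_boundaries_strict(self, depth, kept):
        dosage = pd.DataFrame({"v0": [1, 0, 2, 1, 0, 1]},
                              index=[f"s{i}" for i in range(6)])
        d = pd.DataFrame(10, index=dosage.index, columns=dosage.columns)
        d.iloc[0, 0] = depth
        g = assoc.filter_genotypes(
            self._matrix(dosage, depth=d), maf_min=0.0, sample_missing_max=1.0
        )
        assert (g.dosage.iloc[0, 0] != assoc.MISSING) == kept

    def test_gq_boundary_strict(self):
        dosage = pd.DataFrame({"v0": [1, 0, 2, 1]}, index=list("abcd"))
        gq = pd.DataFrame(99, index=dosage.index, columns=dosage.columns)
        gq.iloc[0, 0] = 60
        g = assoc.filter_genotypes(
            self._matrix(dosage, gq=gq), maf_min=0.0, sample_missing_max=1.0
        )
        assert g.dosage.iloc[0, 0] == assoc.MISSING

    def test_low_maf_snp_dropped(self):
        dosage = small_genotypes(20, 3, seed=1)
        dosage["rare"] = 0
        dosage.loc["s0", "rare"] = 1  # MAF 0.025
        g = assoc.filter_genotypes(self._matrix(dosage))
        assert "rare" not in g.snp_ids

    def test_high_missingness_sample_dropped(self):
        dosage = small_genotypes(10, 10, seed=2)
        dosage.loc["s0", dosage.columns[:2]] = assoc.MISSING  # 20% > 10%
        g = assoc.filter_genotypes(self._matrix(dosage), maf_min=0.0)
        assert "s0" not in g.sample_ids

    def test_exclusion_list_applied_verbatim(self):
        dosage = small_genotypes(10, 4, seed=3)
        g = assoc.filter_genotypes(
            self._matrix(dosage), maf_min=0.0, exclusion_list=["v1", "v3"]
        )
        assert set(g.snp_ids) <= {"v0", "v2"}

    def test_everything_removed_is_an_error(self):
        dosage = pd.DataFrame({"v0": [0, 0, 0, 0]}, index=list("abcd"))
        with pytest.raises(ValueError, match="every SNP"):
            assoc.filter_genotypes(self._matrix(dosage))


class TestStructurePcs:
    def test_populations_separate_on_leading_pcs(self):
        geno, _, _ = simulate_association_dataset(300, 300, k_pops=3, seed=4,
                                                  fst=0.2)
        pcs, var = assoc.structure_pcs(assoc.GenotypeMatrix(geno), k=4)
        # leading PCs dominate: structured data has a low-rank component
        assert var[0] > 2 * var[3]

    def test_permutation_equivariance(self):
        geno, _, _ = simulate_association_dataset(50, 40, k_pops=2, seed=5)
        pcs, _ = assoc.structure_pcs(assoc.GenotypeMatrix(geno), k=3)
        perm = list(reversed(geno.index))
        pcs_perm, _ = assoc.structure_pcs(
            assoc.GenotypeMatrix(geno.loc[perm]), k=3
        )
        # same subspace: per-PC scores agree up to sign
        for c in pcs.columns:
            r = np.corrcoef(pcs.loc[perm, c], pcs_perm[c])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_k_beyond_rank_rejected(self):
        geno = small_genotypes(5, 3)
        with pytest.raises(ValueError, match="rank"):
            assoc.structure_pcs(assoc.GenotypeMatrix(geno), k=10)


class TestGwas:
    def test_planted_snp_detected_unadjusted_and_adjusted(self):
        geno, _, phen = simulate_association_dataset(
            1500, 100, 2, causal_spec=[("snp", 0, 3.0)], seed=6
        )
        g = assoc.GenotypeMatrix(geno)
        pcs, _ = assoc.structure_pcs(g, k=5)
        res = assoc.gwas(assoc.GenotypeMatrix(geno[["snp00000"]]), phen, pcs)
        assert res.loc["snp00000", "significant"]

    def test_k_zero_runs_unadjusted(self):
        geno, _, phen = simulate_association_dataset(200, 5, 1, seed=7)
        res = assoc.gwas(assoc.GenotypeMatrix(geno), phen, None)
        assert res["pvalue"].notna().all()

    def test_monomorphic_snp_flagged_and_skipped(self):
        geno, _, phen = simulate_association_dataset(100, 3, 1, seed=8)
        geno["mono"] = 1
        res = assoc.gwas(assoc.GenotypeMatrix(geno), phen, None)
        assert res.loc["mono", "flag"] == "monomorphic"
        assert np.isnan(res.loc["mono", "pvalue"])

    def test_sample_mismatch_rejected(self):
        geno, _, phen = simulate_association_dataset(50, 3, 1, seed=9)
        with pytest.raises(ValueError, match="sample"):
            assoc.gwas(assoc.GenotypeMatrix(geno), phen.iloc[:-5], None)

    def test_gaussian_family_for_log_copy_number(self):
        rng = np.random.default_rng(10)
        geno = small_genotypes(400, 3, seed=10)
        y = pd.Series(
            0.8 * geno["v0"] + rng.normal(0, 1, 400), index=geno.index
        )
        res = assoc.gwas(assoc.GenotypeMatrix(geno), y, None, family="gaussian")
        assert res.loc["v0", "pvalue"] < 1e-10

    def test_multiallelic_screen_then_collapse(self):
        rng = np.random.default_rng(11)
        n = 600
        alleles = pd.DataFrame(
            {"alt1": rng.binomial(2, 0.3, n), "alt2": rng.binomial(1, 0.02, n)},
            index=[f"s{i}" for i in range(n)],
        )
        eta = 1.2 * alleles["alt1"] - 0.5
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))), index=alleles.index)
        pvals, sig = assoc.multiallelic_factor_screen(alleles, y, None, alpha=0.05)
        assert sig["alt1"] and not sig["alt2"]
        dose = assoc.collapse_multiallelic(alleles, ["alt1"])
        assert dose.max() <= 2


@pytest.fixture(scope="module")
def stepwise_problem():
    rng = np.random.default_rng(12)
    n = 800
    X = pd.DataFrame(
        {
            "PC1": rng.normal(size=n),
            "snpA": rng.binomial(2, 0.3, n).astype(float),
            "envA": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        }
    )
    eta = 1.0 * X["PC1"] + 0.8 * X["snpA"] - 0.7 * X["envA"]
    y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))), index=X.index)
    classes = {"PC1": "structure", "snpA": "genetic", "envA": "environment",
               "noise1": "environment", "noise2": "genetic"}
    return y, X, classes


class TestStepwise:
    def test_noise_dropped_signal_retained(self, stepwise_problem):
        y, X, classes = stepwise_problem
        fit = assoc.stepwise_glm(y, X, classes)
        final = set(fit.terms.index) - {"const"}
        assert final == {"PC1", "snpA", "envA"}
        assert set(fit.drop_history) == {"noise1", "noise2"}

    def test_all_significant_is_fixed_point(self, stepwise_problem):
        y, X, classes = stepwise_problem
        keep = ["PC1", "snpA", "envA"]
        fit = assoc.stepwise_glm(y, X[keep], {k: classes[k] for k in keep})
        assert set(fit.terms.index) - {"const"} == set(keep)
        assert fit.drop_history == []

    def test_pure_noise_collapses_to_intercept(self):
        rng = np.random.default_rng(13)
        n = 300
        X = pd.DataFrame({f"z{i}": rng.normal(size=n) for i in range(4)})
        y = pd.Series(rng.binomial(1, 0.5, n), index=X.index)
        fit = assoc.stepwise_glm(y, X, {c: "environment" for c in X.columns})
        assert set(fit.terms.index) == {"const"}
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self, stepwise_problem):
        y, X, classes = stepwise_problem
        rng = np.random.default_rng(14)
        finals = []
        for _ in range(5):
            perm = list(rng.permutation(X.columns))
            fit = assoc.stepwise_glm(
                y, X[perm], classes, check_order_robustness=False
            )
            finals.append(frozenset(fit.terms.index) - {"const"})
        assert len(set(map(frozenset, finals))) == 1


class TestCollinearity:
    def test_duplicate_and_negated_columns_flagged(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x, "c": -x, "d": rng.normal(size=200)})
        flags = assoc.collinearity_screen(df)
        pairs = {frozenset((r.var_a, r.var_b)) for r in flags.itertuples()}
        assert frozenset(("a", "b")) in pairs and frozenset(("a", "c")) in pairs
        assert not any("d" in p for p in pairs)

    def test_independent_columns_clean(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("wxyz"))
        assert len(assoc.collinearity_screen(df)) == 0

    def test_constant_column_flagged_separately(self):
        df = pd.DataFrame({"c": [1.0] * 10, "x": np.arange(10.0)})
        flags = assoc.collinearity_screen(df)
        assert (flags["flag"] == "constant").any()


class TestDeviancePartition:
    def test_orthogonal_predictors_partition_additively(self):
        rng = np.random.default_rng(17)
        n = 2000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(X["a"] + X["b"] + rng.normal(0, 1, n), index=X.index)
        classes = {"a": "genetic", "b": "environment"}
        fit = assoc.stepwise_glm(y, X, classes, family="gaussian")
        part = assoc.deviance_partition(y, X, fit, classes, family="gaussian")
        p = part.set_index("class")["deviance_explained"]
        assert p["genetic"] + p["environment"] == pytest.approx(p["full"], abs=0.03)

    def test_duplicated_classes_share_variation(self):
        rng = np.random.default_rng(18)
        n = 1000
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, n)})
        y = pd.Series(x + rng.normal(0, 0.5, n), index=X.index)
        classes = {"a": "genetic", "b": "environment"}
        fit = assoc.stepwise_glm(y, X, classes, family="gaussian", alpha=1.0,
                                 check_order_robustness=False)
        part = assoc.deviance_partition(y, X, fit, classes, family="gaussian")
        p = part.set_index("class")["deviance_explained"]
        assert p["genetic"] + p["environment"] > 1.5 * p["full"]

    def test_null_response_partitions_near_zero(self):
        rng = np.random.default_rng(19)
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(rng.binomial(1, 0.5, n), index=X.index)
        fit = assoc.stepwise_glm(y, X, {"a": "genetic", "b": "environment"},
                                 alpha=1.0, check_order_robustness=False)
        part = assoc.deviance_partition(
            y, X, fit, {"a": "genetic", "b": "environment"}
        )
        assert (part["deviance_explained"] < 0.02).all()

    def test_deviance_explained_bounded_and_monotone(self, stepwise_problem):
        y, X, classes = stepwise_problem
        fits = [
            assoc._fit_glm(y, X[cols], "binomial-logit")
            for cols in (["PC1"], ["PC1", "snpA"], ["PC1", "snpA", "envA"])
        ]
        des = [f.deviance_explained for f in fits]
        assert all(0 <= d <= 1 for d in des)
        assert des == sorted(des)


def irls_logistic_oracle(y, X, n_iter=50):
    """Textbook IRLS for logistic regression (Newton-Raphson on the
    log-likelihood), independent of any fitting library."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        beta = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    dev = -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
    return beta, se, dev


class TestGlmEngine:
    def test_matches_irls_oracle_to_six_decimals(self):
        """The GLM engine agrees with a hand-rolled IRLS on a fixed
        5-observation dataset to 1e-6."""
        y = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        x = np.array([-1.2, 0.3, -0.4, 1.1, 2.0])
        beta, se, dev = irls_logistic_oracle(y, x)
        X = pd.DataFrame({"x": x})
        fit = assoc._fit_glm(pd.Series(y), X, "binomial-logit")
        assert fit.terms.loc["const", "coef"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.terms.loc["x", "coef"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.terms.loc["x", "se"] == pytest.approx(se[1], abs=1e-6)
        assert fit.residual_deviance == pytest.approx(dev, abs=1e-6)
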