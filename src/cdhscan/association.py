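"""Association statistics for CDH distribution: hard SNP filtering,
PC-adjusted per-SNP regression, stepwise GLM simplification, and
deviance partitioning across variable classes.

Per-SNP tests fit ``phenotype ~ dosage + PC1..k`` (logistic for
presence/absence, gaussian for log copy number) and report the Wald
p-value of the dosage term against a genome-wide threshold of 5e-8.
The multi-covariate models start from population structure, genetic and
environmental terms together, drop the least significant term one at a
time until everything clears alpha = 0.01, and then partition the
deviance explained by refitting each variable class alone on the
identical complete-case sample set (the partitions share variation and
are not expected to sum to the full model).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GenotypeMatrix",
    "GlmFit",
    "filter_genotypes",
    "structure_pcs",
    "gwas",
    "multiallelic_factor_screen",
    "collapse_multiallelic",
    "stepwise_glm",
    "collinearity_screen",
    "deviance_partition",
    "GWAS_THRESHOLD",
]

GWAS_THRESHOLD = 5e-8
MISSING = -1  # sentinel for a missing dosage call


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosages with per-call QC and SNP metadata.

    ``dosage`` holds {0,1,2} with -1 for missing.  ``depth`` and ``gq``
    are optional per-call matrices aligned to ``dosage``; ``snp_info``
    (indexed by SNP id) may carry chrom/pos/alleles.
    """

    dosage: pd.DataFrame
    depth: pd.DataFrame | None = None
    gq: pd.DataFrame | None = None
    snp_info: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP over non-missing calls."""
        d = self.dosage.where(self.dosage != MISSING)
        freq = d.mean(axis=0) / 2.0
        return pd.concat([freq, 1 - freq], axis=1).min(axis=1)

    def missingness(self) -> tuple[pd.Series, pd.Series]:
        """(per-SNP, per-sample) fraction of missing calls."""
        miss = self.dosage == MISSING
        return miss.mean(axis=0), miss.mean(axis=1)


def filter_genotypes(
    g: GenotypeMatrix,
    depth_min: int = 3,
    depth_max: int = 20,
    gq_min: int = 60,
    maf_min: float = 0.05,
    snp_missing_max: float = 0.75,
    sample_missing_max: float = 0.10,
    exclusion_list: Sequence[str] = (),
) -> GenotypeMatrix:
    """Hard-filter genotype calls, SNPs and samples.

    Calls must have depth strictly greater than ``depth_min`` and
    strictly less than ``depth_max`` and GQ strictly greater than
    ``gq_min`` (failing calls are set missing).  SNPs with MAF below
    ``maf_min`` or missingness above ``snp_missing_max`` are dropped,
    then samples missing more than ``sample_missing_max`` of calls are
    dropped, then MAF is recomputed and re-applied.  ``exclusion_list``
    (precomputed homology / transposable-element screen) is removed
    verbatim.
    """
    dosage = g.dosage.copy()
    if g.depth is not None:
        bad = (g.depth <= depth_min) | (g.depth >= depth_max)
        dosage = dosage.mask(bad, MISSING)
    if g.gq is not None:
        dosage = dosage.mask(g.gq <= gq_min, MISSING)

    work = GenotypeMatrix(dosage, snp_info=g.snp_info)
    snp_miss, _ = work.missingness()
    maf = work.maf()
    keep_snps = [
        s for s in work.snp_ids
        if maf[s] >= maf_min and snp_miss[s] <= snp_missing_max
        and s not in set(exclusion_list)
    ]
    dosage = dosage[keep_snps]

    _, sample_miss = GenotypeMatrix(dosage).missingness()
    keep_samples = list(sample_miss.index[sample_miss <= sample_missing_max])
    dosage = dosage.loc[keep_samples]

    # MAF shifts once samples are dropped; re-apply
    maf2 = GenotypeMatrix(dosage).maf()
    dosage = dosage[[s for s in dosage.columns if maf2[s] >= maf_min]]
    if dosage.empty or dosage.shape[1] == 0:
        raise ValueError("filtering removed every SNP or sample")
    info = g.snp_info.loc[list(dosage.columns)] if g.snp_info is not None else None
    return GenotypeMatrix(dosage, snp_info=info)


def structure_pcs(g: GenotypeMatrix, k: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of centered dosages (population
    structure covariates).  Missing calls are mean-imputed for the PCA
    only.  Returns (sample x PC scores, variance fractions)."""
    d = g.dosage.where(g.dosage != MISSING).astype(float)
    d = d.fillna(d.mean(axis=0))
    X = d.to_numpy() - d.to_numpy().mean(axis=0)
    rank = min(X.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    var_frac = (s**2 / (s**2).sum())[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=g.dosage.index, columns=cols), var_frac


@dataclass
class GlmFit:
    """A fitted GLM: term table plus deviance bookkeeping."""

    family: str  # binomial-logit / gaussian
    terms: pd.DataFrame  # index term; columns coef, se, pvalue
    null_deviance: float
    residual_deviance: float
    sample_ids: list[str] = field(default_factory=list)
    drop_history: list[str] = field(default_factory=list)

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return (self.null_deviance - self.residual_deviance) / self.null_deviance


def _sm_family(family: str):
    if family == "binomial-logit":
        return sm.families.Binomial()
    if family == "gaussian":
        return sm.families.Gaussian()
    raise ValueError(f"unknown family {family!r}")


def _fit_glm(y: pd.Series, X: pd.DataFrame, family: str) -> GlmFit:
    Xc = sm.add_constant(X, has_constant="add")
    # tight IRLS tolerance: downstream tests compare SEs to 1e-6
    res = sm.GLM(y, Xc, family=_sm_family(family)).fit(maxiter=200, tol=1e-12)
    terms = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "pvalue": res.pvalues}
    )
    return GlmFit(
        family=family,
        terms=terms,
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        sample_ids=list(y.index),
    )


def gwas(
    g: GenotypeMatrix,
    phenotype: pd.Series,
    pcs: pd.DataFrame | None,
    family: str = "binomial-logit",
    threshold: float = GWAS_THRESHOLD,
) -> pd.DataFrame:
    """Per-SNP association: phenotype ~ dosage + PCs, Wald p on dosage.

    Returns a DataFrame indexed by SNP with columns effect, se, pvalue,
    significant, flag.  Monomorphic SNPs are skipped (flag
    'monomorphic'); non-converged or separated fits are flagged, not
    dropped.  Missing dosages are dropped per SNP (complete cases).
    """
    samples = list(g.dosage.index)
    if not phenotype.index.equals(g.dosage.index):
        if set(phenotype.index) != set(samples):
            raise ValueError("phenotype and genotype sample sets differ")
        phenotype = phenotype.loc[samples]
    if pcs is not None and set(pcs.index) != set(samples):
        raise ValueError("PC and genotype sample sets differ")
    rows = {}
    for snp in g.snp_ids:
        dose = g.dosage[snp]
        ok = dose != MISSING
        d = dose[ok].astype(float)
        if d.nunique() < 2:
            rows[snp] = dict(effect=np.nan, se=np.nan, pvalue=np.nan,
                             significant=False, flag="monomorphic")
            continue
        X = pd.DataFrame({"dosage": d})
        if pcs is not None and pcs.shape[1] > 0:
            X = pd.concat([X, pcs.loc[d.index]], axis=1)
        flag = ""
        try:
            with np.errstate(all="ignore"):
                fit = _fit_glm(phenotype.loc[d.index], X, family)
            coef = fit.terms.loc["dosage"]
            eff, se, p = float(coef["coef"]), float(coef["se"]), float(coef["pvalue"])
            if not np.isfinite(p) or se > 1e3:
                flag = "unstable"
        except Exception:
            eff = se = p = np.nan
            flag = "nonconverged"
        rows[snp] = dict(
            effect=eff, se=se, pvalue=p,
            significant=bool(np.isfinite(p) and p < threshold), flag=flag,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def multiallelic_factor_screen(
    allele_counts: pd.DataFrame,
    phenotype: pd.Series,
    pcs: pd.DataFrame | None,
    family: str = "binomial-logit",
    alpha: float = GWAS_THRESHOLD,
) -> tuple[pd.Series, pd.Series]:
    """Factor-coded test for a multi-allelic site.

    ``allele_counts`` has one column per alternate allele (counts
    0/1/2).  Each allele enters the model as its own term; returns
    (per-allele p-values, per-allele significance at ``alpha``) so
    non-significant minor alternates can be removed before additive
    recoding of the remaining allele.
    """
    X = allele_counts.astype(float)
    if pcs is not None:
        X = pd.concat([X, pcs.loc[X.index]], axis=1)
    fit = _fit_glm(phenotype.loc[X.index], X, family)
    p = fit.terms.loc[list(allele_counts.columns), "pvalue"]
    return p, p < alpha


def collapse_multiallelic(
    allele_counts: pd.DataFrame, keep: Sequence[str]
) -> pd.Series:
    """Additive dosage of the retained allele(s) after dropping
    non-significant minor alternates."""
    return allele_counts[list(keep)].sum(axis=1).clip(upper=2)


def stepwise_glm(
    response: pd.Series,
    variables: pd.DataFrame,
    classes: Mapping[str, str],
    family: str = "binomial-logit",
    alpha: float = 0.01,
    check_order_robustness: bool = True,
    n_order_checks: int = 3,
    seed: int = 0,
) -> GlmFit:
    """Backward stepwise simplification of a GLM.

    Starts from all variables, iteratively refits and drops the single
    term with the largest p-value above ``alpha`` (ties broken by
    name-sorted column order) until every remaining term clears alpha.
    Rows with any missing value are removed up front so the null model
    is identical across refits.  When ``check_order_robustness`` the
    procedure is re-run under shuffled variable orders and must reach
    the same final term set.

    ``classes`` maps each variable to its class (structure / genetic /
    environment) for downstream deviance partitioning; it must cover
    every column.
    """
    missing = sorted(set(variables.columns) - set(classes))
    if missing:
        raise ValueError(f"variables missing a class assignment: {missing}")
    data = pd.concat([response.rename("__y__"), variables], axis=1).dropna()
    y = data["__y__"]
    X = data.drop(columns="__y__")

    def run(cols: list[str]) -> tuple[list[str], list[str], GlmFit]:
        cols = list(cols)
        history = []
        fit = _fit_glm(y, X[cols], family)
        while cols:
            pvals = fit.terms.loc[cols, "pvalue"]
            worst = pvals.sort_values(ascending=False)
            # deterministic tie-break: largest p, then name order
            top_p = worst.iloc[0]
            if not (top_p > alpha) and np.isfinite(top_p):
                break
            tied = sorted(worst.index[worst == top_p])
            drop = tied[0] if np.isfinite(top_p) else sorted(
                pvals.index[~np.isfinite(pvals)]
            )[0]
            cols.remove(drop)
            history.append(drop)
            fit = _fit_glm(y, X[cols], family) if cols else _null_fit(y, family)
        return cols, history, fit

    base_cols = sorted(X.columns)
    final_cols, history, fit = run(base_cols)
    if check_order_robustness:
        rng = np.random.default_rng(seed)
        for _ in range(n_order_checks):
            perm = list(rng.permutation(base_cols))
            alt_cols, _, _ = run(perm)
            if set(alt_cols) != set(final_cols):
                raise RuntimeError(
                    "stepwise result depends on variable order: "
                    f"{sorted(final_cols)} vs {sorted(alt_cols)}"
                )
    fit.drop_history = history
    return fit


def _null_fit(y: pd.Series, family: str) -> GlmFit:
    res = sm.GLM(y, np.ones((len(y), 1)), family=_sm_family(family)).fit()
    terms = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "pvalue": res.pvalues}
    )
    terms.index = ["const"]
    return GlmFit(family, terms, float(res.null_deviance), float(res.deviance),
                  list(y.index))


def collinearity_screen(
    variables: pd.DataFrame, threshold: float = 0.70
) -> pd.DataFrame:
    """Flag covariate pairs with |Pearson r| above ``threshold``.

    Advisory only — the caller decides what to exclude.  Constant
    columns (undefined r) are flagged separately with r = NaN.
    """
    rows = []
    const = [c for c in variables.columns if variables[c].nunique() <= 1]
    for c in const:
        rows.append({"var_a": c, "var_b": "", "r": np.nan, "flag": "constant"})
    cols = [c for c in variables.columns if c not in const]
    corr = variables[cols].corr(method="pearson")
    for a, b in itertools.combinations(cols, 2):
        r = float(corr.loc[a, b])
        if abs(r) > threshold:
            rows.append({"var_a": a, "var_b": b, "r": r, "flag": "collinear"})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "flag"])


def deviance_partition(
    response: pd.Series,
    variables: pd.DataFrame,
    final_fit: GlmFit,
    classes: Mapping[str, str],
    family: str = "binomial-logit",
) -> pd.DataFrame:
    """Deviance explained by each variable class alone.

    For each class, refit a model containing only that class's
    surviving terms on the identical complete-case sample set as the
    full model, and report its deviance explained next to the full
    model's.  Shared variation means the per-class figures need not sum
    to the full model.  A class with no surviving terms scores 0.
    """
    surviving = [t for t in final_fit.terms.index if t != "const"]
    samples = final_fit.sample_ids
    y = response.loc[samples]
    rows = [{"class": "full", "n_terms": len(surviving),
             "deviance_explained": final_fit.deviance_explained}]
    for cls in sorted(set(classes.values())):
        terms = [t for t in surviving if classes.get(t) == cls]
        if not terms:
            rows.append({"class": cls, "n_terms": 0, "deviance_explained": 0.0})
            continue
        fit = _fit_glm(y, variables.loc[samples, terms], family)
        rows.append({"class": cls, "n_terms": len(terms),
                     "deviance_explained": fit.deviance_explained})
    return pd.DataFrame(rows)
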