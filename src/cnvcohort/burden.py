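"""CNV burden regressions: global burden, gene-set burden with global-burden
correction and BH-FDR, locus tests with max-T permutation FWER, and
sex-difference likelihood-ratio tests.

Burden predictors come from a :class:`~cnvcohort.genes.BurdenMatrix`; outcomes
are standardized trait T-scores. Gene-set models always include the total
impacted-gene count so a set effect is set-specific rather than a reflection
of overall CNV load. FDR families are (trait x CNV type x stratum) across the
gene-set catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import AssociationResult
from .genes import STRATA, BurdenMatrix


@dataclass(frozen=True)
class BurdenModelSpec:
    """One burden regression: which predictor, outcome and adjustments."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = ("PC1", "PC2", "PC3", "batch", "platform")
    stratum: str = "rare"
    cnv_type: str = "DEL"
    ancestry: str | None = None


def _design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=index)
    cov = covariates.reindex(index)
    # categorical covariates (batch, platform, phase ...) expand to dummies
    cat = cov.select_dtypes(exclude=[np.number])
    num = cov.select_dtypes(include=[np.number])
    if len(cat.columns):
        cat = pd.get_dummies(cat.astype(str), drop_first=True, dtype=float)
    return pd.concat([num.astype(float), cat], axis=1)


def _ols(y: pd.Series, X: pd.DataFrame, term: str, alpha: float = 0.05) -> AssociationResult:
    keep = y.notna() & X.notna().all(axis=1)
    if X.loc[keep, term].std(ddof=0) == 0:
        return AssociationResult(
            estimate=np.nan, ci_low=np.nan, ci_high=np.nan, statistic=np.nan, p=np.nan,
            n=int(keep.sum()), method="ols", flags=["constant_predictor"],
        )
    # covariate levels absent in this subset yield all-zero dummies; drop them
    variable = (X.loc[keep].std(ddof=0) > 0) | (X.columns == term)
    X = sm.add_constant(X.loc[:, variable], has_constant="add")
    Xk = X.loc[keep]
    rank = np.linalg.matrix_rank(Xk.to_numpy(dtype=float))
    if rank < Xk.shape[1]:
        corr = Xk.loc[:, Xk.std() > 0].corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(f"rank-deficient design; most collinear columns: {worst}")
    fit = sm.OLS(y.loc[keep].astype(float), Xk.astype(float)).fit()
    ci = fit.conf_int(alpha).loc[term]
    return AssociationResult(
        estimate=float(fit.params[term]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        statistic=float(fit.tvalues[term]),
        p=float(fit.pvalues[term]),
        n=int(keep.sum()),
        method="ols",
    )


def global_burden(
    spec: BurdenModelSpec,
    matrix: BurdenMatrix,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS of a trait T-score on one global burden column, adjusted.

    ``spec.predictor`` names a column of ``matrix.main`` (e.g.
    ``gene_count_DEL_rare``). Covariates default to ancestry PCs, batch and
    platform; SSRT/RTV callers should add the stimulant-medication flag.
    """
    if spec.predictor not in matrix.main.columns:
        raise KeyError(f"unknown burden column {spec.predictor!r}")
    y = phenotypes[spec.outcome].reindex(matrix.main.index)
    X = pd.DataFrame({spec.predictor: matrix.main[spec.predictor].astype(float)})
    X = pd.concat([X, _design(covariates, matrix.main.index)], axis=1)
    res = _ols(y, X, spec.predictor)
    res.detail.update({"outcome": spec.outcome, "predictor": spec.predictor})
    return res


def bh_fdr(p: pd.Series | np.ndarray, families: pd.Series | np.ndarray | None = None) -> pd.Series:
    """Benjamini–Hochberg step-up q-values, applied within each family.

    NaN p-values propagate as NaN and do not count toward a family's size.
    """
    p = pd.Series(p, dtype=float)
    if families is None:
        families = pd.Series(0, index=p.index)
    families = pd.Series(families, index=p.index)
    q = pd.Series(np.nan, index=p.index, dtype=float)
    for _, idx in p.groupby(families).groups.items():
        vals = p.loc[idx]
        ok = vals.notna()
        if ok.sum() == 0:
            continue
        _, qv, _, _ = multipletests(vals[ok].to_numpy(), method="fdr_bh")
        q.loc[vals[ok].index] = qv
    return q


def geneset_burden(
    matrix: BurdenMatrix,
    phenotypes: pd.DataFrame,
    outcome: str,
    cnv_type: str = "DEL",
    stratum: str = "rare",
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene-set burden regression with global-burden correction.

    For every gene-set column of the requested (type, stratum) family:
    OLS of the trait on the set-specific gene count + the total impacted-gene
    count + covariates. BH-FDR is applied across the sets of this family.
    Sets with zero carriers are skipped and recorded with NaN results.
    """
    suffix = f"|{cnv_type}|{stratum}"
    cols = [c for c in matrix.gene_sets.columns if c.endswith(suffix)]
    y = phenotypes[outcome].reindex(matrix.main.index)
    base = _design(covariates, matrix.main.index)
    global_col = matrix.main["gene_count_total"].astype(float)
    rows = []
    for col in cols:
        name = col.split("|")[0]
        x = matrix.gene_sets[col].astype(float)
        n_carriers = int((x > 0).sum())
        if n_carriers == 0 or x.std() == 0:
            rows.append({"gene_set": name, "beta": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "n_carriers": n_carriers, "skipped": True})
            continue
        X = pd.concat([pd.DataFrame({"set_count": x, "global_count": global_col}), base], axis=1)
        res = _ols(y, X, "set_count")
        rows.append({"gene_set": name, "beta": res.estimate, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p, "n_carriers": n_carriers, "skipped": False})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"]).to_numpy()
        out["cnv_type"] = cnv_type
        out["stratum"] = stratum
        out["outcome"] = outcome
    return out


def select_top_gene_sets(results: pd.DataFrame, p_max: float = 0.05, q_max: float = 0.2) -> list[str]:
    """Gene-sets qualifying for locus follow-up: p < p_max and BH-FDR q < q_max."""
    if results.empty:
        return []
    m = (results["p"] < p_max) & (results["q"] < q_max)
    return results.loc[m.fillna(False), "gene_set"].tolist()


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of columns of M on the column space of C (with intercept)."""
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def locus_burden(
    matrix: BurdenMatrix,
    phenotypes: pd.DataFrame,
    outcome: str,
    gene_universe: set[str] | None,
    cnv_type: str = "DEL",
    covariates: pd.DataFrame | None = None,
    min_carriers: int = 3,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene carrier association with max-T permutation FWER control.

    Genes are restricted to ``gene_universe`` (members of the top associated
    gene-sets for the trait; ``None`` = all genes with indicators) and to
    those with at least ``min_carriers`` carriers of a qualifying CNV of the
    requested type. The trait and each carrier indicator are residualized on
    the covariates; the null distribution of the maximum |t| across genes is
    obtained by permuting the outcome residuals (seeded), which controls the
    family-wise error rate over the locus family.

    Returns (per-gene results, info) where info carries the FWER |t|
    threshold at alpha=0.05 and the permutation settings.
    """
    cols = [c for c in matrix.genes.columns if c.endswith(f"|{cnv_type}")]
    if gene_universe is not None:
        cols = [c for c in cols if c.split("|")[0] in gene_universe]
    y = phenotypes[outcome].reindex(matrix.main.index).astype(float)
    keep = y.notna()
    G = matrix.genes.loc[keep, cols].astype(float)
    carriers = (G > 0).sum(axis=0)
    cols = [c for c in cols if carriers[c] >= min_carriers]
    info = {"n_permutations": n_permutations, "seed": seed, "min_carriers": min_carriers,
            "cnv_type": cnv_type, "outcome": outcome, "alpha": 0.05}
    if not cols:
        info["reason"] = "no gene with enough carriers in the qualifying gene-sets"
        return pd.DataFrame(columns=["gene", "n_carriers", "beta", "t", "p", "p_fwer"]), info

    base = _design(covariates, matrix.main.index).loc[keep]
    C = np.column_stack([np.ones(int(keep.sum()))] + ([base.to_numpy(dtype=float)] if base.shape[1] else []))
    Xr = _residualize(G[cols].to_numpy(dtype=float), C)
    yr = _residualize(y[keep].to_numpy(dtype=float)[:, None], C)[:, 0]
    n = len(yr)
    dof = n - C.shape[1] - 1

    xss = (Xr**2).sum(axis=0)
    xss[xss == 0] = np.nan
    beta = (Xr.T @ yr) / xss
    resid_ss = (yr**2).sum() - beta**2 * xss
    se = np.sqrt(resid_ss / dof / xss)
    t_obs = beta / se
    p_nom = 2 * stats.t.sf(np.abs(t_obs), dof)

    rng = np.random.default_rng(seed)
    yss = (yr**2).sum()
    Xn = Xr / np.sqrt(xss)  # unit-SS columns: t is a monotone function of |r|
    max_r = np.empty(n_permutations)
    perm = np.empty_like(yr)
    for i in range(n_permutations):
        perm[:] = rng.permutation(yr)
        r = np.abs(Xn.T @ perm) / np.sqrt(yss)
        max_r[i] = np.nanmax(r)
    r_obs = np.abs(Xn.T @ yr) / np.sqrt(yss)
    p_fwer = (1 + (max_r[None, :] >= r_obs[:, None]).sum(axis=1)) / (n_permutations + 1)
    r_crit = float(np.quantile(max_r, 0.95))
    info["t_threshold_fwer05"] = float(r_crit * np.sqrt(dof) / np.sqrt(max(1e-12, 1 - r_crit**2)))

    out = pd.DataFrame(
        {
            "gene": [c.split("|")[0] for c in cols],
            "n_carriers": carriers[cols].to_numpy(dtype=int),
            "beta": beta,
            "t": t_obs,
            "p": p_nom,
            "p_fwer": p_fwer,
        }
    ).sort_values("p", kind="stable").reset_index(drop=True)
    return out, info


def sex_burden_lrt(
    matrix: BurdenMatrix,
    sex: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio tests for sex differences in total CNV burden.

    For each of four outcomes — total deletion/duplication length and total
    deletion/duplication gene count — compares the covariate-only OLS model
    with the model adding sex; the deviance difference is chi-square(1).
    Covariates follow the burden convention (PC1–3, plate, phase).
    """
    sex = pd.Series(sex).reindex(matrix.main.index)
    male = (sex.astype(str).str.lower() == "male").astype(float)
    if male.nunique() < 2:
        return pd.DataFrame([{"outcome": "all", "lrt": np.nan, "p": np.nan, "note": "single-sex cohort"}])
    base = _design(covariates, matrix.main.index)
    outcomes = {
        "total_length_DEL": matrix.main["total_length_DEL"],
        "total_length_DUP": matrix.main["total_length_DUP"],
        "gene_count_DEL": matrix.main[[f"gene_count_DEL_{s}" for s in STRATA]].sum(axis=1),
        "gene_count_DUP": matrix.main[[f"gene_count_DUP_{s}" for s in STRATA]].sum(axis=1),
    }
    rows = []
    for name, y in outcomes.items():
        y = y.astype(float)
        if y.std(ddof=0) == 0:
            rows.append({"outcome": name, "lrt": np.nan, "p": np.nan, "note": "constant outcome"})
            continue
        X0 = sm.add_constant(base, has_constant="add") if base.shape[1] else pd.DataFrame(
            {"const": np.ones(len(y))}, index=y.index
        )
        X1 = pd.concat([X0, pd.DataFrame({"male": male})], axis=1)
        f0 = sm.OLS(y, X0.astype(float)).fit()
        f1 = sm.OLS(y, X1.astype(float)).fit()
        lrt = 2 * (f1.llf - f0.llf)
        rows.append({"outcome": name, "lrt": float(lrt), "p": float(stats.chi2.sf(lrt, df=1)), "note": ""})
    return pd.DataFrame(rows)
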