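"""Carrier-group association: 2x2 odds ratios, chi-square enrichment,
per-disorder logistic regression, carrier trait regressions and carrier
demographics.

The 2x2 table convention is (a, b, c, d) = (carrier & outcome+, carrier &
outcome-, noncarrier & outcome+, noncarrier & outcome-), so OR = ad / bc.
Confidence intervals on the OR use the Woolf (log-OR +/- z*SE) construction;
when any cell is zero the Haldane–Anscombe 0.5 correction is applied to all
cells and the result flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # carrier, outcome present
    b: int  # carrier, outcome absent
    c: int  # noncarrier, outcome present
    d: int  # noncarrier, outcome absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    """One test result: effect estimate with CI, test statistic and p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    p: float
    n: int
    method: str
    q: float | None = None
    flags: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "statistic": self.statistic,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "method": self.method,
            "flags": ";".join(self.flags),
        }
        d.update(self.detail)
        return d


def odds_ratio_ci(table: ContingencyTable, alpha: float = 0.05) -> AssociationResult:
    """Odds ratio with Woolf CI and two-sided Fisher-free normal p.

    OR = ad/bc; CI = exp(log OR +/- z_{1-alpha/2} * sqrt(1/a+1/b+1/c+1/d)).
    Zero cells trigger the 0.5 continuity correction on all four cells.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    flags = []
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("continuity_corrected")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    wald_z = np.log(or_) / se
    p = 2 * stats.norm.sf(abs(wald_z))
    return AssociationResult(
        estimate=or_,
        ci_low=lo,
        ci_high=hi,
        statistic=wald_z,
        p=p,
        n=table.total,
        method="odds_ratio_woolf",
        flags=flags,
        detail={"a": table.a, "b": table.b, "c": table.c, "d": table.d},
    )


def chi_square(table: ContingencyTable, correction: bool = False) -> AssociationResult:
    """Pearson chi-square of independence on the 2x2 table (df = 1)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero margin leaves nothing to test")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    return AssociationResult(
        estimate=stat,
        ci_low=np.nan,
        ci_high=np.nan,
        statistic=stat,
        p=p,
        n=table.total,
        method="chi_square" + ("_yates" if correction else ""),
        detail={"df": dof},
    )


def _logit_fit(y: pd.Series, X: pd.DataFrame):
    fit = sm.Logit(np.asarray(y, dtype=float), np.asarray(X, dtype=float)).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
        raise PerfectSeparationError("unstable logistic fit (quasi-separation)")
    return fit


def disorder_logistic(
    diagnosis: pd.Series,
    carrier: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Logistic regression of one disorder on carrier status (0/1).

    Returns the carrier OR (exp of the coefficient) with Wald CI and p.
    A constant carrier indicator (no contrast) is an error; separation is
    flagged in the result instead of reporting coefficients.
    """
    y = pd.Series(diagnosis).astype(float)
    x = pd.Series(carrier).astype(float)
    if x.nunique() < 2:
        raise ValueError("carrier indicator is constant; no contrast to estimate")
    X = pd.DataFrame({"carrier": x})
    if covariates is not None:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    keep = y.notna() & X.notna().all(axis=1)
    try:
        fit = _logit_fit(y[keep], X[keep])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssociationResult(
            estimate=np.nan, ci_low=np.nan, ci_high=np.nan, statistic=np.nan, p=np.nan,
            n=int(keep.sum()), method="logistic", flags=["separation"],
        )
    i = list(X.columns).index("carrier")
    coef, se = fit.params[i], fit.bse[i]
    z = stats.norm.ppf(1 - alpha / 2)
    return AssociationResult(
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        statistic=float(coef / se),
        p=float(fit.pvalues[i]),
        n=int(keep.sum()),
        method="logistic",
        detail={"log_or": float(coef)},
    )


def trait_group_regression(
    t_scores: pd.Series,
    carrier_group: pd.Series,
    covariates: pd.DataFrame | None = None,
    group: str = "significant",
    reference: str = "neither",
    min_group_n: int = 10,
    alpha: float = 0.05,
) -> AssociationResult:
    """Linear regression of a trait on carrier group vs the reference group.

    Participants outside {group, reference} are dropped, so the beta is the
    adjusted mean T-score difference of carriers of ``group`` CNVs versus
    participants with neither type. Groups below ``min_group_n`` scored
    members are skipped (flagged result).
    """
    y = pd.Series(t_scores, dtype=float)
    g = pd.Series(carrier_group).astype(str)
    mask = g.isin([group, reference]) & y.notna()
    x = (g[mask] == group).astype(float)
    if x.sum() < min_group_n or (1 - x).sum() < min_group_n:
        return AssociationResult(
            estimate=np.nan, ci_low=np.nan, ci_high=np.nan, statistic=np.nan, p=np.nan,
            n=int(mask.sum()), method="ols_group_contrast", flags=["group_too_small"],
        )
    X = pd.DataFrame({"carrier": x})
    if covariates is not None:
        X = pd.concat([X, covariates.loc[mask.index[mask]].astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    keep = X.notna().all(axis=1)
    fit = sm.OLS(y[mask][keep], X[keep]).fit()
    ci = fit.conf_int(alpha).loc["carrier"]
    return AssociationResult(
        estimate=float(fit.params["carrier"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        statistic=float(fit.tvalues["carrier"]),
        p=float(fit.pvalues["carrier"]),
        n=int(keep.sum()),
        method="ols_group_contrast",
        detail={"group": group, "reference": reference},
    )


def carrier_demographics(
    tiers: pd.DataFrame,
    age: pd.Series,
    sex: pd.Series,
    respondent: pd.Series,
) -> pd.DataFrame:
    """Compare carrier groups on age (one-way ANOVA), sex and respondent
    (chi-square). Groups with a single level present are skipped with a note."""
    group = tiers["carrier_group"]
    rows = []
    present = [g for g in group.unique()]
    if len(present) < 2:
        return pd.DataFrame(
            [{"variable": "all", "test": "skipped", "statistic": np.nan, "p": np.nan,
              "note": "only one carrier group present"}]
        )
    age = pd.Series(age, dtype=float).reindex(tiers.index)
    samples = [age[group == g].dropna() for g in present]
    f, p = stats.f_oneway(*[s for s in samples if len(s)])
    rows.append({"variable": "age", "test": "anova", "statistic": float(f), "p": float(p), "note": ""})
    for name, var in (("sex", sex), ("respondent", respondent)):
        var = pd.Series(var).reindex(tiers.index)
        tab = pd.crosstab(group, var)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append({"variable": name, "test": "skipped", "statistic": np.nan, "p": np.nan,
                         "note": "single level"})
            continue
        stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append({"variable": name, "test": "chi_square", "statistic": float(stat), "p": float(p), "note": ""})
    return pd.DataFrame(rows)
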