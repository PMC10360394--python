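"""Phenotype harmonization: T-scores, high-trait flags, composites, exclusions.

Traits arrive as raw instrument totals (ADHD total, inattention,
hyperactivity-impulsivity, OCD, anxiety, ASD) or task measures (SSRT ms, RTV
ms). They are standardized to T-scores (mean 50, SD 10) within gender — and
study phase where instruments differ by phase — and a participant is "high
trait" on a measure when their score falls in the most extreme 10% of the
scored sample. Higher is worse for every measure here, including SSRT
(longer stop-signal reaction time = worse inhibitory control) and RTV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class DegenerateInputError(ValueError):
    """Raised when a standardization group has no variance."""


def t_score(raw: pd.Series, grouping: pd.Series | list | None = None) -> pd.Series:
    """Gender(-and-phase)-adjusted T-scores: z within group, scaled to 50/10.

    Missing values stay missing and do not contribute to group moments.
    Groups need >= 2 non-missing values and nonzero variance.
    """
    raw = pd.Series(raw, dtype=float)
    if grouping is None:
        grouping = pd.Series(0, index=raw.index)
    else:
        grouping = pd.Series(grouping, index=raw.index)

    out = pd.Series(np.nan, index=raw.index, dtype=float)
    for _, idx in raw.groupby(grouping).groups.items():
        vals = raw.loc[idx]
        obs = vals.dropna()
        if len(obs) < 2:
            raise DegenerateInputError("standardization group has fewer than 2 scored participants")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError("standardization group has zero variance")
        out.loc[idx] = (vals - obs.mean()) / sd * 10.0 + 50.0
    return out


def flag_high_traits(scores: pd.Series, quantile: float = 0.10) -> pd.Series:
    """Flag the most extreme ``quantile`` of scored participants (high = worse).

    The cutoff is the empirical (1 - quantile) quantile of the non-missing
    scores; ties at the cutoff are all flagged. Missing scores yield missing
    flags (participant excluded from that trait's analyses only).
    """
    scores = pd.Series(scores, dtype=float)
    out = pd.Series(np.nan, index=scores.index, dtype=object)
    obs = scores.dropna()
    if obs.empty:
        return out
    cutoff = np.quantile(obs.to_numpy(), 1.0 - quantile, method="higher")
    out.loc[obs.index] = (obs >= cutoff).astype(int)
    return out


def exclude_small_disorders(diagnoses: pd.DataFrame, min_n: int = 20) -> list[str]:
    """Disorders retained for per-disorder association (cohort cases >= min_n).

    Excluded disorders remain part of the any-diagnosis composite; they are
    only dropped from disorder-specific models.
    """
    counts = diagnoses.sum(axis=0)
    return [d for d in diagnoses.columns if counts[d] >= min_n]


def add_composites(
    phenotypes: pd.DataFrame,
    diagnosis_cols: list[str],
    high_trait_cols: list[str],
) -> pd.DataFrame:
    """Add any_diagnosis / any_high_trait / any_dx_or_high indicator columns."""
    out = phenotypes.copy()
    out["any_diagnosis"] = (out[diagnosis_cols].fillna(0).astype(int).sum(axis=1) > 0).astype(int)
    high = out[high_trait_cols].apply(pd.to_numeric, errors="coerce")
    out["any_high_trait"] = (high.fillna(0).sum(axis=1) > 0).astype(int)
    out["any_dx_or_high"] = ((out["any_diagnosis"] + out["any_high_trait"]) > 0).astype(int)
    return out


def demographic_models(
    diagnoses: pd.DataFrame,
    age: pd.Series,
    gender: pd.Series,
    min_n: int = 20,
    age_cut: float = 12.0,
) -> pd.DataFrame:
    """Per-disorder logistic fits: diagnosis ~ age_group + gender + interaction.

    ``age_group`` is the older/younger split at ``age_cut`` years; gender is
    coded male=1. Disorders with fewer than ``min_n`` cases are skipped.
    Perfect separation is flagged rather than reported as coefficients.
    """
    retained = exclude_small_disorders(diagnoses, min_n=min_n)
    age_grp = (pd.Series(age, dtype=float) >= age_cut).astype(int)
    male = (pd.Series(gender).astype(str).str.lower() == "male").astype(int)
    X = pd.DataFrame({"age_ge_12": age_grp, "male": male})
    X["age_x_male"] = X["age_ge_12"] * X["male"]
    X = sm.add_constant(X, has_constant="add")

    rows = []
    for disorder in retained:
        y = diagnoses[disorder].astype(int)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
                raise np.linalg.LinAlgError("unstable fit")
            for term in ("age_ge_12", "male", "age_x_male"):
                rows.append(
                    {
                        "disorder": disorder,
                        "term": term,
                        "coef": fit.params[term],
                        "p": fit.pvalues[term],
                        "n_cases": int(y.sum()),
                        "flag": "",
                    }
                )
        except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
            rows.append(
                {
                    "disorder": disorder,
                    "term": "",
                    "coef": np.nan,
                    "p": np.nan,
                    "n_cases": int(diagnoses[disorder].sum()),
                    "flag": "separation",
                }
            )
    return pd.DataFrame(rows)
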