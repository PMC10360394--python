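"""Bundled worked-example fixtures from a reference community cohort.

These are the printed summary counts of a 7100-child community genotyping
cohort (two ancestry strata, ~4% classified-CNV carriers): the 2x2
carrier-by-phenotype contingency tables behind the enrichment odds ratios,
the carrier bookkeeping (85 clinically significant + 194 susceptibility = 279
carriers of 287 classified CNVs) and the per-disorder reported-diagnosis
counts. They serve as exact regression fixtures: the association machinery
must reproduce the published odds ratios and prevalences from these counts
alone.
"""

from __future__ import annotations

import pandas as pd

from .association import AssociationResult, ContingencyTable, odds_ratio_ci

COHORT_N = 7100
PHENOTYPED_N = 7050  # participants with diagnosis and >= 1 trait score

CARRIER_COUNTS = {"significant": 85, "susceptibility": 194, "either": 279}
N_CLASSIFIED_CNVS = 287
CARRIERS_WITH_DX_OR_HIGH = 130

#: (a, b, c, d) = carriers with/without the outcome, noncarriers with/without.
#: The noncarrier row (1154/5617 diagnoses, 1840/4931 high traits, 2282/4489
#: either) is shared by every comparison; the carrier rows differ by group.
ENRICHMENT_TABLES: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("significant", "diagnosis"): (33, 52, 1154, 5617),
    ("significant", "high_trait"): (39, 46, 1840, 4931),
    ("significant", "dx_or_high"): (50, 35, 2282, 4489),
    ("susceptibility", "diagnosis"): (45, 149, 1154, 5617),
    ("susceptibility", "high_trait"): (69, 125, 1840, 4931),
    ("susceptibility", "dx_or_high"): (80, 114, 2282, 4489),
    ("either", "diagnosis"): (78, 201, 1154, 5617),
    ("either", "high_trait"): (108, 171, 1840, 4931),
    ("either", "dx_or_high"): (130, 149, 2282, 4489),
}

#: reported-diagnosis counts among the 7050 phenotyped participants
DIAGNOSIS_COUNTS = {
    "adhd": 474,
    "anxiety": 320,
    "asd": 145,
    "eating_disorder": 2,
    "intellectual_disability": 13,
    "language_disorder": 5,
    "learning_disorder": 644,
    "mood_disorder": 96,
    "motor_delay": 4,
    "ocd": 80,
    "tics_tourettes": 84,
    "schizophrenia_spectrum": 6,
    "vcfs": 1,
}


def reference_enrichment() -> pd.DataFrame:
    """Odds ratios (Woolf CIs) for all nine carrier-by-phenotype tables."""
    rows = []
    for (group, outcome), (a, b, c, d) in ENRICHMENT_TABLES.items():
        res: AssociationResult = odds_ratio_ci(ContingencyTable(a, b, c, d))
        rows.append({"carrier_group": group, "outcome": outcome, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p": res.p})
    return pd.DataFrame(rows)


def reference_prevalence() -> dict[str, float]:
    """Carrier prevalence bookkeeping on the reference cohort, in percent."""
    return {
        "either_pct": 100 * CARRIER_COUNTS["either"] / COHORT_N,
        "significant_pct": 100 * CARRIER_COUNTS["significant"] / COHORT_N,
        "susceptibility_pct": 100 * CARRIER_COUNTS["susceptibility"] / COHORT_N,
        "carriers_with_dx_or_high_pct": 100 * CARRIERS_WITH_DX_OR_HIGH / CARRIER_COUNTS["either"],
    }


def reference_diagnoses() -> pd.DataFrame:
    """Per-participant 0/1 diagnosis fixture expanding the printed counts.

    One row per phenotyped participant, one column per disorder; counts per
    column match the published totals (participant-level co-occurrence is not
    published, so flags are assigned independently — sufficient for count-
    based operations such as the small-disorder exclusion).
    """
    idx = pd.RangeIndex(PHENOTYPED_N, name="participant")
    df = pd.DataFrame(0, index=idx, columns=list(DIAGNOSIS_COUNTS), dtype=int)
    for dx, k in DIAGNOSIS_COUNTS.items():
        df.iloc[:k, df.columns.get_loc(dx)] = 1
    return df
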