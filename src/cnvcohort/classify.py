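"""Clinical tier classification of consensus CNVs via catalog matching.

Each consensus CNV is assigned one tier with strict precedence:

``aneuploidy`` > ``recurrent`` (genomic-disorder locus, matched by reciprocal
overlap) > ``non_recurrent`` (overlapping a clinically significant gene) >
``susceptibility`` (overlapping a susceptibility gene) > ``unclassified``.

The first three tiers constitute the "clinically significant" group;
``susceptibility`` variants have disorder-linking evidence insufficient for a
pathogenic call. The engine is data-driven: any locus/gene catalog (e.g. an
ACMG-style or DECIPHER-style list) can be supplied as a TSV; a small synthetic
fixture catalog ships with the package.
"""

from __future__ import annotations

import importlib.resources
import logging

import pandas as pd

from .calls import reciprocal_overlap
from .genes import GeneIndex

logger = logging.getLogger(__name__)

CATALOG_KINDS = ("recurrent_locus", "significant_gene", "susceptibility_gene")
SIGNIFICANT_TIERS = ("aneuploidy", "recurrent", "non_recurrent")

CATALOG_COLUMNS = ["kind", "name", "chrom", "start", "end", "symbol", "required_type", "min_reciprocal_overlap"]


def read_catalog(path) -> pd.DataFrame:
    """Read a catalog TSV (kind, name, chrom, start, end, symbol, required_type, min_reciprocal_overlap)."""
    cat = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "symbol": str})
    missing = [c for c in CATALOG_COLUMNS if c not in cat.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    bad = set(cat["kind"]) - set(CATALOG_KINDS)
    if bad:
        raise ValueError(f"unknown catalog kind(s): {sorted(bad)}")
    loci = cat["kind"] == "recurrent_locus"
    if cat.loc[loci, ["start", "end"]].isna().any().any():
        raise ValueError("recurrent_locus entries require coordinates")
    if cat.loc[~loci, "symbol"].isna().any():
        raise ValueError("gene entries require a symbol")
    return cat


def bundled_catalog() -> pd.DataFrame:
    """The synthetic fixture catalog shipped with the package."""
    ref = importlib.resources.files("cnvcohort.data").joinpath("catalog_fixture.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_catalog(path)


def detect_aneuploidy(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    sex: dict | pd.Series | None = None,
    span_fraction: float = 0.9,
) -> pd.Series:
    """Label calls covering >= ``span_fraction`` of their chromosome.

    Returns a Series aligned to ``calls`` holding a karyotype-style label
    (``trisomy_21``, ``XYY``, ``47,XXX``, ``45,X`` ...) or ``None``. Array
    calls rarely span the full assembly, hence the 90% default. ``sex`` maps
    participant_id -> {"male", "female"} and refines sex-chromosome labels.
    """
    labels: list[str | None] = []
    sex = dict(sex) if sex is not None else {}
    for row in calls.itertuples(index=False):
        length = chrom_lengths.get(row.chrom)
        if length is None:
            raise ValueError(f"missing chromosome length for {row.chrom}")
        if (row.end - row.start) < span_fraction * length:
            labels.append(None)
            continue
        labels.append(_karyotype_label(row.chrom, row.type, sex.get(row.participant_id)))
    return pd.Series(labels, index=calls.index, dtype=object)


def _karyotype_label(chrom: str, ctype: str, sex: str | None) -> str:
    name = chrom.removeprefix("chr")
    if name == "X":
        if ctype == "DUP":
            return "47,XXX" if sex == "female" else "47,XXY"
        return "45,X"
    if name == "Y":
        return "XYY" if ctype == "DUP" else "45,X0_Y_loss"
    return f"{'trisomy' if ctype == 'DUP' else 'monosomy'}_{name}"


def classify_cnv(
    chrom: str,
    start: int,
    end: int,
    cnv_type: str,
    catalog: pd.DataFrame,
    gene_index: GeneIndex | None = None,
    aneuploidy_label: str | None = None,
) -> tuple[str, str | None]:
    """Tier a single CNV against the catalog.

    Returns ``(tier, matched_entry_name)``. Gene-kind catalog entries without
    coordinates are resolved through ``gene_index`` (matched by symbol).
    """
    if aneuploidy_label is not None:
        return "aneuploidy", aneuploidy_label

    hit_symbols: set[str] | None = None

    def overlaps_gene(entry) -> bool:
        nonlocal hit_symbols
        if pd.notna(entry.start) and pd.notna(entry.end) and pd.notna(entry.chrom):
            return entry.chrom == chrom and min(end, int(entry.end)) > max(start, int(entry.start))
        if gene_index is None:
            return False
        if hit_symbols is None:
            hit_symbols = gene_index.genes_hit(chrom, start, end)
        return entry.symbol in hit_symbols

    def type_ok(entry) -> bool:
        return entry.required_type in ("any", cnv_type)

    for entry in catalog.loc[catalog["kind"] == "recurrent_locus"].itertuples(index=False):
        if entry.chrom != chrom or not type_ok(entry):
            continue
        thr = entry.min_reciprocal_overlap if pd.notna(entry.min_reciprocal_overlap) else 0.5
        if reciprocal_overlap(start, end, int(entry.start), int(entry.end)) >= thr:
            return "recurrent", entry.name
    for kind, tier in (("significant_gene", "non_recurrent"), ("susceptibility_gene", "susceptibility")):
        for entry in catalog.loc[catalog["kind"] == kind].itertuples(index=False):
            if type_ok(entry) and overlaps_gene(entry):
                return tier, entry.name
    return "unclassified", None


def classify_calls(
    calls: pd.DataFrame,
    catalog: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    chrom_lengths: dict[str, int] | None = None,
    sex: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """Tier every consensus call; adds ``tier`` and ``matched_entry`` columns.

    Idempotent and deterministic: catalog order breaks ties within a tier.
    """
    out = calls.copy()
    gene_index = GeneIndex(genes) if genes is not None and len(genes) else None
    if chrom_lengths:
        aneu = detect_aneuploidy(out, chrom_lengths, sex=sex)
    else:
        aneu = pd.Series([None] * len(out), index=out.index, dtype=object)
    tiers, names = [], []
    for i, row in zip(out.index, out.itertuples(index=False)):
        tier, name = classify_cnv(
            row.chrom, row.start, row.end, row.type, catalog, gene_index, aneuploidy_label=aneu[i]
        )
        tiers.append(tier)
        names.append(name)
    out["tier"] = tiers
    out["matched_entry"] = names
    return out


def classify_participants(classified_calls: pd.DataFrame, cohort_ids) -> pd.DataFrame:
    """Roll call tiers up to participants.

    ``carrier_group`` is the mutually exclusive three-way split used for
    enrichment tables: participants carrying both a clinically significant
    and a susceptibility CNV are grouped under ``significant`` (significance
    takes precedence); otherwise ``susceptibility`` or ``neither``.
    """
    cohort_ids = pd.Index(pd.unique(pd.Series(list(cohort_ids), dtype=object)), name="participant_id")
    if "tier" not in classified_calls.columns:
        raise ValueError("calls must carry a 'tier' column; run classify_calls first")
    sig = classified_calls.loc[classified_calls["tier"].isin(SIGNIFICANT_TIERS)]
    sus = classified_calls.loc[classified_calls["tier"] == "susceptibility"]
    n_class = (
        pd.concat([sig, sus])["participant_id"].value_counts().reindex(cohort_ids, fill_value=0)
    )
    has_sig = cohort_ids.isin(sig["participant_id"])
    has_sus = cohort_ids.isin(sus["participant_id"])
    group = pd.Series("neither", index=cohort_ids, dtype=object)
    group[has_sus] = "susceptibility"
    group[has_sig] = "significant"
    tiers = pd.DataFrame(
        {
            "has_significant": has_sig,
            "has_susceptibility": has_sus,
            "carrier_group": group,
            "n_classified_cnvs": n_class.astype(int),
        },
        index=cohort_ids,
    )
    n_multi = int((tiers["n_classified_cnvs"] > 1).sum())
    if n_multi:
        logger.info("%d participant(s) carry multiple classified CNVs", n_multi)
    return tiers
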