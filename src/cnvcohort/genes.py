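"""Gene models, gene-sets and per-participant CNV burden matrices.

Gene annotations are DataFrames with columns ``symbol, chrom, start, end,
strand`` (0-based half-open internally; BED is read as-is, GFF3 is converted
from 1-based inclusive on ingest). Gene-sets are plain ``dict[str, set[str]]``
parsed from GMT.

A CNV "impacts" a gene when it overlaps the gene body by at least one base;
at array resolution (calls >= 10 kb) exon-level intersection adds noise
rather than precision. Gene counting is per participant over DISTINCT genes:
a gene hit by two calls of the same type/stratum counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .calls import CNV_TYPES

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["symbol", "chrom", "start", "end", "strand"]
STRATA = ("rare", "less_rare")


def read_bed_genes(path) -> pd.DataFrame:
    """Read a BED6 gene annotation (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("expected BED6 with at least 6 columns")
    out = pd.DataFrame(
        {
            "symbol": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5].astype(str),
        }
    )
    _check_genes(out)
    return out


def write_bed_genes(genes: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            0: genes["chrom"],
            1: genes["start"],
            2: genes["end"],
            3: genes["symbol"],
            4: 0,
            5: genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from GFF3 (1-based inclusive -> half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            symbol = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID")
            rows.append((symbol, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    out = pd.DataFrame(rows, columns=GENE_COLUMNS)
    _check_genes(out)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file into ``{set_name: {symbols}}``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def _check_genes(genes: pd.DataFrame) -> None:
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("gene intervals must satisfy end > start")
    if genes["symbol"].duplicated().any():
        dups = genes.loc[genes["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate gene symbols in annotation: {dups[:5]}")


class GeneIndex:
    """Interval index over a gene annotation for overlap queries."""

    def __init__(self, genes: pd.DataFrame):
        _check_genes(genes)
        self.genes = genes.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.genes.groupby("chrom"):
            self._trees[chrom] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"], grp["symbol"])
            )

    def genes_hit(self, chrom: str, start: int, end: int) -> set[str]:
        """Symbols of genes overlapping [start, end) on ``chrom`` by >= 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def genes_hit(call_chrom: str, call_start: int, call_end: int, genes: pd.DataFrame) -> set[str]:
    """One-shot overlap query; build a :class:`GeneIndex` for repeated use."""
    return GeneIndex(genes).genes_hit(call_chrom, call_start, call_end)


@dataclass
class BurdenMatrix:
    """Participant-level CNV burden, one row per cohort participant.

    main
        Columns ``gene_count_{DEL,DUP}_{rare,less_rare}``, ``gene_count_total``
        (distinct genes hit by either type, both strata pooled — the global
        burden covariate), and ``total_length_{DEL,DUP}`` in bp.
    gene_sets
        Columns ``{set}|{type}|{stratum}``: distinct impacted genes in the set.
    genes
        Columns ``{symbol}|{type}``: binary carrier indicator (>= 1 call of
        the type overlapping the gene, common stratum excluded).
    """

    main: pd.DataFrame
    gene_sets: pd.DataFrame
    genes: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, prefix) -> None:
        """Write matrix blocks and a sidecar column-metadata file."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        self.main.to_csv(prefix.with_suffix(".main.tsv"), sep="\t")
        self.gene_sets.to_csv(prefix.with_suffix(".gene_sets.tsv"), sep="\t")
        self.genes.to_csv(prefix.with_suffix(".genes.tsv"), sep="\t")
        meta = dict(self.metadata)
        meta["columns"] = {
            "main": list(self.main.columns),
            "gene_sets": list(self.gene_sets.columns),
            "genes": list(self.genes.columns),
        }
        prefix.with_suffix(".columns.json").write_text(json.dumps(meta, indent=2, default=str))


def build_burden_matrix(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: dict[str, set[str]] | None,
    cohort_ids,
) -> BurdenMatrix:
    """Build the participant x predictor burden matrix.

    ``calls`` must be consensus calls with ``frequency``/``stratum`` annotated;
    common-stratum calls are excluded from every count. Participants in
    ``cohort_ids`` without calls get all-zero rows; a call from a participant
    not in the cohort is an input-consistency error.
    """
    cohort_ids = pd.Index(pd.unique(pd.Series(list(cohort_ids), dtype=object)), name="participant_id")
    gene_sets = gene_sets or {}
    if "stratum" not in calls.columns:
        raise ValueError("calls must be frequency-stratified before burden computation")
    unknown = set(calls["participant_id"]) - set(cohort_ids)
    if unknown:
        raise ValueError(f"call table contains participants outside the cohort: {sorted(unknown)[:5]}")

    work = calls.loc[calls["stratum"].isin(STRATA)].reset_index(drop=True)
    index = GeneIndex(genes)

    known_symbols = set(genes["symbol"])
    clean_sets: dict[str, set[str]] = {}
    for name, members in gene_sets.items():
        unknown_members = members - known_symbols
        if unknown_members:
            logger.info("gene-set %s: ignoring %d symbol(s) absent from annotation", name, len(unknown_members))
        clean_sets[name] = members & known_symbols

    # per (participant, type, stratum) and (participant, type) distinct gene sets
    hit: dict[tuple, set[str]] = {}
    hit_any: dict[tuple, set[str]] = {}
    lengths: dict[tuple, int] = {}
    for row in work.itertuples(index=False):
        symbols = index.genes_hit(row.chrom, row.start, row.end)
        key = (row.participant_id, row.type, row.stratum)
        hit.setdefault(key, set()).update(symbols)
        hit_any.setdefault((row.participant_id, row.type), set()).update(symbols)
        lengths[(row.participant_id, row.type)] = lengths.get((row.participant_id, row.type), 0) + (
            row.end - row.start
        )

    main = pd.DataFrame(0, index=cohort_ids, columns=_main_columns(), dtype=np.int64)
    set_cols = [f"{name}|{t}|{s}" for name in clean_sets for t in CNV_TYPES for s in STRATA]
    gs = pd.DataFrame(0, index=cohort_ids, columns=set_cols, dtype=np.int64)
    gene_cols = sorted({f"{sym}|{t}" for (pid, t), syms in hit_any.items() for sym in syms})
    gind = pd.DataFrame(0, index=cohort_ids, columns=gene_cols, dtype=np.int64)

    for (pid, ctype, stratum), syms in hit.items():
        main.loc[pid, f"gene_count_{ctype}_{stratum}"] = len(syms)
        for name, members in clean_sets.items():
            gs.loc[pid, f"{name}|{ctype}|{stratum}"] = len(syms & members)
    totals: dict[str, set[str]] = {}
    for (pid, ctype), syms in hit_any.items():
        totals.setdefault(pid, set()).update(syms)
        for sym in syms:
            gind.loc[pid, f"{sym}|{ctype}"] = 1
    for pid, syms in totals.items():
        main.loc[pid, "gene_count_total"] = len(syms)
    for (pid, ctype), L in lengths.items():
        main.loc[pid, f"total_length_{ctype}"] = L

    meta = {
        "n_participants": len(cohort_ids),
        "n_calls_used": int(len(work)),
        "n_calls_common_excluded": int((calls["stratum"] == "common").sum()),
        "gene_sets": {k: len(v) for k, v in clean_sets.items()},
    }
    return BurdenMatrix(main=main, gene_sets=gs, genes=gind, metadata=meta)


def _main_columns() -> list[str]:
    cols = [f"gene_count_{t}_{s}" for t in CNV_TYPES for s in STRATA]
    return cols + ["gene_count_total", "total_length_DEL", "total_length_DUP"]


def subset_chromosome_x(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: dict[str, set[str]] | None,
    cohort_ids,
    x_chrom: str = "chrX",
) -> BurdenMatrix:
    """Burden matrix computed over X-linked genes only."""
    x_genes = genes.loc[genes["chrom"] == x_chrom].reset_index(drop=True)
    bm = build_burden_matrix(calls, x_genes, gene_sets, cohort_ids)
    bm.metadata["subset"] = f"chromosome {x_chrom}"
    return bm
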