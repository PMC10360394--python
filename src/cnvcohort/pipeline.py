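"""End-to-end orchestration: simulate/load -> consensus -> classify ->
phenotype -> associate -> burden -> report.

`run_pipeline` is deterministic for a fixed config (including the seed): the
result bundle's tables are byte-identical across re-runs. Each stage failure
is re-raised as :class:`PipelineStageError` tagged with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    ContingencyTable,
    carrier_demographics,
    chi_square,
    disorder_logistic,
    odds_ratio_ci,
    trait_group_regression,
)
from .burden import (
    BurdenModelSpec,
    geneset_burden,
    global_burden,
    locus_burden,
    select_top_gene_sets,
    sex_burden_lrt,
)
from .calls import CNV_TYPES, ConsensusPolicy, annotate_frequency, consensus_merge, size_filter, stratify_frequency
from .classify import classify_calls, classify_participants, read_catalog
from .genes import STRATA, build_burden_matrix, read_bed_genes, read_gmt, subset_chromosome_x
from .phenotypes import add_composites, demographic_models, exclude_small_disorders, flag_high_traits, t_score
from .simulate import TRAITS, Genome, SimConfig, simulate_cohort, simulate_genome

logger = logging.getLogger(__name__)

#: task measures adjusted for concurrent stimulant medication
STIMULANT_TRAITS = ("ssrt", "rtv")
BURDEN_COVARIATES = ("PC1", "PC2", "PC3", "batch", "platform")
SEX_LRT_COVARIATES = ("PC1", "PC2", "PC3", "batch", "phase")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Thresholds, inputs and seed for one pipeline run."""

    sim: SimConfig | None = None
    input_paths: dict = field(default_factory=dict)  # caller_calls(list)/genes/gene_sets/catalog/chromosomes/phenotypes/covariates
    consensus: ConsensusPolicy = field(default_factory=ConsensusPolicy)
    min_length: int = 10_000
    cluster_reciprocal_overlap: float = 0.5
    high_trait_quantile: float = 0.10
    min_disorder_n: int = 20
    min_trait_group_n: int = 10
    min_locus_carriers: int = 3
    n_permutations: int = 10_000
    min_ancestry_n: int = 100
    traits: tuple[str, ...] = TRAITS
    seed: int = 1
    outdir: str | Path | None = None


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.10g")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True, default=str))
        (outdir / "report.md").write_text(make_report(self))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise PipelineStageError(name, e) from e
        return wrapped
    return deco


@_stage("input")
def _load_inputs(config: RunConfig):
    if config.sim is not None:
        genome = simulate_genome(config.sim)
        cohort = simulate_cohort(config.sim, genome)
        return genome, cohort.caller_calls, cohort.phenotypes, cohort.covariates
    p = config.input_paths
    for key in ("caller_calls", "genes", "gene_sets", "catalog", "chromosomes", "phenotypes", "covariates"):
        if key not in p:
            raise FileNotFoundError(f"missing input path: {key}")
    calls = pd.concat([pd.read_csv(f, sep="\t") for f in p["caller_calls"]], ignore_index=True)
    genes = read_bed_genes(p["genes"])
    gene_sets = read_gmt(p["gene_sets"])
    catalog = read_catalog(p["catalog"])
    chroms = pd.read_csv(p["chromosomes"], sep="\t", index_col=0)["length"].to_dict()
    pheno = pd.read_csv(p["phenotypes"], sep="\t", index_col=0)
    cov = pd.read_csv(p["covariates"], sep="\t", index_col=0)
    genome = Genome(genes=genes, gene_sets=gene_sets, catalog=catalog, chrom_lengths=chroms,
                    causal_set=next(iter(gene_sets)), control_set="")
    return genome, calls, pheno, cov


@_stage("consensus")
def _consensus(config: RunConfig, caller_calls: pd.DataFrame, n: int) -> pd.DataFrame:
    merged = consensus_merge(caller_calls, config.consensus)
    merged = size_filter(merged, config.min_length)
    merged = annotate_frequency(merged, n, config.cluster_reciprocal_overlap)
    return stratify_frequency(merged)


@_stage("classify")
def _classify(genome: Genome, calls: pd.DataFrame, pheno: pd.DataFrame, ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    sex = pheno["sex"].to_dict() if "sex" in pheno.columns else None
    classified = classify_calls(calls, genome.catalog, genes=genome.genes,
                                chrom_lengths=genome.chrom_lengths, sex=sex)
    tiers = classify_participants(classified, ids)
    return classified, tiers


@_stage("phenotype")
def _phenotype(config: RunConfig, pheno: pd.DataFrame, cov: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    out = pheno.copy()
    grouping = out["gender"].astype(str)
    if "phase" in cov.columns:
        grouping = grouping + "|" + cov["phase"].reindex(out.index).astype(str)
    traits = [t for t in config.traits if t in out.columns]
    for trait in traits:
        out[f"t_{trait}"] = t_score(out[trait], grouping)
        out[f"high_{trait}"] = flag_high_traits(out[f"t_{trait}"], config.high_trait_quantile)
    dx_cols = [c for c in out.columns if c.startswith("dx_")]
    out = add_composites(out, dx_cols, [f"high_{t}" for t in traits])
    retained = exclude_small_disorders(out[dx_cols].fillna(0).astype(int), config.min_disorder_n)
    return out, retained


@_stage("associate")
def _associate(config: RunConfig, tiers: pd.DataFrame, pheno: pd.DataFrame, retained: list[str]) -> dict[str, pd.DataFrame]:
    group = tiers["carrier_group"]
    carrier_any = (group != "neither").astype(int)
    outcomes = {"diagnosis": "any_diagnosis", "high_trait": "any_high_trait", "dx_or_high": "any_dx_or_high"}
    rows = []
    for gname, mask in (
        ("significant", group == "significant"),
        ("susceptibility", group == "susceptibility"),
        ("either", group != "neither"),
    ):
        ref = group == "neither"
        for oname, col in outcomes.items():
            y = pheno[col].reindex(tiers.index)
            a = int(((mask) & (y == 1)).sum())
            b = int(((mask) & (y == 0)).sum())
            c = int((ref & (y == 1)).sum())
            d = int((ref & (y == 0)).sum())
            t = ContingencyTable(a, b, c, d)
            orr = odds_ratio_ci(t)
            chi = chi_square(t)
            rows.append({"carrier_group": gname, "outcome": oname, "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": orr.estimate, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                         "or_p": orr.p, "chi2": chi.statistic, "chi2_p": chi.p})
    enrichment = pd.DataFrame(rows)

    dx_rows = []
    for dx in retained:
        y = pheno[f"dx_{dx}" if not dx.startswith("dx_") else dx].reindex(tiers.index)
        res = disorder_logistic(y, carrier_any)
        d = res.to_dict()
        d["disorder"] = dx.removeprefix("dx_")
        dx_rows.append(d)
    disorders = pd.DataFrame(dx_rows)

    tr_rows = []
    for trait in [t for t in config.traits if f"t_{t}" in pheno.columns]:
        for gname in ("significant", "susceptibility"):
            res = trait_group_regression(
                pheno[f"t_{trait}"].reindex(tiers.index), group, group=gname,
                min_group_n=config.min_trait_group_n,
            )
            d = res.to_dict()
            d["trait"] = trait
            tr_rows.append(d)
    traits_tbl = pd.DataFrame(tr_rows)

    demo = carrier_demographics(tiers, pheno["age"].reindex(tiers.index),
                                pheno["sex"].reindex(tiers.index),
                                pheno["respondent"].reindex(tiers.index))
    dx_flags = pheno[[f"dx_{d}" if not d.startswith("dx_") else d for d in retained]]
    dx_flags = dx_flags.rename(columns=lambda c: c.removeprefix("dx_"))
    demo_models = demographic_models(dx_flags.fillna(0).astype(int), pheno["age"],
                                     pheno["gender"], min_n=config.min_disorder_n)
    return {"enrichment": enrichment, "disorder_logistic": disorders,
            "trait_regressions": traits_tbl, "carrier_demographics": demo,
            "demographic_models": demo_models}


@_stage("burden")
def _burden(config: RunConfig, genome: Genome, calls: pd.DataFrame, pheno: pd.DataFrame,
            cov: pd.DataFrame) -> dict[str, pd.DataFrame]:
    ids = pheno.index
    matrix = build_burden_matrix(calls, genome.genes, genome.gene_sets, ids)
    xmatrix = subset_chromosome_x(calls, genome.genes, genome.gene_sets, ids)

    strata_groups: list[tuple[str, pd.Index]] = []
    if "ancestry" in cov.columns:
        for anc, grp in cov.groupby("ancestry"):
            if len(grp) >= config.min_ancestry_n:
                strata_groups.append((anc, grp.index))
    if not strata_groups:
        strata_groups = [("all", ids)]

    traits = [t for t in config.traits if f"t_{t}" in pheno.columns]
    glob_rows, gs_frames, locus_frames = [], [], []
    rng = np.random.default_rng(config.seed)
    for anc, aidx in strata_groups:
        sub = _subset_matrix(matrix, aidx)
        subx = _subset_matrix(xmatrix, aidx)
        ph = pheno.loc[aidx]
        cv = cov.loc[aidx, [c for c in BURDEN_COVARIATES if c in cov.columns]]
        for trait in traits:
            cvt = cv.copy()
            if trait in STIMULANT_TRAITS and "stimulant_medication" in ph.columns:
                cvt["stimulant_medication"] = ph["stimulant_medication"].astype(float)
            for ctype in CNV_TYPES:
                for stratum in STRATA:
                    spec = BurdenModelSpec(outcome=f"t_{trait}", predictor=f"gene_count_{ctype}_{stratum}",
                                           stratum=stratum, cnv_type=ctype, ancestry=anc)
                    res = global_burden(spec, sub, ph, covariates=cvt)
                    row = res.to_dict()
                    row.update({"ancestry": anc, "trait": trait, "cnv_type": ctype, "stratum": stratum})
                    glob_rows.append(row)
                    gs = geneset_burden(sub, ph, f"t_{trait}", cnv_type=ctype, stratum=stratum, covariates=cvt)
                    gs["ancestry"] = anc
                    gs_frames.append(gs)
                    top = select_top_gene_sets(gs)
                    if top:
                        universe = set().union(*(genome.gene_sets[s] for s in top))
                        seed_i = int(rng.integers(0, 2**31 - 1))
                        loc, _info = locus_burden(
                            sub, ph, f"t_{trait}", universe, cnv_type=ctype, covariates=cvt,
                            min_carriers=config.min_locus_carriers,
                            n_permutations=config.n_permutations, seed=seed_i,
                        )
                        loc["ancestry"], loc["trait"], loc["cnv_type"], loc["stratum"] = anc, trait, ctype, stratum
                        locus_frames.append(loc)
            # chromosome-X subset, same family layout, deletions of rare CNVs
            gsx = geneset_burden(subx, ph, f"t_{trait}", cnv_type="DEL", stratum="rare", covariates=cvt)
            gsx["ancestry"] = anc
            gsx["subset"] = "chrX"
            gs_frames.append(gsx)

    sexcov = cov.loc[:, [c for c in SEX_LRT_COVARIATES if c in cov.columns]]
    sex_lrt = sex_burden_lrt(matrix, pheno["sex"], covariates=sexcov)

    out = {
        "global_burden": pd.DataFrame(glob_rows),
        "geneset_burden": pd.concat(gs_frames, ignore_index=True) if gs_frames else pd.DataFrame(),
        "locus_burden": pd.concat(locus_frames, ignore_index=True) if locus_frames else pd.DataFrame(
            columns=["gene", "n_carriers", "beta", "t", "p", "p_fwer"]
        ),
        "sex_burden_lrt": sex_lrt,
    }
    return out


def _subset_matrix(matrix, idx):
    import copy

    sub = copy.copy(matrix)
    sub.main = matrix.main.loc[idx]
    sub.gene_sets = matrix.gene_sets.loc[idx]
    sub.genes = matrix.genes.loc[idx]
    return sub


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and return the result bundle (optionally written)."""
    genome, caller_calls, pheno_raw, cov = _load_inputs(config)
    ids = pheno_raw.index
    calls = _consensus(config, caller_calls, len(ids))
    classified, tiers = _classify(genome, calls, pheno_raw, ids)
    pheno, retained = _phenotype(config, pheno_raw, cov)
    assoc = _associate(config, tiers, pheno, retained)
    burden_tables = _burden(config, genome, calls, pheno, cov)

    prevalence = pd.DataFrame(
        {
            "group": ["significant", "susceptibility", "either", "neither"],
            "n": [
                int((tiers["carrier_group"] == "significant").sum()),
                int((tiers["carrier_group"] == "susceptibility").sum()),
                int((tiers["carrier_group"] != "neither").sum()),
                int((tiers["carrier_group"] == "neither").sum()),
            ],
        }
    )
    prevalence["pct"] = 100 * prevalence["n"] / len(ids)

    tables = {
        "consensus_calls": classified,
        "participant_tiers": tiers.reset_index(),
        "prevalence": prevalence,
        "phenotypes_scored": pheno.reset_index(),
        **assoc,
        **burden_tables,
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_participants": len(ids),
        "thresholds": {
            "min_callers": config.consensus.min_callers,
            "merge_reciprocal_overlap": config.consensus.merge_reciprocal_overlap,
            "cluster_reciprocal_overlap": config.cluster_reciprocal_overlap,
            "min_length": config.min_length,
            "high_trait_quantile": config.high_trait_quantile,
            "min_disorder_n": config.min_disorder_n,
            "min_locus_carriers": config.min_locus_carriers,
            "n_permutations": config.n_permutations,
        },
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "retained_disorders": retained,
    }
    result = PipelineResult(tables=tables, manifest=manifest)
    if config.outdir is not None:
        result.write(config.outdir)
    return result


def make_report(result: PipelineResult) -> str:
    """Human-readable markdown summary of a result bundle. Idempotent."""
    t = result.tables
    lines = ["# Cohort CNV analysis report", ""]
    n = result.manifest.get("n_participants", 0)
    if not n:
        lines += ["Zero participants; no tables.", ""]
        return "\n".join(lines)
    lines += [f"Participants: {n}; seed {result.manifest.get('seed')}.", ""]
    if "prevalence" in t:
        lines += ["## Carrier prevalence", "", "```", t["prevalence"].to_string(index=False), "```", ""]
    if "enrichment" in t and len(t["enrichment"]):
        lines += ["## Phenotype enrichment (odds ratios, Woolf 95% CI)", ""]
        e = t["enrichment"]
        for row in e.itertuples(index=False):
            lines.append(
                f"- {row.carrier_group} x {row.outcome}: OR {row.odds_ratio:.2f} "
                f"({row.ci_low:.2f}-{row.ci_high:.2f}), chi2 p = {row.chi2_p:.2g}"
            )
        lines.append("")
    if "global_burden" in t and len(t["global_burden"]):
        lines += ["## Global burden (beta per impacted gene, T-score units)", ""]
        g = t["global_burden"]
        for row in g.itertuples(index=False):
            lines.append(
                f"- {row.ancestry} {row.trait} {row.cnv_type}/{row.stratum}: "
                f"beta {row.estimate:.3f} ({row.ci_low:.3f}, {row.ci_high:.3f}), p = {row.p:.2g}"
            )
        lines.append("")
    if "geneset_burden" in t and len(t["geneset_burden"]):
        sig = t["geneset_burden"].query("p < 0.05 and q < 0.2")
        lines += [f"## Gene-set burden: {len(sig)} set-family pair(s) at p<0.05, BH-FDR<0.2", ""]
    if "locus_burden" in t:
        lines += [f"## Locus tests: {len(t['locus_burden'])} gene(s) tested", ""]
    return "\n".join(lines)
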