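"""Synthetic cohort generator with known planted effects.

Emulates the structure of a community genotyping cohort: two ancestry strata
(~80/20), three pseudo-callers each detecting a participant's true CNVs with
configurable sensitivity and small breakpoint jitter, polymorphic CNV loci
spanning the rare / less-rare / common frequency strata, ~4% carriers of
catalog-classified CNVs, rare whole-chromosome aneuploidies, quantitative
traits with a planted per-gene burden effect concentrated in a designated
causal gene-set, and diagnoses with a planted carrier odds ratio.

Everything is a deterministic function of the config (including its seed):
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CATALOG_COLUMNS
from .genes import GeneIndex, write_bed_genes, write_gmt

CALLERS = ("callerA", "callerB", "callerC")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort the pipeline targets: 7100 participants,
    80/20 European / East Asian split, consensus CNVs of at least 10 kb,
    ~4% classified-CNV carriers, a carrier diagnosis odds ratio of 3 and a
    per-causal-gene trait shift of 0.15 raw-score units (raw traits have
    residual SD 1). Tests and examples pass smaller ``n_participants``.
    """

    n_participants: int = 7100
    ancestry_fractions: dict = field(default_factory=lambda: {"EUR": 0.8, "EAS": 0.2})
    n_genes: int = 400
    genome_length: int = 1_500_000_000
    n_autosomes: int = 4
    cnv_rate: float = 3.0
    size_range: tuple[int, int] = (10_000, 5_000_000)
    polymorphic_loci: tuple | None = None  # ((chrom, start, end, type, freq), ...)
    carrier_fraction_classified: float = 0.04
    aneuploidy_rate: float = 0.001
    planted_or: float = 3.0
    planted_beta: float = 0.15
    caller_sensitivity: dict = field(
        default_factory=lambda: {"callerA": 0.95, "callerB": 0.90, "callerC": 0.85}
    )
    breakpoint_jitter: float = 0.02
    noise_sd: float = 1.0
    n_gene_sets: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_genes <= 0 or self.n_autosomes < 2:
            raise ConfigurationError("counts must be positive (and >= 2 autosomes)")
        if abs(sum(self.ancestry_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("ancestry fractions must sum to 1")
        if any(not 0 <= f <= 1 for f in self.ancestry_fractions.values()):
            raise ConfigurationError("ancestry fractions must lie in [0, 1]")
        if self.planted_or <= 0:
            raise ConfigurationError("planted_or must be positive")
        if self.size_range[0] < 10_000 or self.size_range[1] < self.size_range[0]:
            raise ConfigurationError("size_range must be ordered with min >= 10 kb")
        if not 0 <= self.carrier_fraction_classified <= 1:
            raise ConfigurationError("carrier_fraction_classified must be a proportion")
        if isinstance(self.caller_sensitivity, (int, float)):
            object.__setattr__(
                self, "caller_sensitivity", {c: float(self.caller_sensitivity) for c in CALLERS}
            )
        if any(not 0 <= s <= 1 for s in self.caller_sensitivity.values()):
            raise ConfigurationError("caller sensitivities must be probabilities")

    @property
    def chromosomes(self) -> dict[str, int]:
        per = self.genome_length // (self.n_autosomes + 1)
        chroms = {f"chr{i + 1}": per for i in range(self.n_autosomes)}
        chroms["chrX"] = per
        return chroms


@dataclass
class Genome:
    genes: pd.DataFrame
    gene_sets: dict[str, set[str]]
    catalog: pd.DataFrame
    chrom_lengths: dict[str, int]
    causal_set: str
    control_set: str

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed_genes(self.genes, outdir / "genes.bed")
        write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        self.catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        pd.Series(self.chrom_lengths, name="length").rename_axis("chrom").to_csv(
            outdir / "chromosomes.tsv", sep="\t"
        )


@dataclass
class Cohort:
    caller_calls: pd.DataFrame  # participant_id, chrom, start, end, type, caller
    true_cnvs: pd.DataFrame  # adds 'origin' in {background, polymorphic, classified, aneuploidy}
    phenotypes: pd.DataFrame  # diagnoses (dx_*), raw traits, stimulant flag, demographics
    covariates: pd.DataFrame  # ancestry, PC1-3, batch, platform, phase
    truth: dict  # planted-effect bookkeeping for calibration

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for caller, grp in self.caller_calls.groupby("caller"):
            grp.to_csv(outdir / f"calls_{caller}.tsv", sep="\t", index=False)
        self.true_cnvs.to_csv(outdir / "true_cnvs.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t")


TRAITS = ("adhd_total", "inattention", "hyperactivity", "ocd", "anxiety", "ssrt", "rtv")
#: traits carrying the planted causal-gene-set deletion-burden effect
PLANTED_TRAITS = ("adhd_total", "inattention")

#: baseline diagnosis rates; the small ones exercise the n<20 exclusion at
#: full cohort size
DIAGNOSIS_RATES = {
    "adhd": 0.065,
    "anxiety": 0.045,
    "asd": 0.020,
    "learning": 0.091,
    "mood": 0.014,
    "ocd": 0.011,
    "tics": 0.012,
    "eating": 0.0003,
    "intellectual_disability": 0.0018,
    "language": 0.0007,
    "motor": 0.0006,
    "schizophrenia_spectrum": 0.0008,
}
#: diagnoses whose odds are multiplied by planted_or in classified carriers
PLANTED_DIAGNOSES = ("adhd", "anxiety")


def simulate_genome(config: SimConfig) -> Genome:
    """Gene annotation, gene-sets and classification catalogs for one cohort.

    Genes are non-overlapping, spread over the autosomes and chromosome X.
    Gene-sets include one designated causal set (carries the planted burden
    effect) and one organ-system-style negative-control set disjoint from it.
    The catalog holds one recurrent genomic-disorder locus plus clinically
    significant and susceptibility genes drawn outside the causal set.
    """
    if config.n_genes < 10:
        raise ConfigurationError("need at least 10 genes")
    rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes
    names = [f"G{i:04d}" for i in range(config.n_genes)]
    # round-robin chromosome assignment keeps every chromosome populated
    chrom_cycle = list(chroms)
    rows = []
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i, name in enumerate(names):
        per_chrom[chrom_cycle[i % len(chrom_cycle)]] += 1
    gi = 0
    for chrom, count in per_chrom.items():
        L = chroms[chrom]
        slot = L // max(count, 1)
        for k in range(count):
            glen = int(rng.integers(20_000, min(200_000, slot - 1)))
            start = int(k * slot + rng.integers(0, slot - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((names[gi], chrom, start, start + glen, strand))
            gi += 1
    genes = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"])

    set_size = max(10, config.n_genes // 10)
    shuffled = list(rng.permutation(names))
    causal = set(shuffled[:set_size])
    control = set(shuffled[set_size : 2 * set_size])  # disjoint negative control
    gene_sets = {"causal_neurodev": causal, "control_organ_system": control}
    for j in range(max(0, config.n_gene_sets - 2)):
        gene_sets[f"set_{j:02d}"] = set(rng.choice(names, size=set_size, replace=False))

    # catalog entries live outside the causal set so classification effects
    # and burden effects stay separable
    pool = [g for g in shuffled[2 * set_size :]]
    sig_genes = pool[:2]
    sus_genes = pool[2:5]
    locus_chrom = "chr1"
    locus_start = int(0.6 * chroms[locus_chrom])
    cat_rows = [
        {
            "kind": "recurrent_locus", "name": "locus_1", "chrom": locus_chrom,
            "start": locus_start, "end": locus_start + 2_000_000, "symbol": "",
            "required_type": "any", "min_reciprocal_overlap": 0.5,
        }
    ]
    glookup = genes.set_index("symbol")
    for sym in sig_genes:
        g = glookup.loc[sym]
        cat_rows.append({"kind": "significant_gene", "name": sym, "chrom": g["chrom"],
                         "start": g["start"], "end": g["end"], "symbol": sym,
                         "required_type": "any", "min_reciprocal_overlap": np.nan})
    for sym in sus_genes:
        g = glookup.loc[sym]
        cat_rows.append({"kind": "susceptibility_gene", "name": sym, "chrom": g["chrom"],
                         "start": g["start"], "end": g["end"], "symbol": sym,
                         "required_type": "any", "min_reciprocal_overlap": np.nan})
    catalog = pd.DataFrame(cat_rows, columns=CATALOG_COLUMNS)
    return Genome(
        genes=genes, gene_sets=gene_sets, catalog=catalog, chrom_lengths=dict(chroms),
        causal_set="causal_neurodev", control_set="control_organ_system",
    )


def _default_polymorphic(genome: Genome, rng: np.random.Generator) -> list[tuple]:
    """Three polymorphic loci, one per frequency stratum."""
    chroms = [c for c in genome.chrom_lengths if c != "chrX"]
    loci = []
    for i, (freq, ctype) in enumerate([(0.002, "DEL"), (0.03, "DEL"), (0.12, "DUP")]):
        chrom = chroms[(i + 1) % len(chroms)]
        L = genome.chrom_lengths[chrom]
        start = int((0.25 + 0.2 * i) * L)
        size = int(rng.integers(50_000, 400_000))
        loci.append((chrom, start, start + size, ctype, freq))
    return loci


def simulate_cohort(config: SimConfig, genome: Genome) -> Cohort:
    """Per-caller CNV call tables, phenotypes and covariates with planted truth.

    True CNVs comprise Poisson background events (log-uniform sizes),
    polymorphic loci realized per participant at their set frequencies,
    one classified CNV per designated carrier (drawn from the catalog) and
    rare whole-chromosome aneuploidies. Each caller reports each true CNV
    independently with its sensitivity and ~2% breakpoint jitter, so the
    two-of-three consensus recovers most true events.

    Raw traits follow ``planted_beta * (causal-set genes deleted) +
    covariate effects + N(0, noise_sd)``; planted diagnoses follow
    ``Bernoulli(logistic(alpha + log(planted_or) * carrier))``.
    """
    rng = np.random.default_rng(config.seed + 104_729)  # distinct stream from the genome
    n = config.n_participants
    ids = np.array([f"P{i:06d}" for i in range(n)])
    chroms = genome.chrom_lengths

    # --- covariates -------------------------------------------------------
    groups = list(config.ancestry_fractions)
    ancestry = rng.choice(groups, size=n, p=[config.ancestry_fractions[g] for g in groups])
    pc1 = rng.normal(0.0, 1.0, n) + np.where(ancestry == groups[0], 0.0, 2.5)
    pc2, pc3 = rng.normal(0.0, 1.0, n), rng.normal(0.0, 1.0, n)
    batch = rng.choice(["B1", "B2", "B3", "B4"], size=n)
    platform = rng.choice(["coreexome", "gsa"], size=n, p=[0.735, 0.265])
    phase = rng.choice(["OSC1", "OSC2"], size=n, p=[0.6, 0.4])
    sex = rng.choice(["male", "female"], size=n)
    age = rng.uniform(4.0, 18.0, n).round(1)
    respondent = rng.choice(["parent", "self"], size=n, p=[0.84, 0.16])
    covariates = pd.DataFrame(
        {"ancestry": ancestry, "PC1": pc1, "PC2": pc2, "PC3": pc3,
         "batch": batch, "platform": platform, "phase": phase},
        index=pd.Index(ids, name="participant_id"),
    )

    # --- true CNVs --------------------------------------------------------
    recs: list[tuple] = []  # (pid, chrom, start, end, type, origin)
    chrom_names = list(chroms)
    chrom_lens = np.array([chroms[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    counts = rng.poisson(config.cnv_rate, n)
    total = int(counts.sum())
    bg_pid = np.repeat(ids, counts)
    bg_chrom = rng.choice(chrom_names, size=total, p=chrom_p)
    lo, hi = np.log(config.size_range[0]), np.log(config.size_range[1])
    bg_len = np.exp(rng.uniform(lo, hi, total)).astype(np.int64)
    bg_type = np.where(rng.random(total) < 0.5, "DEL", "DUP")
    for pid, chrom, ln, ctype in zip(bg_pid, bg_chrom, bg_len, bg_type):
        L = chroms[chrom]
        ln = min(int(ln), int(0.8 * L))
        start = int(rng.integers(0, L - ln))
        recs.append((pid, chrom, start, start + ln, ctype, "background"))

    loci = config.polymorphic_loci or _default_polymorphic(genome, rng)
    for chrom, start, end, ctype, freq in loci:
        carriers = ids[rng.random(n) < freq]
        for pid in carriers:
            recs.append((pid, chrom, int(start), int(end), ctype, "polymorphic"))

    n_class = int(round(config.carrier_fraction_classified * n))
    class_ids = rng.choice(ids, size=n_class, replace=False)
    cat = genome.catalog
    # designated carriers split ~30/70 between clinically significant
    # (locus + significant genes) and susceptibility entries
    w = np.where(cat["kind"] == "susceptibility_gene", 0.7 / max(1, (cat["kind"] == "susceptibility_gene").sum()),
                 0.3 / max(1, (cat["kind"] != "susceptibility_gene").sum()))
    w = w / w.sum()
    for pid in class_ids:
        entry = cat.iloc[int(rng.choice(len(cat), p=w))]
        ctype = entry["required_type"] if entry["required_type"] in ("DEL", "DUP") else (
            "DEL" if rng.random() < 0.5 else "DUP"
        )
        s, e = int(entry["start"]), int(entry["end"])
        if entry["kind"] != "recurrent_locus":
            pad = int(rng.integers(5_000, 50_000))
            s, e = max(0, s - pad), min(chroms[entry["chrom"]], e + pad)
        recs.append((pid, entry["chrom"], s, e, ctype, "classified"))

    aneu_ids = ids[rng.random(n) < config.aneuploidy_rate]
    for pid in aneu_ids:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        L = chroms[chrom]
        ctype = "DUP" if rng.random() < 0.7 else "DEL"
        recs.append((pid, chrom, int(0.02 * L), int(0.97 * L), ctype, "aneuploidy"))

    true_cnvs = pd.DataFrame(recs, columns=["participant_id", "chrom", "start", "end", "type", "origin"])

    # --- caller emission --------------------------------------------------
    call_rows = []
    m = len(true_cnvs)
    starts = true_cnvs["start"].to_numpy()
    ends = true_cnvs["end"].to_numpy()
    lens = ends - starts
    for caller in CALLERS:
        sens = config.caller_sensitivity.get(caller, 0.9)
        detected = rng.random(m) < sens
        jitter_s = (rng.uniform(-1, 1, m) * config.breakpoint_jitter * lens).astype(np.int64)
        jitter_e = (rng.uniform(-1, 1, m) * config.breakpoint_jitter * lens).astype(np.int64)
        cs = np.maximum(0, starts + jitter_s)
        ce = np.maximum(cs + 1000, ends + jitter_e)
        sub = true_cnvs.loc[detected, ["participant_id", "chrom", "type"]].copy()
        sub["start"] = cs[detected]
        sub["end"] = ce[detected]
        sub["caller"] = caller
        call_rows.append(sub)
    caller_calls = (
        pd.concat(call_rows, ignore_index=True)[["participant_id", "chrom", "start", "end", "type", "caller"]]
        .sort_values(["participant_id", "chrom", "start", "end", "caller"], kind="stable")
        .reset_index(drop=True)
    )

    # --- phenotypes -------------------------------------------------------
    index = GeneIndex(genome.genes)
    causal_genes = genome.gene_sets[genome.causal_set]
    burden = pd.Series(0, index=ids, dtype=int)
    dels = true_cnvs.loc[(true_cnvs["type"] == "DEL") & (true_cnvs["origin"] == "background")]
    per_part: dict[str, set] = {}
    for row in dels.itertuples(index=False):
        hits = index.genes_hit(row.chrom, row.start, row.end) & causal_genes
        if hits:
            per_part.setdefault(row.participant_id, set()).update(hits)
    for pid, syms in per_part.items():
        burden[pid] = len(syms)

    is_carrier = pd.Series(np.isin(ids, class_ids).astype(int), index=ids)
    pheno = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    cov_effect = 0.05 * pc1 + 0.10 * (batch == "B2").astype(float)
    for trait in TRAITS:
        planted = config.planted_beta * burden.to_numpy() if trait in PLANTED_TRAITS else 0.0
        pheno[trait] = planted + cov_effect + rng.normal(0.0, config.noise_sd, n)

    log_or = np.log(config.planted_or)
    for dx, rate in DIAGNOSIS_RATES.items():
        alpha = np.log(rate / (1 - rate))
        eta = alpha + (log_or * is_carrier.to_numpy() if dx in PLANTED_DIAGNOSES else 0.0)
        pheno[f"dx_{dx}"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    pheno["stimulant_medication"] = np.where(
        pheno["dx_adhd"] == 1, (rng.random(n) < 0.7), (rng.random(n) < 0.01)
    ).astype(int)
    pheno["age"] = age
    pheno["sex"] = sex
    pheno["gender"] = sex
    pheno["respondent"] = respondent

    truth = {
        "planted_or": config.planted_or,
        "planted_beta": config.planted_beta,
        "planted_traits": PLANTED_TRAITS,
        "planted_diagnoses": PLANTED_DIAGNOSES,
        "classified_carriers": sorted(class_ids.tolist()),
        "causal_burden": burden,
        "polymorphic_loci": [tuple(l) for l in loci],
        "n_aneuploidies": int(len(aneu_ids)),
    }
    return Cohort(caller_calls=caller_calls, true_cnvs=true_cnvs, phenotypes=pheno,
                  covariates=covariates, truth=truth)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-derived) plain dict."""
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ConfigurationError(f"unknown simulation option(s): {sorted(unknown)}")
    if "size_range" in d:
        d = dict(d)
        d["size_range"] = tuple(d["size_range"])
    if "polymorphic_loci" in d and d["polymorphic_loci"] is not None:
        d = dict(d)
        d["polymorphic_loci"] = tuple(tuple(x) for x in d["polymorphic_loci"])
    return SimConfig(**d)
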