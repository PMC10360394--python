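# Methods

This note documents the models, conventions and design choices behind
`cnvcohort`, in the order data flows through the pipeline.

## Coordinates and formats

All intervals are 0-based half-open internally. BED is read and written
as-is; GFF3 gene features are converted from 1-based inclusive on ingest.
Gene-sets use GMT; catalogs, call tables, phenotypes and covariates are
plain TSV. Only gene-level features are used for overlap: at array
resolution (every call ≥ 10 kb) exon-level intersection adds noise rather
than precision, so "a CNV impacts a gene" means ≥ 1 bp of overlap with the
gene body.

## Consensus calling

Array CNV callers disagree on breakpoints, so equality of calls is defined
by reciprocal overlap: RO(a,b) = min(|a∩b|/|a|, |a∩b|/|b|), zero across
chromosomes. Within one participant, chromosome and CNV type, calls are
clustered by single linkage at RO ≥ 0.5 (configurable); a cluster becomes
one consensus event with **union** coordinates and the union of supporting
callers, retained when ≥ 2 distinct callers support it. Union rather than
intersection coordinates were chosen because that is how multi-caller
pipelines report a single supported event; intersection is available via
`ConsensusPolicy(coordinates="intersection")` (an intersection that vanishes
along a single-linkage chain drops the event). Merging is order-independent:
permuting input rows yields the identical consensus set, which the tests
check against a brute-force all-pairs connected-components oracle.

The size floor (10 kb, boundary inclusive) reflects the resolution limit of
genotyping-array CNV detection.

## Cohort frequency and rarity strata

No public convention pins down "the frequency of a CNV" exactly; we use the
field-standard choice: single-linkage RO ≥ 0.5 clustering **across**
participants (same chromosome and type), frequency = distinct carriers in
the cluster / cohort size. Strata: rare f < 0.5%, less-rare 1% ≤ f ≤ 5%,
common f > 5% (excluded from burden because common CNVs are few and behave
differently). The 0.5–1% gap between the strata definitions is folded into
"rare" — the conservative choice that keeps the strata exhaustive — and the
affected calls are listed in a warning so the decision is auditable.

## Tier classification

Classification is a data-driven catalog engine rather than a hard-coded
rule set, so any ACMG-style locus/gene list can be supplied as TSV. Entry
kinds: `recurrent_locus` (matched by RO ≥ 0.5 against the locus, default
configurable per entry), `significant_gene` and `susceptibility_gene`
(matched by ≥ 1 bp overlap, by coordinates or by symbol through the gene
annotation). Each entry carries `required_type` (DEL/DUP/any) to make
type-specific evidence explicit. Precedence is total and deterministic:
aneuploidy > recurrent > non-recurrent significant > susceptibility >
unclassified; classification is idempotent.

Aneuploidy is a call covering ≥ 90% of a chromosome — array calls rarely
span an assembly end to end — labelled karyotype-style (trisomy_21, 45,X,
47,XXX, XYY) using participant sex where available. Sex-chromosome copy
state enters only here; frequency logic treats X/Y like autosomes.

Participants carrying both a significant and a susceptibility CNV are
grouped under "significant" for the mutually exclusive three-way carrier
split; the per-call tiers are retained so the alternative grouping can be
derived.

The shipped `catalog_fixture.tsv` lists recurrent loci and genes recurrently
implicated in neurodevelopmental disorders with **synthetic** placeholder
coordinates on a toy assembly; it exists for tests and demos, not for real
analyses.

## Phenotype harmonization

Raw trait totals are standardized to T-scores (z × 10 + 50) within gender ×
study phase, because instruments differ by phase; groups need ≥ 2 scored
participants and nonzero variance (zero variance is a hard error, not a
silent NaN). "High trait" = score at or above the empirical 90th percentile
of scored participants, ties at the cutoff all flagged; higher is worse for
every measure including stop-signal reaction time (longer = worse
inhibition) and reaction-time variability. Missing scores exclude a
participant from that trait only. Composites: any_diagnosis = OR over
diagnosis flags; any_dx_or_high = any_diagnosis OR any_high_trait.
Disorders with fewer than 20 cohort cases are dropped from per-disorder
models but kept in composites.

## Association models

* 2×2 odds ratios: OR = ad/bc, Woolf CI exp(log OR ± z·√(1/a+1/b+1/c+1/d)).
  A zero cell triggers the Haldane–Anscombe 0.5 correction on all four
  cells, flagged in the result. Model-based ORs are available through
  `disorder_logistic`.
* Chi-square enrichment: Pearson, df = 1, no continuity correction by
  default (Yates behind a flag).
* Per-disorder logistic and carrier trait regressions use the "neither"
  group as reference; trait models skip groups with < 10 scored carriers;
  stop-signal outcomes add the stimulant-medication covariate. Perfect
  separation is flagged, never reported as a coefficient.
* Multiple disorders are tested without family-wise adjustment, matching
  the per-disorder presentation convention; this is noted in the output.

## Burden machinery

Burden matrices count **distinct** genes per participant per (CNV type ×
stratum) — a gene hit by two calls counts once, reading "gene counts per
participant" as per-participant totals. Total lengths sum the rare +
less-rare consensus calls. The global-burden covariate is the count of
distinct genes hit by either CNV type.

Gene-set models regress the trait on the set-specific count plus the global
count plus covariates (ancestry PCs 1–3, genotyping batch, platform;
categorical covariates expand to dummies, levels absent from a subset are
dropped). BH-FDR runs within (trait × type × stratum) families across the
set catalog, matching per-panel presentation; a single pooled family is a
one-line change at the call site. Ancestry strata are analyzed separately
(the two strata are heavily unbalanced); the X-chromosome analysis repeats
the gene-set models over X-linked genes only.

Locus tests take the genes of the sets passing (p < 0.05, FDR < 0.2) for a
trait, keep genes with ≥ 3 carriers, and regress the trait on the binary
carrier indicator (rare-variant setting: dosage adds nothing at a handful
of carriers) with the same covariates as the gene-set tests. Family-wise
error control uses max-T permutation: trait and indicators are residualized
on the covariates (Frisch–Waugh), the outcome residuals are permuted
(default 10 000 permutations, seeded), and the null distribution of the
maximum |t| across genes gives adjusted p-values
(1 + #{max ≥ observed}) / (B + 1). This is assumption-light for sparse
indicators, which is why it was preferred over Bonferroni-type corrections.

Sex-difference tests are likelihood-ratio tests (χ², df = 1) comparing
covariate-only vs covariate+sex OLS models for four outcomes: total
deletion/duplication length and gene count. Covariates: PCs 1–3, batch
(plate) and study phase. Linear, not rank-based, models are used for all
trait outcomes; robust standard errors can be obtained by refitting the
returned model spec.

## Synthetic cohort generator

The generator emulates the structure of a two-ancestry (~80/20) community
genotyping cohort. Defaults are the study conditions, not tuning knobs:
7100 participants; Poisson(3) background CNVs per participant with
log-uniform sizes in [10 kb, 5 Mb] (the floor matches the consensus
pipeline's resolution; the cap keeps events sub-chromosomal); three
polymorphic loci at 0.2% / 3% / 12% frequency covering the strata; 4%
designated classified-CNV carriers split ~30/70 significant:susceptibility;
0.1% whole-chromosome aneuploidies; three pseudo-callers with sensitivities
0.95/0.90/0.85 and ±2% breakpoint jitter (per-caller sensitivities are free
calibration parameters — no published values exist — chosen so two-of-three
consensus recovers most true events); diagnosis base rates spanning 0.03%
to 9% so the n < 20 exclusion is exercised at full cohort size; planted
carrier odds ratio 3 on the ADHD and anxiety diagnoses; planted trait
effect 0.15 raw-score units per deleted causal-set gene on the ADHD-trait
measures (raw residual SD 1); small fixed PC1 and batch effects so
covariate adjustment is exercised. The synthetic genome is a 1.5 Gb toy
assembly (4 autosomes + X) — large enough that background CNVs only rarely
hit catalog entries by chance, keeping total classified-carrier prevalence
near the 4% target; the default 400 genes and 10 gene-sets (1 causal, 1
organ-system-style negative control disjoint from it, 8 neutral) are a
scaled-down stand-in for a full annotation. Everything is a deterministic function of the config
including its seed.

What the generator does **not** emulate: array intensity data (LRR/BAF),
linkage disequilibrium and haplotype structure, pedigrees/relatedness,
caller-specific error modes (it uses independent thinning + jitter), or
realistic gene length/density. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the declared
generative model — not that the pipeline is robust to real-array artifacts
such as waviness, batch-correlated sensitivity or mosaic events.

## Problem sizes in tests and the acceptance script

Planted-effect recovery is checked as 95% CI coverage in ≥ 90 of 100
replicates at n = 5000, generated directly from the relevant model (counts +
trait; carrier + diagnosis) so the check isolates the estimator; the full
simulate→consensus→classify→associate chain is additionally exercised at
n = 5000 in single-replicate tests and in the acceptance script. Null
calibration uses 500 replicates (type-I error within ~3 binomial SDs of
0.05; permutation FWER ≤ 0.07 with 250 permutations per replicate). Oracle
equivalence (clustering, burden counts, BH-FDR, OLS) runs on ≤ 20-call /
≤ 10-test / ≤ 50-sample instances at 10⁻⁸ or exact. The pipeline's
end-to-end determinism is verified byte-for-byte on written bundles.

## Known limitations

* Frequency clustering is single-linkage: a chain of partially overlapping
  calls can join one cluster even when its extremes overlap weakly.
* The catalog fixture's coordinates are synthetic; real analyses must
  supply a real catalog (and a real gene annotation).
* The observed carrier odds ratio in end-to-end synthetic runs is diluted
  below the planted value because background CNVs create carriers with no
  planted diagnosis risk — an intended property of the generative model
  (incidental findings), worth remembering when reading recovery numbers.
* T-score standardization assumes each gender × phase cell is large; tiny
  cells raise errors by design rather than producing unstable scores.
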