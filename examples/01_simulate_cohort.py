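"""Generate a small synthetic cohort and look at its structure.

The generator plants known effects (a carrier diagnosis odds ratio, a
per-gene trait effect in a causal gene-set) so every downstream analysis can
be validated against ground truth.
"""

from cnvcohort import SimConfig, simulate_cohort, simulate_genome

config = SimConfig(n_participants=500, n_genes=120, seed=1)
genome = simulate_genome(config)
cohort = simulate_cohort(config, genome)

print(f"genes: {len(genome.genes)} on chromosomes {sorted(set(genome.genes.chrom))}")
print(f"gene-sets: {list(genome.gene_sets)} (causal = {genome.causal_set!r})")
print(f"catalog entries: {genome.catalog['kind'].value_counts().to_dict()}")
print(f"true CNVs: {len(cohort.true_cnvs)} "
      f"({cohort.true_cnvs['origin'].value_counts().to_dict()})")
print(f"per-caller call rows: {len(cohort.caller_calls)}")
print(f"designated classified carriers: {len(cohort.truth['classified_carriers'])} "
      f"({100 * len(cohort.truth['classified_carriers']) / config.n_participants:.1f}% of cohort)")
# The three callers each miss a fraction of true events (sensitivity < 1), so
# the per-caller row count is below 3x the number of true CNVs; the
# two-of-three consensus downstream recovers most of them.
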