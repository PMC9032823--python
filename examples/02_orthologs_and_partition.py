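"""Build an ortholog table by bidirectional best hits and partition it.

Runs all-vs-all Smith–Waterman between four simulated genomes, keeps
reciprocal best hits with bit score >= 60, assembles gene families
anchored on a reference genome, and counts core / accessory / singleton
families.  Because the genomes are simulated, the recovered partition can
be compared against the generator's ground truth.
"""

from panbbh import SimConfig, simulate_genome_set, build_table, partition

config = SimConfig(
    n_genomes=4,
    n_core=12,
    accessory_spectrum=((2, 4), (3, 3)),
    n_singletons_per_genome=2,
    protein_len=100,
    aa_divergence=0.02,
    nt_divergence=0.02,
    seed=5,
)
genomes, truth = simulate_genome_set(config)

reference = list(genomes)[0]
table = build_table(genomes, reference=reference)
counts = partition(table)
expected = truth.counts()

print(f"reference genome: {reference}")
print(f"recovered: pan={counts.pan} core={counts.core} "
      f"accessory={counts.accessory} singleton={counts.singleton}")
print(f"designed:  pan={expected.pan} core={expected.core} "
      f"accessory={expected.accessory} singleton={expected.singleton}")
pc, pa, ps = counts.percentages()
print(f"\ncore/accessory/singleton shares: {pc}% / {pa}% / {ps}% of the pangenome")
print("(at 2% amino-acid divergence, BBH orthology recovers the design exactly)")
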