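"""Build a toy reference catalog and simulate one oxidized small-RNA library.

Prints the planted class composition: a 21 nt siRNA class, a broad 23-29 nt
piRNA population (TE-, cluster- and genic-3'UTR-derived), miRNA and rRNA
carry-over, and genotype-stable normalization loci.
"""

from pirna_soma import synthetic_data as sim

catalog = sim.build_toy_references(seed=7)
config = sim.SimConfig(seed=7, n_reads=20_000)
reads, manifest = sim.simulate_library(config, "control", catalog)

print(f"genome: {catalog.genome.total_length():,} bp, "
      f"{len(catalog.te_consensus)} TE families, "
      f"{len(catalog.clusters)} piRNA clusters, "
      f"{len(catalog.gene_regions)} coding genes")
print(f"simulated {len(reads):,} reads\n")
print(manifest.class_counts().to_string())
print("\nEach read carries a 3' adapter and per-base errors; the manifest"
      "\nrecords its planted class, source feature, strand and first base.")
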