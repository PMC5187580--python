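"""Preprocess a library and reproduce the compartment pie-chart numbers.

Reads are adapter-trimmed, rRNA-filtered and size-selected, then genome-
aligning reads are classified against the compartment databases in priority
order (sno/tRNA -> miRNA -> TE -> exon -> intergenic). The 23-29 nt window
isolates the piRNA population; about half of it is TE-mapping.
"""

from pirna_soma import synthetic_data as sim
from pirna_soma.compartments import assign_compartments, composition_summary
from pirna_soma.preprocess import preprocess_library
from pirna_soma.signatures import size_profile

catalog = sim.build_toy_references(seed=7)
config = sim.SimConfig(seed=7, n_reads=20_000)
reads, _ = sim.simulate_library(config, "control", catalog)

clean, stages = preprocess_library(reads, config.adapter, catalog.rrna)
for s in stages:
    print(f"{s['stage']:>14}: {s['input']:>6} in -> {s['kept']:>6} kept")

assignments, _ = assign_compartments(clean, catalog.genome,
                                     catalog.compartment_dbs())
print("\n23-29 nt (piRNA) compartment composition:")
print(composition_summary(assignments, size_window=(23, 29))
      .to_string(index=False))

profile = size_profile(clean, catalog.mirna)
print("\nread-length profile (miRNA excluded), 18-32 nt:")
print(profile.loc[18:32].to_string())
print("\nThe 21 nt spike is the siRNA class; the broad 23-29 nt peak is the"
      "\npiRNA population, of which ~49% maps to transposons.")
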