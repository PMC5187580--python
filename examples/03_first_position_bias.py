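"""Measure the 1U bias of TE-antisense piRNAs.

TE-mapping 23-29 nt reads are split sense/antisense by their best consensus
hit; antisense reads are trimmed to a uniform 5'-anchored 23 nt and turned
into a position frequency matrix. Primary piRNAs begin with uracil
(T in cDNA), so position 1 carries most of the information content.
"""

from pirna_soma import synthetic_data as sim
from pirna_soma.preprocess import preprocess_library
from pirna_soma.signatures import first_position_bias, split_te_reads

catalog = sim.build_toy_references(seed=7)
config = sim.SimConfig(seed=7, n_reads=20_000, first_u_prob=0.9)
reads, _ = sim.simulate_library(config, "control", catalog)
clean, _ = preprocess_library(reads, config.adapter, catalog.rrna)

pirna = [r for r in clean if 23 <= len(r.sequence) <= 29]
sense, antisense = split_te_reads(pirna, catalog.te_consensus)
frac = len(antisense) / (len(sense) + len(antisense))
print(f"TE-mapping 23-29 nt reads: {len(sense)} sense, {len(antisense)} "
      f"antisense ({100 * frac:.1f}% antisense; planted 80%)")

pfm = first_position_bias(antisense, size_window=(23, 29), trim_to=23)
print(f"\nPFM over {pfm.n_reads} reads; position-1 frequencies:")
for base, f in zip("ACGT", pfm.freqs[:, 0]):
    print(f"  {base}: {f:.3f}")
print(f"position-1 information content: {pfm.information[0]:.3f} bits "
      f"(positions 2+: max {pfm.information[1:].max():.4f} bits)")
print("\nThe position-1 T frequency estimates the planted 1U probability"
      "\n(0.9 here); downstream positions are near-uniform.")
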