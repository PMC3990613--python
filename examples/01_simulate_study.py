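"""Generate a complete synthetic heterosis study and inspect its ground truth.

Builds two diverged parental references, an inheritance mode per gene, 21 tag
libraries (4 leaf + 2 root + 1 meristem replicates for each of P1, P2 and the
F1 hybrid), a 131-marker map, 266 RILs and 6 environments of phenotypes.
"""

from hetqtl import simulate as sim

ref = sim.generate_reference(n_genes=240, n_chromosomes=12, divergence=0.02,
                             signature_snp_fraction=0.25, seed=1)
truth = sim.generate_inheritance_truth(ref.genes["gene_id"].to_list(), seed=2)
counts, meta, gene_of_sig = sim.simulate_tag_libraries(ref, truth, seed=3)
marker_map = sim.generate_marker_map(seed=4)
genotypes = sim.simulate_ril_genotypes(marker_map, n_lines=266, seed=5)

print(f"genes: {len(ref.genes)} on {ref.genes['chrom'].nunique()} chromosomes")
print(f"signatures differing between parents: {ref.signatures()['differs'].sum()}")
print(f"libraries: {len(meta)}  (tags per library ~ {int(meta['total'].mean()):,})")
print(f"markers: {len(marker_map)}  lines: {len(genotypes)}")
print("\ninheritance modes planted (each maps to one expression pattern):")
print(truth.groupby(["mode", "pattern"]).size().to_string())
# Each gene carries true mean abundances (TPM) for P1, P2 and F1; downstream
# stages must recover the pattern column from the simulated tag counts alone.
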