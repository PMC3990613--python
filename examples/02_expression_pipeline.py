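"""Tag-count processing: TPM normalization, filters, matching, summaries.

Numbers printed: per-library-group totals, distinct signatures, how many pass
the reliability (seen in >= 2 libraries) and significance (>= 4 TPM
somewhere) filters, abundance-bin counts, and the percentage of expressed
signatures matching each parental reference.
"""

from hetqtl import expression as expr, simulate as sim

ref = sim.generate_reference(n_genes=120, n_chromosomes=6, seed=1)
truth = sim.generate_inheritance_truth(ref.genes["gene_id"].to_list(), seed=2)
counts, meta, gene_of_sig = sim.simulate_tag_libraries(ref, truth, seed=3)

tpm = expr.normalize_tpm(counts, meta)
flags = expr.apply_filters(counts, tpm)
status = expr.match_to_references(
    list(counts.index), ref.transcripts["P1"], ref.transcripts["P2"]
)
summary = expr.library_summary(
    counts, meta, gene_of_signature=gene_of_sig, match_status=status
)

print(f"column sums after normalization: {tpm.sum(axis=0).round(1).unique()}")
print(f"reliable AND significant signatures: "
      f"{(flags['reliable'] & flags['significant']).sum()} of {len(flags)}")
print("\nper genotype x tissue summary (replicate means):")
cols = ["total_reads", "distinct", "reliable_and_significant",
        "distinct_genes", "pct_match_p1", "pct_match_p2"]
print(summary[cols].round(1).to_string())
# A signature spanning a parental SNP matches exactly one genome, so the
# match percentages sit below 100% by construction.
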