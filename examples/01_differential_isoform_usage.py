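"""Differential isoform usage (DIU) on a simulated paired infection study.

Simulates 60 donors x {control, infected} with 20% of genes carrying a
planted usage shift of 0.15, converts TPMs to proportions, and runs the
multivariate Welch-type test per gene with BH correction.
"""

import isoshift as iso

config = iso.SimulationConfig(seed=42, n_genes=150, frac_diu=0.2, usage_effect=0.15)
quant, sheet, truth = iso.simulate_isoform_matrix(config)

props = iso.compute_proportions(quant, sheet, min_gene_tpm=1.0)
table = iso.diu_table(props, fdr=0.01)

n_planted = int(truth.genes["is_diu"].sum())
hits = table[table["significant"]]
recovered = hits.merge(truth.genes, on="gene_id")["is_diu"].sum()

print(f"genes tested:        {len(table)}")
print(f"planted DIU genes:   {n_planted}")
print(f"significant (q<=1%): {len(hits)}  ({recovered} of them planted)")
print(f"mean effect size among hits: {hits['effect_size'].mean():.3f}")
print(f"genes switching dominant isoform: {int(table['switch_flag'].sum())}")

# Shannon-diversity change: positive values mean more isoform diversity
# after infection; the permutation null tells us what fraction to expect
# by chance (about one half).
per_gene, summary = iso.delta_shannon(props, n_permutations=300, seed=42)
print(f"fraction of genes with increased diversity: {summary['frac_positive']:.2f} "
      f"(null ~{summary['null_frac_positive'].mean():.2f})")

# The effect size is the maximum change in any isoform's relative usage; a
# value near the planted 0.15 for hits and ~0 for the rest confirms the test
# is picking up the planted usage shifts rather than expression changes.
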