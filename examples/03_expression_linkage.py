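"""Linking delta-PSI to expression fold changes across donors.

Simulates skipped-exon events whose per-donor shifts drive log2 fold changes
at a target Spearman correlation of 0.6, then tests whether the observed
per-gene correlation distribution separates from a permuted null.
"""

import isoshift as iso

config = iso.SimulationConfig(seed=3, n_events_per_category={"SE": 150},
                              frac_events_shifted=0.6, rho_dpsi_fc=0.6)
events, annotations, sheet, truth = iso.simulate_event_counts(config)
expr = iso.simulate_expression_changes(config, truth)

psi_records, calls = iso.call_events(events, sheet)
res = iso.gene_level_link(
    psi_records, annotations, expr, n_permutations=100, seed=3,
    significant_events=set(calls.loc[calls["significant"], "event_id"]))

print(f"genes linked:            {len(res.table)}")
print(f"mean observed Spearman:  {res.table['spearman_rho'].mean():.2f}")
print(f"permuted-null mean (sd): {res.null_rhos.mean():.3f} ({res.null_rhos.std():.3f})")
print(f"KS observed vs null:     D={res.ks_stat:.2f}, p={res.ks_p:.1e}")
print(f"fraction rho > 0 among significant-event genes: {res.frac_positive:.2f}")
# A KS p-value far below 0.005 says the delta-PSI / fold-change coupling is
# genuine, not an artifact of the correlation estimator: permuting which
# donor's fold change goes with which delta-PSI destroys it.

# Genome-wide trans-factor scan: which genes' fold changes track the global
# per-donor SE shift?  On linked synthetic data the planted drivers surface.
scan = iso.trans_factor_scan(expr, psi_records, annotations, "SE",
                             significant_events=set(
                                 calls.loc[calls["significant"], "event_id"]))
print(f"scan candidates at FDR<=1%: {int(scan['candidate'].sum())} of {len(scan)}")
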