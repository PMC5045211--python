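"""miRNA seed-site enrichment in shortened 3'UTR extensions.

Simulates tandem-UTR core/extension sequences in two GC strata with one
miRNA's seed sites planted at 3-fold density in the extensions of
significantly shortened UTRs, then recovers it against a length- and
GC-matched background.
"""

import pandas as pd

import isoshift as iso
from isoshift.simulate import default_mirna_set

config = iso.SimulationConfig(seed=9, planted_fold=3.0, utr_ext_len=3000,
                              n_events_per_category={"TandemUTR": 600})
# significance classes normally come from call_events; built directly here
calls = pd.DataFrame({"event_id": [f"TandemUTR_{j:04d}" for j in range(600)],
                      "significant": [j < 200 for j in range(600)]})
regions, truth = iso.simulate_utr_sequences(config, calls)
mirnas = default_mirna_set(config)

# Class-level density: is the extension of shortened UTRs richer in seed
# sites than unchanged ones, and is the core (control region) flat?
per_region, tests = iso.density_by_class(regions, mirnas)
print(f"extension density comparison p = {tests['ext']['p_value']:.1e}")
print(f"core      density comparison p = {tests['core']['p_value']:.2f} (control)")

enrich = iso.mirna_enrichment(regions, mirnas, n_resamples=1000, seed=9)
print("\nper-miRNA enrichment (fold vs GC/length-matched background):")
for r in enrich.itertuples(index=False):
    mark = " <== planted" if r.mirna_id in config.planted_mirnas else ""
    print(f"  {r.mirna_id}: fold={r.fold:.2f} q={r.q_value:.3f} "
          f"significant={r.significant}{mark}")
# Only the planted miRNA should clear FDR <= 10% with fold >= 1.5; the
# composition-matched null keeps GC-driven density differences from
# masquerading as enrichment.
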