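"""Validating 3'UTR shortening with 3'-end sequencing.

Simulates 3'-end read positions around the proximal and distal polyA sites
of tandem UTRs for a 6-donor subset, then (i) builds metagene profiles and
(ii) recomputes PSI directly from site-assigned read counts.
"""

import numpy as np

import isoshift as iso

config = iso.SimulationConfig(seed=21, n_events_per_category={"TandemUTR": 200},
                              frac_events_shifted=0.5, depth_threeprime=500.0)
events, annotations, sheet, truth = iso.simulate_event_counts(config)
reads, sites = iso.simulate_threeprime_reads(config, truth)

# classes from the RNA-seq-style calls
_, calls = iso.call_events(events, sheet)
shortened = calls["significant"] & (calls["mean_delta_psi"] < 0)
cls = dict(zip(calls["event_id"],
               np.where(shortened, "shortened_significant", "unchanged")))
sites["sig_class"] = sites["event_id"].map(cls)

profiles, _ = iso.metagene(reads, sites, window=200, sheet=sheet)
share = (profiles.groupby(["sig_class", "condition", "site_type"])["density"]
         .sum().unstack("site_type"))
print("in-window read share by class/condition (proximal vs distal site):")
print(share.round(3).to_string())
# For shortened UTRs the proximal share rises after infection while
# unchanged UTRs keep a stable profile.

psi3, comparison = iso.psi_from_threeprime(reads, sites, sheet, assignment_radius=100)
print(f"\ndelta-PSI from 3'-end counts, shortened vs unchanged: "
      f"medians {comparison['median_delta_significant']:.2f} vs "
      f"{comparison['median_delta_unchanged']:.2f}, MWU p={comparison['p_value']:.1e}")
print(f"unassigned read fraction: {comparison['unassigned_fraction']:.3f}")
# A negative median for the shortened class reproduces the RNA-seq calls in
# an independent assay that reads transcript 3' ends directly.
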