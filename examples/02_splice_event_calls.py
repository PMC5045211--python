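"""Event-level PSI shifts: estimation, Bayes factors, and directional calls.

Simulates inclusion/exclusion read counts for five RNA-processing categories
(AFE, ALE, RI, SE, TandemUTR).  Shifted tandem UTRs are planted 95% negative
(3'UTR shortening) and skipped exons 80% positive (more inclusion), matching
the directional structure this pipeline is designed to detect.
"""

import isoshift as iso

config = iso.SimulationConfig(
    seed=7,
    n_events_per_category={"AFE": 60, "ALE": 60, "RI": 60, "SE": 100, "TandemUTR": 100},
    frac_events_shifted=0.3,
    delta_psi_magnitude=0.2,
)
events, annotations, sheet, truth = iso.simulate_event_counts(config)

# Per donor: PSI in each condition plus a Bayes factor comparing the two.
# An event is called significant when BF >= 5 in >= 10% of donors AND
# |mean delta-PSI| >= 0.05.
psi_records, calls = iso.call_events(events, sheet)

print(f"{len(calls)} events, {int(calls['significant'].sum())} called significant\n")
print(f"{'category':<10} {'n_sig':>5} {'frac_negative':>14} {'p_one_sample':>13}")
for cat in sorted(calls["category"].unique()):
    r = iso.directional_shift(calls, cat)
    print(f"{cat:<10} {r.n_significant:>5} {r.frac_negative:>14.2f} {r.p_one_sample:>13.2e}")

# TandemUTR should show frac_negative near 0.95 (pervasive shortening) and
# SE near 0.2 (shift towards inclusion); categories without planted
# directionality sit near 0.5 with a non-significant one-sample test.

_, cv_tests = iso.dispersion_summary(psi_records, calls)
se = cv_tests["SE"]
print(f"\nSE delta-PSI coefficient of variation: significant events "
      f"{se['median_cv_significant']:.2f} vs others {se['median_cv_other']:.2f} "
      f"(MWU p={se['p_value']:.1e})")
# Significant events vary less across donors: the calling rule selects
# changes that are consistent across individuals.
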