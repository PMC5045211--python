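"""One-shot end-to-end run on the bundled synthetic study.

Generates every input with known ground truth, runs all analysis stages and
prints the summary the pipeline writes to summary.json.
"""

import json

import isoshift as iso

config = iso.RunConfig(out_dir="scratch/example_run", seed=1,
                       simulation=iso.SimulationConfig(seed=1))
summary = iso.run_pipeline(config)

print(json.dumps({k: v for k, v in summary.items() if k != "per_category"},
                 indent=2, default=str))
print("\nper-category directional shifts:")
for cat, s in summary["per_category"].items():
    print(f"  {cat:<10} n_sig={s['n_significant']:>3}  "
          f"frac_negative={s['frac_negative']:.2f}  p={s['p_one_sample']:.1e}")
# The TandemUTR row should show frac_negative near 0.95 (pervasive 3'UTR
# shortening) and SE near 0.2 (shift towards exon inclusion); stage tables
# and truth.json land in the output directory for inspection.
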