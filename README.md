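# isoshift

Analysis toolkit for **infection-induced isoform dynamics** in paired
(donor × condition) transcriptome designs — the setting where the same
individuals are profiled before and after an immune stimulus and the
question is how RNA *processing*, not just expression level, responds.

It is written for computational biologists studying bulk RNA-seq of immune
cells (e.g. macrophages infected with intracellular bacteria), and covers:

* **Differential isoform usage (DIU).** Isoform proportions
  `p_k = TPM_k / Σ_j TPM_j` per gene and sample; per-gene test of
  `H0: μ_ctl = μ_inf` on the proportion vector via a multivariate
  generalization of Welch's t-test (multivariate Behrens–Fisher). With one
  component dropped to remove the sum-to-one constraint,

  `T² = d′ W⁻¹ d`,  `W = S_ctl/n_ctl + S_inf/n_inf`,

  with p-values from the Krishnamoorthy–Yu F-approximation (exactly the
  two-sided Welch t-test when K = 2) and a label-permutation mode as oracle.
  Effect size = max over isoforms of |mean proportion difference|; isoform
  diversity via Shannon entropy `H = −Σ p_k ln p_k` with a paired
  permutation null for ΔH; dominant-isoform switching; Fisher's exact test
  for DIU × differential-expression overlap.

* **Event-level Ψ (percent spliced in).** For AFE / ALE / RI / SE /
  TandemUTR events, length-adjusted posterior-mean
  `Ψ = (a+1)/(a+b+2)` with `a = inc/ℓ_inc`, `b = exc/ℓ_exc`; per-donor
  Bayes factor `BF = B(i₁+1,e₁+1)·B(i₂+1,e₂+1) / B(i₁+i₂+1,e₁+e₂+1)`
  (independent-Ψ vs shared-Ψ, uniform priors, log-space); the calling rule
  *BF ≥ 5 in ≥ 10 % of donors AND |mean ΔΨ| ≥ 0.05*; directional-shift
  statistics per category (fraction negative, Mann–Whitney, one-sample t),
  ΔΨ dispersion, and per-donor global shifts with cross-category Pearson r.

* **ΔΨ–expression linkage.** Per-gene Spearman correlation across donors
  between ΔΨ and log₂ fold change, with a permuted-correspondence null and
  a two-sample KS test; per-donor global coupling; a genome-wide
  trans-factor scan (BH FDR ≤ 1 %, two-condition intersection).

* **miRNA seed-site enrichment.** TargetScan-style 8mer / 7mer-m8 / 7mer-1A
  counting on UTR sense strands; site-density comparison of shortened vs
  unchanged tandem-UTR extensions (cores as control); per-miRNA enrichment
  against a background resampled to match length (±20 %) and GC (±0.02),
  empirical `p = (1+#{null ≥ obs})/(N+1)`, significant at BH q ≤ 10 % and
  fold ≥ 1.5.

* **3′-end sequencing validation.** Metagene read-density profiles around
  proximal/distal polyadenylation sites (per-event equal weighting) and Ψ
  recomputed from site-assigned 3′-end counts.

* **Synthetic data with ground truth.** A generator emulating the full
  study design (60 paired donors; Dirichlet isoform usage with planted
  shifts; Poisson/Binomial event counts with planted ΔΨ, 95 % negative for
  TandemUTR; planted seed-site enrichment; ΔΨ-correlated fold changes;
  3′-end reads), byte-reproducible from a single seed.

## Worked example

```python
import isoshift as iso

config = iso.SimulationConfig(seed=42, n_genes=150, frac_diu=0.2, usage_effect=0.15)
quant, sheet, truth = iso.simulate_isoform_matrix(config)
props = iso.compute_proportions(quant, sheet, min_gene_tpm=1.0)
table = iso.diu_table(props, fdr=0.01)
```

Running `python examples/01_differential_isoform_usage.py` (which adds the
recovery bookkeeping) prints:

```
genes tested:        150
planted DIU genes:   30
significant (q<=1%): 30  (30 of them planted)
mean effect size among hits: 0.161
genes switching dominant isoform: 2
fraction of genes with increased diversity: 0.60 (null ~0.50)
```

All 30 genes with a planted usage shift of 0.15 are recovered at FDR ≤ 1 %
with no false positives; the mean effect size among hits (0.161) estimates
the planted 0.15, and 60 % of genes show increased isoform diversity against
a permutation null centred at 0.50.

The other `examples/*.py` scripts walk through event calling and
directionality (TandemUTR `frac_negative ≈ 0.97`), ΔΨ–expression linkage
(KS p ≈ 4e-45 at planted ρ = 0.6), miRNA enrichment (planted miRNA at
fold 3.25, q = 0.008; all others near fold 1), and 3′-end validation
(shortened class median ΔΨ −0.19 vs −0.00 for unchanged).

## Acceptance script

`scripts/acceptance.py` regenerates the bundled synthetic study from scratch
and runs the complete pipeline — simulation, DIU, event calls and
directional shifts, linkage, miRNA enrichment, 3′-end validation — with all
randomness keyed to `--seed`, then writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Stage tables, the ground truth and a provenance-stamped `summary.json` land
under `scratch/acceptance_run/`.
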