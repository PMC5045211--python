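# Methods

This note documents the statistical models implemented in `isoshift`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Differential isoform usage (DIU)

**Proportions.** Isoform proportions are `p_k = TPM_k / Σ_j TPM_j` per gene
and sample. Gene-samples below an expression floor (`min_gene_tpm`, default
1 TPM) are masked rather than zero-filled, because proportions of an
unexpressed gene are noise; genes masked in more than 20 % of samples in
either condition are excluded from testing, as are single-isoform genes
(reason codes are reported). The floor and the 20 % rule are this package's
choices, made to stabilize the group covariance estimates.

**Test.** The per-gene null is equality of mean proportion vectors across
conditions with *unequal group covariances* — the multivariate
Behrens–Fisher problem. The last proportion component (isoform-id order) is
dropped to remove the sum-to-one singularity; the statistic is
`T² = d′W⁻¹d` with `W = S₁/n₁ + S₂/n₂` and a ridge of
`1e-8 · trace(W)/(K−1)` on the diagonal purely for numerical invertibility.
P-values use the Krishnamoorthy–Yu (2004) F-approximation: `T²·(ν−p+1)/(νp)
~ F(p, ν−p+1)` with

```
ν = (p + p²) / Σ_i [tr((S̃ᵢW⁻¹)²) + tr(S̃ᵢW⁻¹)²] / (nᵢ−1),  S̃ᵢ = Sᵢ/nᵢ.
```

For K = 2 this reduces *exactly* to the two-sided Welch t-test with
Satterthwaite degrees of freedom (verified to 1e-6 in tests). A
condition-label permutation p-value (`method="permutation"`) serves as the
exact-mode fallback and is the reference implementation the approximation is
tested against (rank agreement > 0.95 on null data). Under the generator's
null (Dirichlet usage, n = 60+60, K = 3) the realized type-I error at
α = 0.05 is within [0.04, 0.06].

Proportions violate the test's normality assumption near the simplex
boundary; with strongly skewed Dirichlet parameters the approximation can be
mildly anti-conservative. The permutation mode is recommended whenever a
gene's proportions are extreme.

**Effect size and diversity.** Effect size is the maximum over isoforms of
the absolute difference in condition-mean proportion — interpretable as "the
largest change in relative usage of any isoform". Isoform diversity uses
Shannon entropy in nats; the log base only rescales ΔH, never its sign, so
the headline fraction of genes with ΔH > 0 is base-invariant. ΔH is computed
on condition-mean proportions (one usage distribution per condition), not as
the mean of per-sample entropies; the permutation null swaps each donor's
condition pair independently, preserving pairing. Dominance uses a majority
rule (mean proportion > 0.5, exposed as `dominance_threshold`), with ties
broken by isoform-id order and flagged.

## Event-level Ψ and Bayes factors

Counts are first converted to length-adjusted rates `a = inc/ℓ_inc`,
`b = exc/ℓ_exc`, because the inclusion isoform has more informative
positions for some categories (here ℓ_inc = 2 for RI and TandemUTR). The
estimator `Ψ = (a+ε)/(a+b+2ε)` with ε = 1 is the posterior mean of a
Beta(1,1) model on the adjusted rates; ε is exposed. Zero-count pairs give
Ψ = 0.5 and are flagged low-information.

The per-donor Bayes factor compares independent-Ψ against shared-Ψ under
Uniform(0,1) priors; binomial coefficients cancel, leaving a ratio of Beta
functions computed with `gammaln`, which admits the real-valued
length-adjusted counts. This is an intentional, documented replacement for a
full generative read-assignment model: it captures the same evidence
(how incompatible the two condition's inclusion fractions are at the
observed depth) without modelling read positions.

The significance rule is *BF ≥ 5 in at least ⌈0.10·n⌉ donors AND
|mean ΔΨ| ≥ 0.05*, with the mean taken over all donors (the mean over
BF-passing donors is also emitted). The dual rule trades sensitivity for
consistency: events passing it have markedly lower ΔΨ coefficient of
variation across donors, which `dispersion_summary` quantifies. On null
synthetic data the false-call rate is < 1 %, dominated by the |mean ΔΨ|
arm (the per-donor mean's standard error at depth 200 and n = 60 is ~0.007,
so 0.05 is a ~7σ gate).

Directional statistics emit both a Mann–Whitney comparison of significant vs
non-significant mean-ΔΨ distributions and a one-sample t-test of significant
mean ΔΨ against zero, because the two formulations answer slightly different
questions and either may be wanted; `frac_negative` is the headline
fraction of significant events shifting toward exclusion/shortening.

## ΔΨ–expression linkage

Per-gene Spearman correlations across donors between the event's ΔΨ and the
gene's per-donor log₂ fold change. The null permutes the donor
correspondence 100 times per gene (pooled across genes); a two-sample KS
test compares observed and null correlation distributions. The
restriction to genes with exactly one annotated event (`single_event_only`,
default on) avoids ambiguous event-to-gene attribution. The trans-factor
scan correlates every expressed gene's fold change with the per-donor mean
ΔΨ of one category — by default the mean over significant events, since
those carry the planted/real signal; a flag switches to all events. Fold
changes are an input; when raw TPMs are supplied instead,
`log2((TPM_inf+c)/(TPM_ctl+c))` with c = 1 is provided as a helper.

## miRNA seed sites and enrichment

Seed matching re-implements the three canonical site types on the mRNA
sense strand (8mer, 7mer-m8, 7mer-1A from miRNA nt 2–8 / 2–7); overlapping
matches each count, a longer-type match is not re-counted as its nested
shorter types, and N bases never match but count toward length. Conserved-
site context scores are out of scope.

"Sequence composition matched" is interpreted as joint length (±20 %
relative) and GC (±0.02 absolute) matching; dinucleotide matching is a
documented extension point. For each foreground (significantly shortened)
extension, candidate backgrounds come from the unchanged class within
tolerance, with both tolerances doubled (and a warning logged) when a
region has no match, up to five times before the region is dropped with a
reason. The null resamples one matched background per foreground region,
`n_resamples` (default 1000) times; the empirical p uses the plus-one
estimator, so min p = 1/(N+1). Significance = BH q ≤ 10 % AND fold ≥ 1.5.
The expressed-miRNA floor (mean normalized count ≥ 1 in any condition) is a
package choice, exposed as a flag. miRNA sequences given in RNA alphabet
are mapped to DNA before reverse-complementation.

Fold estimates are ratio statistics of (small) site counts: their stability
scales as `1/√(total foreground sites)`. Enrichment calls on fewer than a
few dozen foreground regions of typical UTR length are noisy and should be
read qualitatively.

## 3′-end validation

Metagene profiles histogram read 3′ ends at offsets within ±W (default 500
nt) of each polyA site, strand-aware (positive offset = downstream). Each
event is normalized by its total in-window reads across both sites and then
averaged, so deep genes cannot dominate and the proximal/distal *share* is
directly visible; a pooled-read normalization is not provided. Ψ from
3′-end data assigns reads within ±`assignment_radius` (default 100 nt;
protocol-dependent, exposed) of each site and applies the same ε = 1
pseudo-rate; reads between the windows are reported as an unassigned
fraction. On matched synthetic events at depth ≥ 500 the two Ψ routes agree
within 0.05 mean absolute difference.

## Synthetic-data generator

The generator's defaults are the stated world of the emulated design:
60 paired donors; genes with 2–10 isoforms, usage ~ Dirichlet with
concentration 10 around a Dirichlet(1) mean; 10 % of genes with a planted
usage shift of 0.15 (moved between the largest and smallest component, so
the planted effect size is exact); event totals Poisson(200) with Binomial
inclusion reads; 30 % of events shifted by |ΔΨ| = 0.2 with per-category
negative fractions {AFE 0.5, ALE 0.7, RI 0.5, SE 0.2, TandemUTR 0.95} —
the TandemUTR and SE values emulate the observed directionality of 3′UTR
shortening and exon inclusion and are simulation defaults, not
reproductions; donor-level Normal(0, 0.05) variation in true Ψ; 500/2000 nt
UTR cores/extensions in two GC strata (0.40/0.60) with one miRNA's sites
planted at 3-fold density in shortened extensions; fold changes linked to
true per-donor ΔΨ at Spearman ρ = 0.6 via the bivariate-normal relation
`ρ_P = 2·sin(πρ_S/6)`; 3′-end reads (Poisson 500 per event/sample, 6-donor
subset, Normal jitter sd 10 nt). Where the emulated design states no value
(UTR lengths, GC strata, depth of the 3′ assay, donor-level Ψ sd), values
were chosen once as field-typical and are documented here.

Simplifications, hence what a green test does *not* establish: counts are
Binomial given a Poisson total — there is no read-level model, no mapping
bias, no fragment-length structure; sequences are i.i.d. nucleotides with
no dinucleotide structure; planted ΔΨ magnitudes are fixed, not drawn, so
recovery targets are sharp; sign truncation at the [0.01, 0.99] Ψ boundary
is recorded in the truth. Recovery on this generator validates the
statistics and their calibration, not robustness to alignment or
quantification artifacts.

Determinism: one integer seed; per-stage substreams via
`SeedSequence(seed, spawn_key=(stage,))`, so changing one stage's
parameters leaves other stages' outputs byte-identical.

## Numerical choices and degenerate inputs

* Singular pooled covariance after the ridge (e.g. constant proportions)
  → T² = 0, p = 1, flagged degenerate.
* ν ≤ p−1 in the F-approximation (tiny groups) → χ²(p) fallback.
* CV of ΔΨ reported as the sd when |mean| < 1e-8; undefined for a single
  donor.
* Constant ΔΨ or fold change → Spearman masked with a reason, never 0.
* Empty margins in the overlap table → OR undefined, p = 1, flagged.
* Zero-length regions excluded from densities and logged; an empty
  enrichment foreground returns an empty result rather than an error.
* Coordinates are 0-based half-open internally; GFF3 converted at the
  boundary; BED validated on read and write with line numbers in errors.

## Limitations

Isoform quantification, read alignment, differential-expression estimation
and miRNA expression analysis are inputs, not outputs; annotation
construction from transcript models, peak calling of polyA sites,
internal-priming artifact filtering, GO/motif enrichment and cross-species
annotation lifting are out of scope. The pipeline is exercised end-to-end
only on the synthetic generator; applying it to real data requires the
documented input tables (TPM matrix, event counts with informative-region
lengths, sample sheet, fold changes, UTR regions, miRNA set).
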