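# Methods

## Model and procedure

The pipeline treats GWAS integration with molecular QTL panels as four
composable operations on summary statistics.

**Allele harmonization.** All effects are expressed per copy of a single
reference effect allele per SNP (the first study's A1). A study whose
allele pair is swapped relative to the reference has its beta negated and
its frequency complemented; an allele pair that cannot be reconciled even
after swapping removes that SNP from the panel, with a count surfaced in
the run manifest. Palindromic (A/T, C/G) SNPs are counted and passed
through unchanged: without strand information, frequency-based flipping
silently corrupts more data than it repairs, and the desk-scale dialects
here carry no strand field. Duplicate SNP ids within a study keep the
first occurrence.

**IVW meta-analysis.** Standard fixed-effect pooling with weights
w_i = 1/SE_i². The pooled standard error is sqrt(1/Σw_i). A `eq3_literal`
flag instead returns 1/Σw_i — the un-rooted form one sometimes sees
written — purely for audit: that form is dimensionally a reciprocal
variance, and the resulting "Z" = β·Σw grows without bound as studies are
added, so the square-root form is the only self-consistent choice and is
always the default. Per-SNP p-values are recomputed from the pooled Z,
never combined from per-study p-values. SNPs carried by fewer than
`min_studies` studies (default 1) are dropped and counted.

**Empirical-Bayes shrinkage.** The two-level normal model
Ẑᵢ|Zᵢ ~ N(Zᵢ, 1), Zᵢ ~ N(θ, σ²) yields posterior mean
θ + B(Ẑᵢ − θ) with B = σ²/(1+σ²). The plug-in estimates are
θ̂ = mean(Ẑ) and B̂ = 1 − (N−3)/S with S = Σ(Ẑᵢ − θ̂)², the classical
James–Stein construction: (σ²+1)/S is inverse-χ²(N−1), whose mean gives
E[(N−3)/S] = 1/(σ²+1). Numerical choices:

* B̂ is truncated at zero (positive-part estimator). The raw formula goes
  negative whenever S < N−3, which would reverse every effect direction;
  the positive-part version also strictly dominates the raw one in MSE.
  `truncate=False` exposes the literal estimator.
* N ≤ 3 and S = 0 are hard errors (the moment does not exist / B̂ = −∞),
  not silent defaults.
* Shrinkage is fitted on the signed Z-scores of the meta-analysed panel
  in one pool across all chromosomes; there is no per-chromosome or
  LD-block-local fitting (out of scope).
* Downstream SMR consumes beta and se separately, so the revised Z must
  be folded back. Default `mode='beta'` sets β′ = Z′·se (se untouched);
  `mode='z'` sets se′ = β/Z′ (β untouched), leaving se unchanged (and
  counting the row) where Z′ is zero or crosses sign, since a negative or
  infinite se is meaningless. Beta-mode is the default because it keeps
  the uncertainty estimate — the quantity the QTL side must be compared
  against — on its original scale.

A genuine modelling caveat: after shrinkage the *p-value distribution* is
not and cannot be normal (p-values live on [0,1]); what shrinkage
actually guarantees is the exact variance contraction
var(Z′) = B̂²·var(Ẑ), which the tests assert instead.

**SMR.** The Wald ratio b_xy = b_zy/b_zx with the χ²(1) statistic
T = z_zy²z_zx²/(z_zy²+z_zx²) (the delta-method approximation to
b_xy²/var(b_xy)) and se_xy = |b_xy|/√T. Every overlapping SNP–probe pair
is tested by default — the probe-count Bonferroni correction is the
multiplicity control — with `top_snp_only` restoring the classical
one-instrument-per-probe behaviour and `min_instrument_p` available as an
instrument-strength filter (off by default; the pipeline takes the QTL
panel as already screened). Pairs with b_zx = 0 are skipped and counted.
T is bounded by min(z_zy², z_zx²), so weak instruments make the test
conservative rather than anticonservative; the ratio *estimate* under
weak instruments is heavy-tailed, which the test suite observes but does
not assert unbiasedness about. No heterogeneity (HEIDI-style) test and no
LD reference are included.

**Aggregation.** Genes are identified by symbol string; a SNP significant
under two probes of one gene counts once for that gene, while a SNP
mapping to several genes counts in each. Overlap between the eQTL and
mQTL analyses is pure set intersection on SNP ids and gene symbols, with
no special-casing of any locus.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `alpha` | 0.05 | family-wise level; threshold = alpha / n_probes |
| `n_probes_*` | distinct probes in the QTL file | Bonferroni denominator, overridable |
| `min_studies` | 1 | studies required per SNP in the meta-analysis |
| `eb truncate` | on | positive-part shrinkage factor |
| `eb mode` | beta | how revised Z re-enters beta/se |

## Synthetic-data generator

The generator draws each SNP's true score Zᵢ ~ N(θ, σ²) on the scale of a
reference (largest) study and gives study k the observation
Ẑᵢₖ ~ N(Zᵢ·√(n_k/n_ref), 1), the square-root-of-n signal scaling of
association Z-statistics. Betas are placed on the per-allele scale via
se = 1/√(2·n·p(1−p)) with allele frequencies Uniform(0.05, 0.95). Probes
own disjoint cis windows of consecutive SNPs that never cross a
chromosome boundary; instruments have |z_zx| ~ N(20, 3²) with random
sign, the strength typical of genome-wide-significant cis-QTLs. Causal
probes overwrite the trait-side truth in their window with
b_zy = b_xy·b_zx and re-draw every study's observation there at its usual
sampling noise, so the Wald ratio centres on b_xy by construction.

Reference scenario defaults: 20,000 SNPs on 22 chromosomes; five studies
of 1,517 / 1,517 / 1,517 / 54,162 / 314,278 samples (three small clinical
cohorts, a case-control consortium, a biobank); θ = 0, σ² = 1 (a visible
polygenic background, so shrinkage has real work to do); 500 eQTL probes
(n = 1,194) and 1,000 mQTL probes (n = 1,160) of 8 cis-SNPs each; 10
causal probes per panel, 2 causal genes shared between panels; causal
effect b_xy = 0.03 trait-SD per expression-SD. The effect size is chosen
to be realistic for a polygenic disease trait given a ~370k-sample GWAS:
it yields trait-side |Z| ≈ 9–11 at causal SNPs — comfortably detectable
but small enough that the causal mass does not dominate the genome-wide
dispersion S, which would push B̂ toward 1 and disable shrinkage.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent, so there is no tag-SNP ambiguity and no need for clumping),
realistic MAF spectra, allelic heterogeneity within a probe (one causal
window per probe), sample overlap between studies, and population
stratification. Passing end-to-end tests therefore demonstrate that the
statistical machinery is correct under its own assumptions — not that the
pipeline resolves LD-confounded loci on real data, which is exactly the
limitation the out-of-scope HEIDI/colocalization methods address.

## Problem sizes and determinism

The reference scenario (20,000 SNPs, 1,500 probes, five studies) runs the
full pipeline in a few seconds; Monte-Carlo checks use 10,000 replicates
for coverage/type-I rates and 200 replicates × N = 1,000 for the
dominance property, sizes at which binomial error bars are a fraction of
the tolerances asserted. Every random draw flows from a single
`numpy.random.default_rng` seed; a fixed seed reproduces all emitted
files byte-for-byte.

## Known limitations

* Single-SNP SMR cannot distinguish mediation from a shared causal
  variant or LD-linked causal variants; with independent synthetic SNPs
  this distinction is invisible by construction.
* The shrinkage pool is genome-wide; a locus with extreme signal density
  inflates S and weakens shrinkage everywhere (visible in the reference
  scenario: fitted B̂ ≈ 0.66 against the null-only population value 0.5).
* Strand-ambiguous SNPs are never frequency-flipped; on real data with
  mixed strand conventions they should be pre-filtered upstream.
* `mode='z'` back-transformation is undefined at sign changes; affected
  rows keep their original se and are counted in the manifest.
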