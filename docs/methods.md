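# Methods

## Deleterious-variant classification

A biallelic SNP is classified deleterious (a dSNP) iff
`sift_score <= sift_max` **and** `rs_score > rs_min`, with defaults 0.05
and 0 — the conventional SIFT intolerance cutoff and the requirement that
GERP report fewer substitutions than neutrally expected. The rule is a
strict conjunction: a variant missing either score is never deleterious.
This is deliberately conservative; both lines of evidence must agree.
Classification is monotone in both thresholds.

Loss-of-function status is a consequence-term lookup against a
configurable set, defaulting to {stop_gained, stop_lost, start_lost,
splice_acceptor_variant, splice_donor_variant, frameshift_variant}. Terms
outside the recognised vocabulary are logged and treated as non-LOF.

## Polarization and derived-allele frequency

Dosages count derived alleles (0/1/2 per diploid genotype, −1 missing).
The VCF reader polarizes with the `AA` INFO key when it names one of the
two alleles; the default `aa-then-ref` policy falls back to REF-as-ancestral
(counted per file) because upstream polarization pipelines are out of
scope and a recorded fallback keeps analyses runnable; `strict` skips such
records instead. DAF for a site is `sum(dosage) / (2 · n_called)` over
non-missing genotypes.

A dSNP is *fixed* when DAF = 1 **and** the callrate is at least
`fixed_min_callrate` (default 0.8). The floor exists because DAF = 1 from
a handful of called genotypes is not evidence of fixation in the
collection; setting it to 0 recovers a frequency-only rule.

## Mutation burden

Burden is per deleterious locus and per sample:
`burden_het = n_het / n_callable`, `burden_hom = n_hom / n_callable`,
`burden_total = burden_het + burden_hom` — exact by construction, the
identity that makes collection-level components add to the total. Two
deliberate choices, both exposed in `RunConfig`:

* **count-of-loci, not count-of-alleles** (default `burden_mode="loci"`).
  The allele-dosage variant `(n_het + 2 n_hom) / (2 n_callable)` is
  available as `"alleles"`, with components scaled so additivity is
  preserved.
* **per-sample callable denominator** (default). Dividing instead by the
  collection-wide deleterious locus count (`burden_denominator=
  "collection"`) deflates burden for high-missingness samples; it is
  provided for sensitivity analysis.

dBSM (deleterious base substitutions per site per sample) is
`count / (G · N)`; G is supplied in config (`genome_length_bp`, default
2.2 Gb, a mid-size plant assembly — record the assembly actually used).
The storage trend is an ordinary least-squares slope of per-bin dBSM on
storage-year bin midpoints.

## Site-frequency spectra

Each polymorphic site contributes its derived count among called
chromosomes. Sites with missing genotypes are projected down to a common
chromosome count n by hypergeometric expectation; n is the largest value
retaining ≥ 90% of polymorphic sites (`sfs_min_retention`). Complete data
give the identity projection. Sites at sample frequency 1 are tallied as
fixed separately; projected mass at subsample counts 0 and n is dropped as
unobservable. Projected bin contents are therefore fractional in general;
the Poisson likelihood handles that through the gamma function.

## DFE model and alpha

The expected spectrum under the Poisson random field is

    E[x_i] = theta ∫ phi(S) H(S, n, i) dS,
    H(S, n, i) = ∫_0^1 (1 − e^{−S(1−q)}) / ((1 − e^{−S}) q(1−q))
                 · C(n,i) q^i (1−q)^{n−i} dq,

with the neutral limit H(0, n, i) = 1/i. phi is a mixture over scaled
selection S = 4Ns: with probability 1 − p_b, −S ~ Gamma(shape b, mean
|S_d_mean|); with probability p_b, S ~ Exponential(mean S_b_mean). No
nuisance distortion parameters and no divergence counts are modelled; the
minimal mixture keeps the likelihood tractable at collection scale.

The adaptive proportion weights the DFE by the relative fixation rate
r(S) = S / (1 − e^{−S}) (r(0) = 1):

    alpha = E[r(S); S > 0] / E[r(S)].

**Numerics.** The frequency integral uses 64-node Gauss–Legendre on (0, 1)
(`q_nodes`); the sojourn ratio is evaluated in log space for strongly
negative S. The selection integral maps 128 Gauss–Legendre nodes
(`s_nodes`) through each branch's quantile function, making the integral
exact in the density and smooth in the kernel — important for gamma shapes
b < 1 whose density diverges at 0. Verified: neutral theta/i to machine
precision; agreement with an independent adaptive integrator to ≤ 1e−6
relative at moderate selection, and with a 10× denser grid to ~2e−5 at
|S_d_mean| = 400.

**Fitting.** The product-Poisson log-likelihood of a selected and a
neutral spectrum (the neutral class pinning theta_neutral through the 1/i
law) is maximised by L-BFGS-B on transformed parameters (log scales, logit
p_b) from `n_restarts = 10` seeded starts; the best optimum is kept and
non-convergence of all starts is flagged rather than raised. `fix_p_b`
pins the beneficial mass (e.g. 0 for a deleterious-only fit).

**Identifiability caveat.** From polymorphism data alone at moderate n,
alpha is weakly identified: a large mass of nearly-neutral beneficial
mutations (p_b large, S_b_mean → 0), or a tiny mass of very strong ones,
can fit the spectrum while implying a very different alpha, and the
denominator of alpha is dominated by the poorly-constrained nearly-neutral
deleterious mass. The recovery harness
(`validation.dfe_alpha_recovery`) quantifies this directly: at n = 20
chromosomes and theta = 2000, the sampling spread of fitted alpha is of
order 0.1–0.3 and it does not shrink below ~0.05 even at 25× that data
volume. Point estimates of alpha from single spectra of this size should
be treated as indicative; divergence data or external constraints on the
beneficial class are needed for sharp alpha estimates.

## Expression profiling

A gene is expressed when TPM ≥ `tpm_expressed_min` (default 1.0) in at
least `tpm_expressed_min_samples` (default 1) samples — the common
RNA-Seq convention, with sensitivity to the threshold exposed in the
summary. The headline fraction weights by dSNP (each dSNP counts once);
gene-weighting is available via `expression_weighting="gene"`. dSNPs whose
gene is absent from the TPM matrix count as not expressed but stay in the
denominator (logged). Mean TPM/gene/sample is total TPM over the expressed
deleterious genes and all samples divided by genes × samples.

## Contrasts

Associations are OLS of per-sample total burden on one covariate with a
two-sided slope test. Paired group contrasts compare:

* dSNP proportion — two-proportion z-test on (dSNP count, variant count);
* total burden — Welch t-test by default, or a seeded permutation test
  (difference in means, add-one two-sided p, default 10,000 resamples);
* alpha — delta of per-group fits, reported without a p-value by default
  (a parametric bootstrap is deliberately opt-in: it multiplies the fit
  cost and inherits the identifiability caveat above).

Stars mark p < 0.05 / 0.01 / 0.001 per contrast with no multiple-testing
correction by default, matching how such contrasts are conventionally
reported; a Benjamini–Hochberg helper is provided. Direction flags record
whether each delta matches the expectation for the contrast kind (longer
storage → more dSNPs, more burden, less alpha; more regenerations or
higher germination → the reverse). Group splits (e.g. storage ≥ 25 yr vs
≤ 20 yr) are configuration, not code.

## Synthetic collections

The generator emulates the statistical structure the analysis assumes, at
desk scale (70 samples × 5,000 variants by default rather than millions —
chosen to keep the full validation suite runnable in minutes):

* **DAF model**: a rare-skewed Beta(0.3, 2.5) continuous component — under
  which the realized majority of deleterious sites sit at DAF ≤ 0.2 — plus
  a small point mass at 1.0 (fixed class, 2% of deleterious sites by
  default). The shape is a documented default, not a calibration: no
  quantitative DAF histogram exists to calibrate against.
* **Genotypes**: per site with DAF p and inbreeding coefficient F, hom
  derived p² + Fp(1−p), het 2p(1−p)(1−F). Mating system maps to F
  (selfing 0.95, outcrossing 0.05) unless F is given; F = 1 yields zero
  heterozygotes exactly. 5% genotype missingness by default. No linkage.
* **Scores**: deleterious sites draw SIFT ~ U(0, 0.05] and RS > 0;
  neutral sites are forced to fail the conjunction, so with zero
  `label_noise` the classifier recovers the planted set exactly.
* **TPM**: 70% of genes silenced; otherwise zero-inflated log-normal
  (30% zeros, log-mean 1.5, log-sd 1.0) — yielding expressed-deleterious
  fractions around 0.25–0.30.
* **Planted storage effect**: zero-dosage deleterious genotypes are
  promoted to het carriers with probability proportional to
  `burden_slope_per_storage_year · storage_years`, so expected extra
  burden rises linearly with storage while the marginal DAF shape is only
  mildly perturbed. The power harnesses use 0.002/yr (≈ +0.06 burden over
  a 30-yr shelf), a weak but realistic effect size chosen once.
* **Planted alpha gap**: group-level, at the SFS stage —
  `params_with_alpha_delta` solves for the p_b that shifts alpha by the
  requested delta (alpha is monotone in p_b), and `simulate_group_sfs`
  draws Poisson spectra per group. There is no forward-in-time model of
  storage or regeneration dynamics.

What passing tests on this generator do **not** show: robustness to
linkage, to population structure within collections, to genotyping error
correlated with expression level (RNA-Seq calling), or to ancestral
misidentification — real-data features the generator does not emulate.

## Degenerate inputs and tie-breaks

All-missing sites are uncallable (error at DAF; dropped with a warning in
callset assembly). Samples with no callable deleterious locus raise.
Zero-variance covariates and single dBSM bins raise. Identical groups give
delta 0 and p = 1 by convention (no test statistic is computed). SIFT
boundary 0.05 is inclusive; RS boundary 0 is exclusive, both per the
classification convention.
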