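# germload

Deleterious-mutation burden and adaptive-mutation inference for plant
germplasm conserved ex situ.

Seed genebanks conserve millions of accessions, but storage is not
genetically free: drift, viability selection, and mutation accumulation
erode collections over time. `germload` implements the population-genetic
toolkit for quantifying that cost from genotype and expression data on
genebank samples:

* **dSNP classification** — a SNP is deleterious when both lines of
  evidence agree: SIFT score ≤ 0.05 (amino-acid change predicted
  intolerant) and GERP rejected-substitution (RS) score > 0 (site more
  conserved than neutrally expected).
* **Mutation burden per deleterious locus** — for each sample, the
  fraction of its callable deleterious loci carried heterozygous
  (burden_het) or homozygous derived (burden_hom); the decomposition
  `burden_total = burden_het + burden_hom` is exact.
* **dBSM** — deleterious base substitutions per site per sample,
  `count / (G · N)` with G the published assembly length and N the sample
  count.
* **DFE / alpha inference** — a Poisson-random-field fit of a
  gamma + exponential mixture distribution of fitness effects (scaled
  selection S = 4Ns) to derived site-frequency spectra, with the adaptive
  proportion

  `alpha = E[r(S); S > 0] / E[r(S)]`, `r(S) = S / (1 − e^{−S})`.

* **Expression profiling** — which deleterious genes are expressed
  (TPM ≥ 1 in ≥ 1 sample by default) and their mean TPM per gene per
  sample.
* **Conservation contrasts** — OLS association of burden with acquisition
  year, storage years, and germination; paired contrasts (longer vs
  shorter storage, 2 vs 1 regenerations, high vs low germination) of dSNP
  proportion, burden, and alpha with significance stars and
  direction-vs-expectation flags; unique/shared dSNP counts between
  groups.
* **Synthetic collections** — a seeded generator of genebank-like data
  (rare-skewed derived-allele frequencies, selfing/outcrossing
  heterozygosity structure, zero-inflated TPM, passport metadata, optional
  planted storage-year effects) so every stage is testable without
  external data.

## Worked example

```python
import germload as gl

spec = gl.SimSpec(n_samples=70, n_variants=5000, mating_system="selfing",
                  burden_slope_per_storage_year=0.002, seed=42)
coll = gl.simulate_collection(spec)
cfg = gl.RunConfig(seed=42)

callset = gl.build_callset(coll.genotypes, coll.annotations, cfg)
table = gl.burden_table(coll.genotypes, callset.variant_keys, cfg)
means = gl.collection_burden(table)
assoc = gl.burden_association(table, gl.metadata_frame(coll.metadata),
                              "storage_years")
```

prints (via the obvious formatting):

```
dSNPs: 200 of 5000 variants (proportion 0.04000), fixed: 3
mean burden: het 0.0421 + hom 0.1027 = total 0.1448
dBSM (x1e-8): 0.1299
expressed dSNP fraction: 0.270, mean TPM/gene/sample: 5.22
burden ~ storage_years: slope 0.00237/yr, p = 8.59e-10
SY2 (>=25 yr, n=15) vs SY1 (<=20 yr, n=44): delta burden +0.0421 ***, unique dSNPs 0/0, shared 200
```

Reading: 200 of 5000 variants pass the SIFT/RS conjunction; this selfing
collection carries most of its burden as homozygotes (hom 0.103 vs het
0.042 per callable deleterious locus); the planted storage effect of
+0.002 burden/yr is recovered as +0.00237/yr and drives a significant
burden excess in the ≥ 25-yr storage group.

The same stages are scriptable from the shell:

```bash
germload simulate --out-prefix demo --seed 42
germload classify --vcf demo.vcf --annot demo.annotation.tsv --out dsnps.tsv
germload report --vcf demo.vcf --annot demo.annotation.tsv \
    --tpm demo.tpm.tsv --metadata demo.metadata.tsv --out-dir report/
```

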