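# ddase

Absolute transcript quantification from droplet digital PCR (ddPCR) droplet
counts, per-individual allele-specific expression (ASE) testing, and
puberty-state clustering — the statistical toolkit for expression-genetics
studies of the Atlantic salmon *vgll3* locus and systems like it.

## The problem

In Atlantic salmon, genotype at the *vgll3* locus (alleles *E*, "early",
and *L*, "late") is a major determinant of age at maturity. Asking *how*
the locus acts leads to three quantitative questions this package answers:

1. **How much transcript is there?** Duplex RT-ddPCR partitions a reaction
   into ~10⁴ nanoliter droplets; template molecules land in droplets at
   random, so molecule occupancy is Poisson and the mean occupancy λ is
   recovered from the positive-droplet fraction:

       λ̂ = −ln(1 − k/N),   copies/ng = λ̂ · (V_reaction / V_droplet) / m_input

   for `k` positive of `N` accepted droplets and input RNA mass `m`.

2. **Is expression allele-specific?** Within an *EL* heterozygote both
   alleles share one *trans* environment, so an allelic imbalance is
   *cis*-regulatory. Each heterozygote is tested with an exact conditional
   Poisson rate-ratio test on raw positive-droplet counts (the classical
   minimum-likelihood two-sided convention), against a null calibrated
   from heterozygous-DNA control wells (where any deviation from 50:50
   reflects probe efficiency alone). The share of the homozygote
   expression gap explained by *cis* regulation is

       cis% = 2 (mean het L − mean het E) / (mean hom LL − mean hom EE) × 100.

3. **Which maturation state is a sample in?** Samples are clustered in
   (log *amh*/*igf3* rate ratio, *vgll3* copies/ng) space with a
   from-scratch Gaussian-mixture EM, BIC model selection, and a parametric
   bootstrap likelihood-ratio test for the number of components.

RNA-seq SNP-level ASE (exact binomial tests on allele read counts) and a
genotype-stratified maturation-frequency tabulation round out the
pipeline, and every input can be generated synthetically with known ground
truth via `ddase.simulate`.

## Worked example

```python
from ddase import (SimConfig, simulate_het_ase_run, test_sample_ase,
                   estimate_copies_per_ng, cis_contribution, binomial_ase_test)

cfg = SimConfig(seed=42, n_droplets=15_000, input_ng=50.0)
run = simulate_het_ase_run(cfg, total_copies_per_ng=113.8, l_fraction=0.53,
                           assay="vgll3_exon2")
res = test_sample_ase(run, null_fraction_l=0.504)
print(f"k_L={res.k_l}, k_E={res.k_e}, FA(L)={res.fa_l:.3f}, "
      f"p={res.p_value:.3g}, call={res.direction}")

q_l = estimate_copies_per_ng(run, 1)
print(f"L allele: {q_l.copies_per_ng:.1f} copies/ng "
      f"(95% CI {q_l.ci95[0]:.1f}-{q_l.ci95[1]:.1f})")

summary = cis_contribution(60.3, 53.5, 106.35, 91.06)
print(f"cis share: {summary.cis_percent:.1f}% -> reported "
      f"{summary.cis_percent_reported}%")
print(f"binomial ASE p (42 vs 25 reads): {binomial_ase_test(42, 25):.4f}")
```

prints

```
k_L=1831, k_E=1525, FA(L)=0.548, p=1.45e-06, call=L_HIGHER
L allele: 61.3 copies/ng (95% CI 58.5-64.1)
cis share: 88.9% -> reported 89%
binomial ASE p (42 vs 25 reads): 0.0498
```

The simulated heterozygote was generated with 53% of its ~114 copies/ng
coming from the L allele; the test recovers a significant L-biased call
(fractional abundance 0.548 against the DNA-calibrated null of 0.504),
and the per-allele absolute quantification brackets the truth. The cis
statistic applied to the exon-2 group means (heterozygote allele means
60.3/53.5, homozygote means 106.35/91.06 copies/ng) attributes 89% of the
homozygote gap to *cis* regulation.

## Command line

```sh
ddase simulate --seed 4 -o study/      # synthetic well + cohort tables
ddase quantify --wells study/wells.tsv --cohort study/cohort.tsv -o quant.tsv
ddase ase      --wells study/wells.tsv --cohort study/cohort.tsv -o ase.tsv
ddase all      --seed 4 -o report/     # full pipeline -> report.json + TSVs
```

Exit codes: 0 success, 1 validation error, 2 runtime failure.

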