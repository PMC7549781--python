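# Methods

## Droplet partition model and quantification

A ddPCR reaction of volume `V_rxn` (default 20 µL) is partitioned into
droplets of volume `v` (default 0.85 nL); with `N` accepted droplets only
the fraction `N·v/V_rxn` of the reaction is read. Template molecules are
assumed independently and uniformly partitioned, so per-droplet occupancy
is Poisson with mean λ = c·m·v/V_rxn for concentration `c` (copies/ng) and
input mass `m` (ng). The estimator inverts the positive fraction,
λ̂ = −ln(1 − k/N), and converts back to copies/ng with the same volume
constants. The default volumes are vendor-standard values; only their
ratio enters the conversion, both are configuration keys, and the cis and
fractional-abundance statistics are ratios in which the constant cancels.

The 95% CI uses the delta-method variance on the −ln scale,
var(λ̂) = k/(N(N−k)). Exact intervals were considered and rejected: at the
droplet counts where quantification is attempted (k ≥ 10 after QC) the
normal approximation on the log scale is accurate, and downstream use is
descriptive. A fully positive well (k = N) raises `SaturationError` rather
than returning an arbitrary large value.

Replicate wells are averaged *after* per-well normalization (the mean of
per-well copies/ng), not by pooling counts; the two differ whenever input
masses differ between replicates, and the per-well order matches how
duplicate wells are reported.

### QC cascade

Wells are labelled with the first failing rule, in a fixed order:

1. `TOO_FEW_DROPLETS` — fewer than 10,000 accepted droplets;
2. `SATURATED` — positives/accepted > 0.98, applied only to the amh/igf3
   assay (the only assay run near saturation; allele-specific wells that
   truly saturate raise an error instead);
3. `MONOALLELIC_OUTLIER` — heterozygote RNA with λ-corrected fractional
   abundance beyond 0.90 for either allele (likely mislabelling);
4. `GENOTYPE_MISMATCH` — homozygote with signal exclusively on the
   opposite-allele channel.

Labels are independent of the order wells are presented in. Sex/genotype
consistency exclusions are metadata-level filters on the cohort table, not
droplet rules.

## Exact tests

One kernel serves all exact tests: the two-sided minimum-likelihood
("minlike") binomial p-value, which sums every outcome whose likelihood
does not exceed the observed one (with the conventional 1 + 1e-7 relative
tolerance for floating-point ties). The Poisson rate-ratio test
conditions on k₁ + k₂, under which k₁ is binomial with success
probability r·T₁/(r·T₁ + T₂) for null ratio `r` and exposures `T`; with
equal exposures it reduces exactly to the binomial ASE test. A central
(doubled-tail) alternative is available behind a flag. Confidence
intervals for rate ratios are exact conditional (Clopper–Pearson on the
binomial fraction, transformed), hence slightly conservative.

Per-heterozygote ASE uses raw positive-droplet counts with equal
exposures (N, N) — the count process is what is Poisson — while reported
fractional abundance uses λ-corrected rates, so the two conventions are
deliberately mixed and both are documented and switchable. Per-sample
tests are run at α = 0.05 with no multiple-testing correction by default
(each heterozygote is its own experiment in this design); a correction
can be applied downstream on the returned p-values.

### Null calibration

The null L fraction per assay is the mean λ-corrected L fraction across
heterozygous-DNA control wells, treated as a fixed constant (no
uncertainty propagation — the calibration is reused verbatim as the
original analyses did). Assays that cannot amplify genomic DNA (the
5'UTR assay spans an intron–exon boundary) declare a null of exactly 0.5,
i.e. equal probe efficiencies are assumed. Orientation note: nulls are
stored as L-allele fractions (e.g. 0.504 for an exon-2-like assay whose
L probe is slightly more efficient, 0.494 for an exon-3-like assay).

### Known numeric ambiguity

For combined counts of 8 vs 1 reads the exact minlike two-sided p-value
is 20/512 = 0.0390625. Reports of 0.038 for this configuration reflect a
different rounding or convention; this package reports the exact value.
Similarly, 42 vs 25 reads give p = 0.04980, printed as 0.049 under
truncation.

## Cis-contribution statistic

cis% = 2·(mean het L − mean het E)/(mean hom LL − mean hom EE)·100. The
factor 2 reflects gene dosage (homozygotes carry two copies of one
allele). Signs are preserved so anti-directional cis effects are negative;
equal homozygote means make the statistic undefined and raise an error.
Under a pure-cis generator the statistic converges to 100%, under
pure-trans to 0% (verified by simulation at 500 samples/genotype). At
realistic study sizes (tens of individuals per genotype with ~12–17%
biological CV) its sampling error is large, because the homozygote gap in
the denominator is itself noisy — a caveat for interpreting any single
study-scale value. Reported percentages round half away from zero.

## Gaussian mixture clustering

The EM implementation is from scratch (sklearn's mixture model serves
only as an independent cross-check at shared parameters in the tests).
Choices:

- **Initialization**: seeded k-means++ means, pooled sample covariance,
  uniform weights; `n_init` restarts (default 5), best log-likelihood
  wins. A restart whose smallest component weight falls below 1/n is
  discarded and re-seeded (bounded retries).
- **Covariance models**: full, tied, diagonal, spherical; the 2-D density
  uses a hand-coded 2×2 path for speed.
- **Ridge**: when a component covariance nears singularity,
  1e-6 × trace/d is added to the diagonal.
- **Convergence**: relative log-likelihood change below 1e-8 or 500
  iterations; the per-iteration log-likelihood path is stored and is
  non-decreasing (asserted in tests at 1e-9 tolerance).
- **BIC**: minimization convention, −2·loglik + n_params·ln n (some R
  packages report the negative of this; the selected model is the same).

The parametric bootstrap LRT for G vs G+1 refits B simulated datasets
from the fitted G-component model under both hypotheses and ranks the
observed statistic with the add-one rule, p = (1 + #{boot ≥ obs})/(B + 1),
so p is never exactly zero. Identical EM settings are applied to the
observed and bootstrap statistics, which keeps the p-value valid even
with deliberately light settings. The type-I calibration study in the
test suite uses 500 null datasets of n = 60 points at B = 199 with
single-restart EM (tol 1e-4, max 120 iterations) — sizes chosen so the
study completes in minutes while leaving the rejection rate within three
binomial standard errors of α; at these settings the empirical rate is
0.05 and null p-values pass a KS uniformity check.

Confidence ellipses use the covariance eigendecomposition with semi-axes
√(χ²₂(level)·eigenvalue).

The default clustering features are (log amh/igf3 λ ratio, vgll3
copies/ng): the log transform symmetrizes the ratio axis and makes the
Gaussian assumption more plausible; it is a configuration choice, as is
the covariance-model family (default "full").

## Synthetic data

Generators emulate the statistical structure of the real assays:

- **Droplet runs**: a Poisson-drawn molecule total assigned to droplets
  by uniform multinomial placement (distributionally identical to
  independent per-droplet Poissons, but conserving molecule counts
  exactly), per-molecule Bernoulli efficiency thinning (so multi-molecule
  droplets are more likely detected), and optional independent
  per-droplet cross-channel leakage (default 0). Runs with more than 20
  expected molecules per droplet are refused as uninformative.
- **DNA controls**: equal template per allele with an L:E probe
  efficiency ratio, so the measured null fraction converges to r/(1+r).
- **RNA-seq counts**: binomial draws at a specified allele fraction.
- **Cohorts**: binary maturation per male with genotype-specific
  probabilities (defaults 0.207/0.154/0.03 for EE/EL/LL, with EL and LE
  pooled), cohort sizes of order 10² per genotype.
- **Study scenario** (`simulate_study`): heterozygote/homozygote duplex
  panels at exon-2-scale means (60.3/53.5 and 106.35/91.06 copies/ng),
  ~12% lognormal biological CV, a 0.02 SD individual spread of the true
  heterozygote allele fraction, 10 DNA control wells at a 0.504 null, and
  an immature/mature amh-igf3 panel (65 + 14 samples at 107 vs 37
  vgll3 copies/ng with inverted amh/igf3 balance).

What the generators do *not* emulate: fluorescence amplitudes and "rain"
(thresholding is upstream of scope), plate/run batch effects,
overdispersion of droplet volumes, RNA degradation, or reference-bias in
RNA-seq counts (count tables are assumed bias-corrected; extreme skew
only triggers a warning). Passing tests therefore validate the
statistical machinery under the partition model's assumptions, not the
wet-lab layer above it.

Default well sizes (14,000–16,000 accepted droplets) follow typical
instrument output; the QC floor of 10,000 is the relevant constraint and
all counts are configuration-exposed.

## Pipeline

`run_pipeline` chains QC → quantification → replicate averaging → null
calibration → per-heterozygote ASE (replicate wells pooled by summing
counts and exposures) → direction tally → cis summary → clustering →
maturation frequencies, logs every exclusion with its rule, and writes a
JSON report plus TSVs. Reruns with identical configuration and seed are
byte-identical. The heterozygote replicate pooling choice (sum counts,
sum exposures) is equivalent to testing the concatenated droplet
population of the sample's wells.

## Degenerate inputs and tie-breaks

- k = 0 positives: copies/ng = 0 with CI lower bound 0.
- Both allele counts zero: ASE p = 1 with an `undefined` flag.
- Both group variances zero in the Welch test: p = 1 when means are
  equal, 0 otherwise.
- Equal BIC between grid cells: the first-fitted (smaller G, earlier
  covariance model) wins.
- Reported percentages: nearest integer, half away from zero.
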