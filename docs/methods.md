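# Methods

`beltmap` implements a combined linkage-disequilibrium and linkage (cLDLA)
variance-component scan for a dominant monogenic coat-colour locus on a
single chromosome, followed by copy-number quantification of the causal
tandem-multiplication allele. Because the underlying cattle genotypes are
not public, the package ships a synthetic-cohort generator that reproduces
the statistical structure the analysis depends on; everything downstream is
generic and runs equally on real phased input.

## The mapping model

At the midpoint of each sliding window of 40 consecutive SNPs the mixed
linear model

    y = X β + Z q + e,    q ~ N(0, D_RM σ_q²),    e ~ N(0, I σ_e²)

is fitted by REML. Here `y` holds the numeric phenotype codes (non-belted
1, heterozygous belted 2, likely homozygous belted 3, belted with ambiguous
genotype 2.5 — ordinal codes treated as a Gaussian response, as in the
original linear analysis; no threshold model is attempted), `X` contains an
intercept plus principal-component scores of the genomic relationship
matrix, `Z = I`, and `D_RM` is the window's diplotype relationship matrix.
The test statistic is `LRT = 2(ℓ_alt − ℓ_null)` with the null the same REML
at `σ_q² = 0`, referred to χ²₁. The true boundary null is the mixture
½χ²₀ + ½χ²₁, so the χ²₁ reference is conservative; the permutation
calibration test confirms the empirical exceedance of the 5% cutoff stays
below 5%.

REML is solved as a one-dimensional problem in `γ = σ_q²/σ_e²`: one
eigendecomposition of `D_RM` rotates the model so each likelihood
evaluation is O(n p), `σ_e²` is profiled analytically, and `γ` is maximized
over `[0, 10⁶]` by a coarse grid on `log10 γ` followed by bounded Brent
refinement (tolerance 1e-8 in `log10 γ`). A test compares the optimum
against a 2000-point grid-search oracle evaluated with a fully independent
matrix-inversion implementation of the restricted likelihood (agreement
within 1e-6). Negative LRT from numerical noise is clamped at 0. If
`D_RM = I` the two variance components are confounded; the fit is flagged
unidentifiable and LRT set to 0 by convention. Rank-deficient covariate
columns are dropped by pivoted QR with a warning.

### Relationship matrices

Genome-wide structure is corrected with the SNP-dosage genomic relationship
matrix (unified additive relationships): with dosage `x_ij` and frequency
`p_i`,

    A_jk = (1/N) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))      (j ≠ k)
    A_jj = 1 + (1/N) Σ_i (x_ij² − (1+2p_i)x_ij + 2p_i²) / (2p_i(1−p_i))

with frequencies estimated from the analyzed cohort itself. Monomorphic
SNPs are a hard error; the QC MAF filter removes them upstream.

Two component-selection rules are implemented:

* `principal_components(A, var_threshold=0.95)` — the smallest m whose
  eigenvalue sum exceeds 95% of the total positive-eigenvalue variance;
* `parallel_analysis_components(...)` — Horn's parallel analysis: retain
  leading components whose eigenvalues exceed the rank-matched 95th
  percentile of eigenvalues from genotypes permuted independently per SNP.

The pipeline defaults to parallel analysis. At desk scale (n = 110 animals,
one 2000-SNP chromosome) the eigen-spectrum of `A` is dominated by the
Marchenko–Pastur sampling bulk, so the cumulative-variance rule retains
~85% of all components, leaving almost no residual degrees of freedom and
flattening the LRT profile; parallel analysis retains exactly the
structural spikes (breeds, families; typically ~10 here) and restores a
sharp, well-localized peak. Both rules remain available
(`pc_rule=variance`, `--pc-var`).

### Local haplotype IBD

The per-window 2n×2n haplotype kernel `G` is a run-length similarity
surrogate for a coalescent IBD prediction, which would require an effective
population size and mutation age that are not available here: scanning
outward from the window midpoint, `l` (resp. `r`) consecutive identical
alleles to the left (right) give `G(a,b) = l·r/(w/2)²`, `G(a,a) = 1`. The
kernel is monotone in the shared haplotype length around the midpoint —
the property the scan actually needs — and any callable with the same
signature can be plugged in. Missing alleles never match (conservative).
The diplotype matrix is `D_RM = ½ K G Kᵀ` (`K` the 2-haplotypes-per-animal
incidence), i.e. `D_jj = 1 + G(p_j, m_j)`; since the surrogate is not
guaranteed positive semidefinite, negative eigenvalues are clipped to zero
with a 1e-8 diagonal jitter fallback, because REML needs a valid
covariance.

### Confidence interval

One LOD unit equals `2 ln 10 ≈ 4.605` LRT units. The initial interval is
the maximal contiguous run of window midpoints containing the peak with
`LRT ≥ LRT_max − 2·4.605`; because each value represents only a window
midpoint, the interval is then extended by 20 SNP positions on each side,
truncated at the chromosome ends. Windows advance by one SNP by default
(configurable); windows that do not fit at the chromosome edge are skipped.

## Quality control

SNP filters run in a fixed order so each removed SNP has exactly one
primary reason: call rate < 0.95; trio Mendelian error rate > 0.002 (the
published "~0.2%" implemented as strictly greater, configurable);
unknown position; MAF < 0.025 computed on observed alleles; off-target
chromosome. Call rate is per SNP across animals (all published filters are
SNP-level). Trios with any missing member are excluded from the Mendelian
denominator; with no informative trio the rule passes vacuously. Filtering
is idempotent. Phasing and imputation are external (BEAGLE in the original
workflow): the pipeline consumes phased VCF (`|` separator enforced) or the
simulator's truth phase, and never phases genotypes itself.

## IC-Hap search

The published candidate haplotypes were found by manual inspection; the
automated equivalent enumerates every contiguous sub-window of the extended
interval with 4–12 SNPs (bounds are configuration — the published examples
span 5–8 SNPs, which may reflect the data rather than a rule), and keeps an
allele string iff at least one haplotype of *every* belted animal carries
it (dominant carrier logic; ambiguous-genotype belted animals count as
belted by default, configurable to ignore) and *no* haplotype of any
non-belted animal does. Overlapping qualifying windows merge when they
agree on shared SNPs and the merged string still qualifies; contained
blocks are dropped. `intersect_breed_haplotypes` returns the maximal
intervals on which supplied per-breed haplotypes agree, mirroring the
cross-breed reasoning that the locus must lie in sequence common to all
belt haplotypes.

## Copy-number quantification

Copy convention: a non-carrier diplotype has 2 copies of the ~6-kb
candidate segment; a carrier haplotype has k tandem copies (default k = 4,
parameterized — other multiplicities were hypothesized), so expected
candidate/reference ratios are 1, (k+1)/2 = 2.5 and k = 4 for the three
diplotype classes, with nearest-ratio classification (boundaries at the
midpoints 1.75 and 3.25) and `copies = round(2·ratio)`.

* **Depth**: mean per-base depth over the candidate interval divided by the
  mean over reference intervals; invariant to uniform coverage scaling;
  zero reference depth is an error.
* **qPCR**: `Cq = a + b log10(q)` fitted by least squares to a serial
  dilution of a 2-copy reference DNA; efficiency `E = 10^(−1/b) − 1` must
  lie in (0, 1.1] (warning otherwise, and for 2-point fits). Quantities are
  inverted per amplicon and the call is the target/reference quantity
  ratio — no additional calibrator-sample normalization (the published
  protocol does not state one).
* **Junctions**: a head-to-tail array of k units has k−1 internal
  junctions, so `k = round_half_up(S/c) + 1` from S junction-spanning reads
  at per-junction coverage c; half-up rounding reproduces the published
  worked case S = 5, c = 2 → 3 junctions → fourfold unit.
* **Breakpoints**: soft-clip records are grouped by clip side; the mode of
  the mapped endpoints on the better-supported side (ties → smaller
  coordinate) gives one breakpoint and the exact reference match of the
  per-column majority consensus (≥60% per column; an ambiguous column
  truncates, avoiding chimeric consensus from mixed clusters; minimum
  length 15) gives the partner. At least 2 supporting records are
  required; an unmatched consensus raises "breakpoint unresolved" carrying
  the consensus.
* **Private-variant filter**: generic case/control genotype filter — keep
  variants hom-alt in all homozygous cases, het in all obligate
  heterozygotes, hom-ref in every control.

## The synthetic cohort

The generator emulates the mapping cohort: 110 animals from four breed
strata (37/29/26/18, one stratum entirely plain-coloured), scalable to any
size. Haplotypes are mosaics of breed-specific founder haplotypes
(Li–Stephens-style copying, switch probability 0.04/SNP, allele flip
0.002/SNP) drawn from breed frequencies diverged from a shared ancestral
frequency (Beta model, Fst 0.05, ancestral frequencies Uniform(0.1, 0.9)),
so LD decays with distance within breeds on top of a distance-independent
admixture floor across breeds. A mosaic-copying founder model was chosen
over coalescent simulation because the mapping method only needs realistic
local haplotype sharing, and it is fully parameterized with no unstated
population history. The causal belt allele is a haplotype tag, not a SNP —
invisible to the panel, tagged only through LD. Each carrier haplotype
carries a shared ancestral core haplotype intact over a per-side geometric
extent (end probability 0.02/SNP within a 60-SNP core), modelling a recent
introgression whose IBD segment is longer than background LD — the
structure the IC-Hap search exploits. Phenotype groups derive from truth
under strict dominance; a configurable fraction of true heterozygotes is
deliberately mislabelled "likely homozygous" (default 10%) and a fraction
of belted animals "ambiguous" (5%), mirroring the pedigree-based group
assignment and its acknowledged misclassification tolerance. A fixed 10%
of each breed are trio offspring of cohort parents; Mendelian-impossible
offspring genotypes are planted at 0.001/SNP/trio and genotypes set
missing at 0.01 for QC testing. Trio gametes are copied from parents
without additional genotyping error, so planted inconsistencies are the
only Mendelian conflicts.

Read depth is Poisson(mean_cov · copies/2) inside the candidate region and
Poisson(mean_cov) outside; junction-spanning reads are Poisson with mean
`junction_cov · (k−1)` per carrier haplotype (default per-haplotype
coverage mean_cov/2) and carry error-free clipped tails cut from the
simulated reference. qPCR Cq values follow the standard curve with
Gaussian noise. The depth/read model has no sequence errors, GC bias,
mappability structure or fragment-length model, and the qPCR noise is
homoscedastic — so passing tests demonstrate the statistical logic of the
quantification, not robustness to real sequencing artefacts. Likewise the
cohort generator has no explicit multi-generation pedigree (no
effective-population-size calibration is possible from the published
material; defaults are documented, not calibrated), so tests show the
mapping procedure works under the assumed LD/IBD structure, not that the
structure matches any particular real population.

## Problem sizes and numerical choices

Default study conditions are 110 animals and 2000 SNPs on a ~121-Mb
chromosome. Test simulations use 50–110 animals and 300–2000 SNPs; the
planted-locus recovery check runs 20 full-scale replicates, and the null
calibration pools 20 label permutations of a 600-SNP, 80-animal cohort
with a 5-SNP window step (sliding windows are strongly correlated, so
single-permutation window fractions are bimodal and only the pooled rate
is meaningful). All randomness flows from explicit integer seeds through
`numpy` generators; per-stage seeds are spawned from the master seed.
Coordinates are 1-based inclusive internally; BED outputs are converted to
0-based half-open with a header note.

## Known limitations

* The LocIBD surrogate is not the coalescent predictor the original
  procedure delegated to; it preserves monotone haplotype-sharing
  behaviour but its absolute scale is arbitrary (the LRT is invariant to
  that scale only through the variance component).
* The diplotype diagonal uses `1 + G(p,m)`; whether the original
  conversion rescales differently is not stated in the available material.
* Ordinal phenotype codes as Gaussian responses overweight the
  likely-homozygous group when misclassification is high.
* The whole-chromosome scan is single-chromosome by design; no genome-wide
  orchestration or permutation-based genome-wide thresholds.
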