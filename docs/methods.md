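# Methods

This note records the statistical definitions the package implements, the
defaults and why, what the simulators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Data model

A dataset is a samples × loci integer allele matrix plus a population
partition, an optional region partition over populations, and optional x/y
coordinates. Diploid codominant data occupy two adjacent columns per locus;
haploid and binary data one. Missing is 0 (codominant/haploid) and −1
(binary, so that 0 can mean band absence). A half-missing diploid genotype
is rejected at load rather than silently treated as one typed copy: an
ambiguous gene-copy count would corrupt every frequency denominator
downstream. Populations are ordered by first appearance and every output
respects that order. Allele codes are opaque labels — no size semantics.

All allele frequencies are computed from non-missing gene copies only;
weights elsewhere ("typed gene copies") refer to those counts, which keeps
missing data coherent across diversity, differentiation and Shannon
analyses.

## Diversity and Hardy–Weinberg

Per (locus, population) with frequencies p_i over N typed individuals:
Na (observed alleles), Ne = 1/Σp_i², I = −Σ p_i ln p_i, Ho (observed
heterozygote fraction), He = 1 − Σp_i², uHe = 2N/(2N−1)·He and
F = 1 − Ho/He. F is reported blank when He = 0 — a monomorphic locus
carries no fixation signal and 0 would fake one. The HWE test is the
classical chi-square against N p_i² and 2N p_i p_j expectations with
df = k(k−1)/2; cells with zero expectation are skipped and a caution flag
is set when any expected count is below 5. No exact or MCMC test is
offered; the chi-square is the transparent teaching statistic and the
package's scope ends there.

## Differentiation estimators

Per locus over k populations, uncorrected hs = mean_g(1 − Σ p_ga²) and
ht = 1 − Σ p̄_a², with p̄ the **unweighted** mean frequency vector across
populations — the k-symmetric treatment consistent with the k/(k−1)
corrections in the standardized estimators (weighting by sample size is a
defensible alternative; unweighted is the documented choice). With
genotypes available the Nei–Chesser small-sample corrections are applied:
ñ is the harmonic mean number of typed individuals per population, Ho̅ the
mean observed heterozygosity, and

    Hs = ñ/(ñ−1) · (hs − Ho̅/(2ñ)),     Ht = ht + Hs/(ñk).

From Hs and Ht: Gst, Hedrick's G′st, G″st and Jost's Dest as defined in
the README. Multilocus values average Hs and Ht across loci **first** and
substitute the means into each formula, the convention of the
standardized-estimator literature; per-locus values are kept for the locus
jackknife. Published-frequency input (no genotypes) uses the uncorrected
forms and flags outputs accordingly.

Two consequences worth knowing. First, corrected estimators on finite
samples from *identical* populations are O(1/ñ) away from zero (sometimes
negative); the "identical populations ⇒ 0" identity is exact only in
uncorrected/frequency-only mode. Second, negative point estimates are
reported as computed — truncation would bias resampling distributions.

Resampling: permutation moves whole individuals among populations
preserving sizes (one-tailed p = (b+1)/(m+1)); the jackknife deletes one
locus at a time (SE = √(((L−1)/L)·Σ(θ₋ℓ − θ̄)²)); the bootstrap resamples
loci with replacement (95% percentile CI).

## Distance-based AMOVA

The individual squared distance for codominant data is half the squared
Euclidean distance between allele-count vectors per locus, summed over
loci typed in both individuals and rescaled by L/L_shared (an explicit
approximation keeping distances comparable under missingness). This
reproduces the classic seven-case genotype distance table. Haploid and
binary distances are mismatch counts under the same rescaling. One
distance definition feeds AMOVA, PCoA and spatial autocorrelation.

Sums of squares come directly from the matrix (SS_total =
(1/N)Σ_{i<j}d²; within-group analogues per group), variance components
from the standard unequal-size nested ANOVA expectations, and Φ-statistics
as component ratios. Negative components stay in the table; a Φ whose
denominator is ≤ 0 is flagged undefined rather than clamped — except when
there is literally no variation below the stratum, which is a true zero.
Permutation units: individuals among populations (Φ_PT), individuals among
populations within regions (Φ_PR), intact populations among regions
(Φ_RT).

F′st recodes population g's allele a to a + g·(max_allele + 1) — a
deterministic, reversible map that removes all allele sharing between
populations while preserving within-population genotype structure — and
divides observed Φ_PT by the recoded Φ_PT(max).

**Known property, not a defect**: for biallelic loci under within-
population HWE the codominant distance reduces to squared dosage
difference, and the two-stratum AMOVA (no within-individual stratum) has
expected Φ_PT ≈ 2F/(1+F) where F is the frequency-variance Fst of the
generating process — e.g. ≈ 0.18 at F = 0.1. Φ_PT is a genotype-level
statistic and is *not* numerically interchangeable with Fst/Gst even
though both are "among-population fractions"; Gst on the same data
recovers ≈ F. The acceptance suite records this honestly.

## Shannon partition

Per locus with population allele distributions q_g weighted by typed gene
copies w_g: sHt = H(Σ w_g q_g / Σ w), sHs = Σ w_g H(q_g)/Σ w, and with
regions sHr built the same way from region-pooled mixtures. The mutual
information sH_UA = sHt − sHs, and the three-level identity
I_pop/total = I_region/total + I_pop/region holds *by construction* (the
region mixture interpolates between the other two), which is why the test
asserts it to 1e-12. Indices are in nats; a bits display divides by ln 2
and leaves every identity intact. Multilocus values are unweighted means
of per-locus indices. Gene-copy (not individual) weighting is the
documented choice for unequal samples with missing data.

## Spatial autocorrelation and heterogeneity

With C the Gower-centering of the individual distance matrix, the
correlogram coefficient for distance class h is

    r_h = 2 Σ_{(i,j)∈S_h} c_ij / Σ_i w_i c_ii,

S_h the pairs whose geographic distance lies in class h and w_i the number
of such pairs containing i — summed between-individual covariance over
summed within-individual variance, bounded in [−1, 1]. Classes are
half-open (lo, hi], the first closed at its lower bound, so every pair is
classified exactly once; even-width classes up to the maximum pairwise
distance are the default. The permutation null shuffles genotype rows
against coordinates (95% envelope); the bootstrap resamples pairs within a
class (95% CI).

Heterogeneity between correlograms computed on the same class
specification: t²_h = Σ_d (r_dh − r̄_h)²/σ̄²_h with σ̄²_h the mean
per-dataset permutation variance of r_h (m_r permutations; this variance
choice is isolated in one argument so a bootstrap variance is a one-line
swap), and ω = Σ_h t²_h. Significance permutes dataset membership of whole
individuals — genotype and coordinates move together — holding the
variance scaling fixed.

**Limitation**: the membership permutation assumes individuals are
exchangeable between the compared datasets under the null. That is exact
when the datasets are samples from a single spatial process (the
calibration design used here: one simulated landscape split at random into
two samples, giving ~5% rejection at α = 0.05). Two *independently
generated* clustered landscapes are not exchangeable unit-wise — family
and coordinate configurations differ — and the test rejects far above
nominal there even when the generating process is identical. Comparisons
should therefore be read as "do these samples share one spatial genetic
process", which is the question the test was built for.

## Linkage disequilibrium

Phase-known: D = p_AB − p_A p_B, D′ = D/D_max with the sign-dependent
D_max, r = D/√(p_A p_a p_B p_b), χ² = n·r² with df = 1 and n the number of
counted haplotypes; all measures are undefined (flagged) at a monomorphic
margin. Phase-unknown: only the double heterozygote is phase-ambiguous;
the EM algorithm splits its count between coupling and repulsion phases in
proportion to p_AB p_ab vs p_Ab p_aB, re-estimates frequencies from
expected counts, and iterates from linkage-equilibrium starting values
until the largest frequency change is below 1e-10 (cap 1000 iterations).
The biallelic two-locus likelihood is well behaved, so a single
deterministic start keeps runs reproducible; the observed-data
log-likelihood is recorded per iteration and asserted non-decreasing. The
EM χ² uses 2N gene copies as the unit count. Locus pairs are scanned for
all biallelic loci; raw p-values by default with an optional Bonferroni
column — no stronger multiplicity machinery is built in.

## Simulators

* `sim_island`: per locus, ancestral frequencies uniform on the simplex;
  population frequencies from Dirichlet(p_anc(1−F)/F) — the Balding–
  Nichols compound with E[frequency-variance Fst] = F — then HWE genotype
  sampling. Defaults k = 4, n = 30, L = 10, F = 0.1, 2 alleles; the
  recovery analysis uses k = 8, n = 50, L = 100 biallelic at F = 0.1.
  Not emulated: mutation models, migration history, linkage — so passing
  tests say nothing about stepwise-mutation markers or non-equilibrium
  demography.
* `sim_haplotypes`: haplotype probabilities (p_A p_B + D, p_A p_b − D,
  p_a p_B − D, p_a p_b + D), n diploid pairs drawn, returned both phased
  and collapsed to the 3×3 genotype table. Inadmissible D for the margins
  is an error.
* `sim_spatial`: full-sib families from random parent pairs, each family
  placed within `radius` of a cluster center uniform in a 100-unit square
  (defaults: 20 families × 5 sibs, 10 loci, 8 alleles). Small radius puts
  relatives at short distances — unambiguous positive fine-scale structure
  with one intensity knob. Not emulated: continuous isolation-by-distance,
  overlapping generations, dispersal kernels.

All generators are pure functions of their arguments; the same seed gives
bitwise-identical output.

## Problem sizes and calibration design

Calibration replicate counts: 500 datasets per permutation-test family
(1000 for Mantel), each with m = 99 permutations, so the null rejection
rate at α = 0.05 is Binomial with SE ≈ 0.01 against the [0.03, 0.07]
acceptance band; the heterogeneity power analysis uses 100 replicates of
radius-1 vs radius-10 landscapes at n = 100 each. Null datasets are
panmictic pools with arbitrary labels (differentiation/AMOVA/Shannon),
independent Euclidean matrices (Mantel), and a single spatial process
split at random into two samples (ω). EM recovery uses 200 replicates at
n = 1000, D = 0.1.

Numerical conventions: permutation p-values are always (b+1)/(m+1),
one-tailed greater; PCoA axes fix sign by making the first nonzero
loading positive; eigenvalues below 1e-9 (relative) are treated as null
axes; exact symmetry is enforced by averaging M with its transpose after
floating-point accumulation.
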