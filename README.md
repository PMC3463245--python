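# popstruct

A scriptable Python toolkit for classical population-genetic analysis of
diploid codominant (e.g. microsatellite), haploid and binary (e.g. AFLP)
marker data, with a focus on the statistics practitioners reach for when
summarising population structure:

* **Diversity summaries** per locus and population: Na, Ne = 1/Σp²,
  Shannon's I, Ho, He = 1 − Σp², unbiased uHe, fixation index F, plus a
  chi-square Hardy–Weinberg test.
* **Standardized differentiation**: Nei–Chesser corrected H_S/H_T and
  G_ST = (H_T − H_S)/H_T, together with the standardizations
  G′_ST = G_ST(k − 1 + H_S)/((k − 1)(1 − H_S)) (Hedrick),
  G″_ST = k(H_T − H_S)/((kH_T − H_S)(1 − H_S)) and Jost's
  D_est = (k/(k − 1))(H_T − H_S)/(1 − H_S); permutation tests, jackknife
  SEs and bootstrap CIs over loci; pairwise population matrices; all of it
  also computable from published allele-frequency tables alone.
* **Distance-based AMOVA** (2- and 3-level) on individual squared genetic
  distances with Φ-statistics, permutation tests at the correct
  exchangeable unit, and standardized F′_ST = Φ_PT/Φ_PT(max) obtained by
  recoding alleles to maximal differentiation.
* **Shannon information partition**: sH_T, sH_S (and sH_R with regions) and
  the mutual information sH_UA = sH_T − sH_S between allele and population
  identity, with the exact three-level additivity
  I_pop/total = I_region/total + I_pop/region.
* **Ordination and matrix comparison**: Gower-centered PCoA and Mantel
  tests, including Mantel cross-comparison of pairwise-population matrices
  of different statistics.
* **Multilocus spatial autocorrelation**: correlogram r per geographic
  distance class with permutation envelopes and pair-bootstrap CIs, plus
  t²/ω heterogeneity tests between correlograms.
* **Biallelic linkage disequilibrium**: D, D′, r, r² with known phase, and
  maximum-likelihood (EM) estimation of D and r from unphased genotypes.
* **Interchange**: a canonical worksheet-style genotype CSV (documented
  below), published allele-frequency CSVs, and export to GenePop,
  STRUCTURE and FSTAT.
* **Simulators with known truth**: Balding–Nichols island-model genotypes,
  phased haplotype pairs at specified D, and spatially clustered families —
  the test surface for every estimator.

## The canonical genotype file

A plain CSV with three header rows, mirroring the familiar worksheet
layout: row 1 `n_loci, n_samples, n_pops, size1, size2, ...`; row 2
`title, , , pop1, pop2, ...`; an optional `Region, , , r1, r2, ...` row;
row 3 `Sample, Pop, locus1, , locus2, , ...` (two columns per locus for
diploid data, one otherwise), optionally ending `, , X, Y` when coordinate
columns follow the genotypes. Allele codes are positive integers and 0 is
missing (a diploid genotype must be entirely missing — half-missing
genotypes are rejected). Binary data use 1/0 for band presence/absence and
−1 for missing.

## Worked example

```sh
popstruct simulate island --seed 7 --pops 4 --n 25 --loci 10 \
    --fst 0.15 --alleles 4 --out island.csv
popstruct diff island.csv --stat dest --permute 999 --jackknife --seed 7 \
    --out diff.csv
```

The tail of `diff.csv` (the multilocus row) reads:

```
locus,Hs,Ht,k,n_harmonic,Gst,Gprime_st,Gpprime_st,Dest,Dest_perm_p,Dest_jackknife_se
multilocus,0.54991...,0.62797...,,,0.12430...,0.32679...,0.35357...,0.23123...,0.001,0.02683...
```

Read: within-population gene diversity H_S ≈ 0.550 against total
H_T ≈ 0.628 gives G_ST ≈ 0.124 — about 12% of diversity lies among
populations under the simulator's Balding–Nichols target of 0.15 (one
10-locus realization) — while the standardized estimators
(G′_ST ≈ 0.327, D_est ≈ 0.231 ± 0.027 jackknife SE) are larger because
they correct for the high within-population diversity of multiallelic
markers. The permutation p = 0.001 (999 permutations) is the floor
(b + 1)/(m + 1): no permuted dataset reached the observed D_est.

The same analyses are importable:

```python
import popstruct as ps

ds = ps.sim_island(seed=7, k_pops=4, n_per_pop=25, L_loci=10,
                   fst=0.15, n_alleles=4)
est = ps.differentiation(ds)            # per-locus table + multilocus dict
phi = ps.amova_two_level(ps.genotype_distance(ds), ds.pops).phi["Phi_pt"]
```

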