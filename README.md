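# lmdh — dispersal ability, population differentiation and diversification

`lmdh` is an analysis pipeline for island arthropod surveys that asks how
dispersal ability shapes the geographical structuring of genetic variation
within mitochondrial lineages, and whether that structuring carries through
to diversification at the genus level.  It targets the classic oceanic-island
design: spiders (ballooning vs non-ballooning) and beetles (winged vs
wingless) sampled at sites nested within islands, sequenced for the COI
barcode region.

The pipeline has four analytical stages, each available as a library module
and driven by a numbered script under `analysis/`:

1. **Lineage delimitation** (`lmdh.delimitation`). All sequences of an order
   are clustered by UPGMA on pairwise Kimura 2-parameter distances

   d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

   with P and Q the transition and transversion proportions over
   pairwise-deleted sites.  Cutting the ultrametric tree where merge heights
   exceed τ/2 yields lineages of maternal dispersal history (LMDHs): maximal
   clades whose within-clade cophenetic divergence never exceeds the maximum
   intraspecific divergence threshold τ (6.8% for spiders, 5% for beetles by
   default).

2. **Population structure** (`lmdh.structure`).  For every lineage sampled
   in ≥2 populations with >3 individuals — populations being sites within an
   island, or whole islands at the archipelago scale — two fixation indices
   are estimated from haplotype frequencies:

   G_ST = (h_T − h_S)/h_T  (haplotype distances unweighted),
   N_ST = (v_T − v_S)/v_T  (haplotype pairs weighted by K2P distance δᵢⱼ),

   using unbiased diversity estimators h_k = n_k/(n_k−1)(1 − Σᵢ p²_ki) and
   v_k = n_k/(n_k−1) Σᵢⱼ p_ki p_kj δᵢⱼ, equal population weights, and the
   h_S/(ñK) total-diversity correction (ñ the harmonic mean sample size).
   N_ST > G_ST indicates phylogeographically structured variation; a
   permutation test over haplotype relabellings of δ is provided.

3. **Diversification proxies** (`lmdh.diversification`).  Per genus (or
   genus partition per colonization event), one sequence per species enters
   a UPGMA tree on uncorrected p-distances; internal node heights give the
   mean node divergence, the maximum node divergence (a crown-age proxy),
   and the age-richness rate ARR = S/t_max with S the endemic species
   richness.  A strict clock (e.g. 0.0125 subs/site/Myr for spider COIa,
   0.0168 for Polyphaga COIa) converts heights to Myr.

4. **Comparative tests** (`lmdh.comparative`).  Wilcoxon rank-sum tests
   (exact when both groups ≤20 and tie-free) compare indices between
   dispersive and non-dispersive groups; Spearman rank correlations relate
   per-genus mean fixation indices to endemic richness.

Because the field collections are not bundled, `lmdh.synthetic_data`
generates complete surveys with the same statistical structure: finite-island
structured-coalescent genealogies (via msprime) with migration rate M set by
the dispersal category, K2P sequence evolution along the genealogy, lineages
separated far above τ, and genus tables with category-dependent richness and
known crown ages.  Every stage of the pipeline is tested against this
generator and against independent brute-force oracles.

## Worked example

```
python analysis/01_simulate_study.py      # default seed 42
python analysis/02_delimit_lineages.py
python analysis/03_population_structure.py
python analysis/04_diversification.py
python analysis/05_group_comparisons.py
```

prints, among other lines:

```
delimited 40 lineages from 1920 specimens
Rand index against generating truth: 1.0000
  dispersive: mean within-island N_ST = 0.007 over 19 lineages
  non_dispersive: mean within-island N_ST = 0.738 over 20 lineages
NST_by_dispersal: W=590.0, p=2.9e-11 (n=20+19, exact)
S_by_dispersal: W=292.5, p=0.000455 (n=15+13, normal_approx)
arr_by_dispersal: W=272.0, p=0.0112 (n=15+13, exact)
```

Reading this: delimitation at τ recovered the generating partition exactly
(Rand index 1.0); non-dispersive lineages (M = 0.2 migrants per deme-size
generation) show strong within-island fixation while dispersive lineages
(M = 20) are nearly panmictic; and both species richness and the ARR
diversification proxy are significantly higher in the non-dispersive genera,
the direction the pipeline is designed to detect.

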