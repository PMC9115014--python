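# Methods

## Lineage delimitation

Delimitation operates on pairwise Kimura 2-parameter (K2P) distances.
Positions where either sequence carries anything other than an unambiguous
A/C/G/T are excluded for that pair only (pairwise deletion); ambiguity codes
are never fractionally matched, which keeps distances deterministic.  A
saturated pair (non-positive logarithm argument) raises an error rather than
returning a capped value: barcode-scale divergences (≤ ~20%) never reach
saturation, so a saturated input signals corrupted data and should not be
silently folded into the tree.

The UPGMA implementation is classic average linkage: merge height is half
the inter-cluster distance, and after a merge the distance to every other
cluster is the size-weighted mean of the members' distances.  Two numerical
choices matter:

- **Tie-breaking.**  Among equal-minimum pairs, the pair whose sorted
  combined member-label tuple is lexicographically smallest merges first.
  Ties are common for identical sequences (distance 0) and this rule makes
  the tree, and hence the partition, reproducible.
- **Duplicate collapsing.**  Exact-duplicate sequences are collapsed before
  the distance matrix and their multiplicities seed the initial UPGMA
  cluster sizes.  This is arithmetically identical to clustering the full
  matrix (duplicates merge at height 0 and contribute their count to later
  weighted averages) while shrinking the matrix roughly an order of
  magnitude on survey-scale data.

Lineages (LMDHs) are the maximal subtrees whose merge heights are all
≤ τ/2 — equivalently, every within-lineage cophenetic distance is ≤ τ and
merging any two lineages would exceed that bound.  τ bounds the *cophenetic*
distance, not the raw pairwise distance; cutting a UPGMA tree at a
divergence threshold means exactly this, but the raw-pairwise reading is a
plausible misreading, so the choice is stated here.  Defaults are τ = 0.068
for spiders and τ = 0.05 for beetles; the beetle value follows the
antecedent beetle survey convention and is configurable.

## Fixation indices

G_ST uses haplotype frequencies only; N_ST weights haplotype pairs by a
genetic distance (K2P between haplotype representatives by default).  Both
use unbiased within-population estimators with the n_k/(n_k−1) correction,
equal population weighting, and the h_S/(ñK) (resp. v_S/(ñK)) correction to
total diversity, ñ being the harmonic mean sample size.  This follows the
ordered/unordered-allele estimator family of the standard population-genetics
software for these indices; exact numeric parity with any particular program
is not claimed.  The correctness surface is instead structural and testable:
N_ST computed with unit distances equals G_ST to 1e−12 on any table, the
mean of N_ST over random relabellings of the distance matrix matches G_ST
within Monte-Carlo error, and complete fixation gives exactly 1.

Populations with fewer than two individuals are dropped before anything else
(the unbiased estimator is undefined at n_k = 1).  A lineage is analysed at
a scale only if it then retains ≥2 populations and >3 individuals.  Negative
estimates are reported as computed — truncating at zero would bias the
dispersive/non-dispersive comparison — and lineages whose total diversity is
non-positive are emitted flagged undefined rather than as numbers.

Haplotypes within a lineage are equivalence classes under exact match after
dropping, lineage-wide, every column that is not A/C/G/T in all members; the
representative is the first member by specimen label.

The permutation diagnostic (`nst_permutation_null`) relabels haplotypes over
the distance matrix: geography-relatedness association is destroyed while
frequencies are kept, so the observed N_ST ranking high in the null
distribution indicates phylogeographic structure beyond frequency
differentiation.  It is an optional diagnostic, not part of the main scan.

## Diversification proxies

Per genus unit, one sequence per species enters a UPGMA tree on uncorrected
p-distances.  Node heights (substitutions/site per lineage) give the mean
node divergence, the maximum node divergence (crown-age proxy), and
ARR = S/t_max.  Genus partitioning by colonization event is the caller's
responsibility, expressed through the grouping column — the package does not
infer colonization history.

Heights convert to time under a strict clock, t = height/r, with published
per-group rates (subs/site/Myr per lineage): spiders COIa 0.0125 (±0.0036),
Polyphaga COIa 0.0168 (±0.0018), COIb 0.0177 (±0.0019), Adephaga COIa
0.0113 (±0.0034), COIb 0.0145 (±0.0054).  The ± values are carried as
metadata only.  Two interpretation choices are flagged: rates are taken as
*per-lineage* (node height divides by r directly; if a pairwise-divergence
reading were intended, a factor of two applies — configurable by supplying a
halved rate), and the strict-clock conversion of UPGMA heights replaces
relaxed-clock Bayesian dating entirely, which is defensible here because the
two approaches are used for the same summary statistics (mean/max node
divergence) and p-distance UPGMA heights are monotone, near-linear
transforms of time at these depths.  The residual finite-sites bias of
p-distances is real (≈3% at 3 Myr under the spider rate, growing with age);
the parameter-recovery test compares against the saturation-adjusted
expectation computed from the K2P transition matrix.

min–max normalization of ARR to [0, 1] is applied within each order
separately, since substitution scales and richness distributions differ
between orders; it refuses degenerate (all-equal) input.

Reported percentages are rounded half-up: integer precision for coverage
tallies, one decimal for assignment rates.

## Comparative tests

Wilcoxon rank-sum tests are two-sided, use midranks for ties, and switch
from exact enumeration to the tie-corrected normal approximation with
continuity correction when either group exceeds 20 observations or ties are
present (scipy's `mannwhitneyu` supplies both paths; exactness is verified
against full enumeration in the tests).  Spearman correlations use the t
approximation on n−2 degrees of freedom.  One- vs two-sided choice and tie
handling are conventions, not derivable from the study design; two-sided
midrank defaults are used throughout.

## Synthetic data generator

The generator emulates the survey's statistical skeleton, not its biology:

- **Genealogies** follow the finite-island structured coalescent (msprime,
  haploid demes of size 1): k lineages in a deme coalesce at rate k(k−1)/2,
  and each lineage migrates to a uniformly chosen other deme at total rate
  M/2.  Time is in deme-size generations; M is the composite migration
  parameter and no attempt is made to split deme size from migration
  fraction.  Sites are demes; islands are groups of sites; migration is
  uniform across all demes, so "island" structure in the generator is purely
  a sampling-scale grouping.
- **Sequences** evolve by the K2P jump process: substitution events are
  Poisson with rate θ_site per site per time unit; each event hits a uniform
  site and is a transition with probability κ/(κ+2) (default κ = 2),
  transversions splitting evenly.
- **Between-lineage divergence** is imposed by a star backbone: each
  lineage's root is placed Poisson(L·D_sep/2) substitutions from a per-order
  ancestral sequence (D_sep = 0.15), rather than simulating deep coalescence.
- **Genus tables** draw richness per category as 1 + Poisson(mean − 1) with
  means 5.65 (non-dispersive) and 2.93 (dispersive) — the direction and
  magnitude typical of wing-dimorphic island beetle faunas — and crown ages
  uniform on 0.5–6 Myr, the range of young-island in-situ radiations.  Genus
  alignments evolve on random ultrametric trees (deepest split at the crown
  age, other splits uniform below it) at the per-order COIa clock rate.

Default study shape (the "strong-effect" preset): 4 islands × 3 sites × 4
specimens per site per lineage, 20 lineages per dispersal category split
between spiders and beetles, M = 0.2 (non-dispersive) vs M = 20
(dispersive), L = 658 bp, θ_site = 5e−5.  θ_site was chosen from island-model
expectations so that intra-lineage divergences land around 0.3–1.5% —
typical intraspecific COI variation — and stay far below τ even in the deep
tail of coalescence times, while between-lineage distances concentrate near
D_sep ≫ τ.  The null preset sets both categories to M = 2, an intermediate
rate at which fixation indices remain defined for essentially all lineages.

What the generator does **not** emulate: selection, recombination
(irrelevant for mtDNA), demographic change, island ontogeny and asymmetric
inter-island migration, unequal site occupancy, sequencing error, gaps and
ambiguity codes, and rate variation among lineages.  Passing tests therefore
demonstrate that the estimators and the pipeline logic behave correctly
under the model's assumptions — not that those assumptions hold for any
particular field dataset.

## Problem sizes and calibration experiments

The replicated experiments run at: 100 replicates per migration rate for the
G_ST-vs-M monotonicity check; 100 replicate full studies for the
strong-effect direction check (expected ≥95% of studies with higher mean
non-dispersive N_ST); 200 replicate full studies for the null type-I check
(expected ≤10% rejections at α = 0.05); 200 replicates of 20-vs-20
per-lineage simulations for the power check (expected >80% rejections).
The category comparison statistic is the per-lineage mean N_ST over
within-island scales, compared between categories by Wilcoxon; lineage
values are independent across lineages, which is what makes the null
calibration meaningful.

## Known limitations

- Exact numeric parity with existing fixation-index software is not
  verified, only the internal identities described above.
- The beetle threshold (0.05) is a convention, not estimated from data.
- ARR inherits the usual age-richness caveats (no extinction model); the
  package computes the proxy and leaves interpretation to the analyst.
- Mixed-effects and phylogenetically corrected models are out of scope; the
  pipeline emits tidy per-lineage and per-genus tables ready for external
  model fitting.
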