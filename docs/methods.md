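# Methods

This note documents the models, default parameters and numerical choices
behind `hetqtl`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Study design being modelled

A two-parent cross (P1 = Nipponbare-like, P2 = 93-11-like) with an F1 hybrid
profiled by 3'-anchored 17-base tag sequencing in three tissues — 4 leaf,
2 root and 1 meristem replicate library per genotype (21 libraries) — and a
RIL population (F5–F7 by selfing) genotyped at 131 SSR-style markers on 12
chromosomes, phenotyped for yield traits in 6 environments.

## Tag expression

* **Signature rule.** The signature is the 17-mer starting at the 3'-most
  `GATC` that retains 13 downstream bases; anchors closer to the 3' end are
  skipped in favour of the nearest qualifying one upstream.
* **Normalization.** TPM = count × 10⁶ / library total; column sums are
  conserved to 10⁶ ± 0.5 exactly (a tested invariant).
* **Filters.** Reliability = non-zero count in ≥ 2 of the 21 libraries;
  significance = ≥ 4 TPM in ≥ 1 library, on per-library TPM, not group
  means. Both thresholds are parameters with these defaults.
* **Abundance bins.** TPM is rounded half away from zero to an integer
  before binning, so the printed integer edges (1–100, 101–1000,
  1001–10000, > 10000) partition expressed signatures exactly.
* **Positional classes.** Class 1 = sense match at a gene's canonical
  3'-anchored signature; 2 = other sense-exonic; 3 = antisense-exonic;
  4/5 = sense/antisense intronic (only reachable when an exon table is
  supplied — synthetic gene models are single-exon); 6 = within 500 bp
  downstream of a gene on its 3' side; 7 = intergenic. Multi-hit signatures
  take the highest-precedence (lowest-numbered) class.
* **Replicate means** include zeros for replicates lacking the signature, so
  a tag seen in one of four leaf libraries contributes mean/4.
* **Genome matching** is sense-strand exact substring search against the
  parental transcript sets (a reverse-complement option exists, off by
  default, since the tags are strand-specific). Matching against whole
  chromosomes is available through the same interface.

## Inheritance-pattern classification

Presence = group-mean TPM ≥ 4. Decision order: F1 absent with ≥ 1 parent
present → EPAF1; F1 present with both parents absent → SEF1; with exactly
one parent → EOPF1. When all three are present, `f1 > HP·τ` → AHPL and
`f1 < LP/τ` → BLPL (τ = 2 by default); any in-band value is assigned to the
nearest of LP, MP = (HP+LP)/2 and HP **in log space**, with ties preferring
HPL, then LPL. The log-space nearest-centre rule is the package's resolution
of overlapping HP/LP/MP bands: it is scale-free, symmetric, and reduces to
the obvious answer whenever the bands are disjoint. Pattern calls are made
at gene level after summing allelic signature abundances per gene.

## QTL mapping

* **Map function.** Kosambi in both directions: d(Morgans) = ¼·ln((1+2r)/(1−2r)),
  r = ½·tanh(2d). RIL-by-selfing map expansion uses Haldane–Waddington
  R = 2r/(1+2r); residual heterozygosity of F5–F7 lines is ignored
  (genotypes are coded ±1).
* **Scan.** Regression on the conditional expectation of the QTL code given
  flanking markers (Haley–Knott for RILs), step 1 cM, LOD =
  (n/2)·log₁₀(RSS_reduced/RSS_full). Missing flanks fall back to the nearest
  informative markers; a line with no informative marker on a chromosome
  contributes an expected code of 0.
* **Cofactors.** Forward stepwise selection by RSS reduction, partial-F
  entry threshold 2.5, at most 5 markers; cofactors within ± 10 cM of the
  evaluated position are dropped there. With 0 cofactors the scan is simple
  interval mapping.
* **Thresholds.** Phenotypes permuted across lines (genotypes fixed);
  threshold = order statistic ⌈(1−α)·n_perm⌉ of the per-permutation
  genome-wide maximum LOD. Defaults n_perm = 1000, α = 0.01; the bundled
  pipeline and calibration tests use 200 permutations, a problem size chosen
  so the full suite runs in minutes, and verified to keep the empirical
  type-I error within [0.002, 0.03].
* **Calling.** One QTL per maximal contiguous super-threshold region; peak at
  grid resolution; flanking markers are the nearest markers at/outside the
  region ends. Additive effect = (mean phenotype of lines with positive
  expected code − negative)/2, positive = P1 allele increases the trait;
  R² = 100·(RSS_cofactors − RSS_full)/TSS at the peak. The class-mean
  effect estimator is unbiased when the peak coincides with a marker and
  attenuates between markers (the code's conditional expectation shrinks
  toward 0), which is why parameter-recovery checks plant QTLs on markers.
* **Aggregation.** Same-trait records on one chromosome merge when their
  marker intervals overlap in cM (a shared flanking marker counts), chains
  merging transitively. Mean LOD = arithmetic mean of constituent peak LODs
  rounded half away from zero to 1 decimal; selection keeps rounded mean
  LOD ≥ 5. On the bundled multi-environment worked example this rule
  reproduces all 27 published groupings and all but two of the printed
  averages (two printed values are internally inconsistent with their own
  constituents by 0.1).

## Gene–QTL integration

The physical window of a merged QTL is the closed bp interval between its
flanking markers. A gene belongs to the window iff its **start** coordinate
lies inside (an any-overlap mode exists behind a flag); this start-coordinate
rule makes counts unambiguous when genes straddle a boundary. Genes are then
joined to per-tissue patterns, TF family (at most one per gene), a
chromatin-related flag and functional-category labels, all consumed as input
lists. "Differentially expressed" summaries exclude MPL by default; the full
table always retains every pattern.

## Synthetic-data generator

What it emulates, and the defaults that define the study conditions:

* **References:** 240 single-exon genes (300–600 bp) on 12 chromosomes,
  parent divergence 0.02 substitutions/base outside the signature; 25% of
  genes carry one substitution inside the signature's 13 downstream bases so
  their tags match exactly one parent. Every transcript has its anchor
  implanted 17 bases from the 3' end and no other anchor, making the
  signature unique and well defined.
* **Inheritance truth:** equal shares of the 8 modes; low-parent abundance
  log-uniform on 20–80 TPM; high/low parent ratio log-uniform on 3–12
  (several-fold parental divergence is what this design selects for in
  differentially expressed genes); over-dominant F1 = 3 × HP, under-dominant
  F1 = LP/3, dominant = the matching parent, additive = mid-parent.
  κ values inconsistent with τ are rejected at generation time because the
  planted mode would be unrecoverable even without noise.
* **Libraries:** 250,000 tags each (a scaled-down stand-in for 1–3 M-tag
  libraries; a config knob). Counts are negative-binomial with dispersion
  0.1 around mean TPM × size/10⁶ ("poisson" and exact-expectation "none"
  models available; "none" is the noise-free limit used by the exactness
  tests, since even zero-dispersion sampling leaves Poisson noise). F1
  libraries split a gene's count equally between the two allelic signatures
  when they differ. A fixed background population (2000 unannotated
  signatures, log-normal composition) fills each library to its nominal
  size so that per-million normalization returns abundances on the scale of
  the planted means — without it, a 240-gene "transcriptome" would be
  renormalized genotype-dependently and the planted triples destroyed.
* **RILs:** first marker per chromosome is a fair coin per line; each
  interval recombines with probability R = 2r/(1+2r) independently (no
  crossover interference within the simulation; Kosambi is used only as the
  cM ↔ r transform).
* **Phenotypes:** each line's ±1 code at a planted QTL is sampled once from
  its conditional distribution given the flanking markers,
  P(+1) = (1+E[x])/2; trait value = Σ a_q·x_q + environment shift + Gaussian
  residual. Realized per-environment variance fractions are written back
  into the truth record. Tiller angle (1–9) and lodging (0–9) are binned
  from the latent value at integer cut points.

**What passing tests do not show about real data:** no sequencing error or
paralogous signature collisions, no tissue-specific expression differences
beyond replication depth, identical mode and means across tissues, no
residual heterozygosity, no genotype-by-environment interaction beyond
additive shifts, and no missing-data patterns (e.g. weather-dependent trait
loss). Recovery rates measured here are therefore upper bounds on what the
same procedures achieve on real libraries.

## Numerical choices and degenerate inputs

Rounding of reported mean LODs is half away from zero (not banker's).
Positions with a design made singular by cofactors are skipped with one
summary warning per scan. Constant phenotypes yield flat LOD 0 profiles,
empty cofactor sets, and an error from the permutation threshold (a null
quantile of a constant is meaningless). Zero-total libraries are rejected at
normalization but tolerated (as zero rows) by the summary table. Unlinked
adjacent markers (R ≥ 0.5) cap their interval at 50 cM with a warning.

## Known limitations

* The negative-binomial recovery bound illustrates a real design constraint:
  at dispersion 0.1 the per-library count CV has a floor of √0.1 ≈ 32%,
  while the τ = 2 log-band half-widths between adjacent pattern centres
  plateau near 0.35 regardless of parental separation. A single-replicate
  group (the meristem) therefore misclassifies ~20% of band-type genes at
  this dispersion no matter how the truth is configured; only replication
  fixes it (the 4-replicate leaf groups recover ≥ 90%).
* CIM is realized as Haley–Knott regression with cofactors, not
  mixture-likelihood interval mapping; with a strong single QTL and
  same-chromosome cofactors outside the exclusion window the LOD profile
  can redistribute mass along the chromosome (the merged interval still
  covers the QTL).
* Marker order is taken as given; only distances are estimated.
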