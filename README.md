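# hetqtl

Integrative analysis of heterosis for two-parent / F1-hybrid studies on a
recombinant-inbred-line (RIL) mapping population, built around the design of
tag-based (MPSS-style) expression profiling in rice: **tag counting and
filtering → F1 inheritance-pattern classification → composite interval QTL
mapping → co-location of differentially expressed genes with yield-QTL
intervals** — plus a synthetic-data generator that emits ground truth so the
whole pipeline is testable end to end.

It is aimed at quantitative geneticists and transcriptomics analysts who want
a reusable, tested implementation of this classic study design (and a
simulator to benchmark it), not at users of any one specific dataset.

## The model and statistics

**Tag expression.** A transcript is represented by its 17-base signature: the
substring starting at the 3'-most DpnII site (`GATC`) with ≥ 13 downstream
bases. Counts per library are normalized to transcripts per million
(TPM = count × 10⁶ / library total). A signature is *reliable* if seen in
≥ 2 libraries and *significant* if it reaches ≥ 4 TPM in at least one.

**Inheritance patterns.** For each gene and tissue the F1 group-mean TPM is
compared with the parental means (presence threshold 4 TPM, multiplicative
tolerance τ = 2). With HP/LP the high/low parent and MP their midpoint:

- `f1 > HP·τ` → **AHPL** (above high parent); `f1 < LP/τ` → **BLPL**;
- otherwise the nearest of HP, MP, LP in log space → **HPL / MPL / LPL**;
- presence logic gives **SEF1** (F1-specific), **EOPF1** (one parent + F1)
  and **EPAF1** (parents only, silent in F1).

**QTL mapping.** Genotype codes are x ∈ {+1 (P1), −1 (P2)}. At each 1-cM
grid position the unobserved QTL code is replaced by its expectation given
the flanking markers (Haley–Knott regression), with the Kosambi map function
d = ¼ ln((1+2r)/(1−2r)) as the cM ↔ r transform and the Haldane–Waddington
inflation R = 2r/(1+2r) for RILs by selfing. With stepwise-selected marker
cofactors (window ± 10 cM) the score is

    LOD = (n/2) · log₁₀(RSS_reduced / RSS_full).

Genome-wide thresholds come from permuting the phenotype across lines
(default 1000 permutations, α = 0.01). QTLs detected in several environments
are merged by marker-interval overlap; their **mean LOD** (arithmetic mean of
peak LODs, rounded half away from zero to 1 decimal) must reach ≥ 5 for a
QTL to enter the candidate-gene stage, where genes whose start coordinate
falls between the flanking markers' bp positions are joined to their
patterns and to TF / chromatin / functional annotation lists.

## Worked example

`examples/05_mean_lod_worked_example.py` merges the bundled per-environment
QTL records of the Nipponbare × 93-11 RIL study (six field experiments):

```
64 per-environment records -> 27 merged QTLs, 27 with mean LOD >= 5
  name trait  chrom marker_lo marker_hi  mean_lod  n_environments
qdth-1   DTH      3     RM231     RM489       7.6               6
qdth-3   DTH      6    Con673     RM527      25.0               6
...
qtgw-1   TGW      5     RM413     RM169       6.5               4
```

The days-to-heading QTL flanked by RM231–RM489 on chromosome 3 averages
LOD 7.6 over its six detections; the 1000-grain-weight QTL on chromosome 5
averages 6.5 over four — a positive additive effect means the Nipponbare
allele increases the trait. The other examples (`examples/01`–`06`) simulate
a study, run the expression and pattern stages, scan for a planted QTL and
execute the full pipeline; each prints the numbers it computes and one line
on what they mean. The same stages are scriptable from a shell:

```bash
hetqtl simulate --out study/ --seed 1
hetqtl qtl --geno study/genotypes.csv --pheno study/phenotypes.csv \
           --map study/marker_map.csv --trait DTH --perms 1000 --out qtl/
hetqtl run --config pipeline.yaml
```

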