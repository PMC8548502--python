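# Methods

This note records the models behind each stage, the defaults and why,
the numerical conventions, and what the synthetic world can and cannot
establish.

## Study design assumed

Two cohorts share one expression matrix: wild-caught adults from paired
forest/urban sites in four municipalities (default sizes
Aguadilla 11/16, Arecibo 18/16, Mayagüez 12/9, San Juan 11/21; 114
total), each acclimated for 2 h to one of three temperatures
(night 15 °C, forest day 25 °C, urban day 32 °C), plus 16 common-garden
animals from Mayagüez lineages split across the two day treatments
(forest 3 at 25 °C / 4 at 32 °C; urban 5/4 — the alternative published
split, forest 4/3, is config-selectable). Every animal has a CT_MAX
measurement; the generator draws it from a truncated normal
(mean 39 °C, sd 1.5, bounds 35–43) with a +0.82 °C shift for wild urban
animals. The sequenced total of 130 is wild + common garden; the
Mayagüez wild sizes are the sequenced municipality totals minus the
common-garden animals.

## Expression model and normalization

Counts are negative binomial with gene-wise lognormal dispersion
(log-mean −3, log-sd 0.5, i.e. BCV ≈ 0.22 at the median) and log2 gene
baselines N(5, 1.5) — library sizes then emerge from the gene means.
Normalization is log2-CPM with a prior count added after CPM scaling:
`log2(count/libsize · 1e6 + prior)`, prior 1.0. Log-fold changes are
differences of group means of log2-CPM, with no dispersion shrinkage:
the inference downstream uses only average fold changes, never per-gene
DE significance. Consequence worth knowing: the prior count compresses
fold changes of weakly expressed genes, so count-level LFC recovery has
heavier tails than the normalized-scale noise would suggest (tested as
median error and sign agreement rather than a tail bound).

## Planted signal structure

The generator states one world and the tests measure recovery in it:

- 600 of 5,000 genes are candidates; each gets a regulator sign (±1)
  and a log2-CPM coupling of 0.5 per sd of CT_MAX. The coupling uses
  the *within-design-group* CT_MAX deviation, and the shared module
  factors (7 modules, loadings 0.5·U(0.5, 1.5)) are residualized
  against the design-group dummies and CT_MAX. Rationale: the planted
  reaction norms carry all group-level structure; leaving chance
  factor–trait or factor–group correlation in place lets correlated
  noise masquerade as signal (at one seed it produced 175 spurious
  candidates and biased the urban maladaptive fraction from 0.51 to
  0.65). Residualization makes the generator's contract — non-candidate
  genes independent of CT_MAX, contrasts centered on the planted norms
  — hold exactly rather than on average.
- Reaction norms: candidates shift 1.5 log2 units between 25 and 32 °C
  (night 15 °C gets −0.5 of the day-25→32 step). The forest direction
  opposes the regulator sign with probability 0.8 (maladaptive); urban
  norms are attenuated ×0.5 and reversed with probability 0.5, so the
  urban maladaptive fraction is ≈0.5 by design.
- Variants: genes tiled on one scaffold at 100 kb spacing with 10 kb
  spans; SNP positions uniform in the span. Ancestral frequencies
  U(0.1, 0.9); habitat frequencies Beta-distributed around them
  (Balding–Nichols) with divergence parameter 0.02 / 0.06 / 0.12 for
  background / adaptive / maladaptive gene sets. F ≥ 1 plants opposite
  fixed alleles (independent Beta draws would fix both habitats for the
  same allele half the time, leaving FST undefined). Within-gene LD
  comes from comonotone haplotype coupling (a haplotype copies one
  shared latent uniform across the gene's SNPs with probability 0.8 for
  candidate genes, 0.3 for background), which preserves per-SNP
  marginals and HWE exactly. Functional classes are drawn per set
  (nonsynonymous/synonymous/noncoding: background 0.15/0.35/0.50,
  adaptive 0.30/0.20/0.50, maladaptive 0.10/0.20/0.70). Genotypes are
  masked missing at rate 0.05.

What a green test does *not* establish: the generator has no read-level
error, no batch or lane structure, no gene-length or GC effects, no
population substructure beyond the two habitats (municipality labels
partition samples but share one habitat frequency draw), no linked
selection outside gene spans, and expression–phenotype causality runs
phenotype→expression rather than the biological direction. Recovery
results validate the estimators' statistical behavior, not the biology.

## Network screen

Unsigned adjacency `|cor|^beta` with signed GS kept separately (the
regulator classes need the sign; module detection does not). Soft power:
smallest beta in 1..20 whose scale-free fit R² (log-frequency vs
log-connectivity over 10 bins) reaches 0.8, else the argmax with a
warning; the pipeline default pins beta = 6 for reproducibility across
runs. The dynamic tree cut is the simple fixed-height variant (cut at
0.99 on average-linkage heights of 1−TOM, minimum module size 30),
chosen over the hybrid PAM variant for determinism; labels are ordered
by descending size with 0 = unassigned. Eigengenes are the first
principal component of row-standardized module expression, sign-oriented
to the module mean profile; module pairs merge while any eigengene
correlation has r² ≥ 0.75, most correlated first, with eigengenes
recomputed after each merge. GS p-values use the t distribution with
n−2 df; BH correction runs within each module (label 0 is its own
group). A memory guard refuses > 20,000 genes unless overridden
(dense n×n doubles).

## Plasticity classification

The congruence rule with epsilon = 0: only an exactly zero LFC is
indeterminate, recorded as its own category rather than silently
dropped (the published percentages sum to 100%, implying no magnitude
threshold). Urban calls reuse the full-cohort regulator classes — the
urban lineage is scored against the same expression–tolerance map, not
an urban-specific one. Between-lineage comparison reports both the
exact binomial test (urban adaptive count against the forest adaptive
proportion) and the continuity-corrected two-proportion χ².

## Divergence correlation and randomization null

Ancestral plasticity = forest common-garden (32 °C mean − 25 °C mean);
evolved divergence = (urban 32 °C mean − forest 32 °C mean). Because
the forest-32 mean enters both with opposite signs, independent noise
alone produces a negative correlation (regression toward the mean).
The null permutes each gene's values independently across the
common-garden samples — preserving every gene's value multiset while
destroying group structure, which is exactly the artifact being
quantified — then recomputes both LFC vectors and Spearman rho;
1000 permutations by default. The empirical p is one-sided toward
"more negative than artifact" with add-one smoothing,
`(1 + #{null ≤ observed}) / (n_perm + 1)`; 2.5th/97.5th percentiles of
the null are reported as limits. Alternative schemes (global shuffle,
within-sample shuffle) are selectable for sensitivity analysis.
Calibration: on pure-noise matrices with the study's group sizes the
rejection rate at α = 0.05 sits inside the binomial 95% band over 100
replicates, with both observed and null rho distributions negative.

## FST, LD, HWE

Genetic divergence is the Weir–Cockerham (1984) two-population θ — the
variance-components (AMOVA-family) estimator — computed per SNP from
dosages with per-SNP missing-data handling; negative estimates are
retained, since clamping would bias set means. Two summaries are
exposed deliberately: per-SNP θ feeds the outlier scan and the Welch
mean contrasts (matching the published analyses), while set-level
divergence uses the multi-locus ratio of summed components
Σa/Σ(a+b+c). The mean of per-SNP ratios is biased toward zero by
per-locus ratio noise (measured ≈0.101 for a planted 0.12 at n=59/71);
the ratio-of-sums form is the field-standard, nearly unbiased set
summary and recovers the planted divergence within ±0.01 at 10,000
SNPs. Optional Gaussian positional smoothing (w = exp(−d²/2σ²), within
scaffold, chunked to bound memory) defaults to σ = 50 kb on the
synthetic 100 kb-spaced scaffold; 5 Mb — the genome-coordinate choice —
is a flag.

LD is unphased genotypic r²: squared Pearson correlation of dosages
over samples complete at both SNPs, for all pairs within non-overlapping
10 kb windows (`window = (pos−1) // 10000` on 1-based positions),
binned at 1 kb (left-closed, right-open); monomorphic-within-complete
pairs are skipped and counted. The candidate-vs-background contrast
uses gene-block permutation (gene labels shuffled, pairs inherit their
gene's label) rather than the original crossed-random-effects mixed
model: the permutation preserves within-gene dependence exactly and
needs no iterative solver; the reference method is recorded in the
report metadata.

HWE deviations use the 1-df χ² against genotype expectations from
observed allele frequencies, computed per population; expected cells
below 5 are flagged but still computed, monomorphic sites return p = 1.
The pipeline pools habitats within each municipality for this scan, so
planted habitat divergence surfaces as a Wahlund excess of homozygotes
concentrated in high-FST candidate genes. Equality-of-proportions tests
everywhere are the continuity-corrected two-proportion χ² (verified
against R's `prop.test`). Empirical outlier thresholds use linear
(type-7) quantile interpolation, recorded in the output.

## Coordinates and formats

VCF positions are 1-based inclusive; BED spans 0-based half-open.
Genotypes are written as GT (0/0, 0/1, 1/1, ./.), with INFO tags GENE,
FCLASS, SET; QUAL is stored rounded to 2 decimals so the
write-read round trip is exact. Reading uses cyvcf2.

## Reproducibility

Every stochastic step takes a seed; the pipeline derives the generator
seed from its own and hashes the full config into each report. Repeat
runs with the same config and seed produce identical reports up to
wall-clock timings. The default full-scale pipeline (5,000 genes,
20,000 SNPs) runs in about a minute and under 1 GB on one CPU.

## Known limitations

- The screen's FDR guarantee is within-module BH under per-gene
  independence assumptions; strongly correlated modules coupled to the
  trait would inflate discoveries (the generator excludes this by
  construction — see the residualization note above).
- The plasticity calls are congruence labels, not fitness measurements.
- The LD permutation tests exchangeability of genes, not of SNP pairs;
  it is conservative when candidate genes differ systematically in SNP
  density.
- Smoothed FST is reported but not used in the contrasts (the original
  smoothing coordinate system is not reproducible from transcriptome
  coordinates).
- Real-data headline values from the motivating study (e.g. ρ = −0.61
  over 632 candidates) require the original accession and are not
  targets of the synthetic world.
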