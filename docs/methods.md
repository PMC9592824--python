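# Methods

`tas2rpop` implements a small-gene-family population-genetic scan: per-gene
diversity statistics, multi-population differentiation, empirical
genome-wide percentile tests, deleteriousness triage of annotated variants,
genotype PCA, a receptor-alignment variability profile, and a coalescent
synthetic-data generator that makes the whole pipeline testable offline.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic fixtures do and do not demonstrate.

## Diversity statistics

All three per-locus statistics are SNP-based; indels and structural
variants are inventoried separately and never enter S, pi, or D (their
counts in real callsets are reported alongside, not mixed in).

**Segregating sites (S).** The number of nucleotide positions variable
among called haplotypes within the locus. A multi-allelic position counts
once. The nonsynonymous/synonymous split covers only positions annotated
to those two classes; stop-gain/stop-loss/start-loss positions count in S
but in neither split, so `S_ns + S_syn <= S`.

**Nucleotide diversity (pi).** The unbiased per-site estimator

    pi = (1/L) * sum_sites  n_c/(n_c-1) * (1 - sum_a p_a^2)

with `n_c` the called haplotype count at the site and `p_a` the allele
frequencies (all alleles, including reference). This equals the exact mean
pairwise Hamming distance between haplotypes divided by L — the package
carries an exact-rational variant (`pi_total_exact`) used by the test suite
to check this identity without float slack. `L` defaults to the gene
table's transcript length and can be switched to the genomic span
(`length_source: span`); user-facing tables report pi in percent.

**Tajima's D.** The standard contrast between the pairwise-difference
estimator of theta and the segregating-site estimator `S/a1`, standardized
by the 1989 variance approximation (constants a1, a2, b1, b2, c1, c2, e1,
e2 as functions of the haplotype count n). D is undefined (reported `na`)
when S = 0 — distinct from a value of 0. Because the variance constants
assume one n, sites with missing calls are dropped from D (logged); pi
keeps them with per-site n_c. The statistic assumes no recombination and
constant population size; the empirical-null machinery below exists
precisely because the constant-size assumption fails in humans.

## Differentiation

**Weir–Cockerham F_ST.** Variance components in the haploid (allele-level)
form, because the input genotypes are phased haplotypes: each haplotype is
an independent allele draw and there is no within-individual component
(c = 0). Per site, with r populations, haploid sizes n_i and alternate
frequencies p_i:

    n_bar = sum(n_i)/r
    n_C   = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r-1)
    p_bar = sum(n_i p_i)/(r n_bar)
    s^2   = sum(n_i (p_i - p_bar)^2) / ((r-1) n_bar)
    a = (n_bar/n_C) [ s^2 - (p_bar(1-p_bar) - s^2 (r-1)/r)/(n_bar-1) ]
    b = (n_bar/(n_bar-1)) [ p_bar(1-p_bar) - s^2 (r-1)/r ]

The multi-locus estimate is the ratio of sums `sum(a)/sum(a+b)` — never a
mean of per-site ratios. Negative per-site and aggregate values are
reported as computed (no clamping). Multi-allelic sites enter once per
decomposed alternate allele. The grouping unit defaults to populations;
super populations are one flag away (`grouping: superpop`). Populations
with zero called haplotypes at a site are excluded from that site and
logged.

A calibration subtlety worth recording: in a d-deme island model the
ratio-of-sums Weir–Cockerham estimate converges to the between-deme
(Hudson-type) quantity `1/(1 + 4Nm·d/(d-1))`, not to Wright's
variance-definition value `1/(1 + 4Nm·(d/(d-1))^2)`; with d = 4 the two
differ by a factor 17/13 ≈ 1.31. The package reports the estimator as
defined and leaves the interpretation to the user.

**Genotype PCA.** Sites are mean-centered by `2*p_hat` and scaled by
`sqrt(p_hat(1-p_hat))` (Patterson scaling; plain centering available via
`pca_scaling: center`). Scores come from the SVD of the sample-by-site
matrix; variance-explained fractions from squared singular values. Missing
dosages are mean-imputed per site, which contributes nothing after
centering. No LD pruning or kinship correction is applied.

## Empirical null and P_E values

Observed per-gene statistics are placed on the genome-wide distribution of
the same statistic computed in adjacent, non-overlapping windows (default
1 kb), after dropping any window that overlaps an exclusion mask
(functional elements, repeats, telomeres — the mask is a required user
input because no canonical set is bundled). The overlap rule is strict by
default (any overlap drops the window; an overlap-fraction threshold is
configurable); trailing partial windows are dropped. Windows where a
statistic is undefined (S = 0 for D, zero F_ST denominator) are counted as
dropped, never imputed, and the provenance counts
(`n_windows_total = retained + dropped`) are carried in the null's header.

The percentile is the empirical CDF with ties counted as "less than or
equal":

    P_E = 100 * #{null values <= observed} / #null values

Values with P_E < 5 or > 95 are flagged as low/high outliers. P_E is
monotone in the observed value by construction, and for observations drawn
from the null it is uniform on [0, 100] up to a discreteness of one part in
the null size. The gene's own footprint is not removed from the null: a
few tens of kb among millions of windows is negligible.

## Variant triage (PHI)

Consequence categories are a closed vocabulary (synonymous, nonsynonymous,
stop_gained, stop_lost, start_lost, inframe, frameshift), consumed from an
upstream annotation table (VEP-style); the package never computes
annotations. PolyPhen-2 scores are banded benign / possibly damaging /
probably damaging at 0.446 and 0.908, with both boundary scores assigned to
possibly-damaging (the published interval is read as closed). SIFT scores
below 0.05 are deleterious; exactly 0.05 is tolerated (the published rule
assigns only "< 0.05" and "> 0.05", and the tie goes to the non-damaging
side). Both tie-breaks are deterministic and documented here.

A variant is a *putatively high impact* (PHI) site iff it is (i) a
nonsynonymous SNP rated possibly/probably damaging by PolyPhen-2 AND
deleterious by SIFT (both scores present and concordant), or (ii) a
stop-gain, stop-loss or start-loss change, or (iii) an indel — inframe and
frameshift alike. Synonymous variants are never PHI. A nonsynonymous
record with neither score is classified not-PHI and carries a warning
reason code rather than failing.

Frequencies follow the source data's convention: the reported "MAF" is the
unfolded alternate-allele frequency and may exceed 0.5 (a folded MAF is
available as a derived field). Singletons are defined on alternate-allele
count exactly 1. The PHI report table applies its frequency threshold
strictly (`> 0.001` by default) and sorts by descending frequency.

## Receptor profile

The multiple alignment of the receptor protein sequences is an input
(aligned FASTA); no aligner is run. Per-receptor variant residues (1-based
ungapped indices) are mapped through each sequence's gap structure to
alignment columns; a column's count is the number of receptors with at
least one variant there, and a column is PHI-flagged if any mapped variant
is PHI. Substructure intervals (EL/TM/IL classes, with the N-terminus
grouped as EL and the C-terminus as IL) must partition the alignment
columns exactly; tallies per substructure are counts of variable and
PHI-flagged columns. Substructure boundaries are a user input in alignment
coordinates; no transmembrane prediction is performed.

## Synthetic-data generator

`simulate_loci` builds complete fixture bundles (phased multi-locus VCF,
panel, annotation table, gene table, BED mask, manifest JSON) from an
msprime coalescent under a symmetric island model with an instantaneous
size change, and places mutations under an infinite-sites model
(`discrete_genome=False`, binary alleles, continuous positions discretized
to unique integer coordinates). Infinite sites keeps the segregating-site
and pairwise-difference oracles exact — no recurrent mutation, no
back-mutation. Haplotypes are paired into diploids in order, so phasing is
known by construction.

Parameters (defaults in parentheses):

* `n_demes` (4), `n_super_demes` (2), `samples_per_deme` (25 diploids):
  a two-level nesting at desk scale.
* `effective_size` (10,000 diploids): ancestral deme size.
* `scaled_migration` (1.2): 4·N·m with m the total immigration fraction
  per deme per generation; the closed-form island expectation
  `1/(1 + 4Nm·(d/(d-1))^2)` is exposed as `expected_island_fst`.
* `growth_factor` (100) and `growth_time` (12,000 generations): recent
  size / ancestral size, applied as one instantaneous expansion. 1 gives
  the constant-size neutral case.
* `mutation_rate` (6e-9 /bp/generation), `locus_length` (1500 bp),
  `n_loci` (23).
* `annotation_mix`: consequence-category proportions (defaults ~67.5%
  nonsynonymous, 27% synonymous, the remainder stop/start changes and
  indels).
* `score_model`: SIFT/PolyPhen-2 score ranges conditional on a latent
  damaging label (damaging fraction 0.25 among nonsynonymous); the latent
  label is recorded in the annotation table so classifier recovery is
  checkable.
* `seed`: mandatory; every stream (ancestry, mutation, annotation, mask)
  derives from it, and a fixed config reproduces the bundle byte for byte.

The defaults were chosen once to emulate the study conditions of a
23-locus bitter-taste-receptor family scan at desk scale: loci of ~1.5 kb
carrying ~30 segregating sites each, a strongly rare-variant-skewed
frequency spectrum (mean Tajima's D near -1.5), moderate differentiation
among four demes (mean weighted F_ST near 0.13), and an annotation mixture
matching the observed consequence proportions. Individual calibration
checks override these dials explicitly (constant size with theta = 5 for
neutrality; 4Nm = 9 for the island check; a single deme for panmixia).

What the generator does **not** emulate: realistic human demography
(out-of-Africa bottlenecks, continental asymmetries), recombination within
loci, sequencing or phasing error, linkage between loci, recurrent
mutation, and genotype missingness (fixtures are fully called; the readers
and statistics support missingness, exercised by hand-written fixtures).
Passing tests on synthetic bundles therefore demonstrate estimator
correctness and pipeline integrity, not robustness to real-data artifacts.

## Numerical and procedural choices

* Coordinates: gene table and VCF are 1-based inclusive; BED is 0-based
  half-open; conversions happen only at the I/O boundary.
* Multi-allelic VCF records are decomposed into one row per alternate
  allele at extraction; decomposition conserves allele counts.
* The sample panel is authoritative for sample membership and nesting; no
  sample count is hard-coded anywhere.
* Genes are processed in gene-table order; excluded rows ("na"
  coordinates) are carried through reporting with no statistics.
* A gene region with zero overlapping variants yields S = 0, pi = 0 and an
  undefined D — not an error.
* Percentile lookups are binary searches on the sorted null; nulls persist
  as TSV with a provenance header (statistic, window size, window counts,
  mask id).
* All writers emit tab-separated UTF-8 with a `#`-prefixed header; floats
  are formatted with fixed precisions so repeated runs are byte-identical.
* Outputs carry a manifest with the config hash and seed.

## Problem sizes used by the test suite and acceptance script

Calibrations run at desk scale, chosen as the smallest sizes at which the
checks are statistically meaningful: 200 random matrices (<= 12 haplotypes,
<= 20 sites) for the exact oracles; 500 constant-size replicate loci
(theta = 5, 50 haplotypes) for the neutrality calibration; 200 island-model
and 200 panmictic loci for the F_ST calibrations; 1,000 draws against a
10,000-value synthetic null for P_E uniformity; the default 23-locus bundle
for the end-to-end scan. Genome-wide null construction against a real
whole-genome callset is supported by the same code paths but is a
cluster-scale undertaking and is not part of the test suite.

## Known limitations

* The haploid W-C estimator is the only F_ST variant; no Hudson or Nei
  estimators, and no diploid genotypic variant (inputs are phased).
* No sliding windows within genes, no folded-SFS tests (Fu & Li), no
  recombination-aware corrections to D — D tests on recombining loci are
  slightly conservative.
* The empirical null's validity depends entirely on the user-supplied
  exclusion mask; results carry mask provenance for that reason.
* VEP/SIFT/PolyPhen-2 are consumed, never computed; nothing is lifted over
  between assemblies; no remote data fetching.
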