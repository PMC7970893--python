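# Methods

## LD estimator

All LD is composite LD: the squared Pearson correlation of allele dosages
(0/1/2) over pairwise-complete individuals. For fully inbred lines this
equals the haplotype-frequency r²; for heterozygous material it is the
standard composite approximation and no phase is estimated. An r² is
reported only when ≥ `min_obs` (default 20) individuals are genotyped at
both markers and both markers are polymorphic over that shared set; below
that, LD is *unknown*, never zero — small-sample r² is upward-biased and
treating it as evidence would trigger false relocations. Dosage-coding
flips (p ↔ 1−p at either marker) leave r² unchanged, and the engine is
tested for exact agreement with a two-pass Pearson oracle.

## Position correction

A marker is flagged as ambiguous iff

- max local r² ≤ `r2_low` (default 0.5, inclusive), where *local* means
  same chromosome within `local_window_mb` (default 10 Mbp) of the
  recorded position, and
- max non-local r² > `r2_high` (default 0.5, strict).

The candidate region is the tightest interval covering the non-local
partners (r² > `r2_high`) on their modal chromosome; a tie in partner
counts between chromosomes is resolved by removal (`multi_region_ambiguity`)
rather than by guessing. A flagged marker relocates to its rank-2 alignment
hit iff that hit lies on the candidate chromosome within
`confirm_window_mb` (default 10 Mbp) of ≥ `min_partners` partners
(default 1; the stricter end-to-end checks use 2); otherwise it is removed
with an explicit reason. Unflagged markers are kept. One pass is the
default; `max_rounds` iterates to a fixpoint if asked. Ties anywhere are
broken by marker-id order, so identical inputs give identical output.
Within-chromosome relocation falls out of the same rule: a marker far from
its high-LD partners on its own chromosome is non-local to them.

Unanchored markers (chromosome `UN`) are excluded from every LD
neighbourhood and are never flagged.

The local window (10 Mbp) is a scale choice, not an estimate: haploblocks
in an inbred breeding panel span well under 10 Mbp, while homoeologous
mis-anchoring moves a marker across chromosomes. Both windows are exposed
as flags.

Known blind spot: two markers of the same haploblock mis-anchored to
nearby false positions on the same chromosome mutually satisfy the local-LD
condition and are undetectable by this (or any purely LD-based) criterion.
The synthetic generator therefore spreads injected misplacements over
distinct blocks so that recovery measurements characterize the algorithm
rather than the collision probability of the injection process.

## QC filters

Alignment-hit filter: keep a marker at its rank-1 hit iff rank-1
mismatches ≤ 1 and any rank-2 hit is ≥ 3 mismatches worse. Genotype filter:
remove monomorphic markers, MAF < 5% and missingness > 5% (both strict, so
exact-boundary markers survive); MAF uses allele counts over 2 × genotyped
individuals with heterozygotes contributing one copy of each allele. Array
cluster-QC: class ∈ {PolyHighResolution, OffTargetVariant}, FLD ≥ 4, and
HomFLD ≥ 8 *when present* — a marker without homozygote clusters (HomFLD
absent) is not removed for that alone, which keeps off-target variants
usable. Each filter returns a per-marker kept/removed ledger with reasons;
chained CLI order is cluster-QC → alignment → genotype, and each stage logs
counts so a "retained N markers" audit is reproducible. All filters are
idempotent.

## LD-kNN imputation

For a missing call at marker m: the `l` (default 30) markers with highest
r² to m form the context; the distance between individuals is the mean
absolute dosage difference over context markers genotyped in both, plus
`epsilon` (1e-6); the `k` (default 5) nearest individuals genotyped at m
vote with weight 1/distance; ties go to the lower dosage. A neighbour must
share ≥ 5 context markers (zero-information matches are worse than the
fallback). Cells with no eligible neighbour fall back to the marker's modal
dosage, and every imputed cell is logged with its method. Non-missing cells
are never altered. Imputation runs *after* position correction in the CLI
pipeline — imputed LD must not drive relocation.

## Temporal signatures

Cohorts are decades of registration (1960s … 2000s, 2010–2020); individuals
without a year, or outside 1960–2020, are excluded and listed. Trajectories
track the panel-wide minor allele by default (ties track the alternate
allele; `--allele-rule` switches). The annual change is the
group-size-weighted OLS slope of cohort frequency (in %) on cohort midpoint
years (1965, …, 2015; the open 2010–2020 cohort uses 2015), in % per year.

Nei's F_ST works from expected heterozygosities with size-weighted allele
frequencies: per locus, H_T = 2p̄(1−p̄) and H_S = Σ w_g 2p_g(1−p_g). The
*pairwise* statistic is the ratio of sums over loci Σ(H_T−H_S)/ΣH_T; the
*per-locus* statistic is the within-locus ratio across all cohorts
(undefined for monomorphic loci). Both variants are tested against direct
hand arithmetic (the single-locus p=(0.2, 0.8) equal-size case gives
H_T = 0.5, H_S = 0.32, F_ST = 0.36 exactly).

The outlier scan keeps the decision surface of a per-locus F_ST genome scan
with an FDR threshold but replaces the Bayesian null with a permutation
null: cohort labels are permuted `n_perm` times (default 1000), p = (1 +
#{perm ≥ obs}) / (1 + n_perm), Benjamini–Hochberg q-values, outlier iff
q < `q_threshold`. Note the attainable p-value floor 1/(1+n_perm): with m
tested loci and a sweep block of k loci, the smallest attainable q is
roughly m/(k(1+n_perm)), so blocks much smaller than ~1% of loci cannot
reach very strict thresholds regardless of effect size — choose `n_perm`
accordingly.

Graphical genotypes code each individual against a reference carrier over
a region: *match* requires equal homozygous calls; any heterozygous call
codes *het* (conservative — never a match, appropriate for a near-inbred
panel); missing propagates. A carrier matches the reference at ≥ 90% of
informative region markers (configurable); the first carrier is the
minimum-registration-year carrier, with ties all listed.

## Structure

PCA is an SVD of the column-centered dosage matrix (missing cells mean-
filled and flagged); explained fractions are squared singular values over
their total. K-means (best of `n_init`) is scored with the spherical-
Gaussian BIC, n·d·log(WSS/(n·d)) + K·d·log(n); the reported K is the elbow
(maximum second difference of the BIC curve), with the min-BIC K alongside
— on p ≫ n marker data the BIC keeps falling with K and the elbow is the
meaningful summary. A WSS floor of 1e-12 guards the degenerate K = n fit.
Clustering runs on the top 50 PC scores by default (stabilizes K-means on
wide matrices); `--use-raw` overrides.

## Synthetic panel generator

The generator emulates a breeding panel of ~220 mostly-inbred cultivars,
165 of them registered 1966–2016 (uniform years forced to span the range,
and forced to include the introgression start year — the introduction event
is part of the design):

- **Haploblock LD**: markers sit on 21 chromosomes (1A…7D) at 250 kb
  spacing in blocks of 10. Per block, a latent allele is drawn per
  individual at a block frequency ~ U(0.35, 0.65) and copied to each marker
  with a flip probability solved (at block frequency 0.5) so the expected
  within-block dosage r² equals the target (default 0.85). Haplotypes are
  doubled to dosages {0, 2} with a 1% heterozygosity injection. Realized
  mean within-block r² lands within ±0.1 of the target at n ≥ 100.
- **Introgression sweep**: carriers of a donor haplotype over a region of
  2A (default 0–6 Mbp) are sampled with probability rising logistically
  (scale 0.4/yr) from 0 at the 1998 start year towards 0.6; the earliest
  eligible cultivar is always a carrier (the introduction itself), so no
  carrier predates the start year.
- **Misplacement**: round(f × n_markers) markers (default f = 0.05), at
  most one per haploblock, are recorded at a random position on a random
  other chromosome; the hits table carries the recorded position at rank 1
  (0 mismatches) and the true position at rank 2, with a configurable
  fraction lacking the rank-2 hit to exercise the removal path.
- **Missingness** (default 2%) is applied uniformly and recorded;
  `mask_cells` masks an exact fraction of non-missing cells for
  imputation scoring.
- All randomness flows from one seed through per-component child
  generators, so equal configs give byte-identical outputs.

What the generator does *not* emulate: realistic wheat recombination maps
or marker densities, population stratification and kinship, genotyping
batch effects, allele-frequency drift unrelated to selection, and
ascertainment bias of array content. Passing recovery tests therefore shows
the algorithms behave as specified under clean haploblock LD with known
truth — not that real-panel quantities (panel F_ST, PC variance fractions,
cluster counts, outlier-locus lists) are reproduced; those depend on the
study's own genotype data and are outside what synthetic checks can
establish.

## Problem sizes used by the end-to-end checks

Misplacement recovery runs at 200 individuals × 1000 markers with f = 0.05
and block r² target 0.85 (relocation ≥ 90% to the true chromosome, ≤ 1%
well-placed markers disturbed, exact count conservation, verified at
`min_partners` = 2). Scan calibration uses 1000 unlinked loci × 1000
permutations against the exact binomial band around the attainable null
rate; sweep power uses 400 individuals (300 year-annotated) with a 50-locus
block among 400 loci, sized so the permutation q-floor and cohort carrier
sampling noise leave headroom at q < 0.01. Imputation recovery masks 5% of
a complete 150 × 300 panel at block r² 0.9 (accuracy > 95% and above the
modal baseline). Carrier tracing runs at the full default 220/165 panel
scale.
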