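# Methods

This note records the models behind `magicpop`, the defaults and why they
were chosen, and what the synthetic data can and cannot say about real
array-genotyped MAGIC populations.

## Funnel design and replicated selection

Crosses are unordered at every tier (reciprocals identified). The replicated
selection problem — choose eight-way crosses so that every four-way is used
exactly *k* times — is solved on the pairing graph whose vertices are the 210
four-way crosses and whose 315 edges are the eight-way crosses. For eight
founders this graph is 3-regular (it decomposes into 35 disjoint K₃,₃
components, one per 4+4 founder split), so *k* = 2 is "all edges minus a
perfect matching" (105 edges removed) and *k* = 1 is a perfect matching
itself. Matchings are found by maximum-weight matching with seeded random
edge weights, restarting with fresh weights if a maximum-cardinality matching
is not perfect; the selection is therefore deterministic given the seed, and
any valid each-four-way-twice subset is an acceptable design — the historical
record does not determine which 105 crosses were omitted.

**Failed-cross substitution.** "Most closely related cross of the same tier"
is formalised as the candidate maximising, in order: shared founders, shared
four-way components, shared two-way components, with lexicographic
tie-breaking on cross id. Founder overlap alone cannot rank eight-way crosses
(they all contain all eight founders), which is why component sharing enters
as the tie-break.

**RIL allocation and pedigree.** `allocate_rils` splits the target population
as equally as possible (counts differ by at most one; the remainder goes to
lexicographically first families), reflecting practice where family sizes are
kept as even as seed set allows. `build_pedigree` gives each RIL one descent
chain from an eight-way F1 plant through `ssd_generations` selfings;
generation labels count the eight-way progeny as F1, so six selfings yield F7
lines. With `rils_per_f1_plant > 1`, consecutive RILs of a family share an
eight-way F1 plant, which creates the "outcrossed plants within funnels"
stratum; the default of one plant per RIL is the strict single-seed-descent
reading.

## Forward simulation

**Map function.** Meiosis uses the Haldane model — no crossover interference,
recombination fraction r = (1 − e^(−2d/100))/2 between markers d cM apart,
independent chromosomes, random starting haplotype. Genetic maps in cM are
agnostic about interference; Haldane is the simplest self-consistent choice
and makes expected crossovers exactly one per Morgan. Meiosis is batched
across individuals per crossing stage, so population-scale simulation is a
few vectorised draws per generation.

**Founders.** Founders are fully inbred (one haplotype each). The number of
founders carrying the variant allele at a marker is drawn from the folded
neutral site-frequency spectrum (weight 1/k + 1/(n−k) for k carriers), which
gives variety-panel-like skew toward low-frequency variants; exact
frequencies (e.g. a 1/8 private allele) and private-founder assignments can
be pinned per marker. Two-way F1s are genetically uniform (inbred × inbred),
so they are constructed rather than sampled.

**Descent tracking.** The founder mosaic stores founder-of-origin per line ×
marker × haplotype; the invariant "dosage equals the sum of founder alleles
at the recorded origins" is checked exactly in the tests.

**Residual heterozygosity** is retained — lines are not forced homozygous at
F7 — matching real F7 RILs (expected residual heterozygosity is the eight-way
F1 level divided by 2^6, about 0.5% under the default founder spectrum).

**Degradation.** Calls are set missing independently at `missing_rate`, then
surviving calls are flipped to a uniformly random other state at
`error_rate`. This emulates array no-calls and miscalls but not their real
correlation structure (probe-specific failure, cluster-calling artefacts).
An optional `drop_double_dwarfs` step removes lines homozygous for designated
alleles at two height loci, mirroring the culling of extreme dwarfs during
seed multiplication; it is off by default.

**Default scale.** The default synthetic population is 8 founders, 21
chromosomes of ~150 cM, ~1000 markers and 700 lines — the genotyped study
population at desk scale. Tests use smaller instances (5 chromosomes, a few
hundred lines) chosen so the whole suite completes in about a minute while
each statistical check retains clear power; the heavy power study runs 100
replicates at the 700-line, 1000-marker scale.

**What the generator does not emulate:** progeny-bulk genotyping (the real
lines were genotyped as F5 bulks of 10 plants; bulk vs single-plant calls are
not modelled), multi-allelic markers, segregation distortion, selection
during SSD beyond the optional dwarf filter, and map error. Passing tests
therefore validate the statistical machinery on clean meiotic data, not
robustness to genotyping artefacts.

## Marker QC and diversity

Filter boundaries follow the stated inequalities exactly: variety panels keep
markers with maf ≥ 0.01 and missing fraction strictly < 0.10; MAGIC panels
drop lines with call rate < 0.75 first, then markers with success rate ≤ 0.91
or maf ≤ 0.05, then one marker of every perfectly correlated pair. "Perfectly
correlated" means identical calls over jointly non-missing lines, allowing a
global allele relabelling; at least two joint observations are required. The
later marker in map order is dropped (unmapped markers sort after mapped,
lexicographically) so pruning is stable and idempotent. Whether line or
marker filtering came first in the original pipeline is not recorded; the
order above is fixed and documented. Candidate duplicate pairs are
pre-screened with a correlation matrix on mean-imputed dosages and then
verified exactly, keeping the step quadratic only over near-duplicates.

Expected heterozygosity is the descriptive He = 2p(1−p) with p from allele
counts (heterozygotes contribute one copy of each allele); no small-sample
correction is applied, matching descriptive use for panels as small as two
lines. Panel comparisons report the He ratio and the segregating-marker
fraction as integer percentages. The published absolute panel values require
the external 64-variety array data and are not reproduced here; only their
ratio arithmetic is implemented and tested.

## Linkage disequilibrium

RILs are treated as inbred: a pair's haplotype table counts only lines
homozygous and non-missing at both markers, each contributing its single
two-locus haplotype; heterozygous lines are excluded rather than phased. At
~1.6% residual heterozygosity per marker the exclusion bias is negligible and
no EM phasing is needed. D′ is reported as |D|/D_max ∈ [0, 1] with the
standard frequency-bounded maximum, r² as D²/(p_A q_A p_B q_B). Pairs with a
monomorphic margin or fewer than two informative lines are flagged, not
silently dropped. Genome-wide heatmap coordinates concatenate chromosomes in
genome order (1A, 1B, 1D, …, 7D) after padding each to 250 cM; the dense
heatmap matrix carries D′ above and r² below the diagonal. Decay curves use
lowess with span 0.1; tricube weighting and three robustifying iterations are
the implementation defaults (only the span is externally fixed). Plotting is
left to the caller — all outputs are numeric tables.

## Recessive segregation under selfing

The base population (the eight-way F1 generation of a replicated funnel) is
taken to be at Hardy–Weinberg proportions: the funnel randomises founder
alleles. Each selfing generation halves heterozygosity and splits the lost
heterozygotes equally between homozygous classes, giving the recessive
phenotype frequency f(q, t) = q² + q(1−q)(1−2^(−t)), which runs from q² at
t = 0 to q in the fully inbred limit. t counts selfing generations from the
eight-way F1 to the scored generation. At q = 1/8, t = 3 the
dominant:recessive expectation is 7.98:1. Ratios and p-values are displayed
at two decimals; unrounded values are returned. Goodness of fit is a Pearson
chi-square with 1 df (scipy), with a warning when an expected class count
falls below 5.

## Association scan

The scan follows the strategy used for funnel-structured populations: line
means are regressed on marker dosage with random intercepts for the pedigree
strata (between funnels; between outcrossed plants within funnels). Fitting
the full mixed model separately per marker is prohibitive at genome scale, so
the variance components are estimated once on the null model by REML
(statsmodels `MixedLM`) and held fixed; each marker is then tested on
GLS-whitened data by the 1-df likelihood-ratio statistic n·ln(RSS₀/RSS₁) —
the two-stage approach standard in genome-wide mixed-model scans. When the
plant-within-funnel stratum has no replication (one RIL per F1 plant) that
component is dropped and noted in the metadata; when funnels have no
replication, or the variance fit fails, the scan falls back to strata as
fixed effects with an F-test (within-stratum demeaning), flagged per scan.
A deliberately naive `method="ols"` ignores strata, for calibration
comparisons.

Numerical details: missing dosages are mean-imputed per marker for testing;
markers with no residual dosage variance are flagged `monomorphic` with an
undefined p; a constant phenotype yields p = 1 everywhere with a
`constant-phenotype` flag; −log₁₀ p is computed through asymptotic-safe log
survival functions (chi-square(1) via 2Φ(−√x); F(1, d) via an incomplete-beta
asymptote where scipy's `logsf` underflows), so extreme peaks keep full
resolution and ties are genuine. Binary phenotypes are analysed on the linear
scale, as for line means. Peak ties are broken by map order.

The Bonferroni threshold is −log₁₀(α/m). Support intervals span the mapped
markers immediately adjacent to the peak in map order (no LOD-drop method);
a peak at a chromosome end yields a flagged one-sided interval. Concordance
tables cross-tabulate observed phenotype against genotype classes under a
user-supplied diagnostic rule, counting discordant lines and excluding
(separately counting) lines missing either value. Covariate rescans enter the
peak as a fixed covariate and exclude it from testing.
Founder-probability (identity-by-descent) mapping is intentionally out of
scope — single-marker regression suffices to place a major locus.

## Known limitations

- The two-stage scan holds variance components at their null estimates; for
  a very large marker effect the components are mildly misestimated, which
  affects p-value scale (not peak location) and is irrelevant to thresholded
  decisions in practice.
- LD treats residual heterozygotes as missing; at early generations (F2–F3,
  ~25% heterozygosity) the inbred-line assumption would discard much of the
  data and an EM phasing step would be needed.
- The folded-spectrum founder generator is exchangeable across founders; real
  variety panels have pedigree-driven founder relatedness.
- `select_replicated_eight_ways` supports usages 1–3 (the 8-founder pairing
  graph's degree); other founder counts enumerate correctly but the selection
  solver assumes 3-regularity.
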