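# magicpop

Design, simulation and genetic analysis of eight-founder MAGIC (Multiparent
Advanced Generation Inter-Cross) populations, written for quantitative
geneticists and breeders who want to plan, emulate or analyse funnel-crossed
recombinant inbred line (RIL) panels such as the winter-wheat MAGIC
populations.

## What it does

A MAGIC funnel combines eight founders through the scheme
`{[(A×B) × (C×D)] × [(E×F) × (G×H)]}`. Identifying reciprocal crosses, eight
founders admit

- n(n−1)/2 = **28** two-way (F1) crosses,
- n(n−1)(n−2)(n−3)/8 = **210** four-way crosses (pairs of founder-disjoint
  F1s), and
- **315** eight-way crosses (pairs of complementary four-ways, e.g. ABCD with
  EFGH, EGFH or EHFG).

`magicpop` covers the full pipeline around that design:

- **design** — enumerate all cross tiers; select a replicated subset in which
  every four-way is used exactly *k* times (the each-four-way-twice design
  keeps 210 of the 315 eight-ways, found as a 3-regular pairing graph minus a
  perfect matching); substitute failed crosses by relatedness; allocate RILs
  to families as equally as possible; build the single-seed-descent (SSD)
  pedigree.
- **simulate** — founder genomes over a centiMorgan map (folded-spectrum
  allele frequencies, founder-private alleles), meiosis under the Haldane map
  function, the funnel and SSD to F(1+t), founder-of-origin mosaics, a fully
  penetrant monogenic recessive trait, and missingness/error degradation.
- **qc** — variety-panel (maf ≥ 0.01, <10% missing) and MAGIC
  (line call rate ≥ 75%, marker success > 0.91, maf > 0.05, perfectly
  correlated duplicates pruned) filters; expected heterozygosity
  He = 2p(1−p) summaries and panel-to-panel diversity ratios.
- **ld** — D, D′ = |D|/D_max and r² from inbred-line haplotypes, heatmap
  matrices on 250 cM-padded genome coordinates, lowess-smoothed decay curves
  (span 0.1).
- **segregation** — the recessive class frequency under selfing from a
  random-mated base, f(q, t) = q² + q(1−q)(1−2^(−t)), expected/observed
  ratios and a 1-df chi-square goodness of fit.
- **scan** — `AssociationScan(genotypes, phenotype, strata).fit()` returns a
  `ScanResult`: a per-marker mixed-model scan with random intercepts for
  funnel and plant-within-funnel (variance components by REML, marker tests
  by a 1-df likelihood ratio on GLS-whitened data), Bonferroni thresholds on
  the −log₁₀ scale, peak support intervals from map-adjacent flanking
  markers, diagnostic-marker concordance tables and covariate rescans.

## Worked example

```python
from magicpop import design, simulate, qc, scan, segregation

fourways = design.enumerate_four_way(8)
eightways = design.enumerate_eight_way(fourways)
plan = design.select_replicated_eight_ways(eightways, per_fourway_usage=2, seed=1)
alloc = design.allocate_rils([ew.id for ew in plan.eightways], 700)
ped = design.build_pedigree(plan, alloc, ssd_generations=6)

gmap = simulate.generate_map(21, 48, 150.0, seed=3)
causal = gmap.markers[500]                      # private to founder H
panel = simulate.generate_founders(gmap, 8, private_allele_spec={causal: "H"}, seed=4)
geno, mosaic = simulate.simulate_magic(plan, ped, panel, gmap, seed=5)
pheno = simulate.attach_recessive_trait(geno, causal)

filtered, report = qc.filter_magic_panel(geno, gmap=gmap, return_report=True)
strata = scan.StrataDesign.from_pedigree(ped)
result = scan.AssociationScan(filtered, pheno, strata=strata, gmap=gmap).fit()
```

This prints (via the obvious `print` calls):

```
210 eight-way crosses, 700 F7 RILs
residual heterozygosity at F7: 0.0059
recessive-class frequency: 0.091
QC kept 700 lines x 1004 markers (4 perfectly correlated markers pruned)
expected segregation at F4: 7.98:1
Bonferroni threshold (1%): 5.00
peak marker: 4B_m0019, -log10 p = 824.8
support interval: 2.15 cM on chromosome 4B
```

Reading the numbers: six selfing generations leave ~0.6% residual
heterozygosity (the eight-way F1 starts at ~34% and halves each generation);
the recessive class segregates near the q = 1/8 carrier expectation, and the
closed-form expectation at the F4 generation — where such traits are scored —
is 7.98:1 dominant:recessive. The scan's peak lands 0.06 cM from the causal
site: the causal marker itself was pruned during QC because a neighbouring
marker duplicated it perfectly, so its retained proxy carries the association
— exactly the situation diagnostic-marker tables are used to check. The
recessive-class frequency (0.091 here vs the 0.123 F7 expectation) drifts
between simulations because RILs within a family share descent.

Each module is also exposed as a CLI subcommand
(`magicpop design|simulate|qc|ld|segregation|scan`), reading and writing
tab-delimited tables (and optionally VCF v4.2 for genotypes).

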