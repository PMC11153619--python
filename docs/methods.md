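# Methods

## The detection problem

A young sex-determining region (SDR) leaves two orthogonal traces in
sex-pooled whole-genome sequencing. In the heterogametic sex (males, for an
XY system), every individual is heterozygous X/Y at sites where the two
gametologues have diverged, so the pooled alt-read fraction concentrates at
0.5 while the homogametic pool stays homozygous; and sequence that exists
only on the Y is hemizygous — covered at half the diploid rate in the male
pool and at essentially zero in the female pool. Both traces are weak per
site or per base but strong positionally: real sex-linked divergence is
clustered in one genomic block, while the screen's false positives scatter.
Every stage in this package is therefore a per-site (or per-base) filter
followed by distance clustering and a genome-wide ranking.

## SNP screen

Per pool, the genotype is classified from the alt fraction
f = (alt_fwd + alt_rev) / (DP4 total):

| class | condition |
|---|---|
| LOW_DEPTH | total < `min_depth` (default 15) |
| HOM_REF | f ≤ `hom_max_frac` (default 0.07) |
| HOM_ALT | f ≥ 1 − `hom_max_frac` |
| HET | `het_low` ≤ f ≤ `het_high` (default 0.45–0.55) |
| AMBIGUOUS | otherwise |

All bounds are inclusive; whether the original screen treated boundaries
strictly is not recoverable, so inclusivity is declared and tested at the
boundaries explicitly. Total depth is the DP4 sum rather than the caller's
DP, so the thresholds see exactly the per-allele counted reads. Both pools
must pass `min_depth`. XY mode keeps male-HET with female-HOM_REF *or*
HOM_ALT (the reference base may itself be the Y allele); ZW mode
interchanges the sexes. INDELs and MNPs are screened like SNPs and can be
excluded with `--snps-only`.

At pool depth ~40 the alt-fraction of a true 0.5 site has a binomial
standard deviation of ~0.08, so the strict 45–55% window retains roughly
half of the truly sex-linked sites (the exact Poisson-binomial value at the
defaults is 0.475). This is intrinsic to the thresholds, not a defect: the
discovery signal is the cluster count, and ~50 retained sites in one 66-kb
block still dwarf the background. Consequently "recovery" of a planted
region is measured positionally — does the rank-1 cluster overlap the true
block and span the planted sites — not as per-site retention, which the
acceptance summary reports honestly as its own quantity.

## Clustering and ranking

Single-linkage by gap on 1-based point positions: consecutive positions
join one cluster iff their distance is ≤ `max_gap` (default 9000 bp, the
merge distance also used for coverage runs). Clusters never span contigs.
The gap rule is applied to the simplest reading of "maximal distance of
variants" — merge iff p_{i+1} − p_i ≤ max_gap — with the boundary case
(equality merges) fixed and tested, since distance-merge tools differ by
one at the boundary. Duplicate positions (e.g. SNP and INDEL at one site)
collapse to one point for clustering. Ranking is by member count
descending, ties by span descending then (contig, start); singleton
clusters are kept by default (`min_cluster_size = 1`). The XY and ZW scans
run side by side and the ratio of their top counts is the screen's contrast
statistic; an empty side yields NA rather than a division error.

## Coverage scan

The two bedgraph tracks are unioned on their common breakpoint refinement
(absent coverage = 0, each input's total mass preserved), then each is
normalized by its own modal coverage peak: the span-weighted mode of the
integer coverage values, zero excluded, ties to the smallest value — the
dominant nonzero peak of a whole-genome coverage histogram is the diploid
depth, and normalizing by it puts diploid sequence at 1.0 regardless of
library size (scale invariance is a tested property). The mode is taken
genome-wide per track, not per contig: sex-linked sequence is a negligible
fraction of the span. A base is selected iff normalized male coverage lies
in [`male_low`, `male_high`] = [0.25, 0.75] (inclusive) and normalized
female coverage is < `female_max` = 0.05 (strict, as printed in the source
description of the method). Selected runs merge across gaps ≤ `max_gap`;
a cluster's score is its selected-base count (gaps are not counted), so
scores are conserved under any re-chunking of the input intervals.
Read-level artifacts (mappability, GC bias) are assumed handled upstream;
the track is taken as given.

## Cross-species amplicon stage

Individuals sequenced at deep amplicon coverage are genotyped with the same
fraction windows as the pools, with `min_depth` raised to 30 — at depths in
the hundreds the fraction estimates the genotype tightly, and one shared
classifier keeps the semantics identical across stages. Per species, a site
is male-specific when every informative male is HET and every informative
female homozygous; LOW_DEPTH samples are excluded from the quorum (target
enrichment is uneven and a dropout should not veto a site), but at least
one informative sample per sex is required. Strictness is a parameter
(`max_discordant` per sex, default 0). Sites are matched across species by
shared reference coordinates only — no liftover — and stratified by the
number of supporting species k; anti-monotonicity of the k-filter is a
tested invariant.

## Simulator

The generator plants known truth into the statistical structure the scans
assume, per site and per bin, with one PCG64 stream
(`numpy.random.default_rng(seed)`) consumed in a fixed order so a seed
yields byte-identical outputs.

* **Background SNPs** at rate 0.002/bp; population alt frequency
  p ~ U(0.05, 0.5); each pool's allele count ~ Binomial(2n, p) with n = 22
  individuals per pool (the study-scale pool size), independently per pool
  and per site. Linkage is deliberately not modelled: every stage is
  per-site plus positional clustering, so LD does not affect the
  correctness surface being tested.
* **Reads**: site depth ~ Poisson(40) per pool; alt reads
  ~ Binomial(depth, q(1−ε) + (1−q)ε) with ε = 0.002 — miscalls are folded
  into the draw probability because the screen only ever sees counts —
  and strands split Binomial(·, 0.5). Sites with zero alt reads in both
  pools are not emitted (a caller would not report them).
* **SDR**: one 66-kb block carrying 100 divergent sites at q = 0.5 in the
  heterogametic pool and q = 0 in the other (ZW mirrors the sexes).
* **Y insertion**: a separate 55-kb contig with no variants; per-base
  coverage Poisson at λ/2 in the male pool and λ·0.01 in the female pool
  (the small spurious female coverage emulates mismapping), versus λ
  elsewhere. Coverage is per-base Poisson emitted as bin-averaged values
  (Poisson(λ·width)/width per bin, default 100 bp) to keep bedgraphs small.
* **Amplicon panel**: five species with (4♂3♀, 5♂4♀, 5♂3♀, 4♂5♀, 4♂5♀)
  samples over an 80-kb region; 30 shared male-specific sites in a 5-kb
  5′ block and 10 species-private male-specific sites per species
  elsewhere; per-sample counts Binomial at Poisson(800) depth.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: within-pool population structure (the real
pools mixed two closely related taxa), linkage disequilibrium, mapping and
reference bias, repeat-driven coverage artifacts, indel realignment noise,
and caller-specific genotype-likelihood behavior. The planted signal is
idealized (fully sex-linked, fully divergent); partially sex-linked or
recombining regions would show intermediate allele-balance signatures that
the fixed windows handle less cleanly.

## Numerical and design choices

* Coordinates: VCF positions 1-based; BED/bedgraph 0-based half-open; all
  cluster arithmetic on 1-based points, converted only when writing BED.
* VCF depth dialects: per-sample DP4 quadruples preferred, per-sample AD
  (ref, alt) accepted with strands pooled; records with neither are
  skipped and counted, multiallelic records are skipped (the screen is a
  two-allele test and decomposition would need depths the dialect may
  lack).
* Modal-peak ties break to the smallest value; an all-zero track is a hard
  error rather than a silent 0-division.
* Desk-scale default genome for simulations: one 10-Mb contig plus the Y
  contig — large enough that ~20,000 background SNPs exercise the
  false-positive behavior of every filter, small enough that a full
  20-seed recovery study runs in well under a minute per stage.
* Empirical false-positive rates (background SNPs passing the screen,
  autosomal bases passing the coverage selection) depend directly on the
  error rate and are reported by the acceptance summary rather than
  asserted at a fixed bound.

## Known limitations

The screen's fixed fraction windows are tuned to the pooled design (equal
pool sizes, moderate depth); very deep pools would warrant narrower het
windows, very shallow ones wider. The coverage stage's strict female bound
(< 0.05) makes boundary bases sensitive to the integer modal estimate at
low spurious coverage. Cross-species intersection assumes a shared
reference; coordinate drift between assemblies is out of scope, as are
statistical significance tests for cluster sizes — the method reports
ranked descriptive counts, and its validation here is recovery of planted
truth, not a null model.
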