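# Methods

## Chromosome-quotient model

The classifier assumes one male and one female sample mapped to a common
assembly, with depth reported per base after upstream mapping-quality
filtering (MAPQ ≥ 30 is the usual choice; that filter lives upstream of
the depth table and is not applied here). Copy number drives expectation:
with single-copy coverage c per sex, expected depth is c on autosomes in
both sexes, c (female) vs c/2 (male) on the X, and 0 vs c/2 on the Y.

**Modal depth.** Single-copy coverage is estimated as the argmax of the
integer depth histogram over depths ≥ 1, pooled over scaffolds of length
≥ `min_scaffold_len`. Zeros are excluded because zero-depth loci are the
object of the disqualification rules, not coverage evidence; short
scaffolds are excluded because their depth is noisy. Ties break toward
the smaller depth for determinism. Note that a Poisson depth distribution
with integer mean λ has exactly tied mass at λ−1 and λ, so on simulated
data the estimate legitimately alternates between the two across seeds;
this shifts normalized ratios by at most ~1/λ and at most one histogram
bin, and is visible (and harmless) in the acceptance quantities.

**Disqualification (DQ).** Per locus: male raw depth 0 → `DQ_MALE_ZERO`;
otherwise normalized depth > `max_norm_depth` (default 3) in *either* sex
→ `DQ_HIGH_DEPTH`. The high-depth rule is applied symmetrically because
its motivation — repeats and collapsed duplications — affects both sexes.
Female raw depth 0 at a retained locus gives ratio exactly 0, with no
pseudocount: the density of near-zero ratios *is* the Y-linkage signal,
and smoothing it away would destroy the signature.

**Windowing.** Windows are non-overlapping, tiled from position 1 of each
scaffold, 1-based inclusive, default width 5 bp. The window statistic is
the arithmetic mean of the locus ratio over OK loci only (DQ loci do not
renormalize the window; they are simply absent); windows with no OK locus
are omitted and a final partial window is kept when it has ≥ 1 OK locus.

**Classification.** Per scaffold the window means are binned at width
`ratio_bin_width` (0.1) over [0, `max_norm_depth` + 1], values above the
top edge clipping into the last bin and histogram ties breaking toward
the lower bin. The label is decided in this order:

1. length < `min_scaffold_len` (1 Mbp) → `UNASSIGNED_SHORT`;
2. no windows → `AMBIGUOUS` (scaffolds present in the index but absent
   from both depth inputs are reported this way rather than dropped);
3. fraction of windows below `y_ratio_cutoff` (0.3) ≥ `y_low_fraction`
   (0.5) *and* modal bin midpoint < 0.3 → `Y_LINKED` — the Y test runs
   before band membership because trace female mapping can lift a Y
   scaffold's modal bin slightly off zero;
4. modal midpoint in `x_band` [1.7, 2.3] → `X_LINKED`;
5. modal midpoint in `autosome_band` [0.7, 1.3] → `AUTOSOME`;
6. otherwise `AMBIGUOUS`.

The band edges, low-ratio cutoff and majority fraction are design choices
of this package: the underlying procedure reads the labels off a ratio
density plot, so any quantitative cutoff is a formalization. The defaults
are centered on the copy-number expectations with generous width, and all
are exposed in `CQConfig` / the CLI.

A separate `verify_hemizygosity` check flags a scaffold whose mean male
normalized depth over retained loci falls in `hemizygosity_band`
[0.3, 0.7] — ~0.5× is what single-copy (hemizygous) Y sequence must show
in a male normalized by the autosomal mode.

## ROH length classes

Segment lengths partition into short (< 1 Mbp), medium ([1 Mbp, 5 Mbp],
closed — the only boundary reading under which the three printed ranges
tile all lengths) and long (> 5 Mbp). Per individual the package reports
counts and cumulative coverage per class and a shared-bin normalized
length histogram (canonical; a KDE rendering exists for plotting only).
Overlapping segments within an individual are summed as-is — the upstream
HMM caller is responsible for emitting non-overlapping runs.

## Synthetic generator

`simulate_depth_pair` emulates the post-mapping depth signal directly (no
reads, no alignment): per-locus expected depth = coverage × copy factor
(autosome 1/1, X 0.5/1, Y 0.5/0 for male/female), with

* counts Poisson by default, or gamma-mixed Poisson with variance
  mean × (1 + `dispersion`);
* `repeat_fraction` of loci (default 0.01 in the scarab scenario)
  with expectation multiplied by `repeat_multiplier` (5) in both sexes —
  representing the small minority of collapsed-repeat loci that survive
  MAPQ filtering with inflated depth, most of which the > 3× DQ rule then
  removes;
* `dropout_rate` (0.001) of loci forced to zero depth per sex
  independently (local mapping failure);
* on the Y, `y_female_contamination` (0.005) of loci receive sparse,
  low-mean female coverage (mean 0.05 × female coverage) instead of a
  uniform lift, so the near-zero ratio density survives contamination.

Coverage defaults (male 65×, female 60×) match a HiFi male plus Illumina
female design. The scarab scenario has 9 autosomes, one X and one
1.1 Mbp-proportioned Y; only the largest autosome (93.2 Mbp) and the Y
are pinned lengths, the rest interpolate an N50 of 69.5 Mbp reached at
the 4th scaffold. On the Y, repeat-inflated male loci (~2.5× normalized)
escape the symmetric DQ rule because the female side is zero; with the
1% repeat fraction this lifts the mean male normalized depth from 0.50
to ≈ 0.52–0.53, still well inside the hemizygosity band — a deliberate
stress on the check rather than a calibration of it.

What the generator does **not** model: mappability structure, GC bias,
partial sex-linkage within a scaffold, pseudoautosomal regions, allele
dropout correlated along the genome, and read-level errors. Passing tests
therefore demonstrate that the statistics recover the copy-number signal
they target under a faithful coverage model, not that real libraries are
free of the artifacts the DQ rules exist for.

`simulate_roh_set` draws per-individual segment counts Poisson(40),
classes from mixture weights (default 0.9/0.1/0.0 short/medium/long),
lengths log-uniform within each class range, and places segments without
overlap by partitioning each scaffold's free space with Dirichlet gaps.
Counts and length laws are package choices of a realistic
reduced-representation ROH callset; the class structure is what the
summaries consume, so tests condition on it, not on the length law.

## Problem sizes and numerics

Simulation-based tests and the acceptance script run the scenario at
scale 0.01 (≈ 5.7 Mbp of loci per sex, ≈ 1.1 M windows), which keeps a
full pipeline run at a few seconds while leaving per-bin standard errors
of the window-ratio histogram around 2 × 10⁻³ — far below the 0.1 bin
width the classification reads. Truth recovery is asserted across 20
seeds at that scale. Ratio histogram bin membership uses half-open bins
with edge lookup via `searchsorted`, so values landing exactly on an edge
(e.g. a window of exact-ratio 2.0 loci) go to the upper bin regardless of
floating-point division artifacts. Window means are exact bincount sums
divided by counts; no accumulation tricks are needed at these sizes.

## Known limitations

* One male and one female sample; no replicate handling or ploidy other
  than XY male-heterogamety.
* Classification is per whole scaffold: a fusion of autosomal and
  X-linked sequence lands wherever its pooled ratio histogram peaks, and
  genuinely mixed scaffolds surface only as `AMBIGUOUS`.
* The depth-table surface means alignment handling (MAPQ filtering,
  duplicate marking) is the caller's responsibility.
* The ROH module consumes segment calls; it does not implement the HMM
  caller or the variant filtering upstream of it.
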