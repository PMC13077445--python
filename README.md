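# cqpipe

Chromosome-quotient sex-scaffold classification and runs-of-homozygosity
(ROH) length profiling, built for genome projects that have a male and a
female resequencing sample mapped to the same assembly — typically a
non-model organism with an XY system whose sex chromosomes cannot be
assigned from karyotype or synteny alone.

## The method

**Chromosome quotient (CQ).** On an XY system, males and females differ in
sex-chromosome copy number: autosomes are 2:2, the X is 2 (female) : 1
(male), the Y is 0 : 1. After normalizing each sex's per-base depth *d* by
that sex's **modal depth** *m* (the most frequent depth, a robust estimate
of single-copy coverage), the windowed female:male ratio

&nbsp;&nbsp;&nbsp;&nbsp;CQ = mean over a window of (d_F / m_F) / (d_M / m_M)

is expected to sit near **1** on autosomes, near **2** on the X, and near
**0** on the Y (where male normalized depth itself is ~0.5×, hemizygous
single copy). Before windowing, loci are disqualified (DQ) when the male
raw depth is 0 (male reads should map everywhere) or when normalized depth
exceeds 3 in either sex (repeats / collapsed duplications); loci with zero
*female* depth are retained with ratio exactly 0, since those are the Y
signature. Scaffolds shorter than 1 Mbp are reported `UNASSIGNED_SHORT`
rather than classified, and each remaining scaffold is labelled from the
most populated bin of its window-ratio histogram.

**ROH profiling.** Homozygous segments called upstream (e.g. by
`bcftools roh`) are classified as short (< 1 Mbp), medium (1–5 Mbp) or long
(> 5 Mbp) and summarized per individual as counts, cumulative coverage and
a length density. Short-dominated profiles indicate long-term small
effective population size; long segments indicate recent inbreeding.

A seeded synthetic generator produces two-sex depth tracks (with
copy-number structure, overdispersion, collapsed-repeat inflation, dropout
and trace female-on-Y contamination) and mixture-controlled ROH sets, so
every stage is testable without sequencing data.

## Worked example

```sh
cqpipe simulate --scale 0.002 --seed 1 --out-dir sim
cqpipe classify sim/male_depth.tsv sim/female_depth.tsv sim/genome.fai \
    --min-scaffold-len 2000 --out-prefix cq
cat cq.classification.tsv
```

```
scaffold     length  class     modal_ratio  frac_low_ratio  mean_male_norm  n_windows
scaffold_01  186400  AUTOSOME  1.05         0               1.00016         37280
scaffold_02  162000  AUTOSOME  1.05         0               0.999732        32400
...
scaffold_10  56000   X_LINKED  2.05         0               0.499502        11200
scaffold_11  2200    Y_LINKED  0.05         1               0.521711        440
```

(whitespace aligned for readability; the file is tab-separated)

Each row is one scaffold: `modal_ratio` is the midpoint of the most
populated 0.1-wide bin of windowed female:male normalized depth ratios
(≈1 autosome, ≈2 X, ≈0 Y); `frac_low_ratio` is the fraction of windows
below 0.3 (≈1 only on the Y); `mean_male_norm` is the mean male normalized
depth over retained loci — ≈0.5 on the hemizygous X and Y, ≈1 elsewhere.
The labels recover the simulated truth (`sim/truth.tsv`) exactly.

For ROH summaries:

```sh
cqpipe simulate --scale 0.002 --seed 1 --roh-samples 46 --out-dir sim
cqpipe roh-summarize sim/roh.bed --out-prefix roh --plot
```

which writes per-individual category counts/coverage (`roh.profiles.tsv`)
and a per-individual length histogram (`roh.density.tsv`).

All parameters (window size, bands, DQ cutoff, coverages, …) are exposed
as CLI flags and via `--config` YAML; every run writes a JSON manifest
with input digests for reproducibility.

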