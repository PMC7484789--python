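# rloopkit

Quantitative analysis of R-loop resolution phenotypes in proliferating
cells. R-loops — co-transcriptional RNA:DNA hybrids with a displaced DNA
strand — obstruct replication forks, and chromatin remodellers such as
INO80 have been implicated in clearing them. Testing that idea requires
several unrelated quantitative readouts, and this package implements all of
them as one tested toolbox:

- **DNA-fibre analysis** — fork speed (`speed = length × 2.59 / pulse`,
  kb/min), sister-fork symmetry classification (< 25 % length difference),
  longer/shorter arm ratios and the fraction of > 2-fold asymmetric forks;
- **3D nuclear colocalization** — puncta segmentation (26-connectivity,
  ≥ 10 voxel size filter), voxel-overlap colocalization percentages,
  per-object property ANOVA, and the van Steensel cross-correlation
  function test for non-random colocalization;
- **Locus turnover kinetics** — the FC-I(log2) = log2(I_t2/I_t1)
  fold-change statistic for live-imaged locus reporters sampled every
  6 min, its positive/negative (formation/resolution) decomposition,
  condition-comparison verdicts, and recovery of birth–death rates
  (λ formation, µ resolution) from traces;
- **Genomic co-enrichment** — peaks-per-gene counting (BED, half-open),
  pairwise and expression-controlled partial correlation
  r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), chromatin-state fold
  enrichment with an exact conservation identity;
- **Growth epistasis** — the multiplicative independence expectation
  V = %growth_a × %growth_b / 100, rescue folds, and the growth-normalized
  cell-death index;
- **Synthetic data** — seeded generators for every input above with
  recorded ground truth (stall flags, colocalization flags, latent R-loop
  counts, direct-association effects, interaction terms), so each estimator
  is validated against a known answer.

It is aimed at cell and genome biologists quantifying replication stress,
R-loop dynamics or colocalization data, and at anyone needing a tested
reference implementation of these metrics.

## Worked example

```python
from rloopkit import fibre, kinetics
from rloopkit.synthetic import (FibreSimConfig, KineticsSimConfig,
                                gen_fibre_population, gen_locus_trace)

# fork speed for a 20 µm tract laid down in a 20 min pulse
print(fibre.fork_speed(20.0, 20.0))            # 2.59  (kb/min)

# a fibre population where 60% of origins carry one stalled fork
pop = gen_fibre_population(FibreSimConfig(n_tracks=250, stall_prob=0.6,
                                          stall_severity=0.7, seed=42))
s = fibre.summarize_pairs(pop.pairs)
print(s["frac_symmetric"], s["median_ratio"], s["frac_fold_asymmetric"])
# 0.244 2.433 0.584

# pooled FC-I over five simulated cells at a stationary locus
cells = [gen_locus_trace(KineticsSimConfig(seed=s)) for s in range(5)]
pooled = kinetics.pool_series([
    kinetics.fci_series(kinetics.relative_intensity(
        kinetics.LocusTrace.from_frame(c.trace)))
    for c in cells])
print(pooled.n_total, pooled.frac_pos, pooled.frac_neg)
# 1250 0.512 0.488
```

The fibre summary shows what stalling does to sister forks: only 24 % of
pairs remain within the 25 % symmetry band, the median longer/shorter ratio
is 2.4, and 58 % of pairs differ by more than 2-fold (the stall probability
was 0.6; noise pushes a few pairs across the cutoff in each direction). The
kinetics example pools 5 × 250 FC-I values from a locus at steady state:
positive (net formation) and negative (net resolution) intervals balance at
≈ 51 % / 49 %, as they must when formation equals resolution on average.

A full end-to-end run over synthetic inputs for every stage:

```sh
rloopkit demo --seed 0 --out demo_run
```

writes per-stage tables, summary JSONs and a checksummed run manifest under
`demo_run/`. Individual stages are available as
`rloopkit {simulate,fibre,coloc,kinetics,genomics,growth}` (see `--help`).

## Layout

```
src/rloopkit/
  synthetic.py    ground-truth simulators for every pipeline input
  fibre.py        fork speed, sister-fork symmetry, Tukey summaries
  imaging3d.py    3D segmentation, voxel-overlap colocalization, CCF
  kinetics.py     FC-I statistic, turnover verdicts, rate recovery
  genomics.py     peak counting, (partial) correlation, state enrichment
  growth.py       growth %, independence prediction V, death index
  io.py           TSV/BED/TIFF readers and writers
  cli.py          the `rloopkit` command-line interface
docs/methods.md   models, assumptions, numerical choices, limitations
```
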