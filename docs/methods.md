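# Methods

`rloopkit` implements the quantitative procedures used to characterize
R-loop resolution phenotypes: replication-fork metrics from DNA-fibre
spreads, 3D nuclear colocalization statistics, a locus-level turnover
statistic for live-imaged R-loop reporters, genome-wide co-enrichment
statistics, and growth-rescue epistasis arithmetic. Every stage can be run
against synthetic inputs with recorded ground truth, which is how the test
suite validates the estimators.

## DNA-fibre fork metrics (`rloopkit.fibre`)

Fork speed converts a labelled tract length to kb/min with the standard
fibre stretching factor,

    speed [kb/min] = length [µm] × 2.59 [kb/µm] / pulse [min].

Sister-fork pairs from a common origin are classified *symmetric* when
(longer − shorter)/longer < 0.25. The denominator choice (longer arm) is a
documented interpretation: it makes the criterion bounded in [0, 1) and
invariant to the order of the arms; the equivalent condition is
shorter/longer > 0.75. Fork stalling is summarized two ways: the
longer/shorter arm ratio per pair, and the fraction of pairs whose ratio
exceeds a fold cutoff (default 2, strict inequality). Pairs with one
zero-length arm have infinite ratio: they count as asymmetric but are
excluded from median ratios, with a logged count, rather than propagating
infinities. Pairs with both arms zero are undefined and excluded entirely.

Speed distributions are summarized as Tukey boxplots: quartiles by linear
(type-7) interpolation — stated so the brute-force oracle in the tests uses
the same convention — and whiskers at the most extreme observations within
1.5×IQR of the box. Group comparisons dispatch to the two-tailed unpaired
Student's t-test, Mann–Whitney U, or Kruskal–Wallis for multiple groups.

## 3D colocalization (`rloopkit.imaging3d`)

Puncta are connected components of voxels above an explicit intensity
threshold inside an optional nuclear mask. Connectivity is 26-neighbour by
default (configurable to 6/18), matching typical commercial 3D particle
analysis. Components under 10 voxels are discarded as background.
Thresholds are always explicit inputs (no silent automatic thresholding),
because any automatic rule would be an undocumented analysis choice.

Per object we report voxel count, intensity sum, centroid (µm) and length.
"Length" is defined here as the peak-to-peak extent of voxel centres
projected on the first principal axis of the object, widened by one voxel
footprint along that axis so a single voxel is one voxel long; commercial
packages do not disclose their length definition, so ours is stated
explicitly.

A channel-B object *colocalizes* when it shares at least one voxel with any
channel-A object; the summary statistic is the percentage of colocalizing B
objects. Colocalizing and non-colocalizing objects are compared per
property (intensity sum, volume, length) with one-way ANOVA.

Randomness of colocalization is tested with the cross-correlation function:
Pearson r between the two channels as one is translated voxel-wise along
one lateral axis (±`max_shift`), restricted to the in-mask overlap. The
reported peak is the shift that best realigns B with A. The verdict rule —
*nonrandom* iff r(0) is the global maximum and exceeds mean + 3 SD of the
baseline r at |shift| > max_shift/2 — is our own documented criterion; no
published cutoff exists for this use.

## Locus turnover kinetics (`rloopkit.kinetics`)

The reporter intensity at a tagged locus is normalized frame-wise by the
co-localized tag intensity; frames where the normalizer drops below 1 % of
its own trace median are dropped and counted. The fold-change statistic is

    FC-I(log2)_k = log2(I_k / I_{k−1})

over consecutive retained frames at the nominal 6-min spacing. Intervals
spanning dropped frames are excluded rather than rescaled, keeping all
values on a common time base (this is why a cell can contribute fewer
values than frames−1). Zeros are excluded from the sign decomposition and
counted separately; fractions are over all values.

Condition comparisons run Kruskal–Wallis (α = 0.05, configurable) on the
pooled totals, the positive subsets and the negative subsets; pooling
across cells rather than per-cell summaries preserves the interval-level
sample size. The verdict is a pure function of the three outcomes:

| total | positives | negatives | verdict |
|---|---|---|---|
| lower | lower | indistinguishable | net_formation_reduced_via_turnover |
| lower | lower | lower (more negative) | formation_suppressed |
| indist. | indist. | indist. | no_effect |
| anything else | | | inconclusive |

The turnover verdict captures the logic that unchanged resolution activity
(negatives) combined with reduced net accumulation (totals, positives)
implies enhanced turnover rather than suppressed formation.

### Birth–death model and rate recovery

The synthetic generator treats the locus R-loop count as an
immigration–death process: formation at rate λ (events/min), each loop
resolving independently at rate µ (per loop per min); stationary mean λ/µ.
Observed at interval dt, the exact transition is binomial survival with
probability e^(−µ·dt) plus Poisson births with mean (λ/µ)(1 − e^(−µ·dt))
(which → λ·dt as µ → 0). Using the exact transition — rather than
Poisson(λ·dt) births — makes the stationary mean exactly λ/µ and the
closed-form checks exact. The reporter is gain·N plus Gaussian noise,
floored at 10⁻⁶ so ratios stay defined; the normalizer is a noisy constant.

Rates are recovered from the moment relation E[ΔI | I] = a − b·I with
b = 1 − e^(−µ·dt) and a = g·(λ/µ)·b (g = intensity units per R-loop).
Plain OLS of increments on the lagged level is available but attenuated by
the per-frame measurement noise that enters both regressor and response
(errors-in-variables). The default estimator therefore instruments the
lagged level with the second lag — consistent when observation noise is
independent across frames — and applies the Kendall small-sample correction
ρ → ρ + (1 + 3ρ)/n to the implied autoregressive coefficient ρ = 1 − b,
which removes the well-known downward finite-sample bias of autoregression
estimates at ρ near 1. The raw intercept and slope are reported uncorrected
(and are exact on noise-free linear data); µ̂ = −ln(ρ)/dt is truncated at 0
with a flag, and λ̂ = a·µ̂/(g·b̂). Standard errors come from the regression,
with the delta method for µ̂. Under the default regime (λ = 0.5/min,
µ = 0.01/min, 251 frames) the mean recovered µ̂ over 100 traces is within
~15 % of truth; with λ = 0 the 95 % CI for λ̂ covers zero in ≥ 90 % of
traces.

## Genomic co-enrichment (`rloopkit.genomics`)

All coordinates are 0-based half-open (BED convention); overlap requires
≥ 1 bp. Interval arithmetic is delegated to pyranges. Peak abundance per
gene is the count of (200 bp) peaks overlapping the gene body; a peak
overlapping several genes counts for each. Spearman is the default
correlation for count abundances (heavy-tailed); Pearson is available.
The first-order partial correlation controlling for expression is

    r_xy·z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²)),

with p from t = r√((n−3)/(1−r²)) on n−3 df; the tests verify it against a
residual-regression oracle (and pingouin) to 1e−10.

Genome bins are classified by presence/absence of each peak type
(both / first-only / second-only / neither); fold enrichment of a region
class across a chromatin-state segmentation is

    fold(class, state) = (bp of class in state / class bp) ÷ (state bp / genome bp),

where the genome is the segmented extent and class regions are merged and
clipped to it — making the conservation identity (genome-fraction-weighted
mean fold = 1 per class) exact. Segmentations are consumed as 4-column BED;
training them is out of scope. DRIP-qPCR enrichment is
(IP/input) ÷ (IP_control/input_control), with an enrichment below 0.1-fold
flagged as background (the mock-IP situation).

## Growth epistasis (`rloopkit.growth`)

Growth percentages are relative to the matched control (either the
end-point control or a time-zero normalization; both are supported by
supplying the appropriate denominator). Under multiplicative independence
the expected combined growth of two perturbations is
V = %a × %b / 100 (percent scale, symmetric, homogeneous of degree two);
the rescue fold is observed/V. The death index is cytotoxicity
fluorescence divided by relative growth of the same population, reported as
fold over the untreated control (exactly 1 for the control itself, and
invariant to global rescaling of fluorescence units).

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* each estimator
assumes, with recorded ground truth:

- **Fibres**: per-arm speeds N(1.5, 0.35) kb/min (typical human fork
  speeds), 250 tracks and 20-min pulses per condition as in the emulated
  experiments. A stall affects one arm of a pair (probability `stall_prob`
  per pair, side uniform) and removes `stall_severity` of its length, so
  the noise-free ratio is 1/(1 − severity). Real fibre data add tract
  breakage, measurement error and origin mis-assignment, none of which are
  modelled.
- **Volumes**: spheres (analytic ground truth for volume/length), not
  irregular blobs; colocalized B objects are centred strictly inside an A
  object, non-colocalized ones are kept beyond the sum of radii, so the
  truth flag is unambiguous. The default colocalized fraction (0.4) sits in
  the middle of the 25–52 % range reported for hybrid–remodeller overlap in
  super-resolved nuclei. No PSF, no depth-dependent blur, no chromatic
  shift.
- **Traces**: the 6-min / 1500-min sampling regime (251 frames). Rate
  defaults (λ = 0.5/min, µ = 0.01/min, stationary count 50) are
  illustrative — no measured per-locus rates exist to fit — and are chosen
  so the signal-to-noise ratio resembles a bright locus array. No
  photobleaching or focus drift.
- **Gene tables**: both signals load on a shared lognormal expression
  covariate and a shared latent direct-association factor; counts are
  rounded, non-negative, laid out as disjoint 200 bp peaks on a toy
  single-chromosome genome with an exactly partitioning 20-state
  segmentation.
- **Plates**: per-well Gaussian noise around condition means; combined
  growth = effect_a × effect_b × interaction, interaction = 1 being the
  independence null.

Passing tests therefore demonstrate estimator correctness under the stated
models, not robustness to the optical, biochemical and mapping artefacts of
real data.

## Numerical choices and degenerate inputs

- Reproducibility: one `numpy.random.Generator` per generator call, seeded
  from the config; identical config ⇒ bitwise-identical tables.
- Quartiles: type-7; documented so oracles match exactly.
- Zero-length arms, empty object groups, empty region classes and
  below-floor normalizer frames are flagged/excluded with counts, never
  silently imputed.
- CCF shifts with empty overlap or zero variance are omitted and logged.
- µ̂ and λ̂ are truncated at zero with flags rather than reported negative.
- Problem sizes in the test suite (64³ volumes, 50–100 seeds, 2000-gene
  tables) were chosen as the smallest sizes at which the binomial /
  Monte-Carlo error bounds in the assertions are meaningful.

## Known limitations

- The colocalization percentage counts merged touching puncta as one
  object, so the observed B-object count can differ slightly from the
  generative count at high densities; the tests allow one object of slack.
- The CCF verdict criterion (peak at zero + 3 SD above far-shift baseline)
  is a heuristic; it is validated only on the synthetic null and
  translation constructions.
- The rate estimator assumes a linear reporter with frame-independent
  noise; multiplicative or autocorrelated noise would require a different
  instrument.
- qPCR conversion from Ct values is not implemented; inputs are linear
  quantities (a conversion assuming efficiency 2 would be trivial to apply
  upstream).
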