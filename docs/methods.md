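# Methods

## Scope and model

`domcycle` classifies the seasonality of monthly environmental time-series
(dissolved organic matter LC-MS features and 16S ASVs at fixed depths) and
quantifies the functional redundancy of metabolic genes in companion
metagenomes. It consumes already peak-picked, batch-corrected feature
tables and already annotated contig-level KO tables; peak picking,
retention-time alignment, batch-effect modelling, amplicon inference and
HMM searching are upstream concerns and out of scope.

## Feature QC

The filter cascade runs annotation → width → blank → RT consistency →
detection → pool RSD, with each stage emitting a per-feature decision
report whose counts reconcile (`n_out` of stage k equals `n_in` of stage
k+1). Threshold defaults: peak width < 15 s (strict), Gaussian shape
correlation > 0.6 with correlation-test p < 0.075, median-RT range < 5 s,
detection in > 50% of sample injections (strict; blanks and pools excluded
from the denominator), pool RSD < 20% over the first pool injection of each
batch (sample standard deviation, n−1, appropriate at n = 5 batches).

The data-adaptive blank filter uses mean log abundance with
log10(intensity + 1); the pseudocount handles undetected (zero)
intensities and is configurable. "25th quartile" is implemented as the
25th percentile with the linear-interpolation quantile definition.
Features are binned by the 20/40/60/80th quantiles of their mean log
abundance over samples + blanks; bins are left-closed, so a feature exactly
at a cut joins the upper bin. A bin with no negative sample−blank contrast
uses threshold 0 (keep features with positive contrast). Because of the
pseudocount, decisions are only approximately invariant to a global
intensity rescale; the invariance is exact in the large-intensity limit and
holds for the shipped worked example over a 20-fold scale range.

Peak profiles are screened with a four-parameter Gaussian (location, scale,
height, offset) fitted by Levenberg–Marquardt from several moment-based
starts; the score is the Pearson correlation between fitted and observed
intensities. Flat profiles have undefined correlation and fail. Pool-RSD
"detected in the pool" is evaluated over the same first-pool-per-batch
injections that define the metric; a feature absent from all of them passes
unconditionally.

An optional per-batch median-centering utility exists but is off by
default: tables are assumed batch-corrected upstream.

## Grid building

Dates map to calendar months regardless of day; replicate observations
within a month (e.g. diel campaigns) are averaged arithmetically. Interior
gaps are filled by linear interpolation between observed months; leading
and trailing gaps are never extrapolated (the grid trims to the observed
span). Undetected intensities enter as 0, not missing — zero is the
pipeline's "not detected" value and absence is biologically meaningful for
ASV series. The relative standard deviation (100·sd/mean, sample sd) of
the gridded values gates later classification; for a sampled cosine of
amplitude A it approaches A/√2 over whole periods. For bimonthly samples of
a 12-month cosine the interpolation error is bounded by (1 − cos(π/6))·A:
the midpoint of a 2-month gap sits π/6 radians from each knot.

## Wavelet engine

The Morlet continuous wavelet transform follows the Torrence & Compo
conventions: the series is standardized to zero mean and unit (sample)
variance, zero-padded to the next power of two, and convolved in the
frequency domain with daughters
ψ̂(sω) = π^(−1/4) √(2πs/δt) e^(−(sω−ω₀)²/2) for ω > 0 (the Nyquist bin
counts as positive). Defaults: ω₀ = 6 and 20 suboctaves per octave —
common analysis-package defaults — with δt = 1 month. The period grid is
geometric with ratio 2^(1/20), anchored so that the 12-month upper period
is an exact grid point (52 periods spanning 2.05–12 months); the "12-month
band" is the set of bins within half a suboctave step of 12 months, which
on this grid is exactly the top bin. Edge effects are retained — no
cone-of-influence masking — because the median-over-time statistics are
computed over all time points; COI masking is not applied anywhere.

Significance uses a pure simulation null: `n_permutations` (default 1000)
standardized Gaussian white-noise series of equal length are transformed,
and p(s,t) = (1 + #{null power ≥ observed}) / (1 + n_permutations); the
add-one correction avoids zero p-values. The simulation is vectorised (one
batched FFT per chunk of permutations) but is algorithmically identical to
a per-series loop.

Classification: the dominant period maximizes the per-period median power;
a series is *significant* when the median p-value at the dominant period is
≤ α (default 0.01) **and** its raw RSD exceeds 25%; it is *seasonal* when
additionally the dominant period falls in the 12-month band. The median
p-value is evaluated at the dominant period after selection (an
interpretation of the procedure; computing medians across all periods first
gives the same dominant-period argmax since the power matrix is shared).
For seasonal series the 12-month band is inverted with the Torrence & Compo
reconstruction constants (C_δ = 0.776, ψ₀(0) = π^(−1/4)) and the peak month
is the calendar month maximizing the climatological mean (average over
years) of the reconstruction — robust to interannual amplitude drift; the
single global maximum is available via `peak_mode="global_max"`. Seasons:
Jan–Mar winter mixed, Apr spring transition, May–Oct summer stratified,
Nov–Dec fall transition; the map is configurable.

Red-noise (AR1) nulls, cross-wavelet coherence and ridge extraction are
out of scope.

## Cohort summaries

The intersection table assigns each seasonal entity to its *exact* set of
depths, enumerating all non-empty subsets (15 rows for four depths), with
per-depth totals attached for marginal checks. Peak-season percentages are
reported within depth and entity kind. Median-power distributions are
compared with the two-sample Kolmogorov–Smirnov test; the asymptotic
p-value is used for cohort-scale samples (hundreds–thousands) and the exact
distribution below n = 30.

## Functional redundancy

Contribution evenness of a KO in a sample is
CE = (D_q − 1)/(S − 1), with D_q the Hill number of order q of the
per-contig RPKM contribution shares and S the SCMG-estimated richness.
The default q = 1 (exponential Shannon entropy) satisfies the metric's
defining endpoints — CE = 0 for a single contributor, CE = 1 when all S
members contribute equally — and those endpoint identities hold for any
q > 0; q is a parameter. CE is defined as 1 when S = 1 and clipped to
[0, 1] with a warning when the effective contributor number exceeds S
(possible when contributors outnumber SCMG-estimated richness). Each contig
is one community member's gene copy; contigs are not aggregated by taxon
for CE (taxon aggregation serves only the functional-taxonomy view).

Richness is the median across the ten SCMG KOs of per-marker distinct
contig counts, rounded half-up — robust to a single anomalous marker; sum
and mean are options. Non-SCMG HMM hits are kept at e-value ≤ 1e−10
(boundary inclusive); SCMG hits are kept by their precomputed score-
threshold pass flag. Core genes require presence (≥ 1 passing contig) in
strictly more than 85% of samples. Functional taxonomy divides a
taxonomic group's RPKM by the total annotated RPKM per (sample, KO);
unannotated contigs are excluded from the denominator, and a KO with zero
annotated RPKM in a sample is omitted (undefined contribution). Group
comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney) test: exact
when both groups are tie-free, normal approximation with tie correction
otherwise, and p = 1 with a warning for fully tied degenerate input.
Significance thresholds: 0.01 for metabolite-level and 0.1 for
season-level comparisons, both configurable.

## Mass annotation

The embedded monoisotopic mass table (H 1.0078250319, C 12 exactly,
N 14.0030740052, O 15.9949146221, P 30.97376151, S 31.97207117, electron
0.00054858 Da) follows the CODATA/IUPAC most-abundant-isotope values.
Printed fragment masses follow the neutral-moiety convention (H₂PO₄ =
96.969); anion/cation conventions add/subtract one electron mass. ppm
matching is boundary-inclusive at ±1 ppm by default; analog deltas compare
neutral masses with a 1 mDa absolute tolerance by default.

## Synthetic data generator

The generator emulates the study design it stands in for: a 37-point
monthly grid (July 2016 – July 2019) at four depths (1, 40, 120, 200 m),
with a configurable fraction of entities carrying a cosine of 2–12 month
period anchored so its maximum falls in a chosen calendar month (default
July, amplitude 10 on baseline 100, Gaussian noise sd 2), optional
partial-year entities whose sinusoid exists only in the grid's second
12-month window, process blanks (one per monthly sampling event), two pool
injections per batch across five batches, and an exact
`round(fraction · n)` subset of blank contaminants constructed with blank
mean ≥ sample mean. Community tables carry `S_true` taxa per sample, one
contig per taxon per SCMG, and per-KO carrier contributions drawn from a
symmetric Dirichlet whose concentration is the single evenness knob
(infinite concentration = exactly equal shares). Noise is Gaussian white
noise — the classifier's null hypothesis — with Student-t noise available
but off by default. All generators are seeded (per-entity seed sequences)
and bit-reproducible.

What the generator does not emulate: chromatographic peak shapes and raw
spectra, retention-time drift, compositionality of relative abundances,
autocorrelated (red) environmental noise, taxon-correlated KO co-occurrence,
and uneven real-world sampling gaps beyond the bimonthly pattern. Passing
tests therefore demonstrate algorithmic correctness and calibration under
the white-noise model, not robustness to red noise or compositional
artifacts in field data.

## Numerical choices and problem sizes

Quantiles use numpy's linear-interpolation definition throughout. Sample
(n−1) standard deviations are used everywhere. Ties in the peak-month
climatology resolve to the earliest calendar month via argmax. Constant
series cannot be standardized and are rejected by the transform; constant
profiles fail the shape screen with undefined correlation.

The test suite's simulation sizes — 500 white-noise replicates at 1000
permutations for calibration, 100 entities at signal-to-noise 2 for
peak-month recovery, 1000 random majorization pairs for Schur-concavity,
cohorts of 30 entities for the full-length vs partial-year power
comparison — were chosen to give three-sigma Monte-Carlo margins on every
asserted rate while keeping the default run under a minute of wavelet
computation.

## Known limitations

- The permutation null is white noise only; serially correlated series can
  be over-called seasonal relative to an AR1 null.
- Median p-values over time points are dependent across cells; the 0.01
  threshold on the median is a decision rule, not a familywise error rate.
- The blank filter's pseudocount makes decisions scale-dependent for
  intensities near zero.
- CE with q = 1 weights contributions logarithmically; rankings can change
  with q when contribution distributions cross.
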