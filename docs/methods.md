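# Methods

## Problem and scope

Transcutaneous bilirubin screening from smartphone images asks whether the
mean red/green/blue intensity of a small glabella skin patch, acquired
through a dermatoscope, carries enough signal about total plasma bilirubin
(TsB, μmol/L) to flag newborns above a clinical warning threshold
(205 μmol/L). The package implements the complete analysis — image review,
uniform-region intensity extraction, correlation, discrimination-limit
screening, and the auxiliary analyses (outlier exclusion, block summaries,
stepwise regression) — plus a synthetic data generator that defines the
study conditions, since the underlying clinical images are not publicly
available.

## Synthetic cohort model

**TsB.** A log-normal truncated to [28, 289] μmol/L. The log-scale SD is
fixed at 0.45; the log-location is solved (Brent's method on the truncated
quantile equation) so that the *truncated* median equals 155 μmol/L. The
solve matters: upper truncation removes ~7% of the untruncated mass, and a
naive location of log(155) leaves a truncated median near 148. Log-normal
was chosen over a symmetric normal because TsB is positive and clinically
right-skewed; median and range are the only distributional summaries
available, so the shape is the minimal assumption consistent with them.
Setting the log-SD to 0 degenerates to a point mass (used in tests).

**Covariates.** Gestational age: truncated normal (mean 39.8, SD 1.4 wk)
on [35, 41], rounded to whole weeks. Postnatal age: 3 days plus a
floor-of-exponential excess (scale 1.25 d) truncated at 9 days — this
reproduces a median equal to the minimum (3 d), as expected when the
metabolic-screening heel-prick visit anchors enrolment. Birth weight:
truncated normal (3455 ± 450 g) on [2440, 4900]. Haemoglobin: truncated
normal (12.4 ± 1.6 mmol/L) on [9.1, 16.9]. Sex: Bernoulli, 51% female.
An optional transcutaneous bilirubin (TcB) value is TsB plus N(0, 17)
noise, clipped at zero; it is carried in the data model but no TcB-specific
statistics are computed. Covariates are drawn independently of TsB.

**Image model.** Expected intensity of channel c for a subject is

    mu_c = alpha_c + beta_c · TsB + gamma_c · postnatal_age

with one N(0, sigma_subj,c) draw per subject and N(0, sigma_pix,c) per
pixel; pixel values are rounded half-away-from-zero (bit-stable across
platforms) and clipped to [0, 255]. Defaults: alpha = (170, 120, 110),
beta = (0.05, 0.25, 0.15) counts per μmol/L, gamma = (0.3, 0.8, 0.5)
counts per day, sigma_pix = 6; image size 64×64. The small postnatal-age
term exists so stepwise regression has a real (but weak) covariate effect
to find. An expected mean outside [0, 255] raises a calibration error
before any noise is added.

**Calibration.** The population correlation between the extracted mean
intensity and TsB is r = beta·sd(TsB) / sqrt(beta²·var(TsB) + V), where V
collects all TsB-independent variance (subject noise, the age term, and a
negligible pixel-noise remainder after averaging ≥256 pixels). Given the
analytic variance of the truncated log-normal (by quadrature) and the
age-term variance (exact, from the discrete excess pmf), sigma_subj,c is
the closed-form value that makes r hit the targets 0.59 (green), 0.46
(blue), 0.21 (red). The slopes beta are fixed first, at scales that keep
the rendered range clear of 8-bit clipping even three subject-SDs out; the
intercepts place typical skin around (178, 162, 139). Consequences worth
noting:

- The intensity *location* is arbitrary (raw per-subject intensities are
  not published), so on synthetic cohorts the meaningful green/blue
  discrimination limit comes from the threshold scan, not from the
  clinical values 212/190 that belong to the original intensity scale.
  Those values are the pipeline defaults for real-image runs and are
  exercised by the worked-example statistics.
- With r = 0.21 and n = 51 the red channel is expected to be
  non-significant (p ≥ 0.05) in roughly two-thirds of cohorts, matching
  its reported null result; the replicate study measures ~69%.
- The positive green **and blue** slopes mirror the reported positive
  correlations. Naive absorption physics predicts the blue channel should
  *fall* with bilirubin; the spectral module (below) shows exactly that
  behaviour. The generator reproduces the measured statistics, not the
  optics — the mechanism behind the positive blue correlation under
  dermatoscope illumination is an open question the data source leaves
  unresolved.

**Artifacts.** Hair is modelled as dark line segments (fixed darkening,
clipped at zero), specular reflections as small disks set to a near-255
level, both at seeded random positions; the count of touched pixels is
recorded in image metadata so QC tests have an oracle. What the generator
does *not* emulate: cephalocaudal colour gradients, melanin/ethnicity
variation beyond a covariate hook, hydration status, illumination
non-uniformity, lens vignetting, and camera post-processing. Passing tests
therefore demonstrate correctness of the pipeline under the stated
statistical structure, not clinical performance on real skin.

## Image pipeline

Region selection scans every window position (summed-area tables) and
takes the square window minimising the summed per-channel population
variance; ties break to the smallest row, then column, of the top-left
corner. This automates what was a manual "most uniform area" marking, so
no claim is made that it replicates an investigator's choices; window side
defaults to 16 px. QC fails a region when >5% of its pixels saturate
(any channel at 255), when more than a configurable fraction deviate >3
within-region SDs from the region mean, or when the region is under 16
pixels. Note the 3-SD local rule can flag at most 1/9 of a sample
(Chebyshev), and one-sided contamination such as hair only while it covers
<10% of the region — heavier contamination inflates the SD until nothing
deviates. The default artifact threshold (0.10) is therefore a boundary
case; tests exercise the rule at a stricter configured threshold.
Summaries report the exact arithmetic mean, median and quartiles (linear
interpolation between order statistics) per channel. Block summaries tile
the mask's bounding box with non-overlapping 2–4 px squares fully inside
the mask and summarise block means — the reading of "average intensity of
4–16 pixels" adopted here.

## Screening statistics

Pearson r uses the textbook covariance formula with a two-sided p from
t = r·sqrt((n−2)/(1−r²)) on n−2 df; constant input is an error, not r = 0.
The outlier rule is single-pass: population mean and SD (denominator n),
drop |v−mean| > 3 SD, no re-iteration. Classification is strict on both
sides (intensity must exceed the limit; TsB must exceed the threshold), so
boundary subjects are negative; sensitivity or specificity with an empty
denominator is reported as undefined (None), never 0 or 100. The threshold
scan scores every integer limit 0–255 and reports the largest limit with
100% sensitivity — the implied selection rule for a screen that must miss
nobody while maximising specificity. Stepwise forward regression adds, per
step, the candidate with the smallest partial-F p-value (equivalent to the
squared-t test of the entering coefficient) when below the entry criterion
0.05 — the conventional default, as no criterion is stated in the source
analysis; ties break by candidate order, collinear candidates (pairwise
|r| ≈ 1) raise an error naming the pair. With a single null candidate the
first-entry rate is exactly the t-test size; with k candidates it grows
toward 1−(1−α)^k, which is why the 500-replicate type-I acceptance check
uses one candidate.

## Spectral module

An exploratory contrast to the phenomenological renderer: bilirubin as a
Gaussian absorption band peaking at 460 nm (default FWHM 100 nm),
oxyhaemoglobin as a 540/576 nm double peak, melanin as a monotone
decreasing power law — all parametric stand-ins, peak-normalised, since no
measured spectra accompany the analysis. Reflectance is two-pass
Beer–Lambert, R = exp(−2·path·Σ conc·ε). The Wratten No. 11 filter is a
piecewise super-Gaussian of order 4 with half-maximum points exactly at
483 and 589 nm and peak 1 at 516 nm ("cut-on/cut-off" read as half-maximum,
the filter-datasheet convention); order 4 keeps transmission below 1e-3
outside ~[430, 650] nm where a plain Gaussian would leak ~10% at 650 nm.
Camera sensitivities are Gaussian bands at 600/530/460 nm, FWHM 70 nm, and
the illuminant is flat — both device curves are unpublished. Channel values
integrate (trapezoid, 1 nm grid) reflected light normalised so a perfect
reflector renders (255, 255, 255). In this model the blue channel is
monotone non-increasing in bilirubin concentration — the physically
expected sign, documented and tested as the deliberate counterpoint to the
calibrated positive statistical correlation.

## Reproducibility and problem sizes

All randomness flows from one root seed; per-cohort and per-subject
streams derive by counter through `numpy.random.SeedSequence`, so partial
re-runs and repeated runs are bit-identical (PNGs, CSVs, JSON manifests
hash equal). Provenance manifests record the seed, a SHA-256 of the
canonicalised configuration (excluding filesystem paths, so identical
analyses hash identically wherever they run) and per-file checksums.

The replicate studies use 200 cohorts of n = 51 (the analysable cohort
size), 64×64 px images and a 16×16 analysis window — sizes at which the
replicate mean of r estimates the population value to ±0.01 or better while
a full study runs in seconds. The acceptance script reruns the entire
pipeline (no cached or stored values) at exactly these sizes.

## Known limitations

- The generator is statistical, not optical: it cannot say anything about
  why green outperforms blue and red on real skin, only reproduce it.
- The full blue-channel confusion table is not reconstructible from the
  published summaries (only sensitivity 10/11 and specificity 60% are
  given), so blue worked examples assert those two quantities only.
- Abstract and results sections of the source analysis disagree on blue r
  (0.48 vs 0.46); calibration targets 0.46.
- Real-image mode (a directory of PNG/TIFF/JPEG patches plus a subject
  table) exercises the same code paths but has only synthetic coverage
  here; JPEG input is accepted with a warning about lossy intensities.
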