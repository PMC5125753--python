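# Methods

This note records the models the package implements, the defaults it
ships, the design decisions taken where the procedure was genuinely
open, and what the synthetic-data studies do and do not demonstrate.

## Track model and statistics

A track is a time-ordered sequence of 2-D positions (μm, seconds) with
oocyte/movie/genotype labels. The anterior reference frame is a point
on the anterior cortex plus a unit vector pointing into the oocyte;
"distance from the anterior" is the signed projection onto that vector
at the track's first position, and a movement is anterior-directed when
the net (initial→final) displacement has a negative projection.

Per-track summaries follow the conventions of manual-tracking studies:
speed is the mean of the frame-to-frame velocities (not net
displacement over duration), path length is the sum of step lengths,
and direction is taken from the initial→final vector. The binary
anterior/posterior class is the sign of the net anterior component, so
the two classes always partition the data (the published frequency
tables sum to 100%). The three-way class adds a "lateral" sector;
since no published definition exists, the default is symmetric ±45°
sectors about the anterior and posterior directions, configurable.
Windcharts default to 30° bins, again configurable, because the
published figures show angular histograms without stating a bin width.

Mobile fractions count a particle as moving when its maximum
displacement from its first position within a 5 s window exceeds a
threshold; the default threshold is 0.5 μm per window, a logged
configuration value chosen to sit well above localisation noise
(~0.02 μm) and well below a directed run at ~0.8 μm/s. An exclusion
distance can drop particles near the anterior, where density precludes
single-particle discrimination. Reversals require the along-axis step
sign to flip **and persist for ≥ 2 consecutive frames**, suppressing
single-frame localisation-noise flips.

Speed comparisons use the two-sided Wilcoxon rank-sum test and a linear
mixed model (response: per-track speed; fixed effect: genotype; random
intercepts: oocyte, and movie nested in oocyte). The mixed-model
p-value is a likelihood-ratio test between maximum-likelihood fits with
and without the fixed effect. ML (not REML) is used so the two
likelihoods are comparable. Caveat, measured directly in the
calibration studies: the χ² reference distribution is anticonservative
when the fixed factor varies only across a handful of clusters
(rejection ~10–14% at 6–20 oocytes with oocyte-level genotype, a known
small-cluster property of the LRT that R's lme4 reproduces to within
|Δp| < 0.01 of this implementation). The shipped calibration study
therefore uses a design in which the factor varies within movies
(10 oocytes × 2 movies × 10 observations), where the measured type-I
error is 5.0% over 300 simulations.

## Recovery kinetics

The pipeline mirrors the published procedure exactly:

1. **Acquisition photobleaching** is calibrated on fixed-sample control
   series by least squares on I(t) = I₀·e^(−pt); experimental series
   are then multiplied by e^(+pt). A non-decaying control clips p at 0
   with a warning rather than fitting a negative rate.
2. **Bi-exponential fit.** The normalised curve is fitted with the
   nonspecific half-time τ_NS fixed at its nurse-cell calibration
   (2.0 min FRAP, 3.2 min photo-conversion; `calibrate_tau_ns` refits
   it from a user's own control series). Photo-conversion enforces the
   t = 0 sum-to-one constraint by parametrising C_RNA = 1 − F_IM − C_NS,
   leaving three free parameters; FRAP fits all three fractions in
   [0, 1]. The optimiser is bounded trust-region least squares
   restarted from five spread initial half-times (5–120 min);
   non-convergence is flagged on the result, never silently replaced.
3. **Nonspecific removal** subtracts the fitted C_NS·e^(−ln2·t/τ_NS)
   term (adding it back, for FRAP) and by default rescales by
   1/(1 − C_NS) so the reported immobile/mobile fractions refer to
   RNA-specific signal only. The source procedure says "remove" without
   specifying rescaling; rescaling is the package's choice (it makes
   fractions sum to one on the RNA scale) and can be switched off.
4. **Single-exponential refit** of the RNA-only signal reports the
   immobile fraction and fluorescence half-time.
5. **MCP–MS2 dissociation** (photo-conversion only) multiplies by
   e^(+k_off·t) with k_off = 0.0017 min⁻¹ for the MS2 C-loop variant —
   a 9% loss over 55 min if uncompensated. The forward simulator
   applies this decay to the RNA-specific component only; FRAP is not
   compensated because the recovering molecules are freshly exchanged.

**Curve comparison** uses the extra-sum-of-squares F-test: one
parameter set fitted to the pooled points (SS_c, df = n₁+n₂−k) against
separate fits (SS_s, df = n₁+n₂−2k), F = ((SS_c−SS_s)/k)/(SS_s/df_s),
with k counting free parameters only (a fixed τ_NS is excluded). All
free parameters are shared under the null. Identical noiseless inputs
give residuals at machine precision; these are treated as zero evidence
(F = 0, p = 1) rather than divided.

### Identifiability of the bi-exponential design

A caution established by this package's own simulation study: with
12 samples spanning 55 min and intensity noise σ = 0.02, the
(F_IM, τ_RNA) pair of the photo-conversion model is poorly identified.
The Cramér–Rao bound at the default truth (F_IM = 0.63, C_NS = 0.20,
τ_RNA = 26 min) gives sd(F̂_IM) ≥ 0.10 and sd(τ̂_RNA) ≥ 34 min for any
near-unbiased estimator, and no 12-point design does materially better
(uniform spacing is near-optimal). The least-squares estimator sits on
a flat F_IM ↔ τ_RNA ridge: a quarter of fits land at the F_IM = 0
bound. Recovery is exact on noiseless data and tightens quickly with
denser sampling (the bound halves at ~45 points). Practical guidance:
sample as densely as acquisition bleaching allows, and treat immobile
fractions from sparse noisy curves as ridge estimates with wide
uncertainty, not point facts.

## Particle profiling

Maxima detection uses prominence semantics: a local maximum is reported
iff it exceeds, by more than the tolerance, the highest saddle
connecting it to higher ground (flood-fill above `value − tolerance`
that meets neither a higher pixel nor an already-accepted equal
maximum). The implementation agrees exactly with an independent
union-find persistence oracle on random images. The tolerance is in
absolute intensity units. On pure Gaussian noise, prominence-filtered
maxima at tolerance = 2σ still occur at ~8 per 10³ px — prominence
cannot distinguish noise summits from signal at that level — so in
practice the tolerance must sit several σ above the noise floor
(< 1 false maximum per 10⁵ px from ~4σ; the shipped recovery study uses
tolerance 10 = 10σ of its noise, half the weakest spot amplitude).

Profiles are the mean over 3 perpendicular pixels along a ±10 px
(146 nm at 14.6 nm pixels) window, fitted with
B + A/(1 + ((x−x₀)/γ)²); FWHM = 2γ·pixel size, and the particle
diameter is the arithmetic mean of the X and Y FWHMs (the published
analysis reports one size per particle without stating the combination
rule). The baseline term B is the package's addition — the source is
silent — and absorbs neighbouring-spot tails and residual background;
r² is computed against the mean-only model on the fitted points.
Acceptance requires r² ≥ 0.8 on both axes and FWHM ratio ≤ 2; maxima
within the profile radius of the edge are rejected as `edge`, and
maxima with a neighbour inside the profile diameter (2 × radius) as
`dense`, since overlapping profiles corrupt the 1-D fits — the stated
motivation for the original high-density exclusion. Each spot carries
exactly one of: accepted, or a single rejection reason (checked in the
order edge, dense, low_r2, axis_ratio).

Summed fluorescence is the background-subtracted sum over the ellipse
with the two FWHMs as axes, baseline = mean of the two fitted B values.
Coordinates are 0-based pixel indices, pixel-centre convention, x =
column, y = row.

## Colocalisation

Background subtraction uses the rolling-ball algorithm (ImageJ-style
semantics via scikit-image); exact parity with any specific plugin
binary is not claimed. The cross-correlation function computes Pearson
r between channel 1 and channel 2 displaced by each integer shift
−N…+N along a chosen axis, over the overlapping region only (no
wrap-around); the sign convention is that a channel-2 copy displaced by
+d peaks at +d. Costes significance scrambles channel 2 in square
blocks (default 8 px, ≈ the PSF FWHM in pixels, Costes' recommendation;
the original plugin's randomisation unit is not published) and reports
p = (1 + #{r_rand ≥ r_obs}) / (n_rand + 1), so p ∈ (0, 1] and is
deterministic given the seed.

## Statistical battery

The binomial directionality test is the exact upper tail
P(X ≥ k | n, ½). Rank tests enumerate exactly up to 8 observations per
group (16 paired differences) without ties, then switch to the
mid-rank, tie-corrected normal approximation; the crossover is the
logged constant `EXACT_N_MAX = 8`. Degenerate all-tied inputs return
p = 1. The t-test is Welch's (the default of the statistical software
the published workflow used). qPCR fold change is 2^(−ΔΔCT). No
multiple-testing correction is applied anywhere, mirroring the source
workflow; users comparing many groups should correct downstream.

## Synthetic-data generators

All generators drive every random choice from one integer seed and
return a ground-truth table with exactly one record per generated
object.

*Tracks* get one direction each — anterior or posterior hemicircle by a
Bernoulli draw of the bias, jittered by a truncated normal of the
lateral spread — one speed from a truncated normal, and rare per-frame
reversals that flip the direction for the remainder of the run; this
matches the near-unidirectional runs seen in vivo ("virtually no
reversals"). Defaults emulate the wild-type condition: 0.78 μm/s mean
speed, 52.6% anterior bias, 2% reversal probability, 0.5 s frames,
4–8 frames per track (giving ~1.4 μm runs), 0.02 μm localisation noise,
starts within 40 μm of the anterior. Published tables do not report
per-track speed variance or track-length distributions, so the spread
parameters are realism choices, not calibrated claims.

*Recovery curves* evaluate the bi-exponential forward model exactly,
then degrade: acquisition bleaching multiplies everything by e^(−pt),
MCP dissociation multiplies the RNA-specific part by e^(−k_off·t)
(photo-conversion only), and Gaussian noise is added last. With all
degradations off the series equals the closed-form curve bitwise.

*Spot images* render each particle as the separable product of
per-axis Lorentzians — deliberately the exact inverse of the analysis
model — at sub-pixel centres with log-normal axis-ratio jitter, on a
flat or linearly tilted background, with Gaussian or Poisson noise
applied after compositing. Defaults: 14.6 nm pixels, 112 ± 10 nm FWHM,
amplitudes 20–60 on background 5 with unit noise (worst-case
amplitude/noise = 20). Non-clustered centres keep a 400 nm minimum
separation (dart-throwing placement with a capacity check); a cluster
fraction places partners at a fixed spacing instead. Two-channel pairs
duplicate a chosen fraction of channel-1 positions (optionally
displaced) and draw the rest independently.

What the generators deliberately do **not** emulate: oocyte anatomy and
cortical geometry, STED depletion physics and its spatially varying
PSF, axial superposition through thick optical sections, detector
artefacts, or movie-level linking errors. Passing the recovery studies
therefore shows the estimators are correct and well calibrated under
their own model assumptions — it does not certify performance on real
images whose violations of those assumptions (dense clusters, PSF
asymmetry, structured background) the quality filters are designed to
flag rather than fix.

## Numerical conventions

Times are seconds for tracks and minutes for kinetics, converted only
at ingest. Images are float64 in memory, written as 32-bit TIFF with
the pixel size in a YAML sidecar. CSV round-trips preserve float64
exactly (17-significant-digit formatting, round-trip parsing). Fits
flag rather than mask non-convergence; a fitted bleach rate below 1e−9
is snapped to exactly 0. The problem sizes of the shipped studies —
200 simulated curves for kinetics recovery, one 768 × 768 image with
200 spots for profiler recovery, 100 seeds for Costes null uniformity,
200–400 simulations per type-I calibration — were chosen to bound the
Monte-Carlo standard error of each reported rate near one percentage
point.
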