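# Methods

## The measurement model

A Raman spectrum of a dry body-fluid trace is modelled on a fixed working
grid of 300–1800 cm⁻¹ in 2 cm⁻¹ steps (751 points), chosen to contain
every chemical band used by the three fluids (smallest 323 cm⁻¹, largest
1744 cm⁻¹).  A simulated spot spectrum is

    y(ν) = Σᵢ wᵢ sᵢ(ν) + b₀ + b₁·(ν − ν₀)/(ν₁ − ν₀) + ε(ν),  y clipped at 0

where `sᵢ` are the fluid's chemical component spectra, `w` the spot's
non-negative abundances, the two middle terms a constant-plus-tilted-line
fluorescence background, and `ε` i.i.d. Gaussian detector noise.

**Component library.**  Eight components across the three fluids, each a
sum of Lorentzian lines at the band positions characteristic of its
dominant chemical species (hemoglobin, fibrin; tyrosine, serum proteins +
choline, spermine phosphate; mucin/proteins, acetates + carbohydrates,
arginine).  Line positions are well established; linewidths are not, so
all lines share a default FWHM of 12 cm⁻¹, a typical solid-phase value.
Relative band amplitudes are drawn log-uniformly in [0.2, 1.0] once under
a frozen seed, making the library a deterministic object.  Each component
additionally carries a 10–30 % admixture of the *intense* bands (≥ 60 % of
the strongest band) of every other component, reproducing the band
cross-mixing that ALS resolution leaves between components; admixed bands
within 20 cm⁻¹ of a receiving component's own band are skipped so band
positions stay identifiable.  Restricting the admixture to intense bands
matters: mixing all bands at 10–30 % widens the rotational-ambiguity set
of the non-negative factorization to the point where no algorithm could
recover the generating components (see "ALS" below).

**Heterogeneity.**  Two levels. Donor level: each sample's abundance
vector is Dirichlet-distributed over the fluid's components with
concentration `donor_variability` (default 50 — donors resemble each other
but are not identical), scaled by a fixed per-fluid overall intensity
(blood 1.2, saliva 0.8, semen 1.0; blood is the strongest Raman scatterer
of the three).  Spot level: weights are jittered multiplicatively,
lognormal with σ = 1/√`donor_variability` ≈ 0.14; saliva gets 2σ,
reflecting its higher spot-to-spot variability.  Baseline offsets b₀, b₁
are drawn per spot, uniform in [0, `baseline_strength`·max signal]
(default 0.3).  Noise σ is max(chemical signal)/`peak_snr` (default 25).
Noise is Gaussian rather than Poisson: the regime is CCD-read-noise
dominated and the additive contract keeps the noise level a single
interpretable number.

**Default campaign.**  17 donor samples per fluid, 10 spots per sample,
seed 42 — 510 spectra.  The acquisition-range option `spots_per_sample=(16, 36)`
matches the instrument's mapping protocol; explicit per-sample spot lists
reproduce the historical campaign totals of 170 blood / 252 saliva / 693
semen spectra exactly (the per-sample composition behind those totals is
not recorded anywhere, so any integer composition can be supplied; the
built-in one uses 17 × 10, 14 × 15 + 3 × 14, and 43 × 14 + 7 × 13).

**What the generator does not emulate:** fluorescence photobleaching,
instrument response and wavelength-calibration error, cosmic-ray spikes
(the despiking preprocessor is exercised on synthetic spikes in tests
instead), substrate contributions, and fluid mixtures.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative assumptions — not field performance on real traces.

## Preprocessing

Despiking uses a modified z-score (0.6745·|dev|/MAD > z, default 8) of the
first differences within a centred rolling window (default 11 channels);
flagged points are replaced by the window median of unflagged intensities.
Genuine Raman bands spread over several channels and survive; one- or
two-channel cosmic-ray spikes do not.  Statistics operate on
vector-normalized spectra (unit Euclidean norm); normalization mode is a
config switch, and area normalization is available.  Multi-file datasets
are linearly interpolated onto the intersection of their axes.

## Signatures

**Rank (SFA).**  Eigenvalues of the covariance of the mean-centered
matrix; Malinowski's indicator IND(k) = RE(k)/(c−k)² with
RE(k) = √(Σ_{j>k} λⱼ/(r(c−k))), where c is the smaller and r the larger
matrix dimension — the indicator's standard orientation; with c taken as
the channel count (751) the indicator is monotone decreasing even on
pure-noise matrices.  The argmin is searched within [1, max_k] because IND
dives spuriously as k approaches c.  On noisy data IND is known to be
unstable, so the per-fluid signature ranks are fixed (blood 2, semen 3,
saliva 3 chemical components) and SFA is an advisory tool; the cumulative
explained variance is always reported alongside.

**ALS.**  Alternating exact non-negative least squares (active-set NNLS
per row/column), initialized from the k most mutually dissimilar spectra
(iteratively picking the row with the largest residual against the span of
the rows already picked — deterministic, no random restarts needed).
Stops when the relative lack-of-fit change drops below 1e-6, the fit is
numerically exact (lack-of-fit < 1e-7), or after 500 iterations.
Non-negative factorizations are only unique up to a rotation, so the
converged solution is normalized to its **maximum-contrast
representative**: for each component, the largest multiple of every other
component that keeps it non-negative is subtracted (one small linear
program per component; the product C·S and both factors' non-negativity
are preserved).  This is the convention under which the generating
components are recoverable (matched cosine ≥ 0.95 on noise-free data);
without it ALS lands on an arbitrarily mixture-heavy member of the
ambiguity set.  Components are max-normalized with the scale moved into
the concentrations.

**Fitting.**  A signature is its k components plus an all-ones constant
and a 0→1 ramp.  Fitting solves bounded-variable least squares: component
weights ≥ 0, baseline weights free.  R² = 1 − SSE/TSS may be negative for
terrible fits and is deliberately not clipped; RMSE = √(SSE/n) exactly.
The baseline is handled only at fit time — ALS runs on the chemical
signal's k components alone — so the background is never double-counted.

## Classifiers

**SIMCA.**  Per class: PCA with a components (default 3);
T² limit = a(n−1)/(n−a)·F⁻¹(α; a, n−a); Q limit by Jackson–Mudholkar from
the discarded eigenvalues, falling back to the Box χ² moment approximation
when the JM expression degenerates (nearly noise-free classes).  Class
assignment minimizes the reduced distance √((T²/T²ₗᵢₘ)² + (Q/Qₗᵢₘ)²);
membership requires that distance ≤ √2.  α defaults to 0.95.

**LDA family.**  Spectra are compressed to PCA scores retaining 99 %
variance (capped at 20) or to PLS scores; under any cross-validation the
compression is refit on each training fold — fitting it globally would
leak the held-out spectrum into its own model and inflate accuracy.
Pooled covariance gets a one-time ridge of 1e-8·trace/dim if singular.
Priors are equal everywhere: the campaign's class imbalance reflects
sampling effort, not prevalence.  Argmax ties break toward the first
class in the fixed order blood < saliva < semen.  Variants: naive Bayes
(diagonal per-class Gaussians), stratified covariance (per-class full
covariance, a quadratic rule), and pooled-covariance Mahalanobis
nearest-mean.

**PLS-DA.**  SIMPLS (deterministic; no X deflation) on one-hot
indicators.  The latent-variable count is selected by cross-validated
RMSECV with the one-standard-error rule — the smallest count within one SE
of the minimum — guarding against overfitting the LV count; the default
splitter is venetian-blind with 10 folds (the four splitters all follow
their textbook index formulas and are deterministic given (n, scheme,
seed)).  Prediction is pure argmax over predicted indicators; the
predictions are not probabilities (rows sum to 1 by linear algebra but
individual values leave [0, 1]).

**Consensus.**  Each engine votes per spectrum; a strict majority wins,
otherwise the spectrum is flagged "ambiguous".  The blind-test protocol
holds out whole donors (never individual spectra), so unknowns share no
donor with any training spectrum.

## Problem sizes and determinism

Default experiment sizes: 510-spectrum campaign; ALS on ≤ 200 spectra per
fluid; leave-one-out LDA refits compression and classifier 510 times
(PCA switches to a Gram-matrix eigendecomposition when channels outnumber
spectra — identical results, about 4× faster).  The full default pipeline
(generate → preprocess → signatures → SIMCA → LOO-LDA → PLS-DA → blind
test) runs in about one minute on one CPU.  Identical config and seed give
byte-identical reports; wall-clock timings go to the logger, never into
the report.  Reports carry the config hash, and a report file is never
silently overwritten with different content.

## Known limitations

- The synthetic generator is the only data source; all 100 % headline
  figures certify the pipeline under its assumptions, not real-world
  performance.
- SFA's indicator function remains heuristic; rank choices for signatures
  are config, not inference.
- The maximum-contrast ALS convention is the right one for sparse,
  band-limited spectra; for data whose true components overlap everywhere
  it would over-sharpen.
- Mixtures of fluids, substrate backgrounds and probability-calibrated
  outputs are out of scope.
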