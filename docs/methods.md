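# Methods

## The autocorrelation model

Single-point FCS records photon counts from a femtoliter confocal volume at
25–50 kHz for minutes.  The normalized autocorrelation of the intensity
fluctuations, G(τ) = ⟨δF(t)·δF(t+τ)⟩/⟨F⟩², is modelled as free 3D diffusion
of the labelled transcription factor plus exchange with two populations of
immobile chromatin sites:

    G(τ) = [f_D / (2^{3/2} N)] · (1 + τ/τ_D)^{-1} · (1 + τ/(ω² τ_D))^{-1/2}
           + f_short · e^{-τ/τ_short} + f_long · e^{-τ/τ_long}

with N the mean number of fluorescent molecules in the confocal volume, τ_D
the characteristic diffusion time, ω the axial/radial waist ratio of the
observation volume, and τ_short/τ_long the residence times on short- and
long-lived sites.  The reciprocal of a residence time is the dissociation
rate k_off.  The model assumes the reaction-dominant regime (τ_D ≪
residence times), immobile non-depleting sites, pseudo-first-order binding,
and a single fluorescent species of uniform brightness.

### Amplitude convention and population fractions

The equation is implemented literally: the 1/(2^{3/2}N) prefactor applies
only to the diffusive term, `f_short`/`f_long` are the bare amplitudes of
the exponential terms, and `f_D + f_short + f_long = 1` is enforced at the
parameter level.  Under this convention the stored `f` values of a fitted
curve are *amplitudes*, not occupancies: for species of equal brightness
every component's zero-lag amplitude is (occupancy)/N up to the common
geometric factor, so the *shares* of the total amplitude estimate the
occupancies.  `FitResult.population_fractions` reports these shares
(A_i / ΣA_i with A_D = f_D/(2^{3/2}N)); they are the quantity to compare
against the simulator's equilibrium occupancies.  The absolute fitted N is
convention-dependent and, for the simulator's truncated z profile (below),
differs from the analytic V_eff value; no result in this package depends on
it.

### Fitting

`fit_acf` minimises weighted residuals (weights 1/sem when per-lag errors
are available, uniform otherwise) with lmfit's trust-region least squares.
Internal parameters are the three amplitudes and three timescales; `f_long`
is parametrized as a fraction of the amplitude budget left by `f_short`, so
the sum-to-one convention can never be violated mid-optimisation.  ω is
fixed at 5 by default (ω and τ_D are poorly separable on noisy curves) and
can be freed.  Lags below three sampling intervals are excluded when the
curve's bin width is known (shot-noise/afterpulsing guard).

Initialisation: the `"auto"` policy matches the total amplitude to G at the
smallest lags, places τ_D at the half-decay lag, and seeds τ_short/τ_long
at 0.01 s/1 s.  Because the half-decay lag grossly overestimates τ_D
whenever the bound amplitudes hold the curve up, additional starts walk a
τ_D ladder at 0.1× and 0.01× the half-decay lag, plus jittered (±50%)
restarts.  Among converged local optima, a solution with τ_D <
min(τ_short, τ_long) — the arrangement the model is meant to describe — is
preferred unless its residual is more than 5% worse; the remaining
short/long label-swap degeneracy is resolved by relabelling so that
τ_short < τ_long.  Fitting is fully deterministic (fixed internal jitter
stream).

## ACF estimation

`direct_acf` is the O(n·k) oracle: G(k) = ⟨F_t F_{t+k}⟩/(⟨F_t⟩⟨F_{t+k}⟩) − 1
over overlapping samples, with means taken separately over the head and
tail segments at each lag (symmetric normalization, robust to slow drift).
Lag 0 is never reported (shot-noise dominated).  `multitau_acf` evaluates
the same estimator on a quasi-logarithmic ladder: linear lags within the
first octave (identical to `direct_acf` there, by construction), then bin
width doubling per level with lags m/2+1…m in rebinned units.  The ladder
descends while the rebinned signal retains at least 1.5·m samples; the
resulting deepest lags (~T/3 for a trace of length T) anchor slow
exponential tails during fitting.

`segment_acf` averages multi-tau curves over equal contiguous segments and
reports the per-lag standard error for weighted fitting.  Per-segment
curves are normalized by the *whole-trace* mean, not per-segment means:
subtracting segment-local means also subtracts any correlation component
slower than a fraction of the segment length, which visibly truncates a
2 s residence time measured with 16 s segments.  With global-mean
normalization the remaining finite-trace bias is of order 2·Στ_c/T ≈ 1%
of G(0) for the default conditions.

## The Brownian-dynamics generator

`simulate_trace` propagates point particles through a periodic cube with a
3D Gaussian observation volume at its centre.  Each particle carries a
three-state continuous-time Markov chain (free ↔ short-bound, free ↔
long-bound, no direct short↔long exchange) sampled by exponential waiting
times; bound particles are immobile but stay fluorescent at their fixed
position — this is what generates the exponential ACF terms.  Free
particles take Gaussian steps of variance 2·D·dt per axis each sampling
bin; if the configured rates or diffusion coefficient are too fast for the
sampling interval (rate·dt ≥ 0.1 or step ≥ w_xy/4) the bin is internally
sub-divided, up to a capped factor.  Expected counts per bin are
dt·brightness·Σ exp(−2x²/w_xy² − 2y²/w_xy² − 2z²/w_z²); realized counts
are Poisson.  A single seed (via `numpy.random.SeedSequence` spawning)
determines everything bit-for-bit.

`expected_params_from_config` maps the generative configuration to model
observables in closed form: τ_D = w_xy²/4D, τ = 1/k_off per site class,
occupancies from the chain's stationary distribution (detailed balance),
and N = concentration × π^{3/2}w_xy²w_z.

Default conditions emulate the acquisition regime used throughout: 50 kHz
sampling for 162 s (2.7 min), τ_D = 1 ms (D = 15.625 µm²/s at w_xy =
0.25 µm), τ_short = 0.1 s, τ_long = 2 s, occupancies 0.5/0.3/0.2 (k_on =
6/0.2 s⁻¹, k_off = 10/0.5 s⁻¹), 36 particles in a 2.5 µm box (N ≈ 1.0
molecules in V_eff) at 37.5 kHz/molecule peak brightness (≈14 kHz mean
count rate).  Two constraints shaped the concentration choice: the literal
amplitude convention requires (f_short+f_long)/N < 1, and the sampling
noise of the 2 s component — only ~15 long-binding events intersect the
observation volume per trace — shrinks with particle number.

Known idealisations: w_z (1.25 µm) is half the box edge, so the z profile
is truncated (~5% of its infinite-volume weight) and nearly flat across
the box; intensity is continuous over the periodic boundary and amplitude
shares are unaffected, but the absolute fitted N is not comparable to the
V_eff formula.  Intermittent trapping also makes free-particle motion
slightly sub-diffusive on 0.1–1 s scales ("stop-and-go"), a real physical
effect absent from the additive model; on the default conditions it
contributes ≲0.04 to the fitted long-component share.  No photobleaching,
afterpulsing, dead time, or cellular geometry.

### What recovery tests show

Pooled over 50+ independent simulated acquisitions at the defaults, the
recovered τ_D and τ_short centre within a few percent of truth and the
median occupancy shares within ~0.05.  *Single-trace* estimates of the
slow component scatter widely — per-trace τ_long has an IQR of roughly
0.9–2.5 s around the 2 s truth, and even the median of a 20-trace batch
varies from ~1.0 to ~2.1 s between seed batches.  This is an information
limit, not an estimator defect: a 162 s trace contains only ~15
long-binding events that intersect the observation volume, and refits
from truth-centred initialisations confirm the dispersed values are
global optima of their curves.  Real measurements share this limit; the
package, like the underlying experiments, draws conclusions from
distributions over many cells/traces, and any single batch median should
be read with that scatter in mind.

## Synthetic nuclei and image metrics

Scenes are single 2D confocal sections (224×224 px at 0.1 µm/px): an
elliptical nucleus (semi-axes 4.5–7.5 µm), 1–3 elliptical nucleoli (total
1–12% of the nuclear area, rendered at half the nucleoplasmic level), flat
background of 100 a.u. inside the nucleoplasm, and Gaussian foci.  A focus
of "radius" r has half-width at half-maximum r (FWHM = 2r).  Foci centres
keep a distance of at least 2×(r_i + r_j) so that thresholded footprints
never merge; placements are uniform, peripheral (normalized radial
coordinate > 0.9), perinucleolar (within 1–4 px of a nucleolus), interior,
or boundary (peripheral ∪ perinucleolar).  The normalized radial
coordinate is computed from the masks alone as d_centroid/(d_centroid +
d_boundary) — exact for a disc, monotone for convex shapes — and the same
map is used by the generator and the feature extractor, so "peripheral"
means one thing.  Optional noise is scaled Poisson calibrated so the
background SNR equals the configured value.

All intensity metrics operate on the nucleus *excluding nucleoli*, with
population (ddof = 0) standard deviations:

* **CV** = SD/mean of that region.
* **Foci**: pixels strictly above mean + 2·SD, 8-connected components.
  The *size* of a candidate structure is the area of the largest connected
  region above the halfway level between the component's peak and the
  nucleoplasmic mean; structures smaller than a resolution-limited spot
  (area < π·(resolution_px/2)², default resolution 0.25 µm at NA 1.35)
  are discarded.  For a Gaussian focus this area is π·HWHM², independent
  of how much of its tail clears the detection threshold, so the filter
  genuinely measures object size: a thresholded-pixel count would retain
  a bright sub-resolution speck whose faint skirt covers a few pixels.
  Per-focus records keep both areas (half-maximum and thresholded).
* **I_r,foci** = mean intensity over all retained focus pixels divided by
  the region mean.
* **DAPI**: each cell's integrated intensity divided by its colony mean
  (removing colony-level illumination/staining gain exactly); the
  synthetic colony table draws DNA-content proxies per phase (G1 = 1,
  ES = 1.25, MS = 1.5, LS = 1.75, G2 = 2, lognormal CV 5%) times a
  per-colony lognormal gain.
* **Group contrasts**: two-sided (or one-sided) permutation tests on the
  difference of means for consecutive stages — a transparent substitute
  for the mixed-model contrasts used with clustered microscopy data, and
  labelled as such in output.

## Replication-stage classification

Feature extraction reduces each nucleus to counts and geometry of its
detected foci: n, mean/median half-maximum area, and interior vs boundary
membership (boundary = peripheral ∪ perinucleolar; perinucleolar means the
centroid lies within 6 px of a nucleolus, wider than the 1–4 px placement
ring so that centroid drift cannot flip the label).  The decision tree:

1. fewer than 2 foci → **G** (homogeneous; G1/G2 are pooled — DNA content,
   not the focal pattern, separates them);
2. at most 10 foci with mean area ≥ 2× a reference area (20 px², the
   typical half-maximum area of an early-S focus under the default
   rendering) → **LS**, even when the foci sit at the periphery;
3. otherwise compare interior and boundary counts: margin
   |interior − boundary|/n below 0.2 → **DISCARD** (ambiguous
   transitioning cell), interior majority → **ES**, boundary majority →
   **MS**.

All thresholds live in `PCNARuleConfig`.  The qualitative rules are fixed
by how practitioners stage these cells by eye; the numbers (0.2 margin,
factor 2, 10 foci, shell at 0.9) quantify words like "similar", "bigger"
and "few" and are conventions, not measurements.  The shell threshold
deserves a note: with an area-uniform focus distribution the outer shell
r_norm > t contains a 1 − t² fraction of foci, so t = 0.75 would put 44%
of a homogeneous early-S pattern "at the periphery" and the margin rule
would discard most genuine early-S cells; t = 0.9 (outer 10% radially,
19% by area) keeps homogeneous patterns interior-dominated while the
rendered mid-S patterns remain fully boundary-dominated.  Classification
uses only geometry and relative thresholds, so calls are invariant to any
positive rescaling of image intensity.

## Reproducibility

Every stochastic stage draws from `numpy.random.Generator` streams rooted
in an explicit seed; workflows derive per-stage, per-item seeds as the
SHA-256 of (global seed, stage name, item index), so batches are
reproducible and parallel-safe.  `run_workflow` writes a manifest with the
SHA-256 of every output; rerunning an identical configuration reproduces
identical hashes.

## Problem sizes

The test suite and the acceptance script run the FCS recovery on 20 and 8
full-length (162 s) traces respectively, the focus metrics on 100 scenes
per condition, the classifier on 200 scenes (50 per stage), and the DAPI
table on 1000 cells — sizes comparable to the cell counts of the
underlying experiments (typically 26–58 cells per condition) while keeping
a complete run in minutes on one CPU.

## Limitations

* The additive diffusion + two-exponential model is an approximation to
  the full reaction–diffusion correlation function; the simulator realises
  the true process, and the residual model mismatch (a few percent of the
  slow amplitude) is inherited by any fit of real data too.
* Single-trace estimates of slow binding are intrinsically noisy (see
  above); conclusions should rest on distributions over traces.
* Scenes are 2D with idealised geometry and no PSF convolution; masks are
  inputs, never inferred (segmentation is upstream of this package).
* The discard rule's behaviour depends on the shell/ring conventions; when
  comparing against manual staging, calibrate `PCNARuleConfig` on a small
  annotated set first.
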