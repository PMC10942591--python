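# Methods notes

## Membrane fluctuation model

The height of a substrate-proximal membrane patch is modeled as a sum of
independent overdamped spatial modes. Mode *q* feels the restoring
coefficient

    E(q) = κq³ + σq + γ/q            [J/m³],

with bending rigidity κ, lateral (fluctuation-)tension σ and harmonic
confinement γ, is damped by an effective viscosity η_eff, and is driven
at an effective temperature A·T (A = 1 is purely thermal; A > 1 absorbs
active, ATP-dependent forcing). Each mode is an Ornstein–Uhlenbeck
process with relaxation time τ_q = 4η_eff/E(q) and stationary variance
s_q² = A·k_BT·Δq/(4π·E(q)); summing the per-mode Lorentzians over
q ∈ [q_min, q_max] gives the one-sided temporal spectrum

    PSD(f) = (4 η_eff A k_BT/π) ∫ dq / [(4η_eff·2πf)² + E(q)²].

The simulator draws the modes (exact discrete OU transitions — mean
decay e^(−dt/τ), matched stationary variance — so there is no time-step
bias even for fast modes); the fitter integrates the closed form by
trapezoid quadrature on ≥200 log-spaced nodes (converged to ≪0.1%;
verified against adaptive quadrature). The two routes are checked
against each other in the tests, Parseval included.

Pixels are simulated independently: the fitting never uses cross-pixel
covariance, so spatial correlation would add realism without adding
validation power.

## Parameter defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| σ | 5×10⁻⁵ (= 50 pN/µm) | N/m | mid-range lymphocyte membrane tension |
| η_eff | 10 | Pa·s | places mode corner frequencies E(q)/(8πη_eff) at ≈0.6–5 Hz, inside the measurable band of a ~20 Hz camera; membrane-proximal damping is orders of magnitude above bulk water |
| γ | 10⁸ | N/m³ | moderately tethered substrate-proximal membrane |
| A | 1 | — | thermal baseline |
| κ | 15 k_BT | J | fixed during fitting |
| T | 300 | K | k_BT = 4.14×10⁻²¹ J; configurable |
| fs, frames | 19.91 Hz, 2048 | | one tension measurement ≈ 103 s |
| q_max | π/pixel (pixel 180 nm) | 1/m | spatial Nyquist |
| q_min | 2π/7.2 µm | 1/m | adhered-patch scale (~40 px); see below |

q_min is set by the size of the adhered membrane patch, not by the
4×4-pixel analysis ROI: the height at a point contains modes up to the
patch scale, and restricting the band to the ROI scale leaves a single
octave of wavenumbers over which the fixed-bending-term model can mimic
any tension (the σ-profile of the fit residual becomes flat to ~10⁻⁴
decades). Both bounds are configurable.

The camera integrates each frame over its exposure; the generator
averages 4 exact-OU substeps per frame (configurable), and the fitter
can compare against the exposure-damped, alias-folded sampled spectrum
(`exposure=1.0`), which is the correct comparison curve when mode
relaxation times approach the frame interval. Without this correction
the band-edge spectrum is biased by fold-back of above-Nyquist power.

## Identifiability of the spectral fit

The four-parameter fit (σ, η_eff, γ, A; κ fixed) has a nearly flat
likelihood direction: rescaling (σ, η_eff, γ, A) jointly leaves the
spectrum invariant except through the fixed bending term, so per-ROI
estimates carry order-of-magnitude uncertainties even when the fitted
curve is visually perfect (Fisher analysis at 2048 frames gives
sd(log₁₀σ) ≈ 0.5–2 decades per ROI depending on spectral averaging).
Relative comparisons — tension maps, before/after trajectories — remain
meaningful because the amplitude responds monotonically to σ, but
absolute recovery requires constraining the degeneracy. `fit_helfrich`
therefore accepts `fix={"A": 1.0}` (or any subset of parameters held at
known values); with A fixed, sd(log₁₀σ) drops to ≈0.05 per 16-pixel ROI
and the synthetic studies recover the median tension to ~5%.

A corollary: if the mode relaxation times sit far above the Nyquist
frequency (e.g. η_eff ≈ 0.1 Pa·s with these q bounds, where every
τ_q ≲ 1 ms against a 50 ms frame), the in-band spectrum is constant to
0.1% and *no* estimator can recover individual parameters from it; the
measurable band must bracket the corner frequencies for tension mapping
to be quantitative. The test suite includes a case documenting this
regime.

ROI spectra average the 16 per-pixel periodograms of a 4×4 tile before
fitting (reducing spectral noise ~4× without changing the expectation);
per-pixel fits are used for full-resolution tension maps, where masked
entries record non-convergent or excluded pixels.

Fitting is done on log₁₀PSD vs log₁₀f over a default band of 0.2 Hz to
0.8·Nyquist (excluding drift and the camera-noise floor), with bounded
multi-start least squares seeded by a coarse log-spaced grid search;
R² of the log-fit and a convergence flag are reported. Default bounds:
σ ∈ [10⁻⁹, 10⁻³] N/m, η_eff ∈ [10⁻³, 10²] Pa·s, γ ∈ [10⁰, 10¹²] N/m³,
A ∈ [0.1, 100].

## What the generators emulate — and what they do not

* **Heights/IRM**: stationary mode dynamics, the cosine interference
  relation, additive Gaussian camera noise. Not modeled: partial
  coherence, higher interference branches, EMCCD multiplicative noise,
  cytoskeleton-coupled (non-stationary) dynamics, spatial correlation
  between pixels. Passing tests show the estimator chain is correct and
  calibrated under the model; they do not certify behavior under model
  mismatch on real cells.
* **Polarized cells**: rigid ellipses translating along fixed headings
  with an exactly split intensity; masks are taken from a
  uniform-intensity twin channel, as they would come from an evenly
  distributed cytoskeletal stain (thresholding the polarized channel
  itself would truncate the mask at high skew). No shape change,
  uropod morphology or noise.
* **Tracks**: ideal Brownian / constant-speed persistent walkers; no
  localization noise or track fragmentation.
* **Puncta**: disk-shaped objects placed uniformly without mutual
  overlap; the randomization null re-places disks with areas resampled
  from the detected distribution, total area matched within 5%
  (redrawn until matched, tolerance relaxed with a warning after 100
  attempts). Because observed fields and null fields share the same
  placement rules, the test is exactly calibrated on synthetic data
  (measured type-I ≈ 3–5% at α = 0.05).

## Numerical and convention choices

* Sample standard deviations use ddof = 1 throughout.
* Welch: segment length n/8, 50% overlap, Hann window, mean detrend;
  the zero-frequency bin is dropped.
* AR ("pcov"): forward linear prediction solved by least squares
  without windowing; candidate orders 4–40 (step 2), selection by RMS
  log₁₀ distance to the Welch estimate over the fit band. The selection
  tracks Welch noise by construction, so AR spectra inherit ~10%
  wiggle; ill-conditioned orders are skipped.
* Tension trajectories: per-time-point median and IQR over valid ROIs;
  two-sided Mann–Whitney U of each post-baseline point against
  baseline, Bonferroni-corrected over the number of comparisons.
* Polarity geometry: 0-based pixel coordinates, x = column,
  y = row (increasing downward); ellipses from second image moments of
  the binary mask (semi-axes 2√eigenvalues); the bisector passes
  through the ellipse center; pixels exactly on the bisector are
  tie-broken by their perpendicular component so reversing the
  direction swaps the halves exactly, and a pixel exactly at the center
  belongs to neither half. All reported angles are relative (between
  the polarization vector and displacement), so the axis convention
  cancels. Frames displacing < 0.5 px reuse the last valid direction
  and are dropped if none exists.
* Linking is greedy nearest-neighbor (closest pair first, ties by
  lowest index) within a displacement gate — adequate for the sparse
  fields generated here; dense crossings would need global assignment.
* MSD: time-averaged over sliding origins (the plotted convention),
  fixed-origin variant behind a flag; lags capped at half the track
  length; groups with < 3 tracks omitted.
* Overlap = ≥1 shared pixel between objects, computed from the query
  side; Manders M1/M2 use Otsu thresholds unless given.
* Drift correction is integer-pixel phase correlation to frame 0;
  sub-pixel registration is out of scope.
* All generators take explicit seeds and are bit-reproducible.

## Problem sizes used in the shipped studies

Synthetic studies run at 30 ROIs × 16 pixels × 2048 frames for tension
recovery, 200 tracks × 30 steps for MSD, 2–4 cells × 5 skews for
polarity, and 5-cell × 2-time-point pools (30 objects per field) for
the colocalization calibration (100–200 repeats). These sizes give
each estimate a sampling error several times smaller than the
tolerance it is tested against.

## Known limitations

* Absolute tension accuracy on real data depends on the fixed-A (or
  otherwise constrained) fit being appropriate; strongly active
  membranes violate A = 1.
* The cosine inversion assumes the first branch; membrane excursions
  beyond ~λ/4n fold back and are clipped with a warning.
* The AR order selection has no parsimony penalty (it matches the FFT
  estimate, as specified); use a restricted order range when the
  underlying process is known to be low order.
* The colocalization null assumes disk-like, non-overlapping objects;
  elongated puncta would need the optional mask-resampling variant.
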