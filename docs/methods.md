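# Methods

## The temporal fluctuation (running-SD) pipeline

The quantity of interest is local, transient Ca²⁺ release activity in a
fluorescence movie `F(t, y, x)` whose mean level may itself rise several-fold
over seconds.  The pipeline separates three time scales: the slow global
elevation (below ~1 Hz), puff transients (a few to ~20 Hz), and photon shot
noise (white).  Concretely:

1. **Black subtraction.**  The camera offset is a per-camera scalar supplied
   with the movie; results below zero are retained as noise about zero.
2. **Spatial blur.**  Each frame is convolved with a 2-D Gaussian,
   σ = 2 px by default (≈1 µm at 0.53 µm/px), truncated at 4σ, reflective
   borders.  This trades lateral resolution for per-pixel SNR at the spatial
   scale of a puff (~1 µm).
3. **Temporal band-pass.**  A Butterworth band-pass (3–20 Hz, order 2)
   applied pixel-wise removes the global rise and attenuates high-frequency
   shot noise while retaining puff-band fluctuations.  It is applied
   zero-phase (forward–backward) by default so SD transients stay aligned
   with the ΔF/F₀ trace plotted on the same axis; a causal mode is available.
   The Butterworth order is a free choice (order 2 default) — the method is
   defined by its corner frequencies, not a specific roll-off.
4. **Running moments.**  For every pixel, the population variance
   (mean-of-square − square-of-mean, divide-by-n) over a centred 20-frame
   boxcar (160 ms at 125 frames/s); its square root is the running SD.
   Frames whose window is incomplete are NaN rather than computed with a
   shrunken window.
5. **Shot-noise correction.**  Poisson photon noise contributes a variance
   proportional to the mean intensity, so the SD stack is corrected by
   subtracting `c · sqrt(running mean of the blurred movie)`, with the same
   20-frame window for the mean as for the variance (alignment), and a floor
   of zero inside the square root.  The corrected SD is *not* clipped at
   zero.

### Shot-noise scale calibration

`c` cannot be derived from first principles because it folds in the camera
conversion gain and the variance transfer of the whole filter chain.  It is
measured on ≥3 uniform-intensity stationary series (a fluorescein dilution
ladder, or `simulate_noise_series`), each passed through the *identical*
blur + band-pass chain: ordinary least squares of mean windowed variance
against mean raw intensity gives `slope` (variance per count) and
`scale_c = sqrt(slope)`.

Two systematic effects matter and are handled explicitly:

* **Windowed-variance shrinkage.**  The band-passed noise is correlated over
  ~`fs / bandwidth` frames, so a 20-frame window recovers only part of the
  stationary variance.  Because the calibration measures variance through the
  same window, the shrinkage cancels between calibration and analysis.  The
  analytic expectation (inverse FFT of |H|⁴ → autocovariance → window
  formula, times the squared-kernel sum of the blur) is used as an
  independent oracle in the tests; the fitted slope agrees with it to <3%.
* **SD-estimator (Jensen) bias.**  `E[sqrt(v)] < sqrt(E[v])` for a short
  window of correlated noise — about 4–6% for the default chain.  Subtracting
  `sqrt(slope)·sqrt(mean)` would therefore leave a systematically negative
  corrected SD.  The calibration additionally regresses the mean windowed
  *SD* on `sqrt(mean intensity)` (`sd_slope`), which absorbs the bias
  exactly (the windowed SD scales exactly with `sqrt(mean)` in
  distribution), and the pipeline uses `sd_slope` for the correction when
  present.  `scale_c = sqrt(slope)` is kept as the classical definition and
  as the fallback.

Edge caveats: reflective blur borders raise the local noise variance within
~4σ of the frame edge, and the zero-phase filter has a start-up transient of
roughly `fs / band_low` frames; calibration averages exclude both regions.
Whole-cell statistics should be taken over a cell mask away from the frame
border (as with real cells) and, for precision work, away from the first and
last ~0.3 s of a record.

### The spatial cross-check

Temporal SD could in principle respond to spatially uniform flicker.  The
spatial pipeline guards against this: the band-passed movie is filtered per
frame with a difference of Gaussians (σ = 2 px and 8 px — ≈1 µm vs ≈4 µm), a
spatial band-pass that suppresses both pixel-to-pixel shot noise and
cell-scale gradients; the spatial variance over the cell mask is reduced to
a per-frame SD, corrected with a scale calibrated by the same
variance-vs-mean procedure applied to DoG-filtered images, and smoothed with
a 160 ms boxcar.  On simulated flurries the temporal and spatial whole-cell
traces correlate with r > 0.9.  The spatial variance must be calibrated over
a region much larger than the DoG correlation length (~σ_wide); the
calibration therefore never crops the frame to less than half its extent.

The spatial variance is computed over the supplied mask; passing an all-true
mask reproduces a full-field analysis.

### Power spectra

ROI traces are high-passed at 1 Hz (to strip the slow global rise),
mean-detrended, Hann-tapered, and their one-sided periodograms averaged
across ROIs.  Each periodogram is rescaled so its integral equals the
filtered trace variance, making Parseval's relation exact by construction.
Puff flurries appear as a broad 1–20 Hz power excess over the flat
shot-noise floor.

## Derived metrics

* **ΔF/F₀** — `(F − F₀)/F₀` with `F₀` the mean of the 100 frames preceding
  the stimulus (per pixel for movies, scalar for ROI traces); baseline length
  configurable, error if any baseline falls at or below a configurable floor.
* **SD-vs-ΔF/F₀ scatter** — per-frame SD samples over the rising phase
  (stimulus → ΔF/F₀ argmax) binned by concurrent ΔF/F₀ at 0.1 width; bins
  with fewer than 3 samples are not reported; optional max-normalization.
  Empirically this relationship is an inverted U peaking near ΔF/F₀ ≈ 2, and
  the simulator's event-rate profile reproduces that shape for testing.
* **Puff activity** — trapezoidal integral under the SD trace over a window
  (negative excursions included); **activity ratio** — that integral per unit
  peak ΔF/F₀, optionally normalized to a reference response.
* **Kinetics** — 20→80% rise and 80→20% fall times of the post-stimulus peak
  by linear interpolation; undefined values (flat trace, non-decaying tail)
  are NaN, not errors.

## Flux decomposition

With first-order removal (rate `k`), the release flux is
`r(t) = dF/dt + k·F`.  Choices:

* `k` is fitted as `A·exp(−k·t) + C` on a decaying tail window (default: the
  final 30% of the post-peak record in the CLI).  The additive offset guards
  against imperfect return to baseline; the fit rejects rising segments and
  non-positive optima.
* The derivative uses central differences on a 5-sample boxcar-smoothed copy
  of F (raw frame-to-frame differences of noisy ΔF/F₀ would dominate r);
  the `k·F` term uses the raw trace; smoothing is configurable and
  `smoothing_window=1` disables it.  Round-trip accuracy on a noiseless
  boxcar flux at 8 ms sampling: RMSE ≈ 2% of pulse height, cumulative
  release within 0.01%.
* **Punctate fraction (initial)** — compares areas under mean control vs
  puff-suppressed release traces up to the global peak, on group-mean traces
  without amplitude normalization, clipped to [0, 1].
* **Punctate fraction (total)** — `initial_fraction × cumulative%(t_ce)`
  where `t_ce` is the time puff activity has ceased.  How that time is chosen
  is a convention: here, the first time after the flurry peak that the
  whole-cell SD falls below 10% (configurable) of its peak.
* **Diffusion time** — `x²/(2·dims·D)`; 5 µm at 20 µm²/s in 2-D gives
  0.3125 s (~300 ms), the scale argument that slow inter-site diffusion
  cannot explain a smooth, sustained fluorescence component.

## The synthetic-data generator

`simulate_movie` emulates the imaging statistics the analysis assumes — it
is explicitly *not* a reaction–diffusion model of IP₃R gating, CICR or ER
luminal dynamics.  Photon rate per pixel:
`baseline · (1 + global(t) + Σ puffs)`, with counts
`gain · Poisson(rate) + black + N(0, read²)`.

Defaults (a TIRF-style recording): 125 frames/s, 0.53 µm/px, baseline 80
photons/frame/pixel (~400 counts at gain 5 counts/photon), black offset 100
counts, read noise 1.5 counts.  The global rise is
`(1 − e^(−u/τ))² · e^(−k·u)` normalized to its requested peak (default 6.9
ΔF/F₀, τ = 1 s, k = 0.22 s⁻¹): the squared-exponential onset is C¹-smooth,
matching the observed smoothly graded rises which carry no power in the
3–20 Hz band — a kinked onset would leak into the SD band and misrepresent
the phenomenon being emulated.  Puff sites are separable kernels: a 2-D
Gaussian footprint (σ = 1 µm) times `(1 − e^(−u/20 ms)) · e^(−u/60 ms)`
(unit peak, ~0.2 s above 5% of peak), amplitude 0.5 ΔF/F₀ per event —
inside the observed envelope of tens-to-hundreds of ms and a few µm.  Event
timing is an inhomogeneous Poisson process (default ceiling 8 Hz/site) whose
rate follows an inverted U in the concurrent global ΔF/F₀ centred at 2,
gated to the rising phase; explicit event lists give deterministic fixtures.
Optional phenomenological dye saturation (`dff · K/(K + dff)`) supports
high- vs low-affinity indicator comparisons; off by default.  A single seed
fixes all randomness; identical seeds give bit-identical movies.

What passing tests therefore show: the pipeline's noise model, localization,
and flux algebra are correct for movies with Poisson-plus-read camera noise,
stationary sites, and separable puff kernels.  What they do not show:
robustness to cell motion or drift, focus changes, photobleaching,
non-stationary backgrounds, indicator buffering kinetics, or event-shape
families different from the simulated kernel.

## Numerical choices

* Population (divide-by-n) variance throughout, per the mean-of-square
  definition of the running window.
* Temporal filters pad with three periods of the lowest band frequency
  (reflective), capped at the record length; spatial blur uses reflective
  borders; incomplete running windows yield NaN.
* Tiny negative variances from floating-point cancellation are clipped to 0.
* The exponential fit uses bounded Levenberg–Marquardt (trf) with a
  log-derived initial rate; `curve_fit` non-convergence is surfaced as a
  `ValueError`.
* The removal ODE integrator used by the simulator is exponential-trapezoidal
  stepping (exact for the homogeneous part, O(dt²) for the source), accurate
  to <3·10⁻³ against the closed form for a boxcar flux at dt = 2 ms.
* Problem sizes in the test-/acceptance-suite simulations (e.g. 96×96×300
  calibration stacks, 48×48×1500 movies, 100-seed fit ensembles) were chosen
  to give the stated statistical tolerances comfortably at desk-scale
  runtimes.

## Known limitations

* SD units are arbitrary; no attempt is made to calibrate SD amplitude to
  nM Ca²⁺, and puff-site segmentation/event cataloguing is out of scope
  (site coordinates are inputs).
* The shot-noise correction assumes intensity-independent camera gain and
  uncorrelated read noise; EMCCD excess noise folds into the empirical slope
  but intensity-dependent gain would not be captured.
* ΔF/F₀-based flux reconstruction assumes a linear indicator and
  spatially uniform removal; it yields relative, not molar, fluxes.
* Frame-edge and record-edge zones carry the blur/filter artifacts described
  above; masks and analysis windows should avoid them.
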