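# puffsd

Fluctuation analysis for Ca²⁺ imaging movies: resolving localized Ca²⁺
**puffs** hidden inside large, cell-wide Ca²⁺ elevations.

## The problem

IP₃-evoked global Ca²⁺ signals in cells such as HEK293 are punctuated, during
their rising phase, by brief (tens–hundreds of ms), micrometre-scale Ca²⁺
release events ("puffs") from stationary IP₃-receptor clusters.  Once the
bulk fluorescence of an indicator like Cal520 rises several-fold, these
transients become invisible in the raw movie.  `puffsd` implements a
pixel-wise temporal-fluctuation method that recovers them: the local
**running standard deviation** of band-pass-filtered fluorescence, corrected
for photon shot noise, is a quantitative proxy for puff activity at every
pixel and time point — even on top of a ΔF/F₀ ≈ 7 global elevation.

The package is aimed at labs doing TIRF or light-sheet Ca²⁺ imaging
(~100–125 frames/s, EMCCD/sCMOS counts in multi-page TIFF stacks) and ships
with a ground-truthed movie simulator so the whole pipeline is testable
without microscope data.

## The method

For a movie `F(t, y, x)` in camera counts:

1. subtract the camera black offset;
2. Gaussian-blur each frame (σ = 2 px, ≈1 µm at 0.53 µm/px, kernel truncated
   at 4σ);
3. Butterworth band-pass each pixel in time (3–20 Hz, order 2, zero-phase);
4. compute the population variance over a running 20-frame (160 ms) boxcar as
   mean-of-square − square-of-mean, and take the square root;
5. subtract the predicted shot noise, `c·√(running mean of the blurred
   movie)`, where the scale `c` is calibrated from the linear slope of
   variance vs mean on uniform-intensity (fluorescein-style) series passed
   through the identical filter chain.

The corrected SD fluctuates about zero over pure shot noise (negative values
are kept) and lights up wherever temporally transient, spatially confined
release occurs.  A spatial difference-of-Gaussians pipeline (σ = 2 px vs
8 px, per-frame spatial variance) provides an independent cross-check, and
1 Hz-high-passed power spectra diagnose the 1–20 Hz fluctuation excess that
puff flurries produce.

Downstream, the whole-cell signal is decomposed kinetically: with a removal
rate constant `k` fitted as a single-exponential tail decay, the
instantaneous release flux is `r(t) = dF/dt + k·F`, its running integral
gives the cumulative release, and comparing control vs puff-suppressed
release traces partitions release into *punctate* and *diffuse* components.

## Worked example

```python
import numpy as np
import puffsd as P

# calibrate the shot-noise scale on a simulated dilution ladder
series = P.simulate_noise_series(gain=5.0, offset=100.0, read_sigma=1.5,
                                 levels=[20, 50, 100, 200, 400],
                                 shape=(300, 96, 96), seed=101)
cal = P.calibrate_noise_scale(series)
print(f"variance slope {cal.slope:.4f}, correction scale {cal.sd_slope:.4f}")

# a global rise to 6.9 dF/F0 with six active puff sites
sites = [P.PuffSite(y=y, x=x) for y, x in
         [(14, 14), (14, 34), (24, 24), (34, 14), (34, 34), (20, 30)]]
config = P.SyntheticConfig(shape=(1500, 48, 48), puff_sites=sites,
                           global_rise=P.GlobalRise(amplitude=6.9, onset_s=2.0))
movie, truth = P.simulate_movie(config, seed=8)

sd = P.temporal_sd_stack(movie, calibration=cal)
mask = np.zeros((48, 48), bool); mask[8:-8, 8:-8] = True
sd_trace = sd.trace(mask)
baseline = sd_trace.values[sd_trace.times < 1.9]
print(f"baseline SD {baseline.mean():.3f} +/- {baseline.std():.3f} A.U.")
print(f"flurry peak {sd_trace.values.max():.2f} A.U. "
      f"({sd_trace.values.max()/baseline.std():.0f}x baseline spread)")
```

prints

```
variance slope 0.0220, correction scale 0.1427
baseline SD -0.008 +/- 0.096 A.U.
flurry peak 5.53 A.U. (58x baseline spread)
```

i.e. the corrected SD is mean-zero at rest (shot noise fully subtracted) and
the puff flurry during the rising phase stands ~58× above the baseline
spread, while the 6.9 ΔF/F₀ global elevation itself contributes nothing.

A command-line interface wraps the same pipeline:

```bash
puffsd simulate  --seed 11 --out runs/sim
puffsd calibrate --simulate 5 --seed 3 --out runs/cal
puffsd analyze   --movie runs/sim/movie.tif --config run.yaml \
                 --calibration runs/cal/calibration.json --out runs/analysis
```

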