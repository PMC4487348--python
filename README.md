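# peakfill

Baseline estimation for 1-D spectra by **4S peak filling**: Smoothing,
Subsampling, Suppression, Stretching — and Subtraction.

Spectra from MALDI-TOF mass spectrometry, LIBS emission spectroscopy or
Raman scattering sit on a slowly varying background (matrix effects,
fluorescence, instrument drift) that must be removed before peaks can be
compared.  `peakfill` estimates that baseline by pushing the spectrum down
onto it:

1. **Smoothing** — Whittaker smoother: `z = argmin ‖y − z‖² + λ‖Δ²z‖²`,
   with `λ = 10^lam`.  Damps noise spikes and, via λ, centres the final
   baseline inside the noise band.
2. **Subsampling** — partition the channels into buckets (equal-width or
   custom) and keep the **minimum** per bucket.
3. **Suppression** — slide a ±`hw`-bucket window over the vector,
   replacing each value by `min(current, mean(window))`, updating in
   place; each iteration sweeps right then left, and `hw` shrinks
   logarithmically from `hwi` to 1 over `it` iterations, with symmetric
   shrinkage at the vector ends.
4. **Stretching** — interpolate the suppressed values from the bucket
   centres back to full resolution (linear or shape-preserving spline).

Four parameters control everything: `lam` (log10 penalty, default 4),
`bins` (default: one bucket per 10 channels), `hwi` (half the width of
the widest peak — required), `it` (default 10).  Custom, variable-width
bucket edges let the baseline follow sharp local structure — e.g. the
characteristic dips of LIBS baselines — that defeats global methods such
as asymmetric least squares.

The method is particularly suited to non-linear baselines with local
variation and to resolving peak clusters in qualitative work.

## Worked example

Everything can be exercised on synthetic data with a known true baseline:

```python
import math
from peakfill import PeakFiller, generate, maldi_like_preset

spec = maldi_like_preset()                      # 4000-channel MALDI-like spectrum
spectra, truth, peak_free = generate(spec)

sigma_max = max(s for _, _, s in spec.peaks)    # widest simulated peak
hwi = max(1, math.ceil(2 * sigma_max / (spec.n_channels / 400)))

model = PeakFiller(spectra, hwi=hwi, lam=4.0, bins=400, it=10)
res = model.fit()
print(res.summary())
print(f"RMSE vs. true baseline (peak-free channels): "
      f"{res.rmse(truth, peak_free):.3f}  (noise sigma = {spec.noise_sigma})")
```

prints

```
4S Peak Filling baseline estimation
===================================================
spectra:            1 x 4000 channels
axis range:         1000 .. 15000
smoothing lambda:   10^4
bins:               400
initial half-width: 3  iterations: 10
window schedule:    [3, 3, 3, 3, 2, 2, 2, 2, 2, 1]
interpolation:      linear
---------------------------------------------------
spectrum  baseline mean       baseline range
       0         23.774     [7.1143, 64.276]

RMSE vs. true baseline (peak-free channels): 1.278  (noise sigma = 1.0)
```

The schedule line shows the logarithmically shrinking window half-widths
(ending at ±1); the RMSE line scores the estimate against the generator's
ground truth on channels farther than 4σ from every peak — here within
1.3× the noise level.  `res.subtract()` returns the corrected spectra;
`res.smoothed`, `res.subsampled` and `res.suppressed` expose every
intermediate stage.

The same pipeline is available from the shell:

```sh
peakfill synthesize maldi --out-prefix demo --seed 1
peakfill correct demo.tsv --hwi 3 --out-corrected demo.corrected.tsv \
    --out-baseline demo.baseline.tsv
```

`estimate`/`correct` accept `--lambda`/`--no-smooth`, `--bins N` or
`--bin-edges FILE` (two columns of 1-based inclusive channel indices),
`--it`, `--interp {linear,spline}`, and a YAML/JSON `--config` file that
mirrors every flag (explicit flags win).

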