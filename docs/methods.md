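# Methods

## The estimator

`peakfill` estimates the slowly varying background (baseline) of 1-D
spectra — MALDI-TOF mass spectra, LIBS emission spectra, Raman spectra and
the like — by *suppressing* the spectrum down onto its baseline in four
stages, then optionally subtracting the result:

1. **Smoothing.** Each spectrum `y` is replaced by the Whittaker smoother
   fit `z`, the minimiser of `||y − z||² + λ ||D₂ z||²` with `D₂` the
   discrete second-difference operator.  Smoothing has two roles: it
   removes spurious noise spikes that would otherwise be picked up by the
   minimum filter, and — through the size of λ — it positions the final
   baseline *inside* the noise band rather than at its bottom.  That real
   peaks are shrunk by strong smoothing is irrelevant: only the peak-free
   space informs the baseline.
2. **Subsampling.** The channel axis is partitioned into contiguous
   buckets and the minimum smoothed intensity per bucket represents the
   spectrum there.  This simplifies the spectrum's shape while keeping the
   baseline's, and makes the subsequent windowing cheap.
3. **Suppression.** A window of ±`hw` buckets moves across the bucket
   vector and each visited value is replaced by
   `min(current, mean(window))`.  The vector is updated in place as the
   window moves, which converges fast but is directional, so every
   iteration sweeps left-to-right and then right-to-left.  Across the `it`
   iterations the half-width shrinks logarithmically from `hwi` to 1:
   `hw_k = ceil(10^(d_k))`, `d_k` linear from `log10(hwi)` to 0.  Near the
   vector ends the window shrinks symmetrically about the cursor
   (`a = min(hw, j, n−1−j)`), which protects steep terminal baselines.
4. **Stretching.** The suppressed bucket values are placed at the bucket
   centre indices and interpolated back to full resolution — piecewise
   linear by default, or a shape-preserving piecewise cubic (PCHIP)
   through the same knots.  Channels outside the terminal centres take the
   terminal knot values.

Subtraction is plain `original − baseline`; negative residuals are kept,
so with smoothing enabled the corrected noise scatters around zero.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `lam` | log10 of the Whittaker penalty λ | 4.0 | `4` centres the baseline in the noise band; `0` (λ=1) barely smooths, placing the baseline below the spectrum; `None` skips smoothing entirely (baseline at the bottom of the noise band). |
| `bins` | bucket count, or explicit `(start, end)` channel intervals | channels/10 | More buckets = more flexible baseline (risks rising into peaks); fewer = stiffer (risks detaching under concave baselines). Variable widths handle locally sharp structure. |
| `hwi` | initial window half-width, in buckets | — (required) | Start from half the width of the widest peak. Deliberately has no default. |
| `it` | suppression iterations | 10 | Acts like `bins`: too few lets the baseline ride into peaks, too many can detach it under concave baselines. |
| `interp` | stretching method | `linear` | `spline` = PCHIP, shape-preserving. |

Design choices where the procedure is genuinely open:

* **Shrinkage schedule.** "Logarithmic shrinking ending at ±1" is realised
  as `ceil(10^d)` with `d` stepping linearly from `log10(hwi)` to 0; a
  single iteration keeps `hwi`.  Roundoff can push `ceil(10^log10(hwi))`
  one above `hwi`, so the schedule is clipped to `hwi` and made
  non-increasing by a running minimum.  The half-width updates after each
  completed right+left pair, not after each directional sweep.
* **λ scale.** The user-facing parameter is `log10(λ)` so that the
  conventional suggestion "4" and the literal penalty `10⁴` agree.  Both
  readings of "penalty 0" are exposed: `lam=0.0` means λ=1, `lam=None`
  means no smoothing.
* **In-sweep updates.** The window mean uses the working vector's current
  state — values behind *and* ahead of the cursor, whether already updated
  in this sweep or not.
* **Bin remainders.** When the channel count does not divide evenly,
  trailing buckets are one channel wider; centres are index-range
  midpoints (possibly half-integral), mapped to axis units by linear
  interpolation.
* **"Properly constrained smoothing splines."** Realised as PCHIP: a
  monotone, non-overshooting cubic through the knots.  Other constrained
  spline constructions are defensible; this one guarantees the baseline
  never exceeds neighbouring knot values.
* **Degenerate inputs.** Spectra shorter than twice the bucket count are
  rejected rather than silently re-binned; all validation errors name the
  offending parameter.
* **Coordinates.** Internally 0-based with closed `(start, end)`
  intervals; the CLI and bin-edge files use 1-based inclusive indices, the
  convention of the surrounding R-centric ecosystem, converted on load.
* **Multi-spectrum sets** share one bin scheme and one window schedule;
  rows are processed independently.

## Numerical choices

* The Whittaker system `(I + λ D₂'D₂) z = y` is pentadiagonal and solved
  by sparse LU, followed by two iterative-refinement steps whose residual
  is accumulated in extended precision.  The system's condition number
  grows like `16·λ`, and without the refinement penalties beyond ~10⁸ lose
  visible digits (e.g. a constant input stops being an exact fixed point).
  With it, the λ→∞ limit (the least-squares straight line) is reproduced
  to ~10⁻⁸ at λ=10¹².
* Subsampling and suppression use explicit sequential loops with plain
  float accumulation.  This fixes the floating-point evaluation order, so
  an independently written loop oracle can be compared *bitwise*, and it
  is fast enough because these stages run at bucket resolution (hundreds
  of points).  One consequence: a window mean of a constant vector can
  round one ulp below the constant; the identity `mean = current` is exact
  whenever the window sum is exactly representable (e.g. dyadic values).
* Suppression is monotone by construction — `min(current, mean)` never
  raises a value — and the whole pipeline is equivariant under increasing
  affine maps `y ↦ a·y + c` (the smoother is linear with constants in the
  penalty's null space; min, mean and interpolation commute with such
  maps).  Both properties are asserted over randomised instances.

## The synthetic generator

The generator exists because the method's original illustration data
(MALDI-TOF and LIBS spectra) are not deposited anywhere; it produces
spectra whose true baseline is known, so recovery error is measurable.
A recipe (`SyntheticSpec`) is a baseline family (linear, polynomial,
exponential decay, or a flat-top sigmoid dip/ridge composition), a list of
Gaussian peaks `(centre, height, σ in channels)`, an additive Gaussian
noise level, and a seed.  Channels farther than 4σ from every peak centre
form the *peak-free mask* used for scoring (Gaussian mass beyond 4σ is
negligible).

Two presets fix the study conditions:

* **MALDI-like** — 4000 channels on a 1000–15000 m/z axis; baseline
  `60·exp(−t/0.35) + 5` (≈65 decaying to ≈8 counts); 20 Gaussian peaks,
  heights 10–120, widths σ = 3–15 channels, drawn reproducibly from the
  preset seed; noise σ = 1.0.  Scale and shape follow the decaying-
  baseline-under-a-peak-cluster geometry typical of linear-mode MALDI-TOF.
* **LIBS-like** — 2000 channels on a 300–600 nm axis; baseline at 40
  counts with flat-bottom dips (depth 25, half-width 40 channels) near
  360 nm and 530 nm and a steep flat-top ridge (height 35, half-width 25)
  near 400 nm; 30 narrow lines (heights 30–300, σ = 2–5 channels); noise
  σ = 0.8.

The generator does *not* emulate instrument physics — detector
saturation, isotope envelopes, heteroscedastic or chemical noise, peak
shape asymmetry, axis warping between spectra.  Passing recovery tests
therefore demonstrates that the algorithm tracks smooth-plus-local
baseline structure under additive Gaussian noise, not that it is robust to
every artefact of real instruments.

## Reference configurations used in the tests

* **MALDI-like recovery** uses the suggested defaults: λ = 10⁴, 400
  buckets (channels/10), `it` = 10, and `hwi` from the half-the-widest-peak
  rule.  The package reads a peak's width as 4σ (±2σ), giving
  `hwi = ceil(2·σ_max / channels-per-bucket)` = 3 buckets.  Recovery RMSE
  on peak-free channels is ≈1.3× the noise σ (bound: 2×).
* **LIBS-like recovery** demonstrates variable bucket widths: 8-channel
  buckets inside the dips, 5-channel buckets over the steep ridge,
  20-channel buckets elsewhere (`libs_like_bin_edges`), with `lam=0.0`
  (λ=1), `hwi=1`, `it=2`.  Heavy smoothing is counterproductive here — the
  tall narrow emission lines smear into the narrow buckets — while no
  smoothing at all leaves the bucket-minimum bias of the raw noise
  (≈2σ for 20-sample buckets); λ=1 removes the spike sensitivity without
  smearing.  Recovery RMSE ≈1.4σ (bound: 2×).
* **Noise centring** uses a 1000-channel pure-noise spectrum with the
  defaults (λ = 10⁴, 100 buckets, `it` = 10) and `hwi` = 1 — the
  half-the-widest-peak rule's minimum, as a featureless spectrum has no
  peak width to halve.  The mean corrected intensity stays within 0.2σ of
  zero (observed ≈0.13σ across seeds).

Problem sizes in the test-suite property checks (vectors ≤ 500 channels,
100 randomised instances per invariant, 50 oracle-equivalence draws) were
chosen to exercise end effects, remainder bins and schedule plateaus well
beyond the sizes where hand-checking is possible while keeping the whole
suite interactive (a few seconds).

## Known limitations

* No convergence-based early stopping: the iteration count is always
  exactly `it`, even when the vector has stopped changing.
* No peak detection, alignment, or alternative baseline methods; the
  estimator assumes a single shared axis with no missing channels.
* Bucket edges are shared across all spectra of a set; baselines whose
  local structure shifts between spectra would need per-spectrum edges.
* The baseline position depends on λ in a data-dependent way; λ = 10⁴
  centres the noise band at the scales of the bundled presets but is not
  universal.
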