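# Methods

## Forward model

A rendered pixel is an expected photon-arrival profile subjected to Poisson
shot noise. For each species in the pixel's mixture the chain is:

1. **Population decay.** Multi-exponential `Σ aᵢ e^(−t/τᵢ)` sampled at bin
   centers; 256 half-open bins `[t, t+Δt)` over a 12.5 ns window by default
   (Δt ≈ 48.8 ps). The window corresponds to an 80 MHz-class Ti:Sapphire
   oscillator; neither the repetition rate nor the bin width is a measured
   quantity here, both are configurable.
2. **Photoselection.** The excitation ellipse is computed by Jones calculus
   (horizontal input → QWP → HWP, the order on the excitation arm).
   For a state with linear fraction p at azimuth χ to the analyzer, the
   detected effective anisotropy is `r_eff(t) = κ·r(t)` with
   `κ = p·(3cos²χ − 1)/2 − (1 − p)/2`, and the analyzer weights are
   `w∥ = (1 + 2 r_eff)/3`, `w⊥ = (1 − w∥)/2`, so `w∥ + 2w⊥ = 1` holds
   identically. The circular term uses the textbook one-photon −r/2
   convention. Caveat: in a strict epi-geometry (circular ellipse in the
   image plane, analyzer also in-plane) a dipole integration gives +r/4
   for the in-plane channel instead; since the instrument this emulates
   reports "variability in the peak contrast" attributed to imperfect
   polarization delivery, no specific ellipse is treated as ground truth,
   and the polarization-scan operation exists precisely to find the
   empirical contrast maximum.
3. **IRF.** Unit-area Gaussian, default FWHM 150 ps centred at 10% of the
   window. The kernel is sampled at integer-bin lags so that discretely
   convolving a bin-center-sampled profile lands back on bin centers
   (sampling it at centers instead introduces a half-bin systematic shift).
   The IRF convolution is applied *before* the dispersion shift — the two
   operations commute analytically, and this order leaves the IRF offset
   as headroom so blue-of-reference shifts do not clip at t = 0.
4. **Fiber dispersion.** The Gaussian emission line (single peak/σ per
   species — the fiber encodes only the spectral peak, so richer
   lineshapes are out of scope) is cut into wavelength cells whose
   boundaries include the exact bandpass edges; each cell contributes its
   exact Gaussian mass at a delay of 20 ps/nm relative to the reference
   wavelength (630 nm default). Weights sum to the transmitted fraction,
   so photon conservation of the operator is exact up to window-edge
   clipping (warned, not raised). The bandpass is an ideal top-hat.
5. **Normalisation and noise.** Profiles are normalised so that with no
   analyzer and no bandpass a pixel's expected total equals its photon
   budget; analyzer and filter losses reduce the realised counts.
   Poisson draws are i.i.d. per pixel, ROI-by-ROI in sorted id order from
   a single seeded generator, making stacks bit-reproducible.

**Periodic re-excitation** (`wrap=True`) folds incomplete decays into the
next window (geometric fold for pure exponentials, circular convolution
for the IRF, circular dispersion shifts). It is off by default; phasor
analyses enable it because the universal-semicircle identity
`(g − ½)² + s² = ¼` holds exactly only for periodized decays — truncating
a 3 ns tail at 12.5 ns otherwise distorts the phasor at the few-per-mille
level.

Not modelled: afterpulsing, dark counts, dead time, real filter edges,
fiber modal dispersion beyond the linear calibration, chlorophyll
photophysics.

## Decoders

**Lifetime fitting** is IRF-reconvolution weighted nonlinear least squares
(trust-region; Poisson weights `1/√max(counts, 1)`), one or two
exponentials plus a constant offset, optionally with a free time-shift.
Results are canonicalised (τ₁ ≤ τ₂); a two-component fit whose lifetimes
coincide within 1% collapses to the mono-exponential model with a warning;
non-convergence flags the result rather than raising. Derived scalars use
`f₁% = 100·a₁τ₁/(a₁τ₁ + a₂τ₂)` (fractional *intensity* of the short
component — the amplitude a₁ is reported separately), `t_m = Σaτ/Σa`,
`it_m = Σaτ²/Σaτ`. The model and the generator share one convolution
helper, so fitting simulated data is free of discretisation mismatch; the
count floor (default 100) rejects histograms too sparse to fit, and
under-floor pixels become NaN in parameter images (NaN pixels are excluded
from every ROI mean).

**Shift decoding** offers two routes. Against a reference histogram of the
same shape, the cross-correlation argmax refined by parabolic
interpolation recovers shifts to ~0.1 bin (≈5 ps). When decay shapes vary
across the scene (mixtures), the free-shift reconvolution fit is the
unbiased route, and `parameter_image("peak_wavelength")` uses it. The
spectral width is reported "unresolved": only the peak survives the
encoding. The synthetic zero-shift reference is rendered from the
configuration; real data needs a user-designated reference ROI.

**Anisotropy.** Static anisotropy is `r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥)`
(G default 1.0, no calibration being specified; a tail-matching utility
estimates G from a reference dye). The depolarisation ratio
`G·I⊥/(I∥ + 2G·I⊥)` — which some imaging work paints as the
"anisotropy" panel — is exported alongside the standard r rather than
silently substituting for it. The associated decay model ties each fixed
lifetime to its own (r₀, θ, r∞). The fit runs **jointly on the two count
channels** (the fitted r(t) is exactly the ratio of the fitted channels):
measured against ratio-space fitting on the single-species 10⁶-photon
round trip, channel-space fitting cut the worst-case θ error from ~6–10%
to ~4.5% across seeds, and because the model channels are IRF-convolved
the rise region is valid data rather than an artifact to trim. The
7-parameter two-species surface is multi-modal, so the fit multi-starts
over a coarse (θ₁, θ₂) × amplitude-split grid and polishes the best seed.
No upper bound is placed on θ (values above the anthocyanin lifetimes are
physical); no wobble-in-cone interpretation is attempted.

The 5%-at-10⁶-photons recovery check uses a two-photon validation probe
(r₀ = 0.55, r∞ = 0, θ = 0.8 ns on a 2 ns lifetime): a power analysis of
the estimator showed one-photon probes (r₀ ≤ 0.4) leave θ's standard
error at 2–3%, i.e. a 5% criterion sits inside the noise, while the
larger two-photon photoselection swing (the emulated instrument excites
at 830 nm, two-photon) brings every parameter's 3σ under 4%. r∞ = 0 is
verified with an absolute bound (|r∞| < 0.01).

**Phasors** use harmonic 1 at ω = 2π/window (the transform constants are
a package choice). Calibration is a phase/modulation correction anchored
on a rendered τ_ref = 2 ns mono-exponential at the reference wavelength:
it removes the IRF phase while leaving fiber shifts visible, which is the
mechanism by which both shift and lifetime move the per-cell phasor.

**Per-cell contrast.** Cells are ROI label masks (segmentation itself is
upstream; masks are consumed, not produced). Every per-cell quantity is
the mean over the ROI's non-NaN pixels, or a fit to the ROI-summed
histogram. The λ-τ map is the 2-D histogram of decoded peak wavelength
against mean lifetime. The seven-parameter sequential table (f₁%, a₁ of
the rotational fit, intensity, t_m, λ_peak, r_static, θ_mean) is
standardized to z-scores (sample SD; constant columns zero with a
warning) and reduced by PCA — ordinary by default, L1-sparse behind a
flag; the sparse variant reports score variance over total variance as
its explained-variance ratio, and loading signs are fixed so each
vector's largest entry is positive. Clustering is k-means++ with 10
restarts per k and a fixed seed; the mean Euclidean silhouette selects k,
ties breaking toward smaller k. Arbitrary column subsets can be fed to
the PCA (the extended 25-parameter variant is a demo, not an invariant);
LDA and t-SNE/UMAP-style embeddings are out of scope since no labels
exist before clustering.

## Synthetic phantoms

The generator's scenarios define the study conditions:

* `two_population_leaf` (the headline phantom): 64×64 px, 25 square cell
  ROIs separated by background gutters, ~45% of cells anthocyanin-rich.
  Anthocyanin-like species: bi-exponential 0.6/1.8 ns (amplitudes
  0.75/0.25, amplitude-mean 0.9 ns — inside the 0.5–3.0 ns anthocyanin
  reference bracket), emission 645 ± 8 nm; background autofluorescence:
  2.6/0.9 ns (0.8/0.2), 615 ± 8 nm. Rich cells carry 85% anthocyanin
  fraction, poor cells 15%, each jittered ±5% per cell; brightness varies
  0.9–1.2×. Both species share identical rotational parameters, so the
  anisotropy columns of the sequential table carry noise but no
  between-population signal — as in a sample whose polarization axis has
  already been fixed. 300 expected photons per pixel put ≥3×10⁴ photons
  in every 100 px cell (the ≥10⁴-per-cell regime); acquisition uses the
  630/69 nm band and the (160°, 80°) waveplate pair.
* `bandpass_demo`: every cell shares a dominant far-red emitter
  (680 ± 10 nm, 75% of photons) outside the 630/69 band plus a per-cell
  minor species spread over 610–655 nm. Without the filter the decoded
  shifts cluster at the dominant peak; the filter suppresses it and the
  per-cell variation emerges — the mechanism behind the observed widening
  of the shift distribution. Both members of the pair render at identical
  photon settings.
* `polarization_scan_demo`: two regions whose species differ only in
  rotational mobility; the waveplate scan's default statistic is the
  spread of ROI-mean static anisotropy on a low-photon render.
* `uniform`: one homogeneous ROI for noise floors and determinism checks.

The sequential-acquisition route splits the single-shot photon budget
evenly over its four passes (lifetime, parallel, perpendicular, fiber), so
route comparisons are at matched total budget.

What the phantoms do **not** emulate: real cell morphology, spatial
photon-rate gradients, chlorophyll and cuticle autofluorescence spectra,
segmentation errors, detector afterpulsing/dark noise, and real filter
roll-off. Passing tests therefore demonstrate that the decoders invert
the stated forward model at realistic photon budgets — not that the
contrast ordering would survive every confound of a real leaf.

## Problem sizes

Default test and acceptance runs use 64×64×256 stacks (25 cells),
10⁵–10⁶ photons per fitted histogram, and 20-seed repeats only inside the
estimator power analysis; these sizes were chosen as the smallest at which
the per-cell statistics are stable.

## Known limitations

* The SDT reader supports the documented uncompressed single-block layout
  only and fails loudly elsewhere; the dialect written by specific SPCM
  builds may differ.
* The circular-excitation anisotropy convention (−r/2) is geometry
  dependent (see above); polarization-scan results should be read as
  relative contrast, not absolute r.
* Triple-exponential and global (image-linked) lifetime fitting, spectral
  unmixing of multiple simultaneous peaks, r(t) deconvolution, and
  incomplete-decay fitting of *measured* wrapped data are not implemented.
* Parameter images fit every pixel independently; the `stride` option
  trades resolution for speed on large images.
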