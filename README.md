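# fiberhdim

Hyperdimensional fluorescence contrast through a single detector: simulate
and decode TCSPC image stacks in which a fluorophore's **emission spectrum**,
**polarization**, and **lifetime** are all encoded in one per-pixel decay
histogram, the way a long multimode fiber plus waveplate-controlled
excitation does it physically on a FLIM microscope.

## Who this is for

FLIM/TCSPC researchers who want to prototype, validate, or teach
fiber-dispersion contrast imaging without a microscope: plant-cell work
separating anthocyanin-rich from anthocyanin-poor cells by their intrinsic
fluorescence is the motivating application, but the pipeline is agnostic to
the sample.

## The encoding and its decoders

A pixel's photon-arrival histogram is modelled as

```
I(x,y,t) = Poisson{ N · IRF ⊗ [ Σᵢ fᵢ aᵢ e^(−t/τᵢ) · w(t) ] ⊛ S(λ→t) }
```

* **Lifetime** — each species decays as Σ aᵢ e^(−t/τᵢ).
* **Polarization** — waveplate angles (HWP/QWP, Jones calculus) set the
  excitation ellipse; dipole photoselection turns the species' anisotropy
  decay r(t) = r₀e^(−t/θ) + r∞ into a time-dependent analyzer weight
  w(t) = (1 + 2κ·r(t))/3, with κ the photoselection factor of the ellipse.
* **Spectrum** — chromatic dispersion in a 30 m fiber delays photons by
  20 ps per nm of emission wavelength (10 nm ↔ 200 ps), convolving the
  Gaussian emission line S(λ) onto the time axis; an optional 630/69 nm
  bandpass restricts it.

Decoders provided:

* `fit_multiexp` — IRF-reconvolution weighted least squares, 1 or 2
  exponentials, optional free time-shift (decodes the spectral peak
  jointly with the lifetimes).
* `estimate_time_shift` — sub-bin cross-correlation lag against a
  reference decay (λ_max decoding: λ = λ_ref + shift / 20 ps·nm⁻¹).
* `fit_associated_anisotropy` — associated anisotropy model, each lifetime
  species carrying its own (r₀, θ, r∞), fitted jointly on the
  parallel/perpendicular channel pair.
* `phasor_transform` — fit-free (g, s) projection,
  g = ⟨cos ωt⟩, s = ⟨sin ωt⟩, ω = 2π/window: lifetimes move the point
  along the universal semicircle, fiber shifts rotate it by exactly ωΔ
  (Fourier shift theorem) — both contrast axes land in one plane.
* `lambda_tau`, `pca_contrast`, `cluster_separation` — λ-τ maps,
  standardized multiparameter PCA, and variable-k k-means with silhouette
  scoring for per-cell contrast.

## Worked example

Render the two-population leaf phantom (25 epidermis-like cell ROIs on a
64×64 grid, two species: a short-lived red-shifted anthocyanin-like pigment
vs. longer-lived autofluorescence), then separate the populations from the
single encoded stack:

```python
from fiberhdim import make_fixture, single_shot_cell_table, cluster_separation

phantom, config, stacks = make_fixture("two_population_leaf", seed=7)
stack = stacks["stack"]
table = single_shot_cell_table(stack, phantom.label_image)
print(table.head(4).round(3))
best_k, labels, sil = cluster_separation(table[["g", "s"]].to_numpy(), (2, 3, 4), seed=7)
print(f"best k = {best_k}, silhouette = {sil[best_k]:.3f}")
```

prints

```
         g      s  intensity    t_m  peak_wavelength
roi
1    0.641  0.478    35815.0  1.287          639.277
2    0.498  0.421    28102.0  2.319          616.088
3    0.500  0.425    26945.0  2.280          617.865
4    0.636  0.475    31573.0  1.321          639.337
best k = 2, silhouette = 0.949
```

Cells 1 and 4 are anthocyanin-rich: shorter mean lifetime (~1.3 ns vs
~2.3 ns) and a red-shifted decoded emission peak (~639 nm vs ~617 nm),
read off the *same* decay curves that the phasor coordinates (g, s) came
from. A k = 2 clustering of the per-cell phasors separates the two
populations with silhouette 0.95 — well above the 0.5 threshold for
substantial cluster structure.

## Command line

```bash
fiberhdim fixtures --scenario two_population_leaf --seed 7 --out fx/
fiberhdim simulate --phantom fx/phantom.json --config fx/config.json --seed 7 --out stack.tiff
fiberhdim contrast --stack stack.tiff --mask fx/mask.tiff --mode phasor --k 2..4 --seed 7 --out out/
fiberhdim polscan  --phantom fx/phantom.json --out scan/        # waveplate-angle contrast scan
fiberhdim fit      --stack stack.tiff --components 2 --kernel 5 --out params/
fiberhdim aniso    --par par.tiff --perp perp.tiff --lifetimes 0.8,2.5 --out aniso/
```

Stacks travel as multi-page TIFF (one page per time channel) with a JSON
sidecar; Becker&Hickl `.sdt` files are read (uncompressed blocks only).
Units everywhere: ns for lifetimes, ps for shifts, nm for wavelengths.

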