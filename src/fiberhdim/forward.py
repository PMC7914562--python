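"""Forward optical model: render spectrally dispersed, polarisation filtered
TCSPC image stacks from a scene phantom.

The rendering chain per species is

    decay(t) * w(t)  ->  fiber dispersion  ->  IRF convolution  ->  Poisson

where ``w(t)`` is the analyzer weight from time-resolved photoselection,
fiber dispersion shifts the decay by ``dispersion_coeff * (lambda - ref)``
integrated over the species' Gaussian emission spectrum (truncated to the
bandpass when one is configured), and the IRF is a unit-area Gaussian.
Profiles are normalised so that with no analyzer and no bandpass a pixel's
expected total equals its photon budget; optical losses reduce it.
"""
from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence

import numpy as np

from .polarization import detection_weight_t, excitation_state
from .types import DecayStack, FiberHdimError, FluorSpecies, InstrumentConfig, ScenePhantom

__all__ = [
    "disperse_decay",
    "spectral_samples",
    "render_pixel",
    "expected_pixel_profile",
    "render_stack",
    "polarization_scan",
    "convolve_irf",
]

Mixture = Sequence[tuple[FluorSpecies, float]]


def fractional_shift(y: np.ndarray, shift_bins: float, circular: bool = False) -> np.ndarray:
    """Delay ``y`` by a (possibly fractional) number of bins.

    Linear two-tap interpolation: conserves the total except for mass pushed
    past the window edges; with ``circular`` the shift wraps (periodic
    excitation) and conserves exactly.
    """
    y = np.asarray(y, dtype=float)
    m = int(np.floor(shift_bins))
    f = shift_bins - m

    def _int_shift(arr: np.ndarray, k: int) -> np.ndarray:
        if circular:
            return np.roll(arr, k)
        out = np.zeros_like(arr)
        if k == 0:
            out[:] = arr
        elif k > 0:
            if k < arr.size:
                out[k:] = arr[:-k]
        else:
            if -k < arr.size:
                out[:k] = arr[-k:]
        return out

    if f == 0.0:
        return _int_shift(y, m)
    return (1.0 - f) * _int_shift(y, m) + f * _int_shift(y, m + 1)


def spectral_samples(
    peak: float,
    width: float,
    config: InstrumentConfig,
    n_samples: int = 301,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretise the Gaussian emission line into (wavelengths, weights).

    The line is cut into cells whose boundaries include the exact bandpass
    edges; each cell's weight is its exact Gaussian mass (CDF difference),
    so the weights sum to the transmitted spectral fraction of the full
    line.  A filter cutting into the line therefore returns weights
    summing to < 1.
    """
    from scipy.special import ndtr  # standard normal CDF

    if width < 0:
        raise FiberHdimError("emission width must be >= 0")
    band = config.bandpass
    if width == 0:
        lam = np.array([peak])
        w = np.array([1.0])
        if band is not None:
            keep = (lam >= band[0]) & (lam <= band[1])
            lam, w = lam[keep], w[keep]
        return lam, w
    edges = np.linspace(peak - 6.0 * width, peak + 6.0 * width, n_samples + 1)
    if band is not None:
        edges = np.union1d(edges, [b for b in band if edges[0] < b < edges[-1]])
    w = ndtr((edges[1:] - peak) / width) - ndtr((edges[:-1] - peak) / width)
    lam = 0.5 * (edges[1:] + edges[:-1])
    if band is not None:
        keep = (lam >= band[0]) & (lam <= band[1])
        lam, w = lam[keep], w[keep]
    return lam, w


def disperse_decay(
    decay: np.ndarray,
    peak: float,
    width: float,
    config: InstrumentConfig,
    n_samples: int = 301,
) -> np.ndarray:
    """Convolve a time profile with the fiber-dispersed emission spectrum.

    Returns ``sum_j S(lambda_j) decay(t - c*(lambda_j - ref))`` on the bin
    grid; the output integral equals (transmitted fraction) x input
    integral, minus any mass shifted outside the timing window (warned).
    """
    decay = np.asarray(decay, dtype=float)
    if decay.shape != (config.n_bins,):
        raise FiberHdimError("decay must be sampled on the config bin grid")
    lam, w = spectral_samples(peak, width, config, n_samples)
    out = np.zeros_like(decay)
    for lj, wj in zip(lam, w):
        shift_ns = config.dispersion_coeff * (lj - config.ref_wavelength) / 1000.0
        out += wj * fractional_shift(decay, shift_ns / config.dt, circular=config.wrap)
    expected = w.sum() * decay.sum()
    if expected > 0 and out.sum() < 1e-9 * expected:
        warnings.warn(
            "dispersion shifted essentially all signal outside the timing window",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def convolve_irf(profile: np.ndarray, config: InstrumentConfig) -> np.ndarray:
    """Convolve a profile (defined from t=0) with the unit-area IRF kernel.

    Linear convolution truncated to the window, or circular convolution
    when the config models periodic re-excitation (``wrap``).
    """
    kernel = config.irf_kernel()
    if config.wrap:
        return np.real(np.fft.ifft(np.fft.fft(profile) * np.fft.fft(kernel)))
    return np.convolve(profile, kernel)[: config.n_bins]


def _folded_emission(species: FluorSpecies, config: InstrumentConfig,
                     weighted: bool) -> np.ndarray:
    """Species emission on the bin grid; periodised over K windows if wrapping.

    ``weighted`` applies the time-resolved analyzer weight w(t) before
    folding (the photoselection state of a photon depends on its true age,
    not its arrival bin).
    """
    n = config.n_bins
    if config.wrap:
        k_periods = max(1, int(np.ceil(8.0 * max(species.lifetimes) / config.window)))
    else:
        k_periods = 1
    t = (np.arange(k_periods * n) + 0.5) * config.dt
    base = species.decay(t)
    if weighted:
        state = excitation_state(config.hwp_angle, config.qwp_angle)
        base = base * detection_weight_t(species, state, config.analyzer, t)
    return base.reshape(k_periods, n).sum(axis=0)


def expected_species_profile(
    species: FluorSpecies,
    config: InstrumentConfig,
    disperse: bool = True,
) -> np.ndarray:
    """Expected (pre-Poisson) unit-budget time profile of one species.

    Normalised by the lossless reference (analyzer "none", no bandpass) so
    the profile sums to the fraction of the photon budget that survives
    analyzer and filter losses.
    """
    norm = _folded_emission(species, config, weighted=False).sum()
    weighted = _folded_emission(species, config, weighted=True)
    # IRF placement first: its offset from t=0 leaves headroom so that
    # blue-of-reference dispersion shifts stay inside the window
    profile = convolve_irf(weighted, config)
    if disperse:
        profile = disperse_decay(profile, species.emission_peak, species.emission_width, config)
    return profile / norm


def expected_pixel_profile(
    mixture: Mixture,
    n_photons: float,
    config: InstrumentConfig,
    disperse: bool = True,
) -> np.ndarray:
    """Expected histogram of a pixel holding ``mixture`` at budget ``n_photons``."""
    fractions = np.array([f for _, f in mixture], dtype=float)
    if fractions.size and not np.isclose(fractions.sum(), 1.0, atol=1e-6):
        raise FiberHdimError(f"mixture fractions sum to {fractions.sum()}, not 1")
    if n_photons < 0:
        raise FiberHdimError("expected photon count must be >= 0")
    out = np.zeros(config.n_bins)
    for (species, frac) in mixture:
        out += frac * expected_species_profile(species, config, disperse=disperse)
    return n_photons * out


def render_pixel(
    mixture: Mixture,
    n_photons: float,
    config: InstrumentConfig,
    rng: np.random.Generator,
    noise: bool = True,
    disperse: bool = True,
) -> np.ndarray:
    """Render one pixel: expected profile, then Poisson shot noise."""
    expected = expected_pixel_profile(mixture, n_photons, config, disperse=disperse)
    if not noise:
        return expected
    return rng.poisson(expected).astype(np.int64)


def render_stack(
    phantom: ScenePhantom,
    config: InstrumentConfig,
    seed: Optional[int] = None,
    noise: bool = True,
) -> DecayStack:
    """Render a full DecayStack from a phantom.

    Pixels within one ROI share the expected profile (same mixture and
    brightness); Poisson draws are i.i.d. per pixel from a generator seeded
    by ``seed`` (default ``config.seed``), drawn ROI-by-ROI in sorted id
    order so the output is bit-reproducible.
    """
    labels = phantom.label_image
    ny, nx = labels.shape
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = np.zeros((ny, nx, config.n_bins), dtype=np.float64 if not noise else np.int64)

    present = [int(i) for i in np.unique(labels)]
    for roi in present:
        if roi != 0 and roi not in phantom.cell_mixtures:
            raise FiberHdimError(f"ROI id {roi} present in label image but has no mixture")

    for roi in present:
        mixture = phantom.cell_mixtures.get(roi, [])
        rate = phantom.brightness.get(roi, 0.0 if roi == 0 else 1.0)
        n_photons = rate * config.photons_per_pixel_scale
        mask = labels == roi
        npix = int(mask.sum())
        if not mixture or n_photons <= 0:
            continue
        expected = expected_pixel_profile(mixture, n_photons, config)
        if noise:
            out[mask] = rng.poisson(np.broadcast_to(expected, (npix, config.n_bins)))
        else:
            out[mask] = expected
    if noise:
        out = out.astype(np.uint32)
    return DecayStack(counts=out, config=config, truth=phantom)


def _default_contrast(stack_builder: Callable[[str], DecayStack], phantom: ScenePhantom,
                      g_factor: float) -> float:
    """Max pairwise |delta r_static| between ROI-mean anisotropies."""
    from .anisotropy import static_anisotropy  # local import avoids a cycle

    par = stack_builder("parallel")
    perp = stack_builder("perpendicular")
    labels = phantom.label_image
    r_values = []
    for roi in phantom.roi_ids:
        mask = labels == roi
        i_par = float(par.counts[mask].sum())
        i_perp = float(perp.counts[mask].sum())
        if i_par + 2.0 * g_factor * i_perp <= 0:
            continue
        r, _ = static_anisotropy(i_par, i_perp, g_factor)
        r_values.append(r)
    if len(r_values) < 2:
        raise FiberHdimError("contrast needs at least two ROIs with signal")
    r_values = np.asarray(r_values)
    return float(np.max(r_values) - np.min(r_values))


def polarization_scan(
    phantom: ScenePhantom,
    config: InstrumentConfig,
    hwp_grid: Sequence[float],
    qwp_grid: Sequence[float],
    contrast_fn: Optional[Callable[[ScenePhantom, InstrumentConfig], float]] = None,
    photons: float = 200.0,
    noise: bool = True,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Scan HWP x QWP angles and score inter-ROI anisotropy contrast.

    Each angle pair gets a low-photon render (parallel and perpendicular
    channels) and the contrast statistic (default: spread of ROI-mean static
    anisotropy).  Returns the contrast matrix (hwp x qwp) and the maximising
    angle pair; ties break toward the smallest angles in grid order.
    """
    hwp_grid = list(hwp_grid)
    qwp_grid = list(qwp_grid)
    if not hwp_grid or not qwp_grid:
        raise FiberHdimError("angle grids must be non-empty")
    if len(phantom.roi_ids) < 2:
        raise FiberHdimError("polarization scan needs >= 2 ROIs to define contrast")
    base_seed = config.seed if seed is None else seed
    matrix = np.zeros((len(hwp_grid), len(qwp_grid)))
    for i, hwp in enumerate(hwp_grid):
        for j, qwp in enumerate(qwp_grid):
            cfg = config.replace(
                hwp_angle=hwp, qwp_angle=qwp, photons_per_pixel_scale=photons
            )
            if contrast_fn is not None:
                matrix[i, j] = contrast_fn(phantom, cfg)
            else:
                pair_seed = (base_seed + 1_000_003 * i + 101 * j) % (2**31 - 1)

                def _build(analyzer: str, cfg=cfg, pair_seed=pair_seed) -> DecayStack:
                    return render_stack(
                        phantom,
                        cfg.replace(analyzer=analyzer),
                        seed=pair_seed + (0 if analyzer == "parallel" else 1),
                        noise=noise,
                    )

                matrix[i, j] = _default_contrast(_build, phantom, cfg.g_factor)
    best = np.unravel_index(int(np.argmax(matrix)), matrix.shape)
    return matrix, (hwp_grid[best[0]], qwp_grid[best[1]])
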