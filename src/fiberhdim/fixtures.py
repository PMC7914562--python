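"""Deterministic synthetic scenes ("phantoms") for testing and demos.

Each scenario emulates a condition of the imaging study on desk-scale
images:

``uniform``
    One homogeneous region, single species — sanity checks and noise floors.
``two_population_leaf``
    A cotyledon-epidermis-like grid of >= 20 cell ROIs split between an
    anthocyanin-rich and an anthocyanin-poor population.  The two species
    carry distinct lifetimes inside the 0.5-3.0 ns anthocyanin reference
    bracket and emission peaks separated within the 630/69 nm band; each
    cell receives >= 10^4 photons.
``polarization_scan_demo``
    Two regions whose species differ only in rotational mobility (hence
    steady-state anisotropy) — the target of the waveplate-angle scan.
``bandpass_demo``
    Cells sharing one bright far-red emitter plus a per-cell minor species
    whose peaks spread across the band; rendered twice (filter off / on) at
    identical photon settings to show the filter widening the decoded
    time-shift distribution.
"""
from __future__ import annotations

import numpy as np

from .forward import render_stack
from .types import DecayStack, FiberHdimError, FluorSpecies, InstrumentConfig, ScenePhantom

__all__ = ["make_fixture", "SCENARIOS", "cell_grid_labels"]

SCENARIOS = ("uniform", "two_population_leaf", "polarization_scan_demo", "bandpass_demo")

# species parameter sets; the anthocyanin-like pigment is short-lived and
# red-shifted relative to the background autofluorescence
ANTHOCYANIN_LIKE = FluorSpecies(
    name="anthocyanin_like",
    lifetimes=(0.6, 1.8),
    amplitudes=(0.75, 0.25),
    emission_peak=645.0,
    emission_width=8.0,
    r0=0.38,
    r_inf=0.04,
    theta_rot=0.4,
)
AUTOFLUOR_LONG = FluorSpecies(
    name="autofluor_long",
    lifetimes=(2.6, 0.9),
    amplitudes=(0.8, 0.2),
    emission_peak=615.0,
    emission_width=8.0,
    r0=0.38,
    r_inf=0.04,
    theta_rot=0.4,
)


def cell_grid_labels(size: int = 64, n_side: int = 5, gutter: int = 2) -> np.ndarray:
    """A grid of square cell ROIs separated by background gutters."""
    labels = np.zeros((size, size), dtype=np.int32)
    cell = size // n_side
    roi = 0
    for gi in range(n_side):
        for gj in range(n_side):
            roi += 1
            r0 = gi * cell + gutter
            c0 = gj * cell + gutter
            r1 = min((gi + 1) * cell, size)
            c1 = min((gj + 1) * cell, size)
            labels[r0:r1, c0:c1] = roi
    return labels


def _uniform(seed: int):
    labels = np.ones((32, 32), dtype=np.int32)
    species = FluorSpecies(
        name="mono", lifetimes=(2.0,), amplitudes=(1.0,),
        emission_peak=630.0, emission_width=0.0,
    )
    phantom = ScenePhantom(labels, {1: [(species, 1.0)]}, {1: 1.0})
    config = InstrumentConfig(seed=seed, photons_per_pixel_scale=300.0)
    return phantom, config, {"stack": render_stack(phantom, config, seed=seed)}


def _two_population_leaf(seed: int):
    rng = np.random.default_rng(seed)
    labels = cell_grid_labels(64, 5, 2)  # 25 cells of ~10x10 px
    n_cells = int(labels.max())
    # split the populations, guaranteeing both are well represented
    rich = set(rng.permutation(np.arange(1, n_cells + 1))[: n_cells // 2])
    mixtures = {}
    brightness = {0: 0.02}
    for roi in range(1, n_cells + 1):
        jitter = float(rng.uniform(-0.05, 0.05))
        f_antho = (0.85 if roi in rich else 0.15) + jitter
        mixtures[roi] = [(ANTHOCYANIN_LIKE, f_antho), (AUTOFLUOR_LONG, 1.0 - f_antho)]
        brightness[roi] = float(rng.uniform(0.9, 1.2))
    phantom = ScenePhantom(labels, mixtures, brightness)
    # 630/69 band, fiber dispersion on, ~3e4 photons per 100 px cell
    config = InstrumentConfig(
        seed=seed,
        photons_per_pixel_scale=300.0,
        bandpass_center=630.0,
        bandpass_width=69.0,
        hwp_angle=160.0,
        qwp_angle=80.0,
    )
    return phantom, config, {"stack": render_stack(phantom, config, seed=seed)}


def _polarization_scan_demo(seed: int):
    labels = np.zeros((32, 32), dtype=np.int32)
    labels[:, :15] = 1
    labels[:, 17:] = 2
    mobile = FluorSpecies(
        name="mobile", lifetimes=(2.0,), amplitudes=(1.0,),
        emission_peak=630.0, emission_width=0.0, r0=0.38, r_inf=0.0, theta_rot=0.2,
    )
    hindered = FluorSpecies(
        name="hindered", lifetimes=(2.0,), amplitudes=(1.0,),
        emission_peak=630.0, emission_width=0.0, r0=0.38, r_inf=0.3, theta_rot=5.0,
    )
    phantom = ScenePhantom(
        labels, {1: [(mobile, 1.0)], 2: [(hindered, 1.0)]}, {1: 1.0, 2: 1.0}
    )
    config = InstrumentConfig(seed=seed, photons_per_pixel_scale=200.0)
    return phantom, config, {"stack": render_stack(phantom, config, seed=seed)}


def _bandpass_demo(seed: int):
    rng = np.random.default_rng(seed)
    labels = cell_grid_labels(64, 5, 2)
    n_cells = int(labels.max())
    dominant = FluorSpecies(
        name="farred_dominant", lifetimes=(1.2,), amplitudes=(1.0,),
        emission_peak=680.0, emission_width=10.0,
    )
    mixtures = {}
    brightness = {0: 0.02}
    peaks = np.linspace(610.0, 655.0, n_cells)
    rng.shuffle(peaks)
    for roi in range(1, n_cells + 1):
        minor = FluorSpecies(
            name=f"cell_pigment_{roi}", lifetimes=(2.2,), amplitudes=(1.0,),
            emission_peak=float(peaks[roi - 1]), emission_width=6.0,
        )
        mixtures[roi] = [(dominant, 0.75), (minor, 0.25)]
        brightness[roi] = 1.0
    phantom = ScenePhantom(labels, mixtures, brightness)
    base = InstrumentConfig(seed=seed, photons_per_pixel_scale=400.0)
    filtered = base.replace(bandpass_center=630.0, bandpass_width=69.0)
    return phantom, base, {
        "no_filter": render_stack(phantom, base, seed=seed),
        "filter": render_stack(phantom, filtered, seed=seed + 1),
    }


def make_fixture(name: str, seed: int = 0
                 ) -> tuple[ScenePhantom, InstrumentConfig, dict[str, DecayStack]]:
    """Build a named deterministic phantom and its rendered stack(s).

    Returns (phantom, config, stacks); most scenarios render a single
    ``"stack"``, the bandpass demo a paired ``"no_filter"``/``"filter"``.
    """
    builders = {
        "uniform": _uniform,
        "two_population_leaf": _two_population_leaf,
        "polarization_scan_demo": _polarization_scan_demo,
        "bandpass_demo": _bandpass_demo,
    }
    if name not in builders:
        raise FiberHdimError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return builders[name](int(seed))
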