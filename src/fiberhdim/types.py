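"""Core domain types for fiber-HDIM simulation and analysis.

Unit conventions used throughout the package (and on every CLI surface):
lifetimes and timing windows in nanoseconds, time-shifts and IRF widths in
picoseconds, wavelengths in nanometres, angles in degrees.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FluorSpecies",
    "InstrumentConfig",
    "ScenePhantom",
    "DecayStack",
    "FiberHdimError",
]


class FiberHdimError(ValueError):
    """User-facing error (bad input, bad configuration, malformed file)."""


# hard physical ceiling on the initial anisotropy; one-photon collinear
# dipoles give 0.4, two-photon photoselection allows up to 4/7 ~ 0.571
R0_TWO_PHOTON_MAX = 4.0 / 7.0


@dataclass(frozen=True)
class FluorSpecies:
    """A fluorophore: decay components, emission spectrum, rotational mobility.

    The decay is a sum of exponentials ``I(t) = sum_i a_i exp(-t/tau_i)``;
    the emission spectrum is a single Gaussian (peak, sigma); depolarisation
    follows ``r(t) = r0 * exp(-t/theta_rot) + r_inf``.
    """

    name: str
    lifetimes: tuple[float, ...]
    amplitudes: tuple[float, ...]
    emission_peak: float
    emission_width: float
    r0: float = 0.4
    r_inf: float = 0.0
    theta_rot: float = 1.0

    def __post_init__(self) -> None:
        lifetimes = tuple(float(t) for t in self.lifetimes)
        amplitudes = tuple(float(a) for a in self.amplitudes)
        object.__setattr__(self, "lifetimes", lifetimes)
        object.__setattr__(self, "amplitudes", amplitudes)
        if len(lifetimes) != len(amplitudes) or len(lifetimes) < 1:
            raise FiberHdimError(
                f"{self.name}: need matching, non-empty lifetimes/amplitudes"
            )
        if any(t <= 0 for t in lifetimes):
            raise FiberHdimError(f"{self.name}: lifetimes must be positive")
        if any(a < 0 for a in amplitudes) or sum(amplitudes) <= 0:
            raise FiberHdimError(
                f"{self.name}: amplitudes must be non-negative with positive sum"
            )
        if self.emission_width < 0:
            raise FiberHdimError(f"{self.name}: emission_width must be >= 0")
        if not (-0.5 <= self.r_inf <= self.r0 <= R0_TWO_PHOTON_MAX):
            raise FiberHdimError(
                f"{self.name}: need -0.5 <= r_inf <= r0 <= {R0_TWO_PHOTON_MAX:.3f}"
            )
        if self.theta_rot <= 0:
            raise FiberHdimError(f"{self.name}: theta_rot must be positive")

    # -- derived photophysics -------------------------------------------------

    def decay(self, t: np.ndarray) -> np.ndarray:
        """Multi-exponential population decay evaluated at times ``t`` (ns)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, tau in zip(self.amplitudes, self.lifetimes):
            out += a * np.exp(-np.clip(t, 0.0, None) / tau)
        out[t < 0] = 0.0
        return out

    def anisotropy(self, t: np.ndarray) -> np.ndarray:
        """r(t) = r0 exp(-t/theta_rot) + r_inf."""
        t = np.asarray(t, dtype=float)
        return (self.r0 - self.r_inf) * np.exp(-np.clip(t, 0.0, None) / self.theta_rot) + self.r_inf

    def steady_state_anisotropy(self) -> float:
        """Intensity-weighted time average of r(t) (closed form)."""
        num = 0.0
        den = 0.0
        for a, tau in zip(self.amplitudes, self.lifetimes):
            th = self.theta_rot
            num += a * ((self.r0 - self.r_inf) * tau * th / (tau + th) + self.r_inf * tau)
            den += a * tau
        return num / den

    def mean_lifetime(self) -> float:
        """Amplitude-weighted mean lifetime (ns)."""
        a = np.asarray(self.amplitudes)
        tau = np.asarray(self.lifetimes)
        return float((a * tau).sum() / a.sum())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FluorSpecies":
        d = dict(d)
        d["lifetimes"] = tuple(d["lifetimes"])
        d["amplitudes"] = tuple(d["amplitudes"])
        return cls(**d)


@dataclass(frozen=True)
class InstrumentConfig:
    """Timing, IRF, fiber dispersion, polarisation optics and photon budget.

    Defaults describe an 80 MHz-class two-photon FLIM system: 12.5 ns window
    over 256 TCSPC channels, 150 ps FWHM Gaussian IRF centred at 10% of the
    window, and the 30 m GRIN-fiber dispersion calibration of 20 ps/nm
    (10 nm of wavelength per 200 ps of time-shift).
    """

    n_bins: int = 256
    window: float = 12.5           # ns
    irf_center: float = 1.25       # ns
    irf_fwhm: float = 150.0        # ps
    dispersion_coeff: float = 20.0  # ps/nm
    ref_wavelength: float = 630.0  # nm mapped to zero extra delay
    bandpass_center: Optional[float] = None  # nm; None disables the filter
    bandpass_width: Optional[float] = None   # full width, nm
    hwp_angle: float = 0.0         # degrees
    qwp_angle: float = 0.0         # degrees
    analyzer: str = "none"         # "parallel" | "perpendicular" | "none"
    g_factor: float = 1.0
    photons_per_pixel_scale: float = 500.0
    seed: int = 0
    r_max: float = 0.4
    two_photon: bool = False
    wrap: bool = False  # periodic re-excitation: incomplete decays fold into the next window

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise FiberHdimError("n_bins must be >= 2")
        if self.window <= 0:
            raise FiberHdimError("window must be positive")
        if self.dispersion_coeff < 0:
            raise FiberHdimError("dispersion_coeff must be >= 0")
        if self.g_factor <= 0:
            raise FiberHdimError("g_factor must be positive")
        if self.analyzer not in ("parallel", "perpendicular", "none"):
            raise FiberHdimError(f"unknown analyzer {self.analyzer!r}")
        if (self.bandpass_center is None) != (self.bandpass_width is None):
            raise FiberHdimError("bandpass_center and bandpass_width go together")
        if self.two_photon and self.r_max == 0.4:
            # two-photon photoselection permits r0 up to 4/7
            object.__setattr__(self, "r_max", R0_TWO_PHOTON_MAX)

    # -- time axis ------------------------------------------------------------

    @property
    def dt(self) -> float:
        """Bin width (ns); bins are half-open [t, t + dt)."""
        return self.window / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dt

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.dt

    @property
    def bandpass(self) -> Optional[tuple[float, float]]:
        """(lo, hi) transmission window in nm, or None."""
        if self.bandpass_center is None:
            return None
        half = self.bandpass_width / 2.0
        return (self.bandpass_center - half, self.bandpass_center + half)

    def irf_kernel(self) -> np.ndarray:
        """Unit-area Gaussian IRF as a convolution kernel.

        Sampled at integer-bin lags (t = m dt) so that convolving a
        bin-center-sampled profile lands back on bin centers.
        """
        sigma = self.irf_fwhm / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        t = np.arange(self.n_bins) * self.dt
        if sigma <= 0:
            k = np.zeros(self.n_bins)
            k[int(round(self.irf_center / self.dt)) % self.n_bins] = 1.0
            return k
        k = np.exp(-0.5 * ((t - self.irf_center) / sigma) ** 2)
        if k.sum() == 0.0:  # sub-bin sigma underflows: fall back to a delta
            k[int(round(self.irf_center / self.dt)) % self.n_bins] = 1.0
        return k / k.sum()

    def replace(self, **kw) -> "InstrumentConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "InstrumentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ScenePhantom:
    """A labelled scene: ROI map plus per-ROI species mixtures and brightness.

    ROI id 0 is reserved for background.  ``cell_mixtures`` maps ROI id to a
    list of (species, fraction) with fractions summing to 1; ``brightness``
    maps ROI id to a relative photon rate (background defaults to 0).
    """

    label_image: np.ndarray
    cell_mixtures: dict[int, list[tuple[FluorSpecies, float]]]
    brightness: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2 or not np.issubdtype(self.label_image.dtype, np.integer):
            raise FiberHdimError("label_image must be a 2-D integer array")
        for roi, mix in self.cell_mixtures.items():
            total = sum(f for _, f in mix)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise FiberHdimError(f"ROI {roi}: mixture fractions sum to {total}, not 1")

    @property
    def roi_ids(self) -> list[int]:
        """Foreground ROI ids present in the label image, sorted."""
        ids = np.unique(self.label_image)
        return [int(i) for i in ids if i != 0]

    def species_names(self) -> list[str]:
        names: list[str] = []
        for mix in self.cell_mixtures.values():
            for sp, _ in mix:
                if sp.name not in names:
                    names.append(sp.name)
        return sorted(names)

    def to_dict(self) -> dict:
        species: dict[str, dict] = {}
        mixtures = {}
        for roi, mix in self.cell_mixtures.items():
            entry = []
            for sp, frac in mix:
                species[sp.name] = sp.to_dict()
                entry.append([sp.name, frac])
            mixtures[str(roi)] = entry
        return {
            "label_image": self.label_image.tolist(),
            "species": species,
            "cell_mixtures": mixtures,
            "brightness": {str(k): v for k, v in self.brightness.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenePhantom":
        species = {k: FluorSpecies.from_dict(v) for k, v in d["species"].items()}
        mixtures = {
            int(roi): [(species[name], float(frac)) for name, frac in mix]
            for roi, mix in d["cell_mixtures"].items()
        }
        brightness = {int(k): float(v) for k, v in d.get("brightness", {}).items()}
        return cls(
            label_image=np.asarray(d["label_image"], dtype=np.int32),
            cell_mixtures=mixtures,
            brightness=brightness,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ScenePhantom":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DecayStack:
    """An X x Y x T photon-count histogram image with timing metadata.

    ``counts`` is indexed (row, col, time-bin); time bin 0 starts at t = 0.
    """

    counts: np.ndarray
    config: InstrumentConfig
    truth: Optional[ScenePhantom] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise FiberHdimError("counts must be a 3-D (Y, X, T) array")
        if self.counts.shape[2] != self.config.n_bins:
            raise FiberHdimError(
                f"stack has {self.counts.shape[2]} time pages but config.n_bins={self.config.n_bins}"
            )
        if np.issubdtype(self.counts.dtype, np.integer) and self.counts.min() < 0:
            raise FiberHdimError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def total_counts(self) -> int:
        return int(self.counts.sum())
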