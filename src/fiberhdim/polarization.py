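"""Excitation polarisation (Jones calculus) and emission detection weights.

The excitation path is modelled as a horizontally polarised laser passing a
quarter-wave plate and then a half-wave plate (the order drawn on the
excitation arm of the instrument); rotating the pair sweeps the excitation
ellipse.  Emission photoselection is reduced to a per-species detection
weight: the fraction of emitted photons accepted by the chosen analyzer
given the species' (time-averaged or instantaneous) anisotropy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import FiberHdimError, FluorSpecies

__all__ = [
    "PolarizationState",
    "excitation_state",
    "detection_weight",
    "photoselection_factor",
]


@dataclass(frozen=True)
class PolarizationState:
    """Fully polarised excitation state in Stokes-like parameters.

    ``linear_fraction`` p = sqrt(S1^2+S2^2)/S0, ``orientation`` the linear
    component's azimuth in degrees, ``circular_fraction`` |S3|/S0; a fully
    polarised state satisfies p^2 + c^2 = 1.
    """

    linear_fraction: float
    orientation: float
    circular_fraction: float
    jones: tuple[complex, complex]

    @property
    def stokes(self) -> tuple[float, float, float, float]:
        ex, ey = self.jones
        s0 = abs(ex) ** 2 + abs(ey) ** 2
        s1 = abs(ex) ** 2 - abs(ey) ** 2
        s2 = 2.0 * (ex * np.conj(ey)).real
        s3 = -2.0 * (ex * np.conj(ey)).imag
        return (s0, s1, s2, s3)


def waveplate(angle_deg: float, retardance: float) -> np.ndarray:
    """Jones matrix of a waveplate with fast axis at ``angle_deg``.

    ``retardance`` is the phase lag of the slow axis (pi for a half-wave
    plate, pi/2 for a quarter-wave plate).
    """
    th = np.deg2rad(angle_deg % 360.0)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])
    core = np.array([[1.0, 0.0], [0.0, np.exp(1j * retardance)]])
    return rot @ core @ rot.T


def excitation_state(hwp_angle: float, qwp_angle: float) -> PolarizationState:
    """Excitation state after QWP then HWP acting on a horizontal input beam."""
    if not (np.isfinite(hwp_angle) and np.isfinite(qwp_angle)):
        raise FiberHdimError("waveplate angles must be finite")
    e_in = np.array([1.0 + 0j, 0.0 + 0j])
    e = waveplate(hwp_angle, np.pi) @ waveplate(qwp_angle, np.pi / 2.0) @ e_in
    ex, ey = complex(e[0]), complex(e[1])
    s0 = abs(ex) ** 2 + abs(ey) ** 2
    s1 = (abs(ex) ** 2 - abs(ey) ** 2) / s0
    s2 = 2.0 * (ex * np.conj(ey)).real / s0
    s3 = -2.0 * (ex * np.conj(ey)).imag / s0
    p = float(np.hypot(s1, s2))
    orientation = float(np.rad2deg(0.5 * np.arctan2(s2, s1)))
    return PolarizationState(
        linear_fraction=p,
        orientation=orientation,
        circular_fraction=float(abs(s3)),
        jones=(ex, ey),
    )


def photoselection_factor(state: PolarizationState, analyzer_angle: float = 0.0) -> float:
    """Scale factor kappa mapping molecular r(t) to the detected effective r.

    For linear excitation at angle chi to the analyzer axis the detected
    anisotropy is ``r_eff = r * (3 cos^2 chi - 1)/2`` (dipole
    photoselection); a circular excitation contributes the standard
    one-photon result ``r_eff = -r/2``.  A fully polarised elliptical state
    is the incoherent p / (1-p) mixture of the two.
    """
    chi = np.deg2rad(state.orientation - analyzer_angle)
    p = state.linear_fraction
    linear_part = (3.0 * np.cos(chi) ** 2 - 1.0) / 2.0
    return float(p * linear_part + (1.0 - p) * (-0.5))


def _weights_from_r(r_eff: np.ndarray | float):
    """(w_parallel, w_perpendicular) from the effective detected anisotropy.

    w_par = (1 + 2 r)/3; w_perp is the average transverse channel
    (1 - w_par)/2 = (1 - r)/3, so w_par + 2 w_perp = 1 identically.
    """
    w_par = (1.0 + 2.0 * np.asarray(r_eff)) / 3.0
    w_perp = (1.0 - w_par) / 2.0
    return w_par, w_perp


def detection_weight(
    species: FluorSpecies,
    state: PolarizationState,
    analyzer: str,
    r_max: float = 0.4,
) -> float:
    """Steady-state fraction of the species' emission passed by the analyzer.

    Uses the intensity-weighted time average of r(t); analyzer "none"
    collects everything (weight 1).
    """
    if analyzer not in ("parallel", "perpendicular", "none"):
        raise FiberHdimError(f"unknown analyzer {analyzer!r}")
    if analyzer == "none":
        return 1.0
    r_ss = species.steady_state_anisotropy()
    if not (-0.5 <= r_ss <= r_max + 1e-12):
        raise FiberHdimError(
            f"{species.name}: steady-state anisotropy {r_ss:.3f} outside [-0.5, {r_max}]"
        )
    kappa = photoselection_factor(state)
    w_par, w_perp = _weights_from_r(kappa * r_ss)
    return float(w_par if analyzer == "parallel" else w_perp)


def detection_weight_t(
    species: FluorSpecies,
    state: PolarizationState,
    analyzer: str,
    t: np.ndarray,
) -> np.ndarray:
    """Time-resolved analyzer weight w(t) built from r(t) (forward model use)."""
    if analyzer == "none":
        return np.ones_like(np.asarray(t, dtype=float))
    kappa = photoselection_factor(state)
    r_eff = kappa * species.anisotropy(t)
    w_par, w_perp = _weights_from_r(r_eff)
    return np.asarray(w_par if analyzer == "parallel" else w_perp)
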