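"""Per-cell hyperdimensional contrast: phasors, lambda-tau maps, PCA, k-means.

The phasor transform projects a decay histogram onto its first Fourier
harmonic,

    g = sum_k I(t_k) cos(n w t_k) / sum_k I(t_k),
    s = sum_k I(t_k) sin(n w t_k) / sum_k I(t_k),   w = 2 pi / window,

so calibrated mono-exponential decays land on the universal semicircle
(g - 1/2)^2 + s^2 = 1/4, and a pure fiber time-shift Delta rotates the
phasor by exactly n*w*Delta (Fourier shift theorem) — which is why both
spectral shift and lifetime move the transform.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, SparsePCA
from sklearn.metrics import silhouette_score

from .types import DecayStack, FiberHdimError, InstrumentConfig

__all__ = [
    "PhasorSet",
    "LambdaTauMap",
    "paint_cells",
    "phasor_transform",
    "phasor_calibration",
    "cell_phasors",
    "lambda_tau",
    "standardize",
    "pca_contrast",
    "cluster_separation",
    "roi_mean_histograms",
]


@dataclass
class PhasorSet:
    """(g, s) coordinates per ROI (or per pixel) at one harmonic."""

    g: np.ndarray
    s: np.ndarray
    roi_ids: np.ndarray
    harmonic: int
    omega: float  # rad/ns
    calibration: tuple[float, float] = (0.0, 1.0)  # (phase shift, modulation ratio)

    def as_points(self) -> np.ndarray:
        return np.column_stack([self.g, self.s])


@dataclass
class LambdaTauMap:
    """2-D histogram of decoded spectral peak vs mean lifetime."""

    hist: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    scatter: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total(self) -> int:
        return int(self.hist.sum())


def paint_cells(label_mask: np.ndarray, parameter_image: np.ndarray
                ) -> tuple[pd.Series, np.ndarray]:
    """Per-ROI mean of non-NaN pixels, and the image repainted with it.

    ROI 0 is background; ROIs with no valid pixel are omitted.  The painted
    image carries NaN outside foreground ROIs.
    """
    label_mask = np.asarray(label_mask)
    parameter_image = np.asarray(parameter_image, dtype=float)
    if label_mask.shape != parameter_image.shape:
        raise FiberHdimError("label mask and parameter image shapes differ")
    painted = np.full(parameter_image.shape, np.nan)
    means: dict[int, float] = {}
    for roi in np.unique(label_mask):
        if roi == 0:
            continue
        values = parameter_image[label_mask == roi]
        values = values[np.isfinite(values)]
        if values.size == 0:
            continue
        m = float(values.mean())
        means[int(roi)] = m
        painted[label_mask == roi] = m
    return pd.Series(means, name="mean"), painted


def phasor_transform(
    hist: np.ndarray,
    config: InstrumentConfig,
    harmonic: int = 1,
    calibration: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """First-harmonic (g, s) phasor of a decay histogram.

    ``calibration`` is a (phase, modulation) correction pair from
    :func:`phasor_calibration`; when given, the raw phasor is rotated by
    the phase and scaled by the modulation ratio.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise FiberHdimError("cannot transform an empty histogram")
    t = (np.arange(hist.size) + 0.5) * (config.window / hist.size)
    w = 2.0 * np.pi * harmonic / config.window
    g = float((hist * np.cos(w * t)).sum() / total)
    s = float((hist * np.sin(w * t)).sum() / total)
    if calibration is not None:
        dphi, mod = calibration
        z = (g + 1j * s) * mod * np.exp(1j * dphi)
        g, s = float(z.real), float(z.imag)
    return g, s


def theoretical_phasor(tau: float, config: InstrumentConfig, harmonic: int = 1
                       ) -> tuple[float, float]:
    """Ideal mono-exponential phasor g = 1/(1+(wt)^2), s = wt/(1+(wt)^2)."""
    w = 2.0 * np.pi * harmonic / config.window
    wt = w * tau
    return 1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)


def phasor_calibration(
    reference_hist: np.ndarray,
    tau_ref: float,
    config: InstrumentConfig,
    harmonic: int = 1,
) -> tuple[float, float]:
    """(phase, modulation) correction putting a known mono-exponential
    reference at its theoretical semicircle point."""
    g_m, s_m = phasor_transform(reference_hist, config, harmonic)
    g_t, s_t = theoretical_phasor(tau_ref, config, harmonic)
    z_m, z_t = g_m + 1j * s_m, g_t + 1j * s_t
    if abs(z_m) == 0:
        raise FiberHdimError("reference phasor has zero modulation")
    ratio = z_t / z_m
    return float(np.angle(ratio)), float(abs(ratio))


def roi_mean_histograms(stack: DecayStack, label_mask: np.ndarray
                        ) -> dict[int, np.ndarray]:
    """Summed decay histogram per foreground ROI."""
    label_mask = np.asarray(label_mask)
    if label_mask.shape != stack.counts.shape[:2]:
        raise FiberHdimError("label mask does not match stack image shape")
    out: dict[int, np.ndarray] = {}
    for roi in np.unique(label_mask):
        if roi == 0:
            continue
        h = stack.counts[label_mask == roi].sum(axis=0).astype(np.float64)
        if h.sum() > 0:
            out[int(roi)] = h
    return out


def cell_phasors(
    stack: DecayStack,
    label_mask: np.ndarray,
    harmonic: int = 1,
    calibration: Optional[tuple[float, float]] = None,
) -> PhasorSet:
    """Calibrated per-cell phasor coordinates from ROI-summed histograms."""
    config = stack.config
    hists = roi_mean_histograms(stack, label_mask)
    roi_ids = np.array(sorted(hists))
    gs = np.array([
        phasor_transform(hists[r], config, harmonic, calibration) for r in roi_ids
    ])
    return PhasorSet(
        g=gs[:, 0], s=gs[:, 1], roi_ids=roi_ids, harmonic=harmonic,
        omega=2.0 * np.pi * harmonic / config.window,
        calibration=calibration or (0.0, 1.0),
    )


def lambda_tau(
    table: pd.DataFrame,
    bins: int | Sequence = 32,
    wavelength_column: Optional[str] = None,
    lifetime_column: Optional[str] = None,
) -> LambdaTauMap:
    """Build the lambda-tau map: 2-D histogram of spectral peak vs lifetime."""
    if wavelength_column is None:
        for cand in ("peak_wavelength", "peak_shift"):
            if cand in table.columns:
                wavelength_column = cand
                break
    if lifetime_column is None:
        for cand in ("t_m", "it_m", "t1"):
            if cand in table.columns:
                lifetime_column = cand
                break
    if wavelength_column is None or lifetime_column is None:
        raise FiberHdimError(
            "table needs a spectral column (peak_wavelength/peak_shift) and a lifetime column"
        )
    x = table[wavelength_column].to_numpy(dtype=float)
    y = table[lifetime_column].to_numpy(dtype=float)
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    scatter = table[[wavelength_column, lifetime_column]].copy()
    return LambdaTauMap(hist=hist, x_edges=xe, y_edges=ye, scatter=scatter)


def standardize(table: pd.DataFrame, columns: Optional[Sequence[str]] = None
                ) -> pd.DataFrame:
    """Z-score columns to mean 0, sample SD 1 (ddof=1).

    Constant columns become all-zero with a warning rather than dividing
    by zero.
    """
    if len(table) < 2:
        raise FiberHdimError("standardization needs at least two rows")
    columns = list(columns) if columns is not None else list(table.columns)
    out = table.copy()
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"column {col!r} is constant; standardized to zeros",
                          RuntimeWarning, stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (x - x.mean()) / sd
    return out


def pca_contrast(
    table: pd.DataFrame,
    n_components: int = 2,
    sparse: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a standardized per-cell table.

    Returns (scores per ROI, loadings, explained variance ratios).  The
    sparse variant uses L1-penalised loadings; its "explained variance" is
    the score variance over the table's total variance.  Sign convention:
    each loading vector's largest-magnitude entry is positive.
    """
    X = table.to_numpy(dtype=float)
    if n_components > X.shape[1]:
        raise FiberHdimError("more components than columns")
    if X.shape[0] < n_components:
        raise FiberHdimError("fewer rows than components")
    if sparse:
        model = SparsePCA(n_components=n_components, random_state=seed)
        scores = model.fit_transform(X)
        loadings = model.components_
        total_var = X.var(axis=0, ddof=1).sum()
        evr = scores.var(axis=0, ddof=1) / total_var if total_var > 0 else np.zeros(n_components)
    else:
        model = PCA(n_components=n_components, random_state=seed)
        scores = model.fit_transform(X)
        loadings = model.components_
        evr = model.explained_variance_ratio_
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    names = [f"PC{i+1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=table.index, columns=names)
    loadings_df = pd.DataFrame(loadings, index=names, columns=table.columns)
    return scores_df, loadings_df, np.asarray(evr)


def cluster_separation(
    points: np.ndarray,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, np.ndarray, dict[int, float]]:
    """Variable-k k-means with mean-silhouette model selection.

    Returns (best_k, labels at best_k, {k: silhouette}); best_k maximises
    the mean Euclidean silhouette, ties breaking toward smaller k.
    """
    points = np.asarray(points, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise FiberHdimError("k_range entries must be >= 2")
    if points.shape[0] < max(ks) + 1:
        raise FiberHdimError("need at least max(k_range)+1 points")
    silhouettes: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(points)
        silhouettes[k] = float(silhouette_score(points, labels))
        labels_by_k[k] = labels
    best_k = ks[0]
    for k in ks[1:]:
        if silhouettes[k] > silhouettes[best_k]:
            best_k = k
    return best_k, labels_by_k[best_k], silhouettes
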