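"""Spectral preprocessing: smoothing, baseline removal, normalisation, resampling.

Two preprocessing tracks are distinguished. The *classical* track, used for
mean-spectra comparison and the PCA-LDA / PCA-SVM chemometric baselines, is
Savitzky-Golay smoothing, then iterative fifth-order polynomial baseline
removal, then per-spectrum min-max normalisation. The *deep* track, used for
the CNN, only resamples each spectrum to the model input length and min-max
normalises it (within-class augmentation is applied separately at the
split stage).

Baseline removal follows the modified-polynomial (peak-clipping) scheme:
fit a degree-5 polynomial to the spectrum, replace every intensity above the
fit by the fit, and iterate until the baseline stops changing. Broad
fluorescence background survives the clipping; narrow Raman peaks do not.

All operations are available both as functions on
:class:`~sersnet.io.Spectrum` / :class:`~sersnet.io.SpectrumSet` and as
scikit-learn transformers on ``(n_spectra, n_points)`` matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DegenerateInputError
from .io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "sg_smooth",
    "remove_baseline",
    "minmax_normalize",
    "resample",
    "run_track",
    "minmax_matrix",
    "SavitzkyGolaySmoother",
    "BaselineRemover",
    "MinMaxPerSpectrum",
    "Resampler",
]


@dataclass
class PreprocessConfig:
    sg_window: int = 11
    sg_polyorder: int = 3
    baseline_degree: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    resample_length: int | None = 2046

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must be odd and > sg_polyorder")
        if self.baseline_degree < 0:
            raise ConfigError("baseline_degree must be >= 0")
        if self.resample_length is not None and self.resample_length < 2:
            raise ConfigError("resample_length must be >= 2")


def sg_smooth(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay (local least-squares polynomial) smoothing."""
    cfg = cfg or PreprocessConfig()
    if cfg.sg_window > len(s):
        raise ConfigError(
            f"sg_window {cfg.sg_window} exceeds axis length {len(s)}"
        )
    y = savgol_filter(s.intensities, cfg.sg_window, cfg.sg_polyorder)
    return s.replace(intensities=y)


def _modpoly_baseline(
    x: np.ndarray, y: np.ndarray, degree: int, max_iter: int, tol: float
) -> np.ndarray:
    # fit in a scaled coordinate for numerical conditioning
    u = (x - x[0]) / (x[-1] - x[0]) if x[-1] > x[0] else x
    scale = np.ptp(y)
    if scale == 0:
        return y.copy()
    work = y.copy()
    baseline = np.polynomial.polynomial.polyval(
        u, np.polynomial.polynomial.polyfit(u, work, degree)
    )
    for _ in range(max_iter):
        work = np.minimum(work, baseline)
        new = np.polynomial.polynomial.polyval(
            u, np.polynomial.polynomial.polyfit(u, work, degree)
        )
        delta = np.max(np.abs(new - baseline)) / scale
        baseline = new
        if delta < tol:
            return baseline
    warnings.warn(
        f"baseline fit did not converge within {max_iter} iterations",
        RuntimeWarning,
        stacklevel=3,
    )
    return baseline


def remove_baseline(
    s: Spectrum, cfg: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Iterative polynomial (peak-clipping) background subtraction.

    Returns ``(corrected, baseline)``. Non-convergence warns and returns the
    last iterate rather than raising.
    """
    cfg = cfg or PreprocessConfig()
    if len(s) <= cfg.baseline_degree + 1:
        raise ConfigError("axis too short for the baseline polynomial degree")
    baseline = _modpoly_baseline(
        s.wavenumbers, s.intensities, cfg.baseline_degree,
        cfg.baseline_max_iter, cfg.baseline_tol,
    )
    return s.replace(intensities=s.intensities - baseline), s.replace(
        intensities=baseline
    )


def minmax_normalize(s: Spectrum) -> Spectrum:
    """Affine rescale of intensities to [0, 1]; rejects constant spectra."""
    lo, hi = s.intensities.min(), s.intensities.max()
    if hi - lo <= 1e-10 * max(1.0, abs(hi), abs(lo)):
        raise DegenerateInputError(
            f"spectrum {s.sample_id!r} is constant; min-max undefined"
        )
    return s.replace(intensities=(s.intensities - lo) / (hi - lo))


def minmax_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise min-max normalisation of a spectra matrix."""
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    degenerate = (hi - lo) <= 1e-10 * np.maximum(
        1.0, np.maximum(np.abs(hi), np.abs(lo))
    )
    if np.any(degenerate):
        bad = int(np.where(degenerate.ravel())[0][0])
        raise DegenerateInputError(f"spectrum at row {bad} is constant")
    return (X - lo) / (hi - lo)


def resample(s: Spectrum, length: int) -> Spectrum:
    """Linear interpolation onto a uniform grid spanning the original range."""
    if length < 2:
        raise ConfigError("resample length must be >= 2")
    new_axis = np.linspace(s.wavenumbers[0], s.wavenumbers[-1], length)
    return Spectrum(
        new_axis,
        np.interp(new_axis, s.wavenumbers, s.intensities),
        s.sample_id,
        s.replicate_id,
        s.group,
    )


def run_track(
    spectra: SpectrumSet, track: str, cfg: PreprocessConfig | None = None
) -> SpectrumSet:
    """Apply a whole preprocessing track to a set.

    ``classical``: SG smooth -> baseline removal -> min-max, per spectrum.
    ``deep``: resample to ``cfg.resample_length`` (if set) -> min-max.
    """
    cfg = cfg or PreprocessConfig()
    out = []
    if track == "classical":
        for s in spectra:
            corrected, _ = remove_baseline(sg_smooth(s, cfg), cfg)
            out.append(minmax_normalize(corrected))
        return SpectrumSet(out, spectra.axis, spectra.class_names)
    if track == "deep":
        axis = spectra.axis
        for s in spectra:
            if cfg.resample_length and cfg.resample_length != len(s):
                s = resample(s, cfg.resample_length)
            out.append(minmax_normalize(s))
        if out:
            axis = out[0].wavenumbers
        elif cfg.resample_length:
            axis = np.linspace(axis[0], axis[-1], cfg.resample_length)
        return SpectrumSet(out, axis, spectra.class_names)
    raise ConfigError(f"unknown track {track!r}")


# -- sklearn transformer facades --------------------------------------------


class _StatelessTransformer(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):
        X = np.asarray(X)
        self.n_features_in_ = X.shape[1]
        return self


class SavitzkyGolaySmoother(_StatelessTransformer):
    """Row-wise Savitzky-Golay smoothing of a spectra matrix."""

    def __init__(self, window: int = 11, polyorder: int = 3):
        self.window = window
        self.polyorder = polyorder

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ConfigError("window must be odd and > polyorder")
        return savgol_filter(X, self.window, self.polyorder, axis=1)


class BaselineRemover(_StatelessTransformer):
    """Row-wise iterative polynomial baseline subtraction."""

    def __init__(self, degree: int = 5, max_iter: int = 100, tol: float = 1e-4):
        self.degree = degree
        self.max_iter = max_iter
        self.tol = tol

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        grid = np.arange(X.shape[1], dtype=float)
        return np.stack(
            [
                row - _modpoly_baseline(grid, row, self.degree, self.max_iter, self.tol)
                for row in X
            ]
        )


class MinMaxPerSpectrum(_StatelessTransformer):
    """Row-wise min-max normalisation to [0, 1]."""

    def transform(self, X):
        return minmax_matrix(np.asarray(X, dtype=float))


class Resampler(_StatelessTransformer):
    """Row-wise linear resampling to a fixed length."""

    def __init__(self, length: int = 2046):
        self.length = length

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.length < 2:
            raise ConfigError("length must be >= 2")
        old = np.linspace(0.0, 1.0, X.shape[1])
        new = np.linspace(0.0, 1.0, self.length)
        return np.stack([np.interp(new, old, row) for row in X])
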