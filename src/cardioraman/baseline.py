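"""Fluorescence baseline estimation and subtraction.

Tissue spectra excited at 532 nm sit on a broad fluorescence background
several times the height of the Raman bands.  Two asymmetric
penalized-least-squares estimators are provided:

``arpls`` (default)
    A two-stage hybrid.  A robust cubic polynomial is first fitted with
    asymmetrically reweighted least squares, capturing the bulk of the
    fluorescence shape; the remainder is smoothed by arPLS — a
    Whittaker smoother whose weights follow a logistic of the residual
    scaled by the noise level estimated from negative residuals.
    Because the weights are centred in the noise rather than under it,
    the corrected spectrum has no noise-floor pedestal and a second
    application is close to a no-op.

``als``
    Classic asymmetric least squares: a Whittaker smoother with fixed
    weights p for points above the baseline and 1−p below, iterated to
    a fixed point.  Simple and widely used, but the estimate rides the
    lower envelope of the noise.

Both minimise Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σᵢ (Δ²z)ᵢ² over the baseline z;
``smoothness`` is λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import BaselineConvergenceError, ValidationError
from .spectrum import RamanSpectrum


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the baseline estimator.

    method:
        ``arpls`` (robust cubic + arPLS smoothing, default) or ``als``
        (classic asymmetric least squares).
    smoothness:
        Regularization λ on the squared second difference of the
        smoothed baseline.  The default 1e7 keeps baseline curvature
        well below the ~14 cm⁻¹ band scale on a 1 cm⁻¹ grid.
    asymmetry:
        Weight p ∈ (0, 1) given to points above the baseline in the
        ``als`` method (ignored by ``arpls``, whose weights are
        noise-adaptive); small values let the fit pass under the
        bands.
    poly_degree:
        Degree of the robust polynomial stage of ``arpls``.
    max_iter:
        Iteration cap on the weight reweighting loop.
    tol:
        Relative change of the weight vector (arpls) or baseline
        (als) below which iteration stops.
    """

    method: str = "arpls"
    smoothness: float = 1e7
    asymmetry: float = 1e-3
    poly_degree: int = 3
    max_iter: int = 50
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.method not in ("arpls", "als"):
            raise ValidationError(f"unknown baseline method {self.method!r}")
        if self.smoothness <= 0:
            raise ValidationError("smoothness must be positive")
        if not (0.0 < self.asymmetry < 1.0):
            raise ValidationError("asymmetry must be in (0, 1)")
        if self.poly_degree < 0:
            raise ValidationError("poly_degree must be non-negative")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be a positive integer")


def subtract_baseline(
    spectrum: RamanSpectrum, config: BaselineConfig | None = None
) -> tuple[RamanSpectrum, RamanSpectrum]:
    """Estimate and subtract the fluorescence baseline.

    Returns ``(corrected, baseline)`` with
    ``corrected.intensities == spectrum.intensities - baseline.intensities``
    pointwise.  Raises :class:`BaselineConvergenceError` if the weight
    iteration has not stabilized within ``max_iter`` iterations.
    """
    if config is None:
        config = BaselineConfig()
    y = spectrum.intensities
    if config.method == "arpls":
        poly = _robust_polynomial(spectrum.shifts, y, config)
        z = poly + _arpls(y - poly, config)
    else:
        z = _als(y, config)
    baseline = spectrum.with_intensities(z)
    corrected = spectrum.with_intensities(y - z)
    corrected.meta["baseline_method"] = config.method
    return corrected, baseline


def _second_difference_penalty(n: int, lam: float) -> sparse.csc_matrix:
    diff2 = sparse.eye(n, format="csc")
    diff2 = diff2[1:] - diff2[:-1]
    diff2 = diff2[1:] - diff2[:-1]
    return lam * (diff2.T @ diff2)


def _logistic_weights(residual: np.ndarray) -> np.ndarray | None:
    """arPLS weights; ``None`` when the data are effectively noise-free."""
    below = residual[residual < 0]
    if below.size < 5:
        return None
    mean, sd = below.mean(), below.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(residual).max())):
        return None
    arg = np.clip(2.0 * (residual - (2.0 * sd - mean)) / sd, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(arg))


def _robust_polynomial(x: np.ndarray, y: np.ndarray, config: BaselineConfig) -> np.ndarray:
    t = (x - x.mean()) / (np.ptp(x) / 2.0)
    design = np.vander(t, config.poly_degree + 1)
    w = np.ones_like(y)
    fit = np.zeros_like(y)
    for _ in range(config.max_iter):
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        fit = design @ beta
        w_new = _logistic_weights(y - fit)
        if w_new is None or np.allclose(w_new, w, atol=1e-4):
            break
        w = w_new
    return fit


def _arpls(y: np.ndarray, config: BaselineConfig) -> np.ndarray:
    n = y.size
    penalty = _second_difference_penalty(n, config.smoothness)
    scale = float(np.ptp(y)) or 1.0
    w = np.ones(n)
    z_prev = np.full(n, np.inf)
    delta = np.inf
    for iteration in range(1, config.max_iter + 1):
        weights = sparse.diags(w, format="csc")
        z = spsolve((weights + penalty).tocsc(), w * y)
        # converged when either the weights or the baseline stop moving
        # (noise-free data make the logistic weights jitter indefinitely
        # while the estimate itself is static)
        z_delta = float(np.max(np.abs(z - z_prev))) / scale
        w_new = _logistic_weights(y - z)
        if w_new is None or z_delta <= config.tol:
            return z
        delta = float(np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-12))
        z_prev = z
        w = w_new
        if delta <= config.tol:
            weights = sparse.diags(w, format="csc")
            return spsolve((weights + penalty).tocsc(), w * y)
    raise BaselineConvergenceError(iterations=iteration, delta=delta, max_iter=config.max_iter)


def _als(y: np.ndarray, config: BaselineConfig) -> np.ndarray:
    n = y.size
    penalty = _second_difference_penalty(n, config.smoothness)
    scale = float(np.ptp(y)) or 1.0
    w = np.ones(n)
    z_prev = np.full(n, np.inf)
    delta = np.inf
    for iteration in range(1, config.max_iter + 1):
        weights = sparse.diags(w, format="csc")
        z = spsolve((weights + penalty).tocsc(), w * y)
        delta = float(np.max(np.abs(z - z_prev))) / scale
        if delta <= config.tol:
            return z
        z_prev = z
        w = np.where(y > z, config.asymmetry, 1.0 - config.asymmetry)
    raise BaselineConvergenceError(iterations=iteration, delta=delta, max_iter=config.max_iter)
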