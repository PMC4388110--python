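"""Covariance kernels of invariant fields and their line restrictions.

For an invariant complex field with spectral measure ``P`` the planar
covariance is a mixture of ring kernels ``Gamma_R(tau) = J0(R*tau)`` (the
characteristic function of the uniform distribution on a circle of radius
``R``).  Restricting the real part of the field to a straight line gives a
stationary scalar process whose covariance ``G`` is the same Bessel mixture
up to normalization; its first two derivatives enter every crossing-count
statistic.

Two normalizations are supported:

* ``"unit"`` (canonical): ``G(0) = 1``.  Crossing and pinwheel counts do not
  change when the field is rescaled, and the two-point (Cramér–Leadbetter)
  matrix is written for a unit-variance process, so this is the internal
  convention of :mod:`opmgrf.crossing_theory`.
* ``"paper"``: ``G(0) = 1/2``, the covariance of the real part of a complex
  field normalized to ``E|z|^2 = 1`` — the convention in which
  ``-G''(0) = (1/4)∫R^2 dP = pi^2 / lambda_sq^2``.

Derivatives are analytic (Bessel identities ``J0' = -J1`` and
``J1'(x) = J0(x) - J1(x)/x``), never finite differences, which keeps the
variance integrand stable near zero lag.
"""

from __future__ import annotations

import numpy as np
from scipy.special import j0, j1

from .spectra import SpectralMeasure

__all__ = [
    "CovarianceProfile",
    "gamma_R",
    "line_covariance",
    "line_covariance_derivatives",
    "spectral_lambda2",
]

_NORMALIZATIONS = {"unit": 1.0, "paper": 0.5}


def gamma_R(R: float, tau) -> np.ndarray | float:
    """Ring kernel ``Gamma_R(tau) = J0(R*|tau|)``; ``gamma_R(R, 0) == 1``.

    This is the covariance of a monochromatic invariant field with unit
    variance, and satisfies the Helmholtz equation
    ``Laplacian(Gamma_R) = -R^2 * Gamma_R`` radially.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    t = np.asarray(tau, dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("tau must not be NaN")
    out = j0(R * np.abs(t))
    return float(out) if np.isscalar(tau) else out


class CovarianceProfile:
    """Line-restricted covariance ``G`` of an invariant field, with analytic
    first and second derivatives, under an explicit normalization."""

    def __init__(self, spectrum: SpectralMeasure, normalization: str = "unit"):
        if normalization not in _NORMALIZATIONS:
            raise ValueError("normalization must be 'unit' or 'paper'")
        self.spectrum = spectrum
        self.normalization = normalization
        self._scale = _NORMALIZATIONS[normalization]
        self._r, self._w = spectrum.nodes()

    # G is even; all evaluators go through |tau|.

    def _bessel_tables(self, t: np.ndarray):
        arg = np.multiply.outer(t, self._r)
        return j0(arg), j1(arg)

    def G(self, tau) -> np.ndarray | float:
        t = np.abs(np.asarray(tau, dtype=float))
        if np.any(np.isnan(t)):
            raise ValueError("tau must not be NaN")
        J0, _ = self._bessel_tables(np.atleast_1d(t))
        out = self._scale * (J0 @ self._w)
        return float(out[0]) if np.isscalar(tau) else out.reshape(t.shape)

    def dG(self, tau) -> np.ndarray | float:
        """First derivative; odd, so ``dG(0) == 0`` exactly."""
        t = np.asarray(tau, dtype=float)
        sign = np.sign(t)
        _, J1 = self._bessel_tables(np.atleast_1d(np.abs(t)))
        out = -self._scale * ((J1 * self._r) @ self._w) * np.atleast_1d(sign)
        return float(out[0]) if np.isscalar(tau) else out.reshape(t.shape)

    def d2G(self, tau) -> np.ndarray | float:
        t = np.atleast_1d(np.abs(np.asarray(tau, dtype=float)))
        J0, J1 = self._bessel_tables(t)
        r = self._r
        out = np.empty(t.shape)
        zero = t == 0
        if np.any(~zero):
            tt = t[~zero]
            out[~zero] = self._scale * (
                -((J0[~zero] * r**2) @ self._w)
                + ((J1[~zero] * r) @ self._w) / tt
            )
        # tau -> 0 limit: d2/dt2 J0(r t) -> -r^2/2
        out[zero] = -0.5 * self._scale * np.sum(self._w * r**2)
        return float(out[0]) if np.isscalar(tau) else out.reshape(np.shape(tau))

    @property
    def lambda0(self) -> float:
        """``G(0)``: 1 under unit normalization, 1/2 under paper normalization."""
        return self._scale

    @property
    def lambda2(self) -> float:
        """Second spectral moment of the line process, ``-G''(0)``."""
        return 0.5 * self._scale * self.spectrum.moment(2)


def line_covariance(P: SpectralMeasure, tau, normalization: str = "paper"):
    """``G(tau)``: (1/2 or 1) × ``∫ J0(R*tau) dP(R)`` depending on
    normalization.  Atomic measures evaluate as finite Bessel sums; annuli
    through the measure's stored quadrature rule."""
    return CovarianceProfile(P, normalization).G(tau)


def line_covariance_derivatives(P: SpectralMeasure, tau, normalization: str = "paper"):
    """``(G'(tau), G''(tau))`` by analytic differentiation under the sum."""
    prof = CovarianceProfile(P, normalization)
    return prof.dG(tau), prof.d2G(tau)


def spectral_lambda2(P: SpectralMeasure, normalization: str = "paper") -> float:
    """``lambda2 = -G''(0)``; equals ``pi^2 / lambda_sq^2`` under paper
    normalization (and twice that under unit normalization)."""
    return CovarianceProfile(P, normalization).lambda2
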