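"""Empirical statistics on sampled maps: crossing counts, pinwheel detection
by plaquette winding numbers, densities, and seeded Monte Carlo ensembles.

This module is the simulation oracle for every closed form in
:mod:`opmgrf.crossing_theory`: the theory predicts, the ensembles here check.
All coordinates are continuous map units; counting windows are half-open
(``[x0, x1) x [y0, y1)``) so that tiling counts add up, and a sampled value
of exactly zero is attributed to the following interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crossing_theory import SegmentQuery
from .fieldsim import FieldSample, GridSpec, sample_field, sample_on_segment
from .spectra import SpectralMeasure

__all__ = [
    "Window",
    "PinwheelDetection",
    "EnsembleSummary",
    "count_crossings_on_segment",
    "detect_pinwheels",
    "empirical_pinwheel_density",
    "mc_crossing_moments",
    "mc_pinwheel_density",
]


@dataclass
class Window:
    """Half-open axis-aligned counting window ``[x0, x1) x [y0, y1)``."""

    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass
class PinwheelDetection:
    """Detected phase singularities: plaquette-center positions and winding
    charges (+1 or -1), with the window and effective counted area."""

    positions: np.ndarray           # (n, 2)
    charges: np.ndarray             # (n,) in {-1, +1}
    window: Window
    n_plaquettes: int
    spacing: float

    @property
    def count(self) -> int:
        return int(self.charges.size)

    @property
    def effective_area(self) -> float:
        """Area actually tiled by the counted plaquettes (avoids edge bias
        when the window edge cuts through a plaquette row)."""
        return self.n_plaquettes * self.spacing**2


@dataclass
class EnsembleSummary:
    """Per-realization counts with mean/variance and standard errors."""

    counts: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def variance(self) -> float:
        return float(np.var(self.counts, ddof=1))

    @property
    def se_mean(self) -> float:
        return float(np.sqrt(self.variance / self.n))

    @property
    def se_variance(self) -> float:
        c = self.counts - self.mean
        m4 = float(np.mean(c**4))
        return float(np.sqrt(max(m4 - self.variance**2, 0.0) / self.n))

    @property
    def normalized_variance(self) -> float:
        return self.variance / self.mean**2

    @property
    def se_normalized_variance(self) -> float:
        # delta method for V/E^2, neglecting the mean-variance covariance
        v, e = self.variance, self.mean
        return float(
            np.hypot(self.se_variance / e**2, 2.0 * v / e**3 * self.se_mean)
        )


# -- crossing counts -------------------------------------------------------


def count_crossings_on_segment(
    sample: FieldSample, theta0: float, convention: str = "projection-zeros"
) -> int:
    """Number of points on the sampled segment where orientation ``theta0``
    is attained.

    ``"projection-zeros"`` counts sign changes of ``Re(exp(-2i*theta0) * z)``
    with linear-interpolation root localization and a half-open endpoint rule
    (a root at the start counts, at the end does not).  Such zeros carry
    ``arg z = 2*theta0 +- pi/2``, i.e. two orientation values per cycle;
    ``"strict-orientation"`` keeps the half with positive conjugate component
    (``Im(exp(-2i*theta0) * z) > 0`` at the root).
    """
    if sample.kind != "segment":
        raise ValueError("need a segment sample")
    w = np.exp(-2j * theta0) * sample.values
    v = w.real
    if np.all(v == 0):
        raise ValueError("degenerate input: projection identically zero")
    if v.size < 2:
        return 0
    exact = v[:-1] == 0
    flips = v[:-1] * v[1:] < 0
    if convention == "projection-zeros":
        return int(np.count_nonzero(exact) + np.count_nonzero(flips))
    if convention == "strict-orientation":
        u = w.imag
        kept = np.count_nonzero(u[:-1][exact] > 0)
        i = np.nonzero(flips)[0]
        frac = v[i] / (v[i] - v[i + 1])
        u_root = u[i] + frac * (u[i + 1] - u[i])
        return int(kept + np.count_nonzero(u_root > 0))
    raise ValueError("convention must be 'projection-zeros' or 'strict-orientation'")


# -- pinwheel detection ----------------------------------------------------


def _plaquette_windings(z: np.ndarray) -> np.ndarray:
    """Winding number of arg(z) around each grid plaquette, by summing the
    four phase increments wrapped to (-pi, pi]."""
    ph = np.angle(z)

    def wrap(d):
        return np.angle(np.exp(1j * d))

    d1 = wrap(ph[:-1, 1:] - ph[:-1, :-1])     # bottom, left -> right
    d2 = wrap(ph[1:, 1:] - ph[:-1, 1:])       # right, bottom -> top
    d3 = wrap(ph[1:, :-1] - ph[1:, 1:])       # top, right -> left
    d4 = wrap(ph[:-1, :-1] - ph[1:, :-1])     # left, top -> bottom
    return np.rint((d1 + d2 + d3 + d4) / (2.0 * np.pi)).astype(int)


def _refine_plaquette(sample: FieldSample, iy: int, ix: int) -> int:
    """Re-evaluate an ambiguous plaquette on a 3x3 local subgrid and sum the
    four sub-plaquette windings."""
    g = sample.grid
    x = g.origin[0] + g.spacing * (ix + 0.5 * np.arange(3))
    y = g.origin[1] + g.spacing * (iy + 0.5 * np.arange(3))
    xx, yy = np.meshgrid(x, y)
    zz = sample.evaluate(np.column_stack([xx.ravel(), yy.ravel()])).reshape(3, 3)
    return int(_plaquette_windings(zz).sum())


def detect_pinwheels(sample: FieldSample, window: Window | None = None) -> PinwheelDetection:
    """Locate phase singularities of a grid sample by plaquette winding.

    The default window is the grid interior minus a one-``lambda_sq`` margin
    on all sides (edge-effect guard).  A phase increment within floating
    precision of pi is ambiguous; the plaquette is re-evaluated on a locally
    refined subgrid from the sample's wave decomposition.
    """
    if sample.kind != "grid":
        raise ValueError("need a grid sample")
    g = sample.grid
    lam = sample.spectrum.lambda_sq
    if window is None:
        window = Window(
            g.origin[0] + lam,
            g.origin[0] + g.spacing * (g.shape[1] - 1) - lam,
            g.origin[1] + lam,
            g.origin[1] + g.spacing * (g.shape[0] - 1) - lam,
        )
    z = sample.values
    ph = np.angle(z)

    def wrap(d):
        return np.angle(np.exp(1j * d))

    d1 = wrap(ph[:-1, 1:] - ph[:-1, :-1])
    d2 = wrap(ph[1:, 1:] - ph[:-1, 1:])
    d3 = wrap(ph[1:, :-1] - ph[1:, 1:])
    d4 = wrap(ph[:-1, :-1] - ph[1:, :-1])
    total = d1 + d2 + d3 + d4
    w = np.rint(total / (2.0 * np.pi)).astype(int)

    ambiguous = (
        (np.abs(np.abs(d1) - np.pi) < 1e-12)
        | (np.abs(np.abs(d2) - np.pi) < 1e-12)
        | (np.abs(np.abs(d3) - np.pi) < 1e-12)
        | (np.abs(np.abs(d4) - np.pi) < 1e-12)
    )
    if np.any(ambiguous):
        if sample.wave_vectors is None:
            raise RuntimeError("ambiguous pi phase increment and no wave data to refine")
        for iy, ix in zip(*np.nonzero(ambiguous)):
            w[iy, ix] = _refine_plaquette(sample, iy, ix)

    cy = g.origin[1] + g.spacing * (np.arange(g.shape[0] - 1) + 0.5)
    cx = g.origin[0] + g.spacing * (np.arange(g.shape[1] - 1) + 0.5)
    cxx, cyy = np.meshgrid(cx, cy)
    inside = window.contains(cxx, cyy)
    hit = inside & (w != 0)
    charges = w[hit]
    if np.any(np.abs(charges) > 1):
        raise RuntimeError("winding |charge| > 1: grid badly under-resolved")
    positions = np.column_stack([cxx[hit], cyy[hit]])
    return PinwheelDetection(
        positions=positions,
        charges=charges,
        window=window,
        n_plaquettes=int(np.count_nonzero(inside)),
        spacing=g.spacing,
    )


def empirical_pinwheel_density(
    detection: PinwheelDetection, scale_wavelength: float
) -> float:
    """Pinwheel count per area ``scale_wavelength**2``.

    Uses the effective (plaquette-tiled) area of the counting window; the
    window must span at least four scale wavelengths per side.
    """
    area = detection.effective_area
    if area < (4.0 * scale_wavelength) ** 2:
        raise ValueError("counting window smaller than (4 * scale_wavelength)^2")
    return detection.count / area * scale_wavelength**2


# -- Monte Carlo ensembles -------------------------------------------------


def mc_crossing_moments(
    P: SpectralMeasure,
    length: float,
    theta0: float = 0.0,
    n_realizations: int = 1000,
    seed=None,
    n_waves: int = 256,
    samples_per_wavelength: int = 64,
    convention: str = "projection-zeros",
) -> EnsembleSummary:
    """Crossing counts on independent field realizations.

    Each realization draws a fresh field (child streams of ``seed``, so the
    summary is reproducible) and counts iso-orientation points on a segment
    of the given length.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    rng = np.random.default_rng(seed)
    seg = SegmentQuery(length=length, theta0=theta0)
    counts = np.empty(n_realizations, dtype=int)
    for i in range(n_realizations):
        s = sample_on_segment(
            P, n_waves=n_waves, segment=seg,
            samples_per_wavelength=samples_per_wavelength, seed=rng,
        )
        counts[i] = count_crossings_on_segment(s, theta0, convention)
    return EnsembleSummary(
        counts=counts,
        config={
            "spectrum": P.to_dict(),
            "ell_over_lambda_sq": length / P.lambda_sq,
            "theta0": theta0,
            "n_realizations": n_realizations,
            "n_waves": n_waves,
            "samples_per_wavelength": samples_per_wavelength,
            "convention": convention,
            "seed": seed,
        },
    )


def mc_pinwheel_density(
    P: SpectralMeasure,
    n_fields: int = 50,
    seed=None,
    n_waves: int = 256,
    window_lambdas: float = 10.0,
    scale_wavelength: float | None = None,
) -> tuple[float, float, EnsembleSummary]:
    """Ensemble pinwheel density over independent fields.

    Returns ``(density, standard_error, summary)`` where density is the mean
    count per ``scale_wavelength**2`` of interior area (default scale:
    ``lambda_sq``).  The counting window is the grid minus a one-lambda_sq
    margin and spans ``window_lambdas`` column spacings per side.
    """
    lam = P.lambda_sq
    if scale_wavelength is None:
        scale_wavelength = lam
    rng = np.random.default_rng(seed)
    grid = GridSpec.square((window_lambdas + 2.0) * lam, lam / 12.0)
    counts = np.empty(n_fields, dtype=int)
    area = None
    for i in range(n_fields):
        s = sample_field(P, n_waves=n_waves, grid=grid, seed=rng)
        det = detect_pinwheels(s)
        counts[i] = det.count
        area = det.effective_area
    summary = EnsembleSummary(
        counts=counts,
        config={
            "spectrum": P.to_dict(),
            "n_fields": n_fields,
            "n_waves": n_waves,
            "window_lambdas": window_lambdas,
            "effective_area": area,
            "seed": seed,
        },
    )
    dens = summary.mean / area * scale_wavelength**2
    se = summary.se_mean / area * scale_wavelength**2
    return dens, se, summary
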