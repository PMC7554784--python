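"""Baseline correction and normalization.

Baseline removal follows the modified-polyfit (iterative clipping) family:
within each wavenumber section a polynomial is fit, points above the fitted
curve are clipped down to it, and the fit repeats until the working spectrum
stops changing (relative tolerance) or an iteration cap is hit.  The final
curve, blended across section joins, is subtracted.  Sections let a
low-order polynomial track an autofluorescence background whose curvature
varies along the spectrum.

Normalization divides each spectrum by its own maximum intensity — there is
no single band reliable enough to normalize every SERS spectrum to, so the
max peak of each spectrum is the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import SpectrumSet

#: Half-width (in grid points) of the blending window at section joins.
BLEND_HALF_WIDTH = 2


@dataclass
class BaselineConfig:
    """Sectional iterative-polyfit baseline settings.

    ``section_bounds`` are interior wavenumber cut points; ``None`` places
    one cut every ``section_span`` cm^-1 (default 500, conventional for
    biological autofluorescence).  ``clip_tol`` is relative to each
    spectrum's intensity range.
    """

    section_bounds: Sequence[float] | None = None
    section_span: float = 500.0
    degree: int = 3
    max_iter: int = 100
    clip_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.section_bounds is not None:
            b = list(self.section_bounds)
            if sorted(b) != b:
                raise ValueError("section_bounds must be ascending")

    def cut_points(self, grid: np.ndarray) -> list[float]:
        if self.section_bounds is not None:
            return [b for b in self.section_bounds if grid[0] < b < grid[-1]]
        cuts = np.arange(grid[0] + self.section_span, grid[-1], self.section_span)
        return list(cuts)


def _clip_fit(x: np.ndarray, y: np.ndarray, degree: int, max_iter: int, tol_abs: float) -> np.poly1d:
    """Iterative clipping polynomial fit; returns the converged polynomial."""
    if x.size < degree + 1:
        raise ValueError(
            f"section with {x.size} points cannot support a degree-{degree} fit"
        )
    # Centered/scaled abscissa keeps the Vandermonde system well conditioned.
    xs = (x - x.mean()) / max(np.ptp(x) / 2.0, 1.0)
    work = y.astype(float).copy()
    coefs = np.polyfit(xs, work, degree)
    for _ in range(max_iter):
        curve = np.polyval(coefs, xs)
        clipped = np.minimum(work, curve)
        if np.max(np.abs(clipped - work)) <= tol_abs:
            break
        work = clipped
        coefs = np.polyfit(xs, work, degree)
    poly = np.poly1d(coefs)
    shift, scale = x.mean(), max(np.ptp(x) / 2.0, 1.0)

    def evaluate(xq: np.ndarray) -> np.ndarray:
        return np.polyval(poly, (xq - shift) / scale)

    return evaluate  # type: ignore[return-value]


def baseline_curve(grid: np.ndarray, y: np.ndarray, cfg: BaselineConfig) -> np.ndarray:
    """Estimated baseline of one spectrum, blended across section joins."""
    cuts = cfg.cut_points(grid)
    bounds_idx = [0] + [int(np.searchsorted(grid, c)) for c in cuts] + [grid.size]
    scale = np.ptp(y) or 1.0
    tol_abs = cfg.clip_tol * scale

    fits = []
    for a, b in zip(bounds_idx[:-1], bounds_idx[1:]):
        if b - a < cfg.degree + 1:
            raise ValueError(
                f"section [{grid[a]:.1f}, {grid[b - 1]:.1f}] has {b - a} points, "
                f"fewer than degree+1 = {cfg.degree + 1}"
            )
        fits.append(_clip_fit(grid[a:b], y[a:b], cfg.degree, cfg.max_iter, tol_abs))

    baseline = np.empty_like(y, dtype=float)
    for (a, b), fit in zip(zip(bounds_idx[:-1], bounds_idx[1:]), fits):
        baseline[a:b] = fit(grid[a:b])
    # Average adjacent section fits over a small window at each join so the
    # corrected spectrum stays continuous.
    for j, cut_idx in enumerate(bounds_idx[1:-1]):
        lo = max(cut_idx - BLEND_HALF_WIDTH, bounds_idx[j])
        hi = min(cut_idx + BLEND_HALF_WIDTH + 1, bounds_idx[j + 2])
        xw = grid[lo:hi]
        baseline[lo:hi] = 0.5 * (fits[j](xw) + fits[j + 1](xw))
    return baseline


def correct_baseline(sset: SpectrumSet, cfg: BaselineConfig | None = None) -> SpectrumSet:
    """Subtract the sectional iterative-polyfit baseline from every spectrum."""
    cfg = cfg or BaselineConfig()
    corrected = np.empty_like(sset.intensities)
    for i in range(sset.n_spectra):
        corrected[i] = sset.intensities[i] - baseline_curve(sset.grid, sset.intensities[i], cfg)
    return sset.replace_intensities(corrected)


def normalize_max(sset: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its own maximum intensity (max becomes 1)."""
    maxima = sset.intensities.max(axis=1)
    bad = np.flatnonzero(maxima <= 0)
    if bad.size:
        raise ValueError(
            f"spectrum {sset.ids[bad[0]]} has non-positive maximum; cannot normalize"
        )
    return sset.replace_intensities(sset.intensities / maxima[:, None])
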