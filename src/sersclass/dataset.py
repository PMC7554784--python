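"""Core containers for Raman spectrum sets and peak matrices.

A :class:`SpectrumSet` holds a stack of spectra measured on one shared
wavenumber grid together with a class label (``control`` or ``trc``) and a
sample/location identifier per spectrum.  A :class:`PeakMatrix` is the
peak-only representation: columns are the union of wavenumbers at which any
spectrum has a local maximum, and an entry is nonzero only where that
particular spectrum peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised class labels, in canonical order (control first).
CLASSES = ("control", "trc")


@dataclass
class SpectrumSet:
    """Spectra on a shared, strictly increasing wavenumber grid.

    Parameters
    ----------
    grid
        Wavenumbers in cm^-1, strictly increasing, at least 3 points.
    intensities
        Matrix of shape ``(n_spectra, len(grid))``.  Raw data is
        nonnegative; baseline-subtracted data may dip below zero.
    labels
        Class per spectrum, one of ``control`` / ``trc``.
    ids
        Sample/location identifier per spectrum (e.g. ``S03/L02``).
    """

    grid: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.grid.ndim != 1 or self.grid.size < 3:
            raise ValueError("grid must be 1-D with at least 3 points")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid wavenumbers must be strictly increasing")
        n, p = self.intensities.shape
        if p != self.grid.size:
            raise ValueError(
                f"intensity columns ({p}) != grid points ({self.grid.size})"
            )
        if not (len(self.labels) == len(self.ids) == n):
            raise ValueError("labels, ids and intensity rows must align")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown label token(s): {sorted(bad)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def class_indices(self, label: str) -> np.ndarray:
        """Row indices of spectra carrying ``label``."""
        return np.flatnonzero(self.labels == label)

    def replace_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """New set with the same grid/labels/ids but different intensities."""
        return SpectrumSet(self.grid, intensities, self.labels.copy(), self.ids.copy())

    def subset_points(self, mask: np.ndarray) -> "SpectrumSet":
        """Restrict to the grid points selected by a boolean mask."""
        return SpectrumSet(
            self.grid[mask], self.intensities[:, mask], self.labels.copy(), self.ids.copy()
        )


@dataclass
class PeakMatrix:
    """Sparse peak-intensity matrix over the union of detected peak positions.

    ``values[i, j]`` equals spectrum ``i``'s intensity at ``peak_grid[j]`` if
    that spectrum has a local maximum there, else 0.
    """

    peak_grid: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    #: Indices of ``peak_grid`` in the source SpectrumSet grid.
    source_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_grid = np.asarray(self.peak_grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.diff(self.peak_grid) > 0):
            raise ValueError("peak_grid must be strictly increasing")
        if self.values.shape[1] != self.peak_grid.size:
            raise ValueError("values columns must match peak_grid")
        if self.peak_grid.size and not np.all(np.any(self.values != 0, axis=0)):
            raise ValueError("every peak column must have at least one nonzero entry")

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]
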