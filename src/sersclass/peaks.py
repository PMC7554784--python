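"""Dimension elimination: wavenumber windows and the peak-only representation.

The peak representation keeps, per spectrum, only the intensities at local
maxima.  The feature space is the union of all spectra's peak wavenumbers:
if any spectrum peaks at a wavenumber, that wavenumber becomes a column, and
spectra without a peak there get 0.  Peak positions are matched exactly on
the shared grid (no tolerance binning) unless a merge tolerance is given.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import peak_prominences

from .dataset import PeakMatrix, SpectrumSet


def restrict_windows(
    sset: SpectrumSet, windows: list[tuple[float, float]]
) -> SpectrumSet:
    """Keep grid points falling inside any ``(lo, hi)`` wavenumber window."""
    mask = np.zeros(sset.n_points, dtype=bool)
    for lo, hi in windows:
        mask |= (sset.grid >= lo) & (sset.grid <= hi)
    if not mask.any():
        raise ValueError(f"no grid points fall inside windows {windows}")
    return sset.subset_points(mask)


def detect_peaks(y: np.ndarray, min_prominence: float = 0.0) -> np.ndarray:
    """Indices of local maxima of one spectrum.

    An interior point is a peak if it is strictly greater than both
    neighbors; a plateau (run of equal values) strictly above both flanking
    values reports its leftmost point.  Endpoints are never peaks.  Peaks
    whose prominence falls below ``min_prominence * (max - min)`` are
    dropped (the default 0 keeps every bare local maximum).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points")
    peaks = []
    i = 0
    n = y.size
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        # run of equal values y[i..j]
        if i > 0 and j < n - 1 and y[i - 1] < y[i] and y[j + 1] < y[i]:
            peaks.append(i)
        i = j + 1
    idx = np.array(peaks, dtype=int)
    if min_prominence > 0 and idx.size:
        threshold = min_prominence * (y.max() - y.min())
        prom = peak_prominences(y, idx)[0]
        idx = idx[prom >= threshold]
    return idx


def build_peak_matrix(
    sset: SpectrumSet, min_prominence: float = 0.0, merge_tol: float = 0.0
) -> PeakMatrix:
    """Peak-only matrix over the union of all spectra's peak wavenumbers.

    ``merge_tol`` optionally merges union positions closer than this many
    cm^-1 into one column (labelled by the leftmost member); it defaults to
    0, i.e. exact shared-grid matching.
    """
    per_spectrum = [detect_peaks(row, min_prominence) for row in sset.intensities]
    union = sorted(set().union(*[set(p.tolist()) for p in per_spectrum]))
    if not union:
        raise ValueError("no spectrum has any local maximum")

    if merge_tol > 0:
        # Greedy left-to-right clustering of union positions within merge_tol.
        col_of: dict[int, int] = {}
        anchors: list[int] = []
        for g in union:
            if anchors and sset.grid[g] - sset.grid[anchors[-1]] <= merge_tol:
                col_of[g] = len(anchors) - 1
            else:
                anchors.append(g)
                col_of[g] = len(anchors) - 1
        columns = anchors
    else:
        col_of = {g: j for j, g in enumerate(union)}
        columns = union

    values = np.zeros((sset.n_spectra, len(columns)))
    for i, idx in enumerate(per_spectrum):
        for g in idx:
            j = col_of[g]
            values[i, j] = max(values[i, j], sset.intensities[i, g])
    source_indices = np.array(columns, dtype=int)
    return PeakMatrix(
        peak_grid=sset.grid[source_indices],
        values=values,
        labels=sset.labels.copy(),
        ids=sset.ids.copy(),
        source_indices=source_indices,
    )
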