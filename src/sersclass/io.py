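"""Plain-text I/O for spectra and cross-validation result tables.

Two spectrum layouts are supported, mirroring common spectrometer export
dialects:

``wide``
    One CSV table: first column class label, second column spectrum id,
    remaining column headers are numeric wavenumbers (cm^-1).

``per-file``
    A directory of two-column whitespace-delimited ``(wavenumber,
    intensity)`` text files plus a ``manifest.csv`` with columns
    ``filename,label,id``.  Files measured on slightly different grids are
    linearly resampled onto the first file's grid (with a warning).

Result tables use the columns of the study's summary table (classifier,
reduction method, dimensions, CV accuracy/std, training CV accuracy/std)
plus an overfit flag, with accuracies rendered to 3 decimals.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import CLASSES, SpectrumSet

RESULT_COLUMNS = [
    "classifier",
    "reduction_method",
    "dimensions",
    "cv_acc",
    "cv_std",
    "train_cv",
    "train_std",
    "overfit",
]

_FLOAT_COLS = ("cv_acc", "cv_std", "train_cv", "train_std")


def _check_labels(labels: Iterable[str]) -> None:
    bad = sorted(set(labels) - set(CLASSES))
    if bad:
        raise ValueError(f"unknown label token(s): {bad}; expected one of {CLASSES}")


def read_spectra(path: str | Path, layout: str = "wide") -> SpectrumSet:
    """Read a :class:`SpectrumSet` from disk.

    Parameters
    ----------
    path
        CSV file (``wide``) or directory containing spectra and a
        ``manifest.csv`` (``per-file``).
    layout
        ``"wide"`` or ``"per-file"``.
    """
    path = Path(path)
    if layout == "wide":
        return _read_wide(path)
    if layout == "per-file":
        return _read_per_file(path)
    raise ValueError(f"unknown layout {layout!r}")


def _read_wide(path: Path) -> SpectrumSet:
    df = pd.read_csv(path)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    labels = df.iloc[:, 0].astype(str).to_numpy()
    ids = df.iloc[:, 1].astype(str).to_numpy()
    _check_labels(labels)
    try:
        grid = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber column header: {exc}") from exc
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavenumber columns are not strictly increasing")
    intensities = df.iloc[:, 2:].to_numpy(dtype=float)
    return SpectrumSet(grid, intensities, labels, ids)


def _read_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    nu, y = data[:, 0], data[:, 1]
    if not np.all(np.diff(nu) > 0):
        raise ValueError(f"{path}: wavenumber column is not strictly increasing")
    return nu, y


def _read_per_file(directory: Path) -> SpectrumSet:
    manifest = pd.read_csv(directory / "manifest.csv")
    if manifest.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    labels = manifest["label"].astype(str).to_numpy()
    _check_labels(labels)
    ids = manifest["id"].astype(str).to_numpy()
    grid = None
    rows = []
    resampled = []
    for fname in manifest["filename"]:
        nu, y = _read_two_column(directory / str(fname))
        if grid is None:
            grid = nu
        elif nu.shape != grid.shape or not np.allclose(nu, grid):
            y = np.interp(grid, nu, y)
            resampled.append(str(fname))
        rows.append(y)
    if resampled:
        warnings.warn(
            f"resampled {len(resampled)} spectra onto the first file's grid "
            f"by linear interpolation: {resampled}",
            stacklevel=2,
        )
    return SpectrumSet(grid, np.vstack(rows), labels, ids)


def write_spectra(sset: SpectrumSet, path: str | Path, layout: str = "wide") -> None:
    """Write a :class:`SpectrumSet` in one of the supported layouts."""
    path = Path(path)
    if layout == "wide":
        df = pd.DataFrame(sset.intensities, columns=[f"{nu:.10g}" for nu in sset.grid])
        df.insert(0, "id", sset.ids)
        df.insert(0, "label", sset.labels)
        df.to_csv(path, index=False)
    elif layout == "per-file":
        path.mkdir(parents=True, exist_ok=True)
        records = []
        for i in range(sset.n_spectra):
            fname = f"spectrum_{i:03d}.txt"
            np.savetxt(
                path / fname,
                np.column_stack([sset.grid, sset.intensities[i]]),
                fmt="%.6f",
            )
            records.append((fname, sset.labels[i], sset.ids[i]))
        pd.DataFrame(records, columns=["filename", "label", "id"]).to_csv(
            path / "manifest.csv", index=False
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Convert CVResult rows to a DataFrame in the summary-table schema."""
    if not len(results):
        raise ValueError("empty results")
    extras = ["data_type", "normalized", "mode", "seed"]
    rows = []
    for r in results:
        row = {
            "classifier": r.classifier,
            "reduction_method": r.reduction_method,
            "dimensions": r.dimensions,
            "cv_acc": r.cv_acc,
            "cv_std": r.cv_std,
            "train_cv": r.train_cv,
            "train_std": r.train_std,
            "overfit": r.overfit,
        }
        for name in extras:
            if hasattr(r, name):
                row[name] = getattr(r, name)
        rows.append(row)
    columns = RESULT_COLUMNS + [e for e in extras if any(e in r for r in rows)]
    return pd.DataFrame(rows, columns=columns)


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write CVResult rows as CSV, accuracies rendered to 3 decimals."""
    df = results_to_frame(results)
    for col in _FLOAT_COLS:
        df[col] = df[col].map(lambda v: f"{v:.3f}")
    df.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results_table`."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    return df
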