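"""Wavenumber-marker annotation and band-clustering summaries.

After feature selection, the surviving wavenumbers are the candidate
spectral markers.  This module matches them against a literature
band-assignment lookup (the bundled default covers 1116-1665 cm^-1 —
Amide I / Amide III, tyrosine, collagen, nucleobase bands — and is a
plain CSV users can replace or extend; the ``reference`` column carries
opaque citation tags for the user's own bibliography) and quantifies how
strongly the selection clusters inside a wavenumber band of interest.
No biological causation is implied by a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AnnotationTable:
    """Rows of (wavenumber cm^-1, assignment text, reference tag)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"wavenumber", "assignment"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        wn = self.frame["wavenumber"].to_numpy(dtype=float)
        if np.any(np.diff(wn) < 0):
            raise ValueError("annotation wavenumbers must be ascending")
        if self.frame["assignment"].astype(str).str.strip().eq("").any():
            raise ValueError("empty assignment text")

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "AnnotationTable":
        """Bundled band-assignment lookup (1116-1665 cm^-1)."""
        with resources.files("sersclass.data").joinpath("band_assignments.csv").open() as fh:
            return cls(pd.read_csv(fh))


def annotate(
    selected,
    table: AnnotationTable | None = None,
    tol: float = 2.0,
) -> pd.DataFrame:
    """Match selected wavenumbers to annotation rows within ``tol`` cm^-1.

    Every table row within tolerance is reported, nearest first (multiple
    assignments for one band are all preserved); a selected wavenumber
    with no match is flagged ``unassigned``.  The default tolerance of
    2 cm^-1 spans about two steps of a ~1.1 cm^-1 instrument grid.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    table = table or AnnotationTable.default()
    wn = table.frame["wavenumber"].to_numpy(dtype=float)
    rows = []
    for nu in np.asarray(selected, dtype=float):
        dist = np.abs(wn - nu)
        hits = np.flatnonzero(dist <= tol)
        if hits.size == 0:
            rows.append(
                {
                    "selected": nu,
                    "matched": np.nan,
                    "distance": np.nan,
                    "assignment": "unassigned",
                    "reference": "",
                }
            )
            continue
        for h in hits[np.argsort(dist[hits], kind="stable")]:
            rec = table.frame.iloc[h]
            rows.append(
                {
                    "selected": nu,
                    "matched": wn[h],
                    "distance": float(dist[h]),
                    "assignment": rec["assignment"],
                    "reference": rec.get("reference", ""),
                }
            )
    return pd.DataFrame(rows, columns=["selected", "matched", "distance", "assignment", "reference"])


def cluster_summary(selected, band: tuple[float, float]) -> dict:
    """Fraction of selected wavenumbers inside ``band`` plus the maximal
    runs of consecutive selected peaks lying inside it.

    Returns ``{"fraction": float, "runs": [(lo, hi, count), ...]}`` where
    each run spans consecutive members of the sorted selection that all
    fall inside the band.
    """
    sel = np.sort(np.asarray(selected, dtype=float))
    if sel.size == 0:
        raise ValueError("empty selection")
    lo, hi = band
    inside = (sel >= lo) & (sel <= hi)
    fraction = float(inside.mean())
    runs = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((float(sel[start]), float(sel[i - 1]), i - start))
            start = None
    if start is not None:
        runs.append((float(sel[start]), float(sel[-1]), sel.size - start))
    return {"fraction": fraction, "runs": runs}
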