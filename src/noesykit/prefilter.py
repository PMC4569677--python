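"""Peak-list pre-filters for artifact-rich ("unrefined") NOESY peak lists.

Three filters are provided, intended to run before automated NOE assignment:

* :func:`filter_no_assignment` — the classical chemical-shift-match filter:
  a peak is kept only if every dimension matches at least one assigned shift
  within the per-nucleus tolerance window.
* :func:`filter_weak_peaks` — removes weak cross-peaks.  A peak ``p`` is weak
  if ``|I_p|**(-1/6) > |I_min|**(-1/6) * fraction`` (default fraction 0.9),
  where ``I_min`` is the smallest intensity magnitude in the list: its
  calibrated distance would exceed 90 % of the longest calibrated distance.
* :func:`filter_high_density_lines` — removes solvent-line artifacts.  Peaks
  are projected onto the heteronuclear 2D plane, binned on a grid whose cell
  size is twice the assignment tolerance per dimension, and every peak in a
  cell whose density exceeds ``<rho> + n*sigma_rho`` (default n=1) is removed.
  The mean and standard deviation are taken over *all* cells of the bounding
  grid, empty ones included (population statistics over the full spectrum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .peaks import Peak, PeakList, project_to_2d

__all__ = [
    "DensityGrid",
    "FilterReport",
    "ShiftTable",
    "read_shift_table",
    "filter_weak_peaks",
    "build_density_grid",
    "filter_high_density_lines",
    "filter_no_assignment",
    "weak_intensity_threshold",
]


@dataclass
class FilterReport:
    """Bookkeeping for one or more filter passes over a peak list."""

    n_input: int = 0
    n_removed_weak: int = 0
    n_removed_density: int = 0
    n_removed_no_assignment: int = 0
    removed_ids: dict[str, list[int]] = field(default_factory=dict)
    removed_cells: list[tuple[int, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_weak": self.n_removed_weak,
            "n_removed_density": self.n_removed_density,
            "n_removed_no_assignment": self.n_removed_no_assignment,
            "removed_ids": self.removed_ids,
            "removed_cells": [list(c) for c in self.removed_cells],
        }


@dataclass
class DensityGrid:
    """2D binning of projected peaks with full-spectrum density statistics.

    ``cell_index`` maps integer cell coordinates ``(i, j)`` to the ids of the
    peaks they contain; cells absent from the mapping are empty but still
    enter ``rho_mean`` / ``rho_sd`` (population SD over all ``n_cells`` cells).
    """

    cell_index: dict[tuple[int, int], list[int]]
    rho_mean: float
    rho_sd: float
    cell_sizes: tuple[float, float]
    origin: tuple[float, float]
    n_cells: tuple[int, int]

    def density(self, cell: tuple[int, int]) -> int:
        return len(self.cell_index.get(cell, ()))

    def high_density_cells(self, n: float) -> list[tuple[int, int]]:
        """Cells whose density strictly exceeds ``rho_mean + n*rho_sd``."""
        threshold = self.rho_mean + n * self.rho_sd
        return sorted(c for c, ids in self.cell_index.items() if len(ids) > threshold)


def weak_intensity_threshold(pl: PeakList, fraction: float = 0.9) -> float:
    """Intensity magnitude below which a peak is classified as weak.

    The weak criterion ``|I_p|**(-1/6) > |I_min|**(-1/6) * fraction`` is
    equivalent to ``|I_p| < fraction**(-6) * |I_min|``.
    """
    i_min = min(_abs_intensity(p) for p in pl.peaks)
    return fraction ** -6 * i_min


def _abs_intensity(p: Peak) -> float:
    mag = abs(p.intensity)
    if mag == 0.0:
        raise ValueError(f"peak {p.id} has zero intensity; cannot calibrate")
    return mag


def filter_weak_peaks(pl: PeakList, fraction: float = 0.9) -> tuple[PeakList, FilterReport]:
    """Remove weak cross-peaks in a single pass.

    A peak ``p`` is weak if ``|I_p|**(-1/6) > |I_min|**(-1/6) * fraction``,
    with ``I_min`` the smallest intensity magnitude of the *original* list
    (no iteration to a fixed point).  Magnitudes are used because NOESY
    volumes may be negative from phasing.  Survivor order is preserved.
    """
    if not pl.peaks:
        raise ValueError("cannot filter an empty peak list")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    i_min = min(_abs_intensity(p) for p in pl.peaks)
    ref = i_min ** (-1.0 / 6.0) * fraction
    survivors, removed = [], []
    for p in pl.peaks:
        if _abs_intensity(p) ** (-1.0 / 6.0) > ref:
            removed.append(p.id)
            p.flags.add("weak")
        else:
            survivors.append(p)
    report = FilterReport(
        n_input=len(pl.peaks),
        n_removed_weak=len(removed),
        removed_ids={"weak": removed},
    )
    return pl.with_peaks(survivors), report


def build_density_grid(pl: PeakList) -> DensityGrid:
    """Bin the 2D projection of ``pl`` on a grid of 2x-tolerance cells.

    The grid is anchored at the minimum projected coordinates and covers the
    bounding box of all peaks.  Cell assignment uses half-open intervals
    ``[origin + k*w, origin + (k+1)*w)``; the maximal coordinate falls in the
    last cell.  Density statistics are population moments over every cell of
    the bounding grid, empty cells counting zero.
    """
    points = np.asarray(project_to_2d(pl))
    widths = (2.0 * pl.tolerance_for_dimension(0), 2.0 * pl.tolerance_for_dimension(1))
    origin = points.min(axis=0)
    span = points.max(axis=0) - origin
    n_cells = tuple(int(span[d] // widths[d]) + 1 for d in range(2))
    idx = np.floor((points - origin) / np.asarray(widths)).astype(int)
    idx = np.minimum(idx, np.asarray(n_cells) - 1)  # max coordinate -> last cell
    cell_index: dict[tuple[int, int], list[int]] = {}
    for peak, (i, j) in zip(pl.peaks, idx):
        cell_index.setdefault((int(i), int(j)), []).append(peak.id)
    total = n_cells[0] * n_cells[1]
    counts = np.zeros(total)
    counts[: len(cell_index)] = [len(v) for v in cell_index.values()]
    rho_mean = float(counts.sum() / total)
    rho_sd = float(np.sqrt(np.mean(counts**2) - rho_mean**2))
    return DensityGrid(
        cell_index=cell_index,
        rho_mean=rho_mean,
        rho_sd=max(rho_sd, 0.0),
        cell_sizes=(widths[0], widths[1]),
        origin=(float(origin[0]), float(origin[1])),
        n_cells=(n_cells[0], n_cells[1]),
    )


def filter_high_density_lines(pl: PeakList, n: float = 1.0) -> tuple[PeakList, FilterReport]:
    """Remove every peak sitting in a high-density cell of the 2D projection.

    Cells with density strictly above ``<rho> + n*sigma_rho`` are flagged as
    solvent lines and all their peaks removed; survivor order is preserved.
    """
    if not pl.peaks:
        raise ValueError("cannot filter an empty peak list")
    grid = build_density_grid(pl)
    hot = set(grid.high_density_cells(n))
    hot_ids = {pid for cell in hot for pid in grid.cell_index[cell]}
    survivors, removed = [], []
    for p in pl.peaks:
        if p.id in hot_ids:
            removed.append(p.id)
            p.flags.add("high_density")
        else:
            survivors.append(p)
    report = FilterReport(
        n_input=len(pl.peaks),
        n_removed_density=len(removed),
        removed_ids={"density": removed},
        removed_cells=sorted(hot),
    )
    return pl.with_peaks(survivors), report


@dataclass
class ShiftTable:
    """Assigned chemical shifts: (residue, atom_name, ppm) records.

    The nucleus of each atom is inferred from the first letter of its name
    (pseudo-atoms ``Q*``/``M*`` count as protons), so each peak dimension is
    matched only against shifts of its own nucleus type.
    """

    entries: list[tuple[int, str, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("shift table is empty")

    def shifts_for_nucleus(self, nucleus: str) -> np.ndarray:
        vals = [ppm for _, name, ppm in self.entries if _element_of(name) == nucleus]
        return np.asarray(vals)


def _element_of(atom_name: str) -> str:
    lead = atom_name.lstrip("0123456789")[:1].upper()
    if lead in ("Q", "M"):  # pseudo-atom / methyl conventions
        return "H"
    return lead


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read a TSV shift table with columns ``atom_name<TAB>residue<TAB>ppm``."""
    entries: list[tuple[int, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            try:
                entries.append((int(fields[1]), fields[0], float(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return ShiftTable(entries)


def filter_no_assignment(
    pl: PeakList, shifts: ShiftTable | Sequence[tuple[int, str, float]]
) -> tuple[PeakList, FilterReport]:
    """Discard peaks for which no assignment possibility exists.

    A peak survives iff every dimension has at least one assigned shift of the
    matching nucleus within its tolerance window, ``|delta ppm| <= tolerance``
    (closed window).  Heavy-atom/proton bonding consistency is deliberately
    not checked — this is a pure shift-match pre-filter.
    """
    if not isinstance(shifts, ShiftTable):
        shifts = ShiftTable(list(shifts))
    per_dim = []
    for dim in range(3):
        vals = shifts.shifts_for_nucleus(pl.nucleus_types[dim])
        per_dim.append((vals, pl.tolerance_for_dimension(dim)))
    survivors, removed = [], []
    for p in pl.peaks:
        ok = True
        for dim, shift in enumerate(p.shifts):
            vals, tol = per_dim[dim]
            if vals.size == 0 or not np.any(np.abs(vals - shift) <= tol):
                ok = False
                break
        if ok:
            survivors.append(p)
        else:
            removed.append(p.id)
            p.flags.add("no_assignment")
    report = FilterReport(
        n_input=len(pl.peaks),
        n_removed_no_assignment=len(removed),
        removed_ids={"no_assignment": removed},
    )
    return pl.with_peaks(survivors), report
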