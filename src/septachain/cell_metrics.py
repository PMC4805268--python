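"""Per-cell fluorescence, membrane-based diameter, and population summaries.

Two capture modes mirror the two ways a cell's reporter signal can be
read off a straightened chain:

* **integrated** — sum over a box spanning the cell's axial interval and
  a centred lateral band, minus background × box area.  Background is
  subtracted as a global term rather than per-pixel-clamped, which would
  bias dim cells upward.
* **mean along axis** — mean of the thin axial profile over the cell's
  interval, minus background.  Preferable when chains lie close together
  and boxes would overlap a neighbour.

The membrane-based diameter is the distance between the two outermost
peaks of the perpendicular membrane profile; note this systematically
underestimates the true diameter for micron-sized cells (see
``psf_simulation``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import MetricsParams
from .septum_detection import CellRecord, parabolic_refine
from .straightening import StraightenedChain, axial_profile


# ------------------------------------------------------------ fluorescence

def _cell_columns(sc: StraightenedChain, cell: CellRecord) -> np.ndarray:
    a, b = cell.axial_interval
    return (sc.positions_um >= a) & (sc.positions_um < b)


def integrated_fluorescence(
    cell: CellRecord,
    sc: StraightenedChain,
    role: str = "reporter",
    box_width_um: float | None = None,
    background: float = 0.0,
) -> float:
    """Integrated fluorescence in a cell-bounding box, background-corrected.

    The box spans the cell's half-open axial interval and a lateral band
    of ``box_width_um`` centred on the axis (full band if None or wider
    than the band).  Result = raw sum − background × box area (pixels).
    """
    raster = sc.rasters[role]
    cols = _cell_columns(sc, cell)
    n_rows = raster.shape[0]
    if box_width_um is None:
        rows = n_rows
    else:
        rows = int(round(box_width_um / sc.pixel_size))
        if rows > n_rows:
            import warnings

            warnings.warn("box width exceeds straightening band; clamping",
                          stacklevel=2)
            rows = n_rows
        rows = max(1, rows)
    mid = (n_rows - 1) // 2
    half = (rows - 1) // 2
    lo = max(0, mid - half)
    box = raster[lo:lo + rows][:, cols]
    val = float(box.sum() - background * box.size)
    cell.fluor_integrated = val
    return val


def mean_axis_fluorescence(
    cell: CellRecord,
    sc: StraightenedChain,
    role: str = "reporter",
    averaging_rows: int | None = None,
    background: float = 0.0,
    boundary_guard_um: float = 0.15,
) -> float:
    """Mean intensity along the cell's axis segment, background-corrected.

    ``boundary_guard_um`` excludes a short stretch at each end of the
    interval: at the septa the finite PSF mixes the neighbouring cells'
    cytoplasmic signal, which would bias the mean of a cell whose
    neighbours differ strongly in expression.  The guard is skipped when
    the cell is too short for it.
    """
    _, prof = axial_profile(sc, role, averaging_rows)
    a, b = cell.axial_interval
    if b - a > 4 * boundary_guard_um:
        a, b = a + boundary_guard_um, b - boundary_guard_um
    cols = (sc.positions_um >= a) & (sc.positions_um < b)
    if not cols.any():
        cell.fluor_mean_axis = float("nan")
        return cell.fluor_mean_axis
    val = float(prof[cols].mean() - background)
    cell.fluor_mean_axis = val
    return val


# ----------------------------------------------------------- peak distance

def two_peak_distance(
    profile: np.ndarray,
    spacing: float,
    min_prominence_frac: float = 0.2,
) -> float:
    """Distance between the two outermost prominent maxima of a profile.

    Peak positions are refined by a parabolic fit through each peak and
    its neighbours.  Returns NaN when fewer than two peaks qualify.
    Shared by the membrane-based diameter measurement and the PSF
    projection simulation.
    """
    profile = np.asarray(profile, dtype=float)
    rng_ = profile.max() - profile.min()
    if rng_ == 0 or len(profile) < 3:
        return float("nan")
    idx, _ = find_peaks(profile, prominence=min_prominence_frac * rng_)
    if len(idx) < 2:
        return float("nan")
    lo, hi = idx[0], idx[-1]
    p_lo = lo + parabolic_refine(profile, lo)
    p_hi = hi + parabolic_refine(profile, hi)
    return float((p_hi - p_lo) * spacing)


def cell_diameter_membrane(
    sc: StraightenedChain,
    cell: CellRecord,
    role: str = "membrane",
    n_stations: int = 3,
) -> float:
    """Cell diameter from the perpendicular membrane profile, in um.

    At ``n_stations`` columns around the cell's axial midpoint the
    distance between the two outermost membrane peaks is measured and
    averaged.  NaN (flagged) when no station shows two peaks.
    """
    raster = sc.rasters[role]
    a, b = cell.axial_interval
    mid_um = 0.5 * (a + b)
    mid_col = int(np.argmin(np.abs(sc.positions_um - mid_um)))
    cols = [c for c in range(mid_col - n_stations // 2,
                             mid_col - n_stations // 2 + n_stations)
            if 0 <= c < raster.shape[1]]
    dists = [two_peak_distance(raster[:, c], sc.pixel_size) for c in cols]
    dists = [d for d in dists if np.isfinite(d)]
    val = float(np.mean(dists)) if dists else float("nan")
    cell.diameter = val
    return val


# --------------------------------------------------------------- summaries

def chain_length_class(cell_count: int) -> str:
    """Chain-length class: singlets/doublets, 3–4 cells, or 5 and more."""
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    if cell_count <= 2:
        return "1-2"
    if cell_count <= 4:
        return "3-4"
    return "5+"


@dataclass
class PopulationSummary:
    values: np.ndarray            # per-cell fluorescence
    bin_edges: np.ndarray
    counts: np.ndarray
    cum_x: np.ndarray             # sorted intensities
    cum_frac: np.ndarray          # empirical CDF, ends at 1
    class_table: pd.DataFrame     # per chain-length class: n, mean, sd, fraction


def summarize_population(
    cells: Sequence[CellRecord],
    chains_cell_counts: dict[int, int] | None = None,
    bins: int = 40,
    value_field: str = "fluor_mean_axis",
    bin_range: tuple[float, float] | None = None,
) -> PopulationSummary:
    """Histogram, empirical CDF and chain-length-class breakdown.

    ``chains_cell_counts`` maps chain_id -> number of cells in the chain
    (derived from ``cells`` when omitted).  Per-class dispersion is the
    standard deviation (not SEM).  ``bin_range`` lets several frames or
    time points share one binning for comparable histograms.
    """
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    values = np.array([getattr(c, value_field) for c in cells], dtype=float)
    counts, edges = np.histogram(values, bins=bins, range=bin_range)
    order = np.argsort(values, kind="stable")
    cum_x = values[order]
    cum_frac = np.arange(1, len(values) + 1) / len(values)

    if chains_cell_counts is None:
        chains_cell_counts = {}
        for c in cells:
            chains_cell_counts[c.chain_id] = chains_cell_counts.get(c.chain_id, 0) + 1
    rows = []
    n_chains = len(chains_cell_counts)
    for cls in ("1-2", "3-4", "5+"):
        chain_ids = {cid for cid, n in chains_cell_counts.items()
                     if chain_length_class(n) == cls}
        member = values[[c.chain_id in chain_ids for c in cells]]
        rows.append({
            "class": cls,
            "n_chains": len(chain_ids),
            "chain_fraction": len(chain_ids) / n_chains if n_chains else 0.0,
            "n_cells": len(member),
            "mean": float(member.mean()) if len(member) else float("nan"),
            "sd": float(member.std(ddof=1)) if len(member) > 1 else float("nan"),
        })
    return PopulationSummary(values=values, bin_edges=edges, counts=counts,
                             cum_x=cum_x, cum_frac=cum_frac,
                             class_table=pd.DataFrame(rows))


CELL_COLUMNS = ["source_id", "chain_id", "cell_index", "axial_start_um",
                "axial_end_um", "length_um", "diameter_um",
                "fluor_integrated", "fluor_mean_axis", "qualified"]


def cells_to_table(cells: Sequence[CellRecord], source_id: str = "") -> pd.DataFrame:
    """Flatten cell records to the exported results-table schema."""
    if not cells:
        return pd.DataFrame(columns=CELL_COLUMNS)
    return pd.DataFrame([{
        "source_id": source_id,
        "chain_id": c.chain_id,
        "cell_index": c.cell_index,
        "axial_start_um": c.axial_interval[0],
        "axial_end_um": c.axial_interval[1],
        "length_um": c.length,
        "diameter_um": c.diameter,
        "fluor_integrated": c.fluor_integrated,
        "fluor_mean_axis": c.fluor_mean_axis,
        "qualified": c.qualified,
    } for c in cells])
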