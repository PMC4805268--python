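"""End-to-end orchestration of the chain-based and nucleoid-based analyses.

``run_chaintracer`` performs the four semi-automated steps on every
frame: chain segmentation from phase contrast, axis tracing and
straightening, septum detection on the axial membrane profile (with
optional scripted manual corrections), and per-cell geometry and
fluorescence measurement.  ``run_nuctracer`` runs the segmentation-free
nucleoid route.  ``compare_methods`` quantifies agreement of the two
single-cell intensity distributions as a Kolmogorov distance.

Runs are deterministic: the same config and seed reproduce identical
output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .cell_metrics import (
    PopulationSummary,
    cell_diameter_membrane,
    cells_to_table,
    integrated_fluorescence,
    mean_axis_fluorescence,
    summarize_population,
)
from .chain_detection import (
    ChainObject,
    measure_chain_diameter_phase,
    segment_chains,
    trace_chain_axis,
)
from .config import RunConfig
from .imaging_io import CalibratedImageSet, load_image_set, modal_background
from .nuc_tracer import classify_bimodal, detect_nucleoids, measure_rois, rois_to_table
from .septum_detection import CellRecord, detect_septa, edit_septa, split_into_cells
from .straightening import StraightenedChain, axial_profile, straighten
from .synthetic_data import (
    GroundTruth,
    _polyline_arclengths,
    generate_chain_field,
    generate_cocci_field,
)

log = logging.getLogger("septachain")


@dataclass
class ChainTracerResult:
    chains: list[ChainObject]
    straightened: dict[int, StraightenedChain]
    septa: dict[int, list]                 # chain_id -> markers
    cells: list[CellRecord]
    table: pd.DataFrame
    summary: Optional[PopulationSummary]
    truth: Optional[GroundTruth] = None


@dataclass
class NucTracerResult:
    rois: list
    table: pd.DataFrame
    labels: Optional[np.ndarray]
    threshold: float = float("nan")
    high_fraction: float = float("nan")
    truth: Optional[GroundTruth] = None


def _obtain_image_set(config: RunConfig,
                      image_set: CalibratedImageSet | None,
                      kind: str = "chains"):
    truth = None
    if image_set is None:
        if config.input:
            if not config.channel_map or config.pixel_size is None:
                raise ValueError("input runs need channel_map and pixel_size")
            image_set = load_image_set(config.input, config.channel_map,
                                       config.pixel_size)
        else:
            fx = config.fixture.model_copy(update={"seed": config.seed})
            if kind == "chains":
                image_set, truth = generate_chain_field(fx)
            else:
                image_set, truth = generate_cocci_field(fx)
    return image_set, truth


def _read_edits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"chain_id", "action", "axial_um"}
    if not required <= set(df.columns):
        raise ValueError(f"edits file must have columns {sorted(required)}")
    return df


def run_chaintracer(
    config: RunConfig | None = None,
    image_set: CalibratedImageSet | None = None,
) -> ChainTracerResult:
    """Chain-based single-cell measurement on one frame.

    Without an input path in the config, a synthetic fixture is
    generated (and its ground truth attached to the result).  Manual
    septum corrections are read from ``config.edits`` (CSV with columns
    chain_id, action in {add, remove}, axial_um).
    """
    config = config or RunConfig()
    image_set, truth = _obtain_image_set(config, image_set, "chains")
    if "phase" not in image_set or "membrane" not in image_set:
        raise ValueError("chain analysis needs phase and membrane channels")
    px = image_set.pixel_size

    chains = segment_chains(image_set["phase"], px, config.chain)
    log.info("segmented %d chain objects", len(chains))
    for ch in chains:
        trace_chain_axis(ch, config.chain)
    traced = [c for c in chains if c.qualified and c.axis is not None]
    log.info("traced %d qualified chain axes", len(traced))

    edits = _read_edits(config.edits) if config.edits else None
    bg = {role: (config.metrics.background
                 if config.metrics.background is not None
                 else modal_background(image_set[role]))
          for role in image_set.channels}
    if not config.metrics.subtract_background:
        bg = {role: 0.0 for role in bg}

    straightened: dict[int, StraightenedChain] = {}
    septa: dict[int, list] = {}
    cells: list[CellRecord] = []
    for ch in traced:
        sc = straighten(image_set, ch, params=config.straighten)
        straightened[ch.chain_id] = sc
        pos, prof = axial_profile(sc, "membrane", params=config.straighten)
        markers = detect_septa(pos, prof, config.septum, chain_id=ch.chain_id,
                               axis_length=sc.axis_length)
        if edits is not None:
            rows = edits[edits.chain_id == ch.chain_id]
            if len(rows):
                markers, reports = edit_septa(
                    markers,
                    add=rows.loc[rows.action == "add", "axial_um"].tolist(),
                    remove=rows.loc[rows.action == "remove", "axial_um"].tolist(),
                    axis_length=sc.axis_length, params=config.septum,
                    chain_id=ch.chain_id)
                for r in reports:
                    log.warning("chain %d: %s", ch.chain_id, r)
        septa[ch.chain_id] = markers
        chain_cells = split_into_cells(ch, markers, params=config.septum)

        measure_chain_diameter_phase(ch)
        box_w = (config.metrics.box_width_um
                 if config.metrics.box_width_um is not None
                 else ch.mean_diameter_phase + 0.3)
        if "reporter" in sc:
            for cell in chain_cells:
                integrated_fluorescence(cell, sc, "reporter", box_w, bg["reporter"])
                mean_axis_fluorescence(cell, sc, "reporter",
                                       config.straighten.avg_rows, bg["reporter"])
        for cell in chain_cells:
            cell_diameter_membrane(sc, cell)
        cells.extend(chain_cells)
    log.info("detected %d septa, resolved %d cells",
             sum(len(m) for m in septa.values()), len(cells))

    table = cells_to_table(cells, image_set.source_id)
    summary = None
    if cells and "reporter" in image_set:
        counts = {cid: sum(1 for c in cells if c.chain_id == cid)
                  for cid in {c.chain_id for c in cells}}
        summary = summarize_population(cells, counts,
                                       bins=config.metrics.histogram_bins)
    return ChainTracerResult(chains=chains, straightened=straightened,
                             septa=septa, cells=cells, table=table,
                             summary=summary, truth=truth)


def run_nuctracer(
    config: RunConfig | None = None,
    image_set: CalibratedImageSet | None = None,
) -> NucTracerResult:
    """Nucleoid-based single-cell measurement on one frame."""
    config = config or RunConfig()
    image_set, truth = _obtain_image_set(config, image_set, "cocci")
    if "dapi" not in image_set:
        raise ValueError("nucleoid analysis needs a dapi channel")
    px = image_set.pixel_size
    rois = detect_nucleoids(image_set["dapi"], px, config.nuc)
    log.info("detected %d nucleoid ROIs", len(rois))
    if "reporter" in image_set:
        bg = (config.metrics.background
              if config.metrics.background is not None
              else modal_background(image_set["reporter"]))
        measure_rois(rois, image_set["reporter"], px, bg)
    table = rois_to_table(rois, image_set.source_id)
    labels, thr, high_frac = None, float("nan"), float("nan")
    if len(table):
        good = table[table.qualified & np.isfinite(
            table.reporter_mean.astype(float))]
    else:
        good = table
    if len(good) >= 10:
        labels, thr = classify_bimodal(good.reporter_mean.to_numpy())
        high_frac = float(np.mean(labels == "high"))
        log.info("bimodal split at %.1f a.u.: high fraction %.3f", thr, high_frac)
    return NucTracerResult(rois=rois, table=table, labels=labels,
                           threshold=thr, high_fraction=high_frac, truth=truth)


def score_septa(
    result: ChainTracerResult,
    truth: GroundTruth,
    tol_um: float = 0.3,
    chain_match_um: float = 2.0,
) -> dict:
    """Score detected septa against a ground-truth record.

    Truth chains are matched to detected chains by axis-midpoint
    distance; marker coordinates are flipped when the traced axis runs
    opposite to the generated centerline.  A true septum counts as
    detected when a marker lies within ``tol_um``; unmatched markers are
    false positives.  Septa of chains that were never detected (or were
    disqualified) count as missed.

    Returns counts plus the missed true positions mapped into each
    detected chain's axis coordinate (usable as a manual-edits file).
    """
    det = {c.chain_id: c for c in result.chains
           if c.qualified and c.axis is not None}
    arclen = {}
    for cid, c in det.items():
        seg = np.linalg.norm(np.diff(c.axis, axis=0), axis=1)
        arclen[cid] = np.concatenate([[0.0], np.cumsum(seg)])

    def to_axis_coord(cid: int, pt: np.ndarray) -> tuple[float, float]:
        """Nearest-vertex projection of a planar point onto a detected axis."""
        d = np.linalg.norm(det[cid].axis - pt, axis=1)
        k = int(np.argmin(d))
        return float(arclen[cid][k]), float(d[k])

    n_true = n_missed = n_false = 0
    missed: list[tuple[int, float]] = []   # (detected chain_id, axial um)
    false_markers: list[tuple[int, float]] = []
    used: dict[int, set[int]] = {cid: set() for cid in det}
    for tc in truth.chains:
        n_true += len(tc.septa)
        t_mid = tc.centerline[len(tc.centerline) // 2]
        best, bd = None, np.inf
        for cid, c in det.items():
            d = float(np.min(np.linalg.norm(c.axis - t_mid, axis=1)))
            if d < bd:
                bd, best = d, cid
        if best is None or bd > chain_match_um:
            n_missed += len(tc.septa)
            continue
        s_all = _polyline_arclengths(tc.centerline)
        marks = [m.axial_position for m in result.septa.get(best, [])]
        for s_true in tc.septa:
            pt = tc.centerline[int(np.searchsorted(s_all, s_true))]
            s_det, _ = to_axis_coord(best, pt)
            cand = [(abs(m - s_det), i) for i, m in enumerate(marks)
                    if i not in used[best]]
            if cand and min(cand)[0] <= tol_um:
                used[best].add(min(cand)[1])
            else:
                n_missed += 1
                missed.append((best, float(np.clip(
                    s_det, 1e-3, det[best].axis_length - 1e-3))))
    for cid, c in det.items():
        for i, m in enumerate(result.septa.get(cid, [])):
            if i not in used[cid]:
                n_false += 1
                false_markers.append((cid, m.axial_position))
    return {"n_true": n_true, "n_missed": n_missed, "n_false": n_false,
            "miss_rate": n_missed / n_true if n_true else 0.0,
            "false_rate": n_false / n_true if n_true else 0.0,
            "missed": missed, "false_markers": false_markers}


def compare_methods(
    chain_table: pd.DataFrame,
    nuc_table: pd.DataFrame,
    chain_col: str = "fluor_mean_axis",
    nuc_col: str = "reporter_mean",
) -> float:
    """Kolmogorov distance between the two per-cell intensity CDFs.

    Zero means the cumulative frequency curves coincide; values below
    ~0.1 indicate the two methods report the same population
    distribution.
    """
    a = chain_table[chain_col].dropna().to_numpy()
    b = nuc_table[nuc_col].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both tables need finite intensity values")
    return float(ks_2samp(a, b, method="asymp").statistic)
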