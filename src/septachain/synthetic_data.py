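"""Ground-truthed synthetic fluorescence fields.

Generates the two kinds of fixtures the analysis is validated against:

* **chain fields** — rod-shaped cells joined end-to-end into chains, with
  a phase-contrast channel (dark rods on a bright background), a membrane
  channel (bright cell outline plus one brighter transverse cross-wall
  per septum), a DAPI channel (1–2 diffraction-limited nucleoid blobs per
  cell) and a reporter channel (per-cell uniform intensity drawn from a
  bimodal low/high mixture);
* **cocci fields** — isolated round cells, one nucleoid each, reporter by
  subpopulation label.

Every randomly drawn quantity is recorded in a :class:`GroundTruth` so
downstream detections can be scored exactly: chain centerlines, septum
positions, per-cell reporter amplitude and total injected signal, nucleoid
centers and subpopulation labels.  Generation is fully deterministic given
the seed.

Cells are painted with flat (butt) ends, so a chain's mask length equals
its centerline arc length exactly and ground-truth axial positions need no
cap correction.  Optics are emulated as a 2-D Gaussian blur of the painted
amplitudes plus additive Gaussian read noise on every channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .config import FixtureParams
from .imaging_io import CalibratedImageSet

_WALL_UM = 0.13          # painted thickness of membrane outline and septa
_CENTERLINE_STEP = 0.02  # um; sampling of centerline polylines


# ---------------------------------------------------------------- truth types

@dataclass
class CellTruth:
    chain_id: int
    index: int                    # 1-based along the chain
    interval: tuple[float, float]  # axial um from chain start
    label: str                    # "low" | "high"
    reporter_amplitude: float     # above background
    n_pixels: int = 0             # interior pixels painted
    total_signal: float = 0.0     # injected reporter sum above background
    nucleoids: list[tuple[float, float]] = field(default_factory=list)  # (x, y) um


@dataclass
class ChainTruth:
    chain_id: int
    centerline: np.ndarray        # (N, 2) um, ordered pole to pole
    arc_length: float             # um
    width: float                  # um
    septa: list[float]            # axial um, interior cell boundaries
    cells: list[CellTruth]


@dataclass
class CoccusTruth:
    center: tuple[float, float]   # um
    diameter: float
    label: str
    reporter_amplitude: float


@dataclass
class GroundTruth:
    pixel_size: float
    background: float
    noise_sigma: float
    mixing_fraction: float
    seed: int
    chains: list[ChainTruth] = field(default_factory=list)
    cocci: list[CoccusTruth] = field(default_factory=list)

    @property
    def cells(self) -> list[CellTruth]:
        return [c for ch in self.chains for c in ch.cells]

    @property
    def all_septa(self) -> list[tuple[int, float]]:
        return [(ch.chain_id, s) for ch in self.chains for s in ch.septa]

    @property
    def nucleoid_centers(self) -> np.ndarray:
        pts = [n for c in self.cells for n in c.nucleoids]
        pts += [c.center for c in self.cocci]
        return np.array(pts, dtype=float).reshape(-1, 2)


# ------------------------------------------------------------------ geometry

def _straight_centerline(length: float) -> np.ndarray:
    n = max(2, int(round(length / _CENTERLINE_STEP)) + 1)
    s = np.linspace(0.0, length, n)
    return np.column_stack([s, np.zeros_like(s)])


def _arc_centerline(length: float, radius: float) -> np.ndarray:
    """Circular arc of given arc length and bend radius, start at origin."""
    n = max(2, int(round(length / _CENTERLINE_STEP)) + 1)
    phi = np.linspace(0.0, length / radius, n)
    x = radius * np.sin(phi)
    y = radius * (1.0 - np.cos(phi))
    return np.column_stack([x, y])


def _transform(poly: np.ndarray, angle_deg: float, offset: np.ndarray) -> np.ndarray:
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    return poly @ rot.T + offset


def _polyline_arclengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


# -------------------------------------------------------------- chain fields

def _draw_labels(rng: np.random.Generator, n: int, p: float) -> list[str]:
    return ["high" if u < p else "low" for u in rng.random(n)]


def _draw_amplitudes(rng: np.random.Generator, labels: Sequence[str],
                     p: FixtureParams) -> list[float]:
    """Per-cell reporter amplitudes: Gaussian mixture component by label."""
    out = []
    for lb in labels:
        if lb == "high":
            a = rng.normal(p.reporter_high, p.reporter_high_sd)
        else:
            a = rng.normal(p.reporter_low, p.reporter_low_sd)
        out.append(max(float(a), 0.0))
    return out


def _min_polyline_distance(a: np.ndarray, tree_b: cKDTree) -> float:
    d, _ = tree_b.query(a)
    return float(np.min(d))


def _place_chains(
    rng: np.random.Generator,
    lengths: Sequence[float],
    width: float,
    field_um: float,
    clearance_um: float,
    bend_radius_um: Optional[float],
    orientation_deg: Optional[float],
    max_tries: int = 400,
) -> list[np.ndarray]:
    """Place centerlines so rods keep >= clearance_um edge-to-edge distance."""
    margin = width / 2 + clearance_um + 0.5
    placed: list[np.ndarray] = []
    trees: list[cKDTree] = []
    min_center_dist = width + clearance_um
    for L in lengths:
        base = (_arc_centerline(L, bend_radius_um) if bend_radius_um
                else _straight_centerline(L))
        ok = False
        for _ in range(max_tries):
            ang = orientation_deg if orientation_deg is not None else rng.uniform(0, 360)
            cand = _transform(base, ang, np.zeros(2))
            lo, hi = cand.min(axis=0), cand.max(axis=0)
            span = hi - lo
            if np.any(span > field_um - 2 * margin):
                continue
            off = np.array([
                rng.uniform(margin - lo[0], field_um - margin - hi[0]),
                rng.uniform(margin - lo[1], field_um - margin - hi[1]),
            ])
            cand = cand + off
            if all(_min_polyline_distance(cand, t) >= min_center_dist for t in trees):
                placed.append(cand)
                trees.append(cKDTree(cand))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {len(lengths)} chains of length {max(lengths):.1f} um "
                f"in a {field_um:.0f} um field without contact; enlarge field_um"
            )
    return placed


def generate_chain_field(
    params: FixtureParams | None = None,
    *,
    field_um: Optional[float] = None,
    bend_radius_um: Optional[float] = None,
    orientation_deg: Optional[float] = None,
    **overrides,
) -> tuple[CalibratedImageSet, GroundTruth]:
    """Generate a multi-channel field of membrane-stained cell chains.

    Parameters beyond the :class:`~septachain.config.FixtureParams` block:
    ``field_um`` fixes the square field side (auto-sized otherwise),
    ``bend_radius_um`` bends every chain into a circular arc of that
    radius, and ``orientation_deg`` forces a common orientation (random
    per chain by default).

    Returns the image set and the full ground-truth record.
    """
    p = (params or FixtureParams()).model_copy(update=overrides)
    rng = np.random.default_rng(p.seed)
    px = p.pixel_size
    r = p.diameter_um / 2

    if isinstance(p.cells_per_chain, int):
        ncells = [p.cells_per_chain] * p.n_chains
    else:
        lo, hi = p.cells_per_chain
        ncells = [int(rng.integers(lo, hi + 1)) for _ in range(p.n_chains)]
    lengths = [n * p.cell_length_um for n in ncells]

    clearance_um = p.clearance_px * px
    if field_um is None:
        capsule_area = sum((L + p.diameter_um) * (p.diameter_um + 2 * clearance_um)
                           for L in lengths)
        field_um = max(max(lengths) + 2 * p.diameter_um + 4 * clearance_um + 2,
                       math.sqrt(capsule_area / 0.08))
    npix = int(round(field_um / px))

    centerlines = _place_chains(rng, lengths, p.diameter_um, field_um,
                                clearance_um, bend_radius_um, orientation_deg)

    membrane = np.zeros((npix, npix))
    phase_drop = np.zeros((npix, npix))
    reporter = np.zeros((npix, npix))
    dapi = np.zeros((npix, npix))

    truth = GroundTruth(pixel_size=px, background=p.background,
                        noise_sigma=p.noise_sigma, mixing_fraction=p.mixing_fraction,
                        seed=p.seed)
    septum_amp = p.septum_contrast * p.membrane_amplitude

    for ci, (poly, n) in enumerate(zip(centerlines, ncells), start=1):
        arclens = _polyline_arclengths(poly)
        L = float(arclens[-1])
        bounds = [k * p.cell_length_um for k in range(n + 1)]
        septa = bounds[1:-1]
        labels = _draw_labels(rng, n, p.mixing_fraction)
        amps = _draw_amplitudes(rng, labels, p)

        # local window around the chain
        pad = r + _WALL_UM + 5 * p.blur_sigma_um + 3 * px
        lo_px = np.maximum(0, np.floor((poly.min(axis=0) - pad) / px).astype(int))
        hi_px = np.minimum(npix - 1, np.ceil((poly.max(axis=0) + pad) / px).astype(int))
        xs = np.arange(lo_px[0], hi_px[0] + 1)
        ys = np.arange(lo_px[1], hi_px[1] + 1)
        gx, gy = np.meshgrid(xs * px, ys * px)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        tree = cKDTree(poly)
        dist, idx = tree.query(pts)
        s = arclens[idx]
        dist = dist.reshape(gy.shape)
        s = s.reshape(gy.shape)

        # flat (butt) ends: clip at the poles so mask length == arc length;
        # points beyond a pole project onto the end vertex (s == 0 or L)
        span = (s > 1e-12) & (s < L - 1e-12)
        interior = (dist <= r) & span
        shell = ((np.abs(dist - r) <= _WALL_UM / 2) & span) | (
            interior & ((s <= _WALL_UM / 2) | (s >= L - _WALL_UM / 2)))
        win = np.s_[lo_px[1]:hi_px[1] + 1, lo_px[0]:hi_px[0] + 1]
        np.maximum(membrane[win], np.where(shell, p.membrane_amplitude, 0.0),
                   out=membrane[win])
        for sb in septa:
            sept = interior & (np.abs(s - sb) <= _WALL_UM / 2)
            np.maximum(membrane[win], np.where(sept, septum_amp, 0.0),
                       out=membrane[win])
        phase_drop[win] = np.maximum(
            phase_drop[win],
            np.where(interior, p.phase_background - p.phase_cell_level, 0.0))

        cells = []
        for k in range(n):
            a, b = bounds[k], bounds[k + 1]
            cell_px = interior & (s >= a) & (s < b)
            reporter[win] = np.maximum(reporter[win],
                                       np.where(cell_px, amps[k], 0.0))
            n_nuc = int(rng.integers(1, 3))
            fracs = (0.5,) if n_nuc == 1 else (0.25, 0.75)
            nucs = []
            for f in fracs:
                s_nuc = a + f * (b - a)
                pt = poly[np.searchsorted(arclens, min(s_nuc, L - 1e-9))]
                nucs.append((float(pt[0]), float(pt[1])))
            npx_cell = int(cell_px.sum())
            cells.append(CellTruth(
                chain_id=ci, index=k + 1, interval=(a, b), label=labels[k],
                reporter_amplitude=amps[k], n_pixels=npx_cell,
                total_signal=amps[k] * npx_cell, nucleoids=nucs))
        truth.chains.append(ChainTruth(
            chain_id=ci, centerline=poly, arc_length=L, width=p.diameter_um,
            septa=list(septa), cells=cells))

    _render_nucleoids(dapi, truth, p)

    sig = p.blur_sigma_um / px
    membrane_img = p.background + gaussian_filter(membrane, sig)
    reporter_img = p.background + gaussian_filter(reporter, sig)
    phase_img = p.phase_background - gaussian_filter(phase_drop, sig)
    dapi_img = p.background + dapi

    channels = {"phase": phase_img, "membrane": membrane_img,
                "dapi": dapi_img, "reporter": reporter_img}
    if p.noise_sigma > 0:
        for role in channels:
            channels[role] = channels[role] + rng.normal(
                0.0, p.noise_sigma, size=channels[role].shape)
    image_set = CalibratedImageSet(channels=channels, pixel_size=px,
                                   source_id=f"synthetic-chains-seed{p.seed}")
    return image_set, truth


def _render_nucleoids(dapi: np.ndarray, truth: GroundTruth, p: FixtureParams) -> None:
    """Add an analytic Gaussian blob per nucleoid (sigma = dapi_sigma_um)."""
    px = p.pixel_size
    sig_px = p.dapi_sigma_um / px
    half = int(math.ceil(4 * sig_px))
    n = dapi.shape[0]
    centers = [nc for cell in truth.cells for nc in cell.nucleoids]
    centers += [c.center for c in truth.cocci]
    for (x_um, y_um) in centers:
        cx, cy = x_um / px, y_um / px
        x0, x1 = max(0, int(cx) - half), min(n - 1, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(n - 1, int(cy) + half + 1)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)[:, None]
        blob = p.dapi_amplitude * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sig_px ** 2))
        dapi[y0:y1, x0:x1] += blob


# --------------------------------------------------------------- cocci field

def generate_cocci_field(
    params: FixtureParams | None = None,
    *,
    n_cells: int = 500,
    field_um: Optional[float] = None,
    **overrides,
) -> tuple[CalibratedImageSet, GroundTruth]:
    """Generate a field of isolated round cells, one nucleoid blob each.

    Cells are placed on a jittered grid so pairwise separation is
    guaranteed without rejection sampling; reporter intensity is uniform
    within each cell at the low/high amplitude of its label.
    """
    p = (params or FixtureParams()).model_copy(update=overrides)
    rng = np.random.default_rng(p.seed)
    px = p.pixel_size
    r = p.diameter_um / 2

    pitch = p.diameter_um + 0.8      # um between grid sites
    jitter = 0.2
    side = int(math.ceil(math.sqrt(n_cells)))
    if field_um is None:
        field_um = side * pitch + 2 * pitch
    npix = int(round(field_um / px))

    sites = [(i, j) for i in range(side) for j in range(side)]
    order = rng.permutation(len(sites))[:n_cells]
    labels = _draw_labels(rng, n_cells, p.mixing_fraction)
    amps = _draw_amplitudes(rng, labels, p)

    reporter = np.zeros((npix, npix))
    phase_drop = np.zeros((npix, npix))
    membrane = np.zeros((npix, npix))
    truth = GroundTruth(pixel_size=px, background=p.background,
                        noise_sigma=p.noise_sigma, mixing_fraction=p.mixing_fraction,
                        seed=p.seed)
    for k, si in enumerate(order):
        i, j = sites[si]
        cx = pitch + i * pitch + rng.uniform(-jitter, jitter)
        cy = pitch + j * pitch + rng.uniform(-jitter, jitter)
        amp = amps[k]
        half = int(math.ceil((r + _WALL_UM) / px)) + 2
        icx, icy = int(cx / px), int(cy / px)
        xs = np.arange(max(0, icx - half), min(npix, icx + half + 1))
        ys = np.arange(max(0, icy - half), min(npix, icy + half + 1))[:, None]
        d = np.sqrt((xs * px - cx) ** 2 + (ys * px - cy) ** 2)
        win = np.s_[ys.ravel()[0]:ys.ravel()[-1] + 1, xs[0]:xs[-1] + 1]
        reporter[win] = np.maximum(reporter[win], np.where(d <= r, amp, 0.0))
        membrane[win] = np.maximum(membrane[win],
                                   np.where(np.abs(d - r) <= _WALL_UM / 2,
                                            p.membrane_amplitude, 0.0))
        phase_drop[win] = np.maximum(
            phase_drop[win],
            np.where(d <= r, p.phase_background - p.phase_cell_level, 0.0))
        truth.cocci.append(CoccusTruth(center=(cx, cy), diameter=p.diameter_um,
                                       label=labels[k], reporter_amplitude=amp))

    dapi = np.zeros((npix, npix))
    _render_nucleoids(dapi, truth, p)

    sig = p.blur_sigma_um / px
    channels = {
        "phase": p.phase_background - gaussian_filter(phase_drop, sig),
        "membrane": p.background + gaussian_filter(membrane, sig),
        "dapi": p.background + dapi,
        "reporter": p.background + gaussian_filter(reporter, sig),
    }
    if p.noise_sigma > 0:
        for role in channels:
            channels[role] = channels[role] + rng.normal(
                0.0, p.noise_sigma, size=channels[role].shape)
    image_set = CalibratedImageSet(channels=channels, pixel_size=px,
                                   source_id=f"synthetic-cocci-seed{p.seed}")
    return image_set, truth
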