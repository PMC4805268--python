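"""Chain identification and axis tracing from the phase-contrast channel.

Cell chains appear as dark filamentous shapes on a brighter background in
phase contrast.  Segmentation is a global threshold (Otsu by default) on
the phase channel, hole filling, small-object and border-object removal.
Each connected component becomes a :class:`ChainObject`.

The chain axis is the longest path through the skeleton of the mask,
found by a double Dijkstra sweep over the skeleton pixel graph, smoothed
by a moving average and extended along the end tangents to the mask
boundary so the poles are included.  Skeleton side branches are tolerated
up to a prune length; a mask whose branches exceed it (e.g. two touching
chains forming a Y) is flagged unqualified and gets no axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, skeletonize

from .config import ChainParams


@dataclass
class ChainObject:
    """One detected cell chain.

    The mask is stored as a local boolean window plus its offset in the
    frame; ``axis`` is an open polyline in micrometres ordered pole to
    pole (``None`` until traced).
    """

    chain_id: int
    mask: np.ndarray              # local bool window
    offset: tuple[int, int]       # (x0, y0) px of mask[0, 0] in the frame
    pixel_size: float
    axis: Optional[np.ndarray] = None       # (N, 2) um
    axis_length: float = 0.0
    mean_diameter_phase: float = float("nan")
    qualified: bool = True

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size ** 2

    def contains_um(self, x_um: float, y_um: float) -> bool:
        """Point-in-mask test in physical coordinates."""
        j = int(round(x_um / self.pixel_size)) - self.offset[0]
        i = int(round(y_um / self.pixel_size)) - self.offset[1]
        if 0 <= i < self.mask.shape[0] and 0 <= j < self.mask.shape[1]:
            return bool(self.mask[i, j])
        return False


def segment_chains(
    phase: np.ndarray,
    pixel_size: float,
    params: ChainParams | None = None,
) -> list[ChainObject]:
    """Identify chain objects as connected foreground components.

    Foreground is intensity below the threshold when ``dark_cells`` (the
    default phase-contrast polarity), above it otherwise.  Holes are
    filled; components under ``min_area_um2`` are dropped; components
    touching the frame border are dropped under the default
    ``border_policy="exclude"``.  A blank (constant) frame yields an
    empty list.
    """
    p = params or ChainParams()
    phase = np.asarray(phase, dtype=float)
    if phase.max() == phase.min():
        return []
    if p.smooth_um > 0:
        phase = ndimage.gaussian_filter(phase, p.smooth_um / pixel_size)
    if p.threshold_method == "fixed":
        if p.fixed_threshold is None:
            raise ValueError("threshold_method='fixed' requires fixed_threshold")
        thr = p.fixed_threshold
    else:
        thr = threshold_otsu(phase)
    fg = phase < thr if p.dark_cells else phase > thr
    fg = ndimage.binary_fill_holes(fg)
    labels, n = cc_label(fg, connectivity=2, return_num=True)

    min_px = p.min_area_um2 / pixel_size ** 2
    chains: list[ChainObject] = []
    cid = 0
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == sl_idx
        if comp.sum() < min_px:
            continue
        if p.border_policy == "exclude":
            ys, xs = sl
            if (ys.start == 0 or xs.start == 0 or
                    ys.stop == phase.shape[0] or xs.stop == phase.shape[1]):
                continue
        cid += 1
        chains.append(ChainObject(chain_id=cid, mask=comp.copy(),
                                  offset=(sl[1].start, sl[0].start),
                                  pixel_size=pixel_size))
    return chains


# ----------------------------------------------------------- skeleton graph

def _skeleton_graph(skel: np.ndarray):
    """Sparse 8-connected graph over skeleton pixels, Euclidean weights (px)."""
    ys, xs = np.nonzero(skel)
    n = len(ys)
    index = -np.ones(skel.shape, dtype=int)
    index[ys, xs] = np.arange(n)
    rows, cols, w = [], [], []
    for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):
        y2, x2 = ys + dy, xs + dx
        ok = (0 <= y2) & (y2 < skel.shape[0]) & (0 <= x2) & (x2 < skel.shape[1])
        ok[ok] &= skel[y2[ok], x2[ok]]
        a, b = index[ys[ok], xs[ok]], index[y2[ok], x2[ok]]
        wt = math.hypot(dy, dx)
        rows += [*a, *b]
        cols += [*b, *a]
        w += [wt] * (2 * len(a))
    g = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    return g, ys, xs


def _longest_skeleton_path(skel: np.ndarray):
    """Longest path by double sweep; returns (path indices (N,2) yx, off-path depth px).

    Only the largest connected skeleton component is traced — opening can
    shed tiny disconnected specks that must not capture the sweep.
    """
    lab, nlab = ndimage.label(skel, structure=np.ones((3, 3)))
    if nlab > 1:
        sizes = ndimage.sum_labels(skel, lab, index=np.arange(1, nlab + 1))
        skel = lab == (1 + int(np.argmax(sizes)))
    g, ys, xs = _skeleton_graph(skel)
    n = len(ys)
    if n == 0:
        return None, 0.0
    if n == 1:
        return np.column_stack([ys, xs]), 0.0
    d0 = dijkstra(g, indices=0)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du, pred = dijkstra(g, indices=u, return_predecessors=True)
    du_f = np.where(np.isfinite(du), du, -1)
    v = int(np.argmax(du_f))
    path = [v]
    while path[-1] != u:
        p_ = pred[path[-1]]
        if p_ < 0:
            break
        path.append(int(p_))
    path = np.array(path[::-1])
    on_path = np.zeros(n, dtype=bool)
    on_path[path] = True
    if on_path.all():
        off_depth = 0.0
    else:
        d_off = dijkstra(g, indices=np.nonzero(on_path)[0], min_only=True)
        d_off = d_off[~on_path]
        off_depth = float(np.max(d_off[np.isfinite(d_off)], initial=0.0))
    return np.column_stack([ys[path], xs[path]]), off_depth


def _moving_average(poly: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(poly) < 3:
        return poly
    w = min(window if window % 2 == 1 else window + 1, 2 * (len(poly) // 2) - 1)
    if w < 3:
        return poly
    pad = w // 2
    ext = np.concatenate([poly[pad:0:-1], poly, poly[-2:-2 - pad:-1]])
    kern = np.ones(w) / w
    out = np.column_stack([np.convolve(ext[:, k], kern, mode="valid")
                           for k in range(2)])
    return out


def trace_chain_axis(chain: ChainObject, params: ChainParams | None = None) -> ChainObject:
    """Trace the chain axis through the mask skeleton (in place; returns chain).

    Branches deeper than ``max(prune_um, 0.9 × estimated mask width)``
    after longest-path extraction disqualify the chain: they indicate
    touching chains rather than the corner spurs thinning produces at
    rod poles, whose depth scales with the mask half-width.
    """
    p = params or ChainParams()
    px = chain.pixel_size
    if chain.mask.sum() == 0:
        chain.qualified = False
        return chain
    # Round the pole corners before thinning: opening with a disk scaled to
    # the inscribed half-width turns a flat-ended rod into a stadium whose
    # skeleton is the clean midline, instead of sprouting diagonal corner
    # spurs whose depth rivals the mask width.  The radius backs off if the
    # opening would fragment the mask (possible for strongly bent chains).
    dist_map = ndimage.distance_transform_edt(np.pad(chain.mask, 1))[1:-1, 1:-1]
    half_w_px = float(dist_map.max())
    work = chain.mask
    r_open = min(int(round(0.8 * half_w_px)), 25)
    eight = np.ones((3, 3))
    while r_open >= 1:
        opened = ndimage.binary_opening(np.pad(chain.mask, r_open),
                                        structure=disk(r_open))
        opened = opened[r_open:-r_open, r_open:-r_open]
        _, ncomp = ndimage.label(opened, structure=eight)
        if ncomp == 1 and opened.sum() >= 0.6 * chain.mask.sum():
            work = opened
            break
        r_open //= 2
    skel = skeletonize(work)
    path_yx, off_depth_px = _longest_skeleton_path(skel)
    if path_yx is None or len(path_yx) < 2:
        chain.qualified = False
        return chain

    width_est_px = 2.0 * float(dist_map[skel].mean()) if skel.any() else 0.0
    allow_px = max(p.prune_um / px, 0.9 * width_est_px)
    if off_depth_px > allow_px:
        chain.qualified = False
        chain.axis = None
        return chain

    # px (local, x=col y=row) -> smooth -> extend to mask boundary -> um
    poly = np.column_stack([path_yx[:, 1], path_yx[:, 0]]).astype(float)
    poly = _moving_average(poly, p.smooth_window)
    poly = _extend_to_boundary(poly, chain.mask)
    poly = poly + np.array(chain.offset, dtype=float)
    poly_um = poly * px
    keep = np.concatenate([[True], np.linalg.norm(np.diff(poly_um, axis=0), axis=1) > 1e-9])
    poly_um = poly_um[keep]
    chain.axis = poly_um
    chain.axis_length = float(np.linalg.norm(np.diff(poly_um, axis=0), axis=1).sum())
    return chain


def _extend_to_boundary(poly: np.ndarray, mask: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Extend both polyline ends along the local tangent until leaving the mask."""
    def inside(pt):
        j, i = int(round(pt[0])), int(round(pt[1]))
        return (0 <= i < mask.shape[0] and 0 <= j < mask.shape[1] and mask[i, j])

    out = [poly]
    k = min(5, len(poly) - 1)
    for end, ref, position in ((poly[0], poly[k], "head"), (poly[-1], poly[-k - 1], "tail")):
        d = end - ref
        nrm = np.linalg.norm(d)
        if nrm == 0:
            continue
        d = d / nrm
        t = step
        last = None
        while inside(end + t * d) and t < max(mask.shape) * 2:
            last = end + t * d
            t += step
        if last is not None:
            ext = (last + (step / 2) * d)[None, :]
            if position == "head":
                out.insert(0, ext)
            else:
                out.append(ext)
    return np.vstack(out)


def measure_chain_diameter_phase(
    chain: ChainObject,
    phase: np.ndarray | None = None,
    station_um: float = 0.2,
    end_margin_um: float = 0.5,
) -> float:
    """Mean mask width perpendicular to the axis, in micrometres.

    At evenly spaced axial stations (excluding a margin at each pole) a
    ray is marched in both perpendicular directions until it leaves the
    mask; the width is the sum of the two crossing distances.  Stores the
    result on the chain and returns it.
    """
    if chain.axis is None:
        raise ValueError("chain axis not traced")
    px = chain.pixel_size
    axis = chain.axis
    seg = np.diff(axis, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    L = s[-1]
    stations = np.arange(end_margin_um, L - end_margin_um + 1e-9, station_um)
    if len(stations) == 0:
        stations = np.array([L / 2])
    widths = []
    half_step = 0.1 * px
    for st in stations:
        k = min(np.searchsorted(s, st, side="right") - 1, len(seg) - 1)
        frac = (st - s[k]) / seglen[k] if seglen[k] > 0 else 0.0
        q = axis[k] + frac * seg[k]
        t = seg[k] / seglen[k]
        nvec = np.array([-t[1], t[0]])
        w = 0.0
        for sgn in (1.0, -1.0):
            d = half_step
            while chain.contains_um(*(q + sgn * d * nvec)) and d < 50:
                d += half_step
            w += d - half_step / 2
        widths.append(w)
    chain.mean_diameter_phase = float(np.mean(widths))
    return chain.mean_diameter_phase
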