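"""Quantitative read-outs of trained networks.

Includes the single-cell stimulus-specific information measure

    I(s, R) = sum_r P(r|s) log2 [ P(r|s) / P(r) ]

computed over quantized firing rates, with the stimulus category s being a
boundary element (side, conformation); the strict element-selectivity
criterion (rates within 5e-5 of 1 for every object containing the element
and within 5e-5 of 0 for every object lacking it); receptive-field
backtracing through the feed-forward weights; boundary segmentation into
(curvature, angular position) elements; curvature x angular-position tuning
heatmaps with local-peak counting; comparison of a heatmap against an
idealized Gaussian-tuned V4 cell; and spatial feature maps of the cells at
maximal information per element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ResponseTable",
    "InfoResult",
    "BoundarySegment",
    "TuningHeatmap",
    "responses_to_matrix",
    "single_cell_information",
    "count_selective_cells",
    "selective_cell_matrix",
    "backtrace_receptive_field",
    "segment_boundary",
    "calibrate_segmentation_threshold",
    "tuning_heatmap",
    "count_heatmap_peaks",
    "v4_model_correlation",
    "feature_map",
]

RESPONSE_COLUMNS = ["cell", "layer", "object", "loc_x", "loc_y",
                    "orientation", "rate"]

# The element-selectivity rate windows: ~1 for every object containing the
# element, ~0 for every object lacking it.
SELECTIVE_HI = 0.99995
SELECTIVE_LO = 0.00005


def make_response_table(records: Iterable[tuple]) -> pd.DataFrame:
    """Assemble a response table (one row per cell x presentation)."""
    df = pd.DataFrame(records, columns=RESPONSE_COLUMNS)
    if ((df["rate"] < 0) | (df["rate"] > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    return df


ResponseTable = pd.DataFrame  # alias: columns RESPONSE_COLUMNS


def responses_to_matrix(table: ResponseTable) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Pivot to (cells x presentations): (matrix, cell_ids, presentation index)."""
    pres_cols = ["object", "loc_x", "loc_y", "orientation"]
    pivot = table.pivot_table(index="cell", columns=pres_cols, values="rate",
                              sort=True)
    if pivot.isna().any().any():
        raise ValueError("response table is not a complete factorial design")
    pres = pivot.columns.to_frame(index=False)
    return pivot.to_numpy(), pivot.index.to_numpy(), pres


# ---------------------------------------------------------------------------
# single-cell information

@dataclass
class InfoResult:
    cell_ids: np.ndarray
    categories: list
    per_category: np.ndarray  # (n_cells, n_categories) bits
    n_bins: int

    @property
    def max_info(self) -> np.ndarray:
        """Per-cell information: the maximum over stimulus categories."""
        return self.per_category.max(axis=1)

    def ranked(self) -> np.ndarray:
        """Cell information sorted in decreasing order (rank-order curve)."""
        return np.sort(self.max_info)[::-1]


def single_cell_information(table: ResponseTable,
                            category_of: Callable[[object], Iterable],
                            n_bins: int = 10) -> InfoResult:
    """Stimulus-specific information each cell carries about each category.

    ``category_of(object_id)`` returns the categories (boundary elements)
    present in that object.  Rates are quantized into ``n_bins`` equal-width
    bins over [0, 1]; P(r) is taken over all presentations and P(r|s) over
    the presentations of objects containing s.  A cell that fires 1 for
    every object containing an element and 0 otherwise attains log2(p) bits
    in a design where each side takes one of p conformations.
    """
    mat, cells, pres = responses_to_matrix(table)
    binned = np.minimum((np.clip(mat, 0.0, 1.0) * n_bins).astype(int), n_bins - 1)
    categories: list = []
    masks: list[np.ndarray] = []
    cat_set: dict = {}
    obj_cats = {obj: tuple(category_of(obj)) for obj in pres["object"].unique()}
    for obj, cats in obj_cats.items():
        for c in cats:
            cat_set.setdefault(c, []).append(obj)
    for c, objs in cat_set.items():
        mask = pres["object"].isin(objs).to_numpy()
        if not mask.any():
            raise ValueError(f"category {c!r} has no presentations")
        categories.append(c)
        masks.append(mask)
    n_cells = mat.shape[0]
    out = np.zeros((n_cells, len(categories)))
    # P(r): histogram over all presentations, per cell
    pr_all = np.stack([
        np.bincount(binned[i], minlength=n_bins) for i in range(n_cells)
    ]).astype(float)
    pr_all /= pr_all.sum(axis=1, keepdims=True)
    for ci, mask in enumerate(masks):
        sub = binned[:, mask]
        pr_s = np.stack([
            np.bincount(sub[i], minlength=n_bins) for i in range(n_cells)
        ]).astype(float)
        pr_s /= pr_s.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pr_s * np.log2(pr_s / pr_all)
        out[:, ci] = np.nansum(np.where(pr_s > 0, term, 0.0), axis=1)
    return InfoResult(cells, categories, out, n_bins)


# ---------------------------------------------------------------------------
# selectivity counting

def _element_masks(pres: pd.DataFrame,
                   membership: Callable[[object], Iterable],
                   elements: Sequence | None) -> tuple[list, list[np.ndarray]]:
    obj_cats = {obj: set(membership(obj)) for obj in pres["object"].unique()}
    if elements is None:
        elements = sorted({e for cats in obj_cats.values() for e in cats})
    masks = []
    for e in elements:
        objs = [o for o, cats in obj_cats.items() if e in cats]
        masks.append(pres["object"].isin(objs).to_numpy())
    return list(elements), masks


def selective_cell_matrix(table: ResponseTable,
                          membership: Callable[[object], Iterable],
                          elements: Sequence | None = None,
                          hi: float = SELECTIVE_HI,
                          lo: float = SELECTIVE_LO) -> tuple[np.ndarray, list, np.ndarray]:
    """Boolean (cells x elements) selectivity matrix.

    A cell is selective for element e iff its rate is >= ``hi`` for every
    presentation of an object containing e and < ``lo`` for every
    presentation of an object lacking e — across all tested locations and
    orientations.
    """
    mat, cells, pres = responses_to_matrix(table)
    elements, masks = _element_masks(pres, membership, elements)
    sel = np.zeros((mat.shape[0], len(elements)), dtype=bool)
    for ei, mask in enumerate(masks):
        pos_ok = (mat[:, mask] >= hi).all(axis=1)
        neg_ok = (mat[:, ~mask] < lo).all(axis=1)
        sel[:, ei] = pos_ok & neg_ok
    return sel, elements, cells


def count_selective_cells(table: ResponseTable,
                          membership: Callable[[object], Iterable],
                          elements: Sequence | None = None,
                          hi: float = SELECTIVE_HI,
                          lo: float = SELECTIVE_LO) -> dict:
    """Number of cells meeting the strict selectivity criterion, per element."""
    sel, elements, _ = selective_cell_matrix(table, membership, elements, hi, lo)
    return {e: int(sel[:, i].sum()) for i, e in enumerate(elements)}


# ---------------------------------------------------------------------------
# receptive-field backtracing

def backtrace_receptive_field(network, cell: int, layer: int | None = None,
                              top_fraction: float | None = None) -> np.ndarray:
    """Effective input-filter weights of one cell via feed-forward products.

    The effective weight of input filter f is the sum over all feed-forward
    paths from f to the cell of the product of the path's synaptic weights.
    Returns an array shaped like the Gabor activation (retina_y, retina_x,
    n_kernels).  With ``top_fraction`` only that fraction of the largest
    weights is kept (the rest zeroed), for overlay plots.
    """
    if layer is None:
        layer = network.n_layers - 1
    n_cells = network.layer_configs[layer].n_neurons
    if not 0 <= cell < n_cells:
        raise ValueError(f"cell {cell} out of range for layer {layer + 1}")
    vec = np.zeros(n_cells)
    vec[cell] = 1.0
    for l in range(layer, -1, -1):
        smap = network.maps[l]
        pre = np.zeros(int(np.prod(smap.pre_shape)))
        np.add.at(pre, smap.indices.ravel(),
                  (smap.weights * vec[:, None]).ravel())
        vec = pre
    shape = (network.bank.retina_size, network.bank.retina_size,
             network.bank.n_kernels)
    eff = vec.reshape(shape)
    if top_fraction is not None:
        thresh = np.quantile(eff, 1.0 - top_fraction)
        eff = np.where(eff >= thresh, eff, 0.0)
    return eff


# ---------------------------------------------------------------------------
# boundary segmentation

@dataclass(frozen=True)
class BoundarySegment:
    curvature: float        # mean signed curvature (1/px; >0 convex outward)
    angle_deg: float        # angular position of the segment midpoint, CCW from right
    arc_length: float


def _closed_resample(contour: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an (N, 2) array with N >= 3")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    closing = np.linalg.norm(pts[0] - pts[-1])
    if closing > 10.0 * max(np.median(seg), 1e-9):
        raise ValueError("open contour: endpoints do not meet")
    loop = np.vstack([pts, pts[:1]])
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(loop, axis=0), axis=1))])
    total = s[-1]
    u = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(u, s, loop[:, 0])
    y = np.interp(u, s, loop[:, 1])
    return np.stack([x, y], axis=1), total / n


def _curvature(pts: np.ndarray, ds: float, smooth: float) -> np.ndarray:
    x = gaussian_filter1d(pts[:, 0], smooth, mode="wrap")
    y = gaussian_filter1d(pts[:, 1], smooth, mode="wrap")
    dx = (np.roll(x, -1) - np.roll(x, 1)) / (2 * ds)
    dy = (np.roll(y, -1) - np.roll(y, 1)) / (2 * ds)
    ddx = (np.roll(x, -1) - 2 * x + np.roll(x, 1)) / ds**2
    ddy = (np.roll(y, -1) - 2 * y + np.roll(y, 1)) / ds**2
    denom = np.maximum((dx**2 + dy**2) ** 1.5, 1e-12)
    return (dx * ddy - dy * ddx) / denom


def _circular_close(mask: np.ndarray, width: int) -> np.ndarray:
    """Binary closing on a circular boolean array (merges nearby runs)."""
    dil = mask.copy()
    for s in range(1, width + 1):
        dil |= np.roll(mask, s) | np.roll(mask, -s)
    ero = dil.copy()
    for s in range(1, width + 1):
        ero &= np.roll(dil, s) & np.roll(dil, -s)
    return ero


def segment_boundary(contour: np.ndarray, threshold: float | None = None,
                     n_resample: int = 720, smooth: float = 4.0,
                     min_floor: float = 1e-3) -> list[BoundarySegment]:
    """Split a closed contour into elements where curvature changes abruptly.

    The contour (math coords, CCW) is resampled at uniform arc length;
    cut points are the centers of runs where |d kappa / ds| exceeds the
    threshold.  Each resulting segment is summarized by its mean curvature
    and the angular position of its midpoint relative to the contour
    centroid (degrees CCW from "right"; "top" is 90).  With ``threshold``
    None, half of the maximum |d kappa / ds| is used, unless that maximum is
    below ``min_floor`` (an effectively constant-curvature contour such as a
    circle), in which case the whole boundary is one segment.
    """
    pts, ds = _closed_resample(contour, n_resample)
    kappa = _curvature(pts, ds, smooth)
    dk = np.abs(np.roll(kappa, -1) - np.roll(kappa, 1)) / (2 * ds)
    close_w = max(2, int(round(smooth)))
    if threshold is None:
        # corners sit orders of magnitude above the arc-interior derivative,
        # so a small fraction of the maximum separates them robustly while a
        # constant-curvature contour (max below the floor) yields no cuts
        mx = float(dk.max())
        if mx < min_floor:
            cuts = np.array([], dtype=int)
        else:
            cuts = _run_centers(_circular_close(dk > 0.05 * mx, close_w))
    else:
        cuts = _run_centers(_circular_close(dk > threshold, close_w))
    centroid = pts.mean(axis=0)
    n = len(pts)
    if cuts.size == 0:
        mid = pts.mean(axis=0)  # degenerate: report whole-contour summary
        ang = np.degrees(np.arctan2(pts[0, 1] - centroid[1],
                                    pts[0, 0] - centroid[0])) % 360
        return [BoundarySegment(float(kappa.mean()), float(ang), n * ds)]
    segments = []
    cuts = np.sort(cuts)
    trim_max = int(round(2 * smooth))
    for a, b in zip(cuts, np.roll(cuts, -1)):
        length = (b - a) % n
        if length == 0:
            length = n
        idx = (a + np.arange(length)) % n
        mid_i = idx[length // 2]
        ang = np.degrees(np.arctan2(pts[mid_i, 1] - centroid[1],
                                    pts[mid_i, 0] - centroid[0])) % 360
        # corner transition zones bleed smoothed curvature into the segment;
        # average over the interior only
        trim = min(trim_max, (length - 1) // 3)
        core = idx[trim:length - trim] if length - 2 * trim >= 1 else idx
        segments.append(BoundarySegment(float(kappa[core].mean()), float(ang),
                                        length * ds))
    return segments


def _run_centers(mask: np.ndarray) -> np.ndarray:
    """Centers of circular runs of True in a boolean array."""
    n = len(mask)
    if mask.all():
        return np.array([0])
    if not mask.any():
        return np.array([], dtype=int)
    # rotate so position 0 is False, find runs linearly
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    d = np.diff(rolled.astype(int))
    run_starts = np.where(d == 1)[0] + 1
    run_ends = np.where(d == -1)[0] + 1
    if len(run_ends) < len(run_starts):
        run_ends = np.append(run_ends, n)
    centers = ((run_starts + run_ends - 1) // 2 + start) % n
    return centers


def calibrate_segmentation_threshold(contour: np.ndarray, n_expected: int,
                                     n_resample: int = 720,
                                     smooth: float = 4.0) -> float:
    """Threshold on |d kappa/ds| that splits a calibration shape into
    exactly ``n_expected`` segments (bisection over observed values)."""
    pts, ds = _closed_resample(contour, n_resample)
    kappa = _curvature(pts, ds, smooth)
    dk = np.abs(np.roll(kappa, -1) - np.roll(kappa, 1)) / (2 * ds)
    lo, hi = float(dk.min()), float(dk.max())
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        n_seg = len(segment_boundary(contour, threshold=mid,
                                     n_resample=n_resample, smooth=smooth))
        if n_seg > n_expected:
            lo = mid
        elif n_seg < n_expected:
            hi = mid
        else:
            return mid
    raise ValueError(
        f"could not find a threshold yielding {n_expected} segments"
    )


# ---------------------------------------------------------------------------
# tuning heatmaps

@dataclass
class TuningHeatmap:
    """Mean response per (curvature bin x angular-position bin).

    Bins never observed are NaN in ``mean`` (flagged via ``counts == 0``),
    not zero-filled.
    """

    mean: np.ndarray        # (n_curv, n_angle)
    counts: np.ndarray
    curv_edges: np.ndarray
    angle_edges: np.ndarray


def tuning_heatmap(presentations: Sequence[tuple[float, Sequence[BoundarySegment]]],
                   angle_bins: int = 16, curvature_bins: int = 8,
                   curvature_range: tuple[float, float] | None = None) -> TuningHeatmap:
    """Average one cell's rate over (curvature, angular position) bins.

    ``presentations`` pairs the cell's firing rate on a presentation with the
    boundary segments of that presentation's stimulus.  Angular bins cover
    the full 0-360 range; the curvature range defaults to the observed span.
    """
    all_k = [seg.curvature for _, segs in presentations for seg in segs]
    if not all_k:
        raise ValueError("no boundary segments supplied")
    if curvature_range is None:
        lo, hi = min(all_k), max(all_k)
        pad = 1e-9 + 0.001 * (hi - lo)
        curvature_range = (lo - pad, hi + pad)
    curv_edges = np.linspace(*curvature_range, curvature_bins + 1)
    angle_edges = np.linspace(0.0, 360.0, angle_bins + 1)
    total = np.zeros((curvature_bins, angle_bins))
    counts = np.zeros((curvature_bins, angle_bins), dtype=int)
    for rate, segs in presentations:
        for seg in segs:
            ci = np.clip(np.searchsorted(curv_edges, seg.curvature, side="right") - 1,
                         0, curvature_bins - 1)
            ai = int(seg.angle_deg % 360.0 // (360.0 / angle_bins))
            total[ci, ai] += rate
            counts[ci, ai] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return TuningHeatmap(mean, counts, curv_edges, angle_edges)


def count_heatmap_peaks(heatmap: TuningHeatmap, fraction: float = 0.6) -> int:
    """Local maxima above ``fraction`` of the heatmap's mean rate.

    8-neighborhood on the (curvature x angle) grid with the angle axis
    circular; a plateau of equal values counts as one peak, and only if it
    is strictly higher than everything adjacent (so a flat map has none).
    Unobserved bins are ignored.
    """
    m = heatmap.mean
    valid = heatmap.counts > 0
    if not valid.any():
        raise ValueError("heatmap has no observed bins")
    ref = fraction * float(np.nanmean(m[valid]))
    nc, na = m.shape
    visited = np.zeros_like(valid, dtype=bool)
    peaks = 0
    for c in range(nc):
        for a in range(na):
            if not valid[c, a] or visited[c, a]:
                continue
            # flood-fill the equal-value plateau containing (c, a)
            val = m[c, a]
            stack = [(c, a)]
            plateau = []
            visited[c, a] = True
            is_peak = val > ref
            has_lower_neighbor = False
            while stack:
                cc, aa = stack.pop()
                plateau.append((cc, aa))
                for dc in (-1, 0, 1):
                    for da in (-1, 0, 1):
                        if dc == 0 and da == 0:
                            continue
                        c2 = cc + dc
                        a2 = (aa + da) % na
                        if not 0 <= c2 < nc or not valid[c2, a2]:
                            continue
                        v2 = m[c2, a2]
                        if v2 == val:
                            if not visited[c2, a2]:
                                visited[c2, a2] = True
                                stack.append((c2, a2))
                        elif v2 > val:
                            is_peak = False
                        else:
                            has_lower_neighbor = True
            if is_peak and has_lower_neighbor:
                peaks += 1
    return peaks


def v4_model_correlation(heatmap: TuningHeatmap, preferred_curvature: float,
                         preferred_angle_deg: float,
                         widths: tuple[float, float] = (0.1, 45.0)) -> float:
    """Pearson correlation with an idealized Gaussian-tuned cell.

    The model surface is a 2-D Gaussian over (curvature, angular position)
    centered on the preferred values, with the angular difference wrapped to
    [-180, 180].  Correlation is computed over observed bins only.
    """
    curv_c = 0.5 * (heatmap.curv_edges[:-1] + heatmap.curv_edges[1:])
    ang_c = 0.5 * (heatmap.angle_edges[:-1] + heatmap.angle_edges[1:])
    dk = (curv_c[:, None] - preferred_curvature) / widths[0]
    da = (ang_c[None, :] - preferred_angle_deg + 180.0) % 360.0 - 180.0
    da = da / widths[1]
    model = np.exp(-0.5 * (dk**2 + da**2))
    mask = heatmap.counts > 0
    obs = heatmap.mean[mask]
    mod = model[mask]
    if obs.std() == 0 or mod.std() == 0:
        raise ValueError("correlation undefined: zero-variance heatmap")
    return float(np.corrcoef(obs, mod)[0, 1])


# ---------------------------------------------------------------------------
# feature maps

def feature_map(info: InfoResult, layer_dims: tuple[int, int],
                tol: float = 1e-9, n_permutations: int = 200,
                seed: int = 0) -> dict:
    """Grid locations of the cells at maximal information, per element.

    For each category, returns the coordinates of the cells whose
    information is within ``tol`` of the category maximum, the mean pairwise
    grid distance of those cells (clustering score), and a permutation null
    (the same count of cells placed uniformly at random).  A score below the
    null mean indicates spatial clustering, the signature of map-like
    (SOM-style) organization.  Categories with zero maximal information are
    returned empty and flagged.
    """
    H, W = layer_dims
    rng = np.random.default_rng(seed)
    out = {}
    for ci, cat in enumerate(info.categories):
        vals = info.per_category[:, ci]
        mx = vals.max()
        if mx <= 0:
            out[cat] = {"coords": np.empty((0, 2), dtype=int), "score": np.nan,
                        "null_mean": np.nan, "empty": True}
            continue
        idx = np.where(vals >= mx - tol)[0]
        coords = np.stack([idx // W, idx % W], axis=1)
        score = _mean_pairwise(coords.astype(float))
        nulls = []
        for _ in range(n_permutations):
            ridx = rng.choice(H * W, size=len(idx), replace=False)
            rc = np.stack([ridx // W, ridx % W], axis=1).astype(float)
            nulls.append(_mean_pairwise(rc))
        out[cat] = {"coords": coords, "score": score,
                    "null_mean": float(np.mean(nulls)), "empty": False}
    return out


def _mean_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d**2).sum(axis=2))
    n = len(coords)
    return float(dist.sum() / (n * (n - 1)))
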