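"""Cortex geometry: pial boundary, depth from the pial surface, artificial
layers, edge/inner splits, and rasterization of point detections.

Depth is the Euclidean distance (μm) from a raster cell to the nearest
pial-boundary cell.  The pial boundary is the set of in-cortex cells
4-adjacent to out-of-mask background; interior holes count as pial
(sulci are lined by leptomeninges), and cells on the raster border with
no background neighbour inside the image are not boundary — the deep
(white-matter) side of a cortical ribbon should therefore touch the
raster edge or be handled by the caller's mask conventions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import CountMatrix, GridSpec


def pial_boundary(cortex_mask: np.ndarray) -> np.ndarray:
    """Boolean raster of pial-boundary cells.

    A cell is boundary iff it is in-cortex and at least one of its four
    edge neighbours (within the image) is background.
    """
    mask = np.asarray(cortex_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cortex mask is empty")
    bg = ~mask
    near_bg = np.zeros_like(mask)
    near_bg[1:, :] |= bg[:-1, :]
    near_bg[:-1, :] |= bg[1:, :]
    near_bg[:, 1:] |= bg[:, :-1]
    near_bg[:, :-1] |= bg[:, 1:]
    boundary = mask & near_bg
    if not boundary.any():
        raise ValueError("mask has no background-adjacent cells; pial surface undefined")
    return boundary


def depth_map(cortex_mask: np.ndarray, resolution_um: float) -> np.ndarray:
    """Per-cell depth (μm) from the pial boundary; NaN outside the cortex.

    Boundary cells have depth 0.  Distances are straight-line (not
    geodesic within the mask); see :func:`geodesic_depth_map` for the
    within-mask alternative.
    """
    if resolution_um <= 0:
        raise ValueError("resolution must be positive")
    mask = np.asarray(cortex_mask, dtype=bool)
    boundary = pial_boundary(mask)
    depth = ndimage.distance_transform_edt(~boundary) * float(resolution_um)
    depth = np.where(mask, depth, np.nan)
    return depth


def geodesic_depth_map(cortex_mask: np.ndarray, resolution_um: float) -> np.ndarray:
    """Depth measured along paths inside the mask (chamfer approximation).

    Optional alternative to the straight-line default; differs only for
    strongly folded masks where the straight line leaves the tissue.
    """
    if resolution_um <= 0:
        raise ValueError("resolution must be positive")
    mask = np.asarray(cortex_mask, dtype=bool)
    boundary = pial_boundary(mask)
    depth = np.full(mask.shape, np.inf)
    depth[boundary] = 0.0
    # iterative chamfer sweeps restricted to the mask
    w1, w2 = 1.0, np.sqrt(2.0)
    offsets_fwd = [(-1, -1, w2), (-1, 0, w1), (-1, 1, w2), (0, -1, w1)]
    for _ in range(mask.shape[0] + mask.shape[1]):
        changed = False
        for sweep in (offsets_fwd, [(-di, -dj, w) for di, dj, w in offsets_fwd]):
            it = (
                range(mask.shape[0])
                if sweep is offsets_fwd
                else range(mask.shape[0] - 1, -1, -1)
            )
            for i in it:
                row = depth[i]
                for di, dj, w in sweep:
                    ni = i + di
                    if ni < 0 or ni >= mask.shape[0]:
                        continue
                    if dj == 0:
                        cand = depth[ni] + w
                    elif dj < 0:
                        cand = np.full_like(row, np.inf)
                        cand[1:] = depth[ni][:-1] + w
                    else:
                        cand = np.full_like(row, np.inf)
                        cand[:-1] = depth[ni][1:] + w
                    better = mask[i] & (cand < row)
                    if better.any():
                        row[better] = cand[better]
                        changed = True
        if not changed:
            break
    depth = depth * float(resolution_um)
    return np.where(mask, depth, np.nan)


def make_layer_masks(
    cortex_mask: np.ndarray,
    resolution_um: float,
    thickness_um: float = 1000.0,
    n_layers: int = 5,
    geodesic: bool = False,
) -> list[np.ndarray]:
    """Partition the cortex into depth bands ("artificial layers").

    Layer k (1-based) is the set of in-cortex cells with depth in
    ``[(k-1)*thickness, k*thickness)``.  Cells deeper than
    ``n_layers*thickness`` are left unassigned.
    """
    if thickness_um <= 0:
        raise ValueError("layer thickness must be positive")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    dm = geodesic_depth_map(cortex_mask, resolution_um) if geodesic else depth_map(
        cortex_mask, resolution_um
    )
    layers = []
    for k in range(1, n_layers + 1):
        lo, hi = (k - 1) * thickness_um, k * thickness_um
        with np.errstate(invalid="ignore"):
            layers.append((dm >= lo) & (dm < hi))
    return layers


def split_edge_inner(
    cortex_mask: np.ndarray, resolution_um: float, depth_um: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split the cortex into the outermost band and everything deeper.

    Returns ``(edge, inner)``: disjoint masks whose union is the cortex.
    """
    if depth_um <= 0:
        raise ValueError("edge depth must be positive")
    mask = np.asarray(cortex_mask, dtype=bool)
    dm = depth_map(mask, resolution_um)
    with np.errstate(invalid="ignore"):
        edge = mask & (dm < depth_um)
    inner = mask & ~edge
    return edge, inner


def rasterize_objects(
    objects: np.ndarray, grid: GridSpec
) -> tuple[CountMatrix, int]:
    """Bin point detections onto a grid; each point adds 1 to its cell.

    Cells are half-open, so a point exactly on an interior cell edge
    belongs to the cell to its right/below.  Returns the count matrix and
    the number of points falling outside the grid.
    """
    pts = np.asarray(objects, dtype=float).reshape(-1, 2)
    counts = np.zeros(grid.shape, dtype=float)
    if pts.shape[0] == 0:
        return CountMatrix(counts, grid), 0
    i, j = grid.cell_of(pts[:, 0], pts[:, 1])
    inside = (i >= 0) & (i < grid.n_rows) & (j >= 0) & (j < grid.n_cols)
    np.add.at(counts, (i[inside], j[inside]), 1.0)
    return CountMatrix(counts, grid), int((~inside).sum())


def mask_grid(cortex_mask: np.ndarray, resolution_um: float) -> GridSpec:
    """The grid of the mask raster itself (origin at its top-left corner)."""
    mask = np.asarray(cortex_mask, dtype=bool)
    return GridSpec(0.0, 0.0, float(resolution_um), mask.shape[0], mask.shape[1])
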