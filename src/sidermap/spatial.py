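"""Layer density profiles, heat-map binning with pixel validity, iron
burden categorization, and category density profiles.

The heat map divides the cortex into square "pixels" (500 μm by default;
250 μm for the edge-only reanalysis).  A pixel is valid when at least one
third of its area lies inside the cortex — i.e. pixels with more than two
thirds of their area outside the cortex are excluded.  Counts are kept
for every pixel so that totals are conserved; profiles and models use
valid pixels only.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import make_layer_masks, mask_grid, rasterize_objects
from .types import GridSpec, HeatMap, LayerProfile, SectionDetections

IRON_CATEGORIES = ("very_low", "low", "medium", "high")
#: Lower bound of each category on integer object counts: 0–5, 6–15, 16–25, 26+.
IRON_CATEGORY_LOWER = (0, 6, 16, 26)


def layer_densities(
    section: SectionDetections,
    layers: Optional[Sequence[np.ndarray]] = None,
    thickness_um: float = 1000.0,
    n_layers: int = 5,
    counts: Optional[np.ndarray] = None,
) -> LayerProfile:
    """Per-layer object densities (objects/mm²) for one section.

    Counts objects whose containing mask cell lies in each layer; a layer
    with zero area (cortex shallower than the band) is missing (NaN), not
    zero.  ``counts`` may supply a pre-warped count matrix on the mask
    grid (e.g. a co-registered marker section); otherwise the section's
    own detections are binned.
    """
    res = section.mask_resolution_um
    if layers is None:
        layers = make_layer_masks(section.cortex_mask, res, thickness_um, n_layers)
    if counts is None:
        cm, _ = rasterize_objects(section.objects, mask_grid(section.cortex_mask, res))
        counts = cm.values
    cell_mm2 = res**2 / 1e6
    dens = np.full(len(layers), np.nan)
    areas = np.zeros(len(layers))
    tallies = np.zeros(len(layers))
    for k, lm in enumerate(layers):
        area = float(lm.sum()) * cell_mm2
        areas[k] = area
        if area > 0:
            tallies[k] = float(counts[lm].sum())
            dens[k] = tallies[k] / area
        else:
            tallies[k] = np.nan
    return LayerProfile(section.case_id, section.region, section.stain, dens, areas, tallies)


def heatmap_grid(
    cortex_mask: np.ndarray,
    resolution_um: float,
    pixel_size_um: float,
    offset_um: tuple[float, float] = (0.0, 0.0),
) -> GridSpec:
    """Heat-map grid anchored at the mask bounding box's top-left corner.

    ``offset_um`` shifts the grid phase (for sensitivity checks); the
    grid is extended so it still covers the whole bounding box.
    """
    ratio = pixel_size_um / resolution_um
    if pixel_size_um <= 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            "pixel size must be a positive integer multiple of the mask resolution"
        )
    for o in offset_um:
        if abs(o / resolution_um - round(o / resolution_um)) > 1e-9:
            raise ValueError("grid offset must be a whole number of mask cells")
    mask = np.asarray(cortex_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("cortex mask is empty")
    x0 = cols.min() * resolution_um + offset_um[0]
    y0 = rows.min() * resolution_um + offset_um[1]
    x1 = (cols.max() + 1) * resolution_um
    y1 = (rows.max() + 1) * resolution_um
    while x0 > cols.min() * resolution_um:
        x0 -= pixel_size_um
    while y0 > rows.min() * resolution_um:
        y0 -= pixel_size_um
    n_cols = int(np.ceil((x1 - x0) / pixel_size_um - 1e-9))
    n_rows = int(np.ceil((y1 - y0) / pixel_size_um - 1e-9))
    return GridSpec(x0, y0, float(pixel_size_um), n_rows, n_cols)


def pixel_cortex_fraction(
    cortex_mask: np.ndarray, resolution_um: float, grid: GridSpec
) -> np.ndarray:
    """Fraction of each heat-map pixel's area lying inside the cortex."""
    mask = np.asarray(cortex_mask, dtype=float)
    ratio = int(round(grid.cell_size_um / resolution_um))
    # index of the heat-map pixel containing each mask cell
    r_idx = np.floor(
        (np.arange(mask.shape[0]) * resolution_um - grid.origin_y) / grid.cell_size_um
    ).astype(int)
    c_idx = np.floor(
        (np.arange(mask.shape[1]) * resolution_um - grid.origin_x) / grid.cell_size_um
    ).astype(int)
    frac = np.zeros(grid.shape)
    ok_r = (r_idx >= 0) & (r_idx < grid.n_rows)
    ok_c = (c_idx >= 0) & (c_idx < grid.n_cols)
    sub = mask[np.ix_(ok_r, ok_c)]
    np.add.at(frac, (r_idx[ok_r][:, None], c_idx[ok_c][None, :]), sub)
    return frac / ratio**2


def bin_heatmap(
    section: SectionDetections,
    pixel_size_um: float = 500.0,
    offset_um: tuple[float, float] = (0.0, 0.0),
    min_cortex_fraction: float = 1.0 / 3.0,
    restrict_mask: Optional[np.ndarray] = None,
    counts: Optional[np.ndarray] = None,
) -> HeatMap:
    """Bin a section's detections into a validity-masked heat map.

    ``restrict_mask`` limits the analysis to a sub-region of the cortex
    (e.g. the outermost 1000 μm band or its complement); validity is then
    judged against that sub-mask.  ``counts`` may supply a pre-warped
    count matrix on the mask grid instead of the section's own points.
    """
    res = section.mask_resolution_um
    mask = section.cortex_mask if restrict_mask is None else np.asarray(restrict_mask, bool)
    grid = heatmap_grid(mask, res, pixel_size_um, offset_um)
    frac = pixel_cortex_fraction(mask, res, grid)
    valid = frac >= min_cortex_fraction
    if counts is None:
        if restrict_mask is None:
            cm, n_out = rasterize_objects(section.objects, grid)
            pix = cm.values
        else:
            # bin at mask resolution first so objects in cells outside the
            # restricted region are dropped, keeping edge + inner = whole
            cm_fine, n_out = rasterize_objects(
                section.objects, mask_grid(mask, res)
            )
            cm_fine.values[~mask] = 0.0
            pix = _aggregate_to_grid(cm_fine.values, res, grid)
    else:
        counts = np.asarray(counts, dtype=float)
        if counts.shape != mask.shape:
            raise ValueError("count matrix must live on the mask raster")
        fine = counts.copy()
        if restrict_mask is not None:
            fine[~mask] = 0.0
        pix = _aggregate_to_grid(fine, res, grid)
        n_out = 0
    return HeatMap(pix, valid, grid, section.case_id, section.region, section.stain, n_out)


def _aggregate_to_grid(values: np.ndarray, resolution_um: float, grid: GridSpec) -> np.ndarray:
    """Sum a mask-resolution matrix into heat-map pixels."""
    out = np.zeros(grid.shape)
    r_idx = np.floor(
        (np.arange(values.shape[0]) * resolution_um - grid.origin_y) / grid.cell_size_um
    ).astype(int)
    c_idx = np.floor(
        (np.arange(values.shape[1]) * resolution_um - grid.origin_x) / grid.cell_size_um
    ).astype(int)
    ok_r = (r_idx >= 0) & (r_idx < grid.n_rows)
    ok_c = (c_idx >= 0) & (c_idx < grid.n_cols)
    np.add.at(out, (r_idx[ok_r][:, None], c_idx[ok_c][None, :]), values[np.ix_(ok_r, ok_c)])
    return out


def categorize_iron(
    count, boundaries: Sequence[int] = IRON_CATEGORY_LOWER
) -> np.ndarray:
    """Iron burden category index (0=very_low .. 3=high) per pixel count.

    Real-valued (warped) counts are rounded half-up to an integer before
    categorization, since the categories are defined on object counts.
    """
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("iron counts must be non-negative")
    ints = np.floor(arr + 0.5)
    cat = np.zeros(ints.shape, dtype=int)
    for k, lo in enumerate(boundaries):
        cat[ints >= lo] = k
    return cat if cat.shape else cat[()]


def scaled_category_boundaries(pixel_size_um: float, base_um: float = 500.0) -> tuple[int, ...]:
    """Category boundaries rescaled by pixel area (e.g. ÷4 at 250 μm).

    Alternative mode for the edge reanalysis; the default keeps the
    original integer boundaries at every pixel size.
    """
    scale = (pixel_size_um / base_um) ** 2
    # half-up rounding, consistent with count rounding elsewhere
    return tuple(max(0, int(np.floor(lo * scale + 0.5))) for lo in IRON_CATEGORY_LOWER)


def category_profile(
    pairs: Iterable[tuple[HeatMap, HeatMap]],
    grouping: str = "brain",
    boundaries: Sequence[int] = IRON_CATEGORY_LOWER,
) -> pd.DataFrame:
    """Mean marker cells/pixel per iron category, per brain or per section.

    ``pairs`` yields co-registered (iron, marker) heat maps on identical
    grids.  Pixels valid in both maps are pooled within each group and
    averaged per category; categories with zero pixels in a group are
    absent from the table (missing, not zero), which downstream feeds the
    incomplete-block rank test.
    """
    if grouping not in ("brain", "section"):
        raise ValueError("grouping must be 'brain' or 'section'")
    rows = []
    for iron, marker in pairs:
        if not iron.same_grid(marker):
            raise ValueError(
                f"grid mismatch between iron and marker maps for section "
                f"{(iron.case_id, iron.region)}"
            )
        both = iron.valid & marker.valid
        cats = categorize_iron(iron.counts[both], boundaries)
        vals = marker.counts[both]
        for c, v in zip(cats, vals):
            rows.append((iron.case_id, iron.region, marker.stain, int(c), float(v)))
    df = pd.DataFrame(rows, columns=["case_id", "region", "stain", "category", "count"])
    keys = ["case_id"] if grouping == "brain" else ["case_id", "region"]
    out = (
        df.groupby(keys + ["stain", "category"], as_index=False)
        .agg(mean_count=("count", "mean"), n_pixels=("count", "size"))
    )
    out["category_label"] = out["category"].map(dict(enumerate(IRON_CATEGORIES)))
    return out


def category_design(profile: pd.DataFrame, n_categories: int = 4) -> pd.DataFrame:
    """Pivot a brain-level category profile into a block design matrix.

    Rows = brains (blocks), columns = iron categories (treatments);
    missing cells stay NaN for the incomplete-block test.
    """
    wide = profile.pivot_table(
        index="case_id", columns="category", values="mean_count", aggfunc="mean"
    )
    wide = wide.reindex(columns=range(n_categories))
    wide.columns = [IRON_CATEGORIES[c] for c in wide.columns]
    return wide


def lobe_summary(sections: Iterable[SectionDetections]) -> pd.DataFrame:
    """Whole-section object density per brain × region × stain.

    Density = detected objects / cortex area (objects/mm²), averaged
    within brain × region when several sections exist.
    """
    rows = []
    for s in sections:
        area = s.cortex_area_mm2()
        if area <= 0:
            continue
        rows.append((s.case_id, s.region, s.stain, s.n_objects / area))
    df = pd.DataFrame(rows, columns=["case_id", "region", "stain", "density"])
    return df.groupby(["case_id", "region", "stain"], as_index=False).agg(
        density=("density", "mean")
    )


def lobe_design(summary: pd.DataFrame, stain: str) -> pd.DataFrame:
    """Blocks = brains, treatments = cortical lobes for one stain."""
    sub = summary[summary["stain"] == stain]
    wide = sub.pivot_table(index="case_id", columns="region", values="density")
    order = [r for r in ("frontal", "temporal", "parietal", "occipital") if r in wide.columns]
    return wide[order]
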