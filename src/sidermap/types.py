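"""Shared domain containers for the section-analysis pipeline.

All coordinates are in micrometres (μm), with the origin at the top-left
corner of the section's mask raster, x increasing rightward (columns) and
y increasing downward (rows).  Every module in the package shares this
frame, so warps, layer masks and heat-map grids compose without per-stage
coordinate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

REGIONS = ("frontal", "temporal", "parietal", "occipital")
STAINS = ("iron", "GFAP", "CD68")
GROUPS = ("cSS", "macrohemorrhage")

#: Exclusion reasons mirroring the bookkeeping of the source workflow.
EXCLUSION_REASONS = (
    "coregistration_failure",
    "poor_tissue_detection",
    "poor_object_detection",
)


@dataclass(frozen=True)
class GridSpec:
    """A raster grid in physical units.

    Cell ``(i, j)`` (row i, column j, 0-based) covers the half-open box
    ``x in [x0 + j*s, x0 + (j+1)*s)``, ``y in [y0 + i*s, y0 + (i+1)*s)``
    with ``s = cell_size_um``.
    """

    origin_x: float
    origin_y: float
    cell_size_um: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size_um <= 0:
            raise ValueError("cell size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive shape")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open cell indices of points; may fall outside the grid."""
        j = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size_um)
        i = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size_um)
        return i.astype(int), j.astype(int)


@dataclass
class SectionDetections:
    """One stained section's object detections plus its cortex mask."""

    case_id: str
    region: str
    stain: str
    objects: np.ndarray  # (N, 2) float array of (x_um, y_um)
    cortex_mask: np.ndarray  # 2-D bool raster
    mask_resolution_um: float
    group: str = "cSS"

    def __post_init__(self) -> None:
        self.objects = np.asarray(self.objects, dtype=float).reshape(-1, 2)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {STAINS}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.mask_resolution_um <= 0:
            raise ValueError("mask resolution must be positive")
        if self.objects.size and not np.all(np.isfinite(self.objects)):
            raise ValueError("object coordinates must be finite")
        if self.cortex_mask.ndim != 2:
            raise ValueError("cortex mask must be a 2-D raster")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.case_id, self.region, self.stain)

    @property
    def n_objects(self) -> int:
        return int(self.objects.shape[0])

    @property
    def mask_usable(self) -> bool:
        return bool(self.cortex_mask.any())

    def cortex_area_mm2(self) -> float:
        return float(self.cortex_mask.sum()) * self.mask_resolution_um**2 / 1e6


@dataclass
class ExclusionRecord:
    case_id: str
    region: str
    stain: str
    reason: str
    stage: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(
                f"unknown exclusion reason {self.reason!r}; expected one of {EXCLUSION_REASONS}"
            )


class ExclusionLog:
    """Per-analysis exclusion bookkeeping.

    Each excluded section appears exactly once per analysis stage, so
    (sections in) = (sections analyzed) + (sections excluded) always holds.
    """

    def __init__(self) -> None:
        self.records: list[ExclusionRecord] = []

    def exclude(self, case_id: str, region: str, stain: str, reason: str, stage: str) -> None:
        key = (case_id, region, stain, stage)
        if any((r.case_id, r.region, r.stain, r.stage) == key for r in self.records):
            raise ValueError(f"section {key[:3]} already excluded at stage {stage!r}")
        self.records.append(ExclusionRecord(case_id, region, stain, reason, stage))

    def excluded_keys(self, stage: Optional[str] = None) -> set[tuple[str, str, str]]:
        return {
            (r.case_id, r.region, r.stain)
            for r in self.records
            if stage is None or r.stage == stage
        }

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class HeatMap:
    """Gridded per-pixel object counts with a validity mask.

    ``counts`` covers every grid pixel; profile and model stages consume
    only pixels where ``valid`` is True (pixels with more than two thirds
    of their area outside the cortex are invalid).  Counts are integers
    for directly binned stains and non-negative reals after warping.
    """

    counts: np.ndarray
    valid: np.ndarray
    grid: GridSpec
    case_id: str = ""
    region: str = ""
    stain: str = ""
    n_outside_grid: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.counts.shape != self.valid.shape or self.counts.shape != self.grid.shape:
            raise ValueError("counts, validity and grid shapes must agree")
        if np.any(self.counts < 0):
            raise ValueError("heat-map counts must be non-negative")

    @property
    def pixel_size_um(self) -> float:
        return self.grid.cell_size_um

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def same_grid(self, other: "HeatMap") -> bool:
        g, h = self.grid, other.grid
        return (
            g.shape == h.shape
            and g.cell_size_um == h.cell_size_um
            and np.isclose(g.origin_x, h.origin_x)
            and np.isclose(g.origin_y, h.origin_y)
        )


@dataclass
class LayerProfile:
    """Object densities (objects/mm²) in 1000 μm depth bands, layers 1..5.

    Layers beyond the available cortical depth are NaN (missing), never 0:
    an absent layer is not an observed zero density.
    """

    case_id: str
    region: str
    stain: str
    densities: np.ndarray  # (n_layers,) objects per mm², NaN where missing
    areas_mm2: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_layers(self) -> int:
        return int(self.densities.shape[0])


@dataclass
class CountMatrix:
    """Dense raster of per-cell object mass (real after warping)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match grid")
        if np.any(self.values < -1e-9):
            raise ValueError("count mass must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())
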