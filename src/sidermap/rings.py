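"""Ring-coefficient model: predicting a marker heat map (GFAP or CD68)
from the iron heat map through weights on concentric square rings.

For every heat-map pixel, the iron count is summarized in the pixel
itself (ring 0) and in up to three 500 μm-thick rings around it: ring k
is the set of pixels at Chebyshev lattice distance k, i.e. the 8-, 16-
and 24-pixel shells.  Each ring value is the mean iron count over the
*valid* (in-cortex) pixels of the shell.  Ring values are put on the
marker's scale through

    s = median(marker counts, pixels with objects)
        / median(iron counts, pixels with objects)

and the model predicts

    predicted_pixel = C_pixel * d_pixel + C_ring1 * d_ring1 + ...

where d_k = s * (ring-k mean iron count) and the coefficients satisfy
C_pixel >= C_ring1 >= ... >= C_ringN >= 0 and sum exactly to 1.00 on a
0.01 grid.  The best combination is found by exhaustive search over the
grid, minimizing the mean absolute per-pixel difference to the actual
marker map.  The per-section "residual" rescales that error by the
median marker count over marker-containing pixels, making sections
comparable.

Coefficients are held as integer hundredths internally, so the simplex
constraints are exact and no floating-point drift can produce an
off-grid combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import HeatMap


@dataclass
class RingDensities:
    """Scaled per-pixel ring values for the fit set of one section.

    ``d`` has shape (n_fit_pixels, n_rings + 1); column 0 is the pixel
    itself.  ``pixel_index`` locates each fit pixel in the heat-map grid.
    """

    d: np.ndarray
    actual: np.ndarray
    pixel_index: np.ndarray  # (n_fit_pixels, 2) row/col
    scale: float
    ring_tallies: np.ndarray  # valid members per ring per pixel


@dataclass
class RingFitResult:
    case_id: str
    region: str
    stain: str
    n_rings: int
    coefficients: tuple[float, ...]
    coefficients_hundredths: tuple[int, ...]
    error: float
    residual: float
    n_pixels: int
    n_ties: int
    predicted: Optional[HeatMap] = None

    def to_record(self) -> dict:
        return {
            "case_id": self.case_id,
            "region": self.region,
            "stain": self.stain,
            "n_rings": self.n_rings,
            "coefficients": list(self.coefficients),
            "error": self.error,
            "residual": self.residual,
            "n_pixels": self.n_pixels,
            "n_ties": self.n_ties,
        }


class SectionSkipped(ValueError):
    """Raised when a section cannot enter the ring fit (degenerate maps)."""


def ring_offsets(k: int) -> np.ndarray:
    """Lattice offsets of the Chebyshev ring at distance k (8k cells, k>=1)."""
    if k == 0:
        return np.array([[0, 0]])
    offs = [
        (di, dj)
        for di in range(-k, k + 1)
        for dj in range(-k, k + 1)
        if max(abs(di), abs(dj)) == k
    ]
    return np.array(offs)


def ring_counts(
    heat: HeatMap, n_rings: int, euclidean: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Raw ring means and valid-member tallies for every grid pixel.

    Returns ``(means, tallies)`` of shape (n_rings + 1, n_rows, n_cols).
    Ring 0 is the pixel's own count (defined only where the pixel is
    valid).  A ring with zero valid members is NaN (undefined).  With
    ``euclidean=True`` shells are binned by rounded centre-to-centre
    Euclidean distance instead of Chebyshev distance.
    """
    if n_rings < 0:
        raise ValueError("n_rings must be non-negative")
    counts = heat.counts
    valid = heat.valid.astype(float)
    nr, nc = counts.shape
    means = np.full((n_rings + 1, nr, nc), np.nan)
    tallies = np.zeros((n_rings + 1, nr, nc))
    means[0] = np.where(heat.valid, counts, np.nan)
    tallies[0] = valid
    padded_c = np.zeros((nr + 2 * n_rings, nc + 2 * n_rings))
    padded_v = np.zeros_like(padded_c)
    if n_rings > 0:
        padded_c[n_rings : n_rings + nr, n_rings : n_rings + nc] = counts * valid
        padded_v[n_rings : n_rings + nr, n_rings : n_rings + nc] = valid
    for k in range(1, n_rings + 1):
        if euclidean:
            offs = _euclidean_ring_offsets(k, n_rings)
        else:
            offs = ring_offsets(k)
        num = np.zeros((nr, nc))
        den = np.zeros((nr, nc))
        for di, dj in offs:
            num += padded_c[n_rings + di : n_rings + di + nr, n_rings + dj : n_rings + dj + nc]
            den += padded_v[n_rings + di : n_rings + di + nr, n_rings + dj : n_rings + dj + nc]
        with np.errstate(invalid="ignore", divide="ignore"):
            means[k] = np.where(den > 0, num / den, np.nan)
        tallies[k] = den
    return means, tallies


def _euclidean_ring_offsets(k: int, n_rings: int) -> np.ndarray:
    offs = [
        (di, dj)
        for di in range(-n_rings - 1, n_rings + 2)
        for dj in range(-n_rings - 1, n_rings + 2)
        if (di, dj) != (0, 0) and int(round(np.hypot(di, dj))) == k
    ]
    return np.array(offs)


def scale_factor(marker: HeatMap, iron: HeatMap) -> float:
    """Median-based factor putting iron counts on the marker's scale.

    Medians are taken over valid pixels holding at least one object
    (count >= 1; warped real-valued counts below one are "no objects"),
    separately in each map.  Sections where either map has no such pixel
    cannot be scaled and are skipped.
    """
    m = marker.counts[marker.valid & (marker.counts >= 1)]
    i = iron.counts[iron.valid & (iron.counts >= 1)]
    if m.size == 0 or i.size == 0:
        raise SectionSkipped(
            "no object-containing pixels in marker or iron map; scale factor undefined"
        )
    return float(np.median(m) / np.median(i))


@lru_cache(maxsize=None)
def _combos_cached(n_rings: int, step_hundredths: int) -> np.ndarray:
    total = 100
    if total % step_hundredths:
        raise ValueError("step must divide 1.00 exactly in hundredths")
    seqs: list[tuple[int, ...]] = []

    def rec(prefix: list[int], remaining: int, cap: int, slots: int) -> None:
        if slots == 0:
            if remaining == 0:
                seqs.append(tuple(prefix))
            return
        # descending order: try the largest feasible value first
        for v in range(min(cap, remaining), -1, -step_hundredths):
            if v * slots < remaining:
                break
            rec(prefix + [v], remaining - v, v, slots - 1)

    rec([], total, total, n_rings + 1)
    return np.array(seqs, dtype=int)


def enumerate_combos(n_rings: int, step: float = 0.01) -> np.ndarray:
    """All monotone non-increasing coefficient combinations summing to 1.

    Returns an integer array of hundredths, shape (n_combos, n_rings+1),
    in deterministic order: descending by C_pixel, then C_ring1, etc.
    Row 0 is always the fully local combination (1.00, 0, ..., 0).
    """
    if n_rings < 0:
        raise ValueError("n_rings must be non-negative")
    step_h = int(round(step * 100))
    if abs(step * 100 - step_h) > 1e-9 or step_h <= 0:
        raise ValueError("step must be a positive multiple of 0.01")
    return _combos_cached(n_rings, step_h).copy()


def ring_densities(
    iron: HeatMap,
    marker: HeatMap,
    n_rings: int,
    euclidean: bool = False,
    scale: Optional[float] = None,
) -> RingDensities:
    """Scaled ring values and actual marker counts over the fit set.

    The fit set is every pixel valid in both maps whose rings all have at
    least one valid member; pixels with any undefined ring are dropped.
    ``scale`` overrides the median-ratio scale factor — used when the
    marker map was itself generated from a known scaled prediction.
    """
    if not iron.same_grid(marker):
        raise ValueError("iron and marker heat maps must share a grid")
    s = scale_factor(marker, iron) if scale is None else float(scale)
    means, tallies = ring_counts(iron, n_rings, euclidean=euclidean)
    both = iron.valid & marker.valid
    defined = both & np.all(np.isfinite(means), axis=0)
    idx = np.argwhere(defined)
    d = (s * means[:, defined]).T  # (n_fit, n_rings+1)
    actual = marker.counts[defined]
    return RingDensities(d, actual, idx, s, tallies[:, defined].T)


def predict_map(rings: RingDensities, combo: np.ndarray) -> np.ndarray:
    """Per-pixel predicted marker counts for one coefficient combination.

    ``combo`` is in hundredths (ints) or as floats summing to 1.
    """
    c = np.asarray(combo, dtype=float)
    if np.issubdtype(np.asarray(combo).dtype, np.integer):
        c = c / 100.0
    if c.shape[0] != rings.d.shape[1]:
        raise ValueError(
            f"combination has {c.shape[0]} weights but {rings.d.shape[1]} ring values"
        )
    return rings.d @ c


def residual_value(error: float, marker: HeatMap, mode: str = "multiply") -> float:
    """Per-section normalization of the fit error by the marker median.

    The median is over valid pixels containing at least one marker
    object.  ``multiply`` reproduces the displayed formula
    (residual = error × median); ``divide`` expresses the error in units
    of the typical per-pixel marker count.  Within a section both are the
    same monotone reordering of errors across models.
    """
    nz = marker.counts[marker.valid & (marker.counts >= 1)]
    if nz.size == 0:
        raise SectionSkipped("no marker-containing pixels; residual undefined")
    med = float(np.median(nz))
    if mode == "multiply":
        return error * med
    if mode == "divide":
        return error / med
    raise ValueError("mode must be 'multiply' or 'divide'")


def fit_ring_model(
    iron: HeatMap,
    marker: HeatMap,
    n_rings: int = 3,
    error_mode: str = "mean",
    residual_mode: str = "multiply",
    min_pixels: int = 10,
    strict_chain: bool = False,
    euclidean: bool = False,
    keep_predicted: bool = False,
    scale: Optional[float] = None,
) -> RingFitResult:
    """Exhaustive constrained search for the best ring coefficients.

    Evaluates every combination on the 0.01 grid and returns the one
    minimizing the per-pixel mean absolute difference between predicted
    and actual marker counts (``error_mode='sum'`` uses the plain sum;
    the argmin is identical within a section).  Ties are broken by
    enumeration order (most local combination first) and reported via
    ``n_ties``.  ``strict_chain`` drops combinations where consecutive
    coefficients are equal.
    """
    rings = ring_densities(iron, marker, n_rings, euclidean=euclidean, scale=scale)
    n_fit = rings.actual.shape[0]
    if n_fit < min_pixels:
        raise SectionSkipped(
            f"only {n_fit} fit pixels (< {min_pixels}); section skipped"
        )
    if error_mode not in ("mean", "sum"):
        raise ValueError("error_mode must be 'mean' or 'sum'")
    combos = enumerate_combos(n_rings)
    if strict_chain and n_rings > 0:
        # strict ordering among nonzero weights: c_k > c_{k+1} unless both 0
        keep = np.array(
            [
                all(a > b or (a == b == 0) for a, b in zip(row[:-1], row[1:]))
                for row in combos
            ]
        )
        combos = combos[keep]
    weights = combos / 100.0
    pred = rings.d @ weights.T  # (n_fit, n_combos)
    abs_diff = np.abs(pred - rings.actual[:, None])
    errors = abs_diff.sum(axis=0) if error_mode == "sum" else abs_diff.mean(axis=0)
    best = int(np.argmin(errors))
    err = float(errors[best])
    ties = int(np.sum(errors == err))
    res = residual_value(err, marker, residual_mode)
    predicted = None
    if keep_predicted:
        pm = np.full(iron.grid.shape, np.nan)
        pm[tuple(rings.pixel_index.T)] = pred[:, best]
        predicted = HeatMap(
            np.nan_to_num(pm, nan=0.0),
            np.isfinite(pm),
            iron.grid,
            iron.case_id,
            iron.region,
            marker.stain,
        )
    return RingFitResult(
        iron.case_id,
        iron.region,
        marker.stain,
        n_rings,
        tuple(float(v) / 100.0 for v in combos[best]),
        tuple(int(v) for v in combos[best]),
        err,
        res,
        n_fit,
        ties,
        predicted,
    )


def compare_ring_models(
    pairs: Iterable[tuple[HeatMap, HeatMap]],
    max_rings: int = 3,
    **fit_kwargs,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Fit 0..max_rings ring models per section; table for the stats stage.

    Returns (long-format results, skipped section keys).  One row per
    section × ring count, with the error, residual and each coefficient.
    """
    rows = []
    skipped = []
    for iron, marker in pairs:
        try:
            for n in range(max_rings + 1):
                fit = fit_ring_model(iron, marker, n_rings=n, **fit_kwargs)
                row = fit.to_record()
                for k in range(max_rings + 1):
                    row[f"c{k}"] = fit.coefficients[k] if k <= n else np.nan
                del row["coefficients"]
                rows.append(row)
        except SectionSkipped:
            skipped.append((iron.case_id, iron.region, marker.stain))
    return pd.DataFrame(rows), skipped
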