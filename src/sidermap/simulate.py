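"""Synthetic cohort generator.

Emulates the statistical structure of a serial-section autopsy study of
cortical superficial siderosis so every pipeline stage can be exercised
and calibrated without human material:

* a cortical ribbon whose pial (outer) surface is a sinusoid, deep side
  reaching the raster edge;
* an iron point process whose intensity decays exponentially with depth
  from the pial surface (superficial siderosis gradient) and is
  laterally multifocal — lognormal-amplitude foci along the surface —
  because siderosis is a patchy, sulcus-centred process, not a uniform
  film;
* a GFAP point process: sparse layer-dependent baseline (the emulated
  detector counts reactive astrocytes only, which are rare in deep
  cortex) plus a response driven by the local iron heat map through
  planted ring coefficients C*, realized as independent per-cell
  Poisson counts.  The response scale is solved self-consistently so
  that the analysis's own median-ratio scale factor, computed on the
  realized maps, equals the true planted scale — making the ring
  model's estimand equal C* by construction;
* a spatially homogeneous CD68 process;
* an optional smooth misalignment warp between "adjacent sections":
  translation plus a sinusoidal field, windowed to vanish at the deep
  raster edge where the block is mounted — each slide's coordinate
  frame is tissue-cropped, so adjacent-section misalignment shows up as
  a smooth interior distortion, to be undone by registration;
* an optional macrohemorrhage focus in which iron intensity is
  multiplied and CD68 acquires a response tied to the *excess* focal
  iron, so a CD68–iron association is planted only in that scenario.

Every random draw comes from a substream deterministically derived from
the master seed and the (case, region) indices, so identical configs
yield byte-identical cohorts.  Ground truth (planted coefficients, warp
parameters, expected counts) is carried alongside and is never consumed
by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import depth_map, make_layer_masks
from .rings import ring_counts
from .spatial import bin_heatmap
from .types import REGIONS, SectionDetections

_MAX_EXPECTED = 1_000_000  # desk-scale guard on per-section expected counts


@dataclass
class SyntheticConfig:
    """Study conditions for a generated cohort.

    Defaults mirror the shape of the emulated study: 19 cases sampled in
    four cortical lobes, three stains per sampling site.
    """

    n_cases: int = 19
    regions: tuple[str, ...] = REGIONS
    # ribbon geometry
    width_um: float = 24000.0
    depth_um: float = 5000.0
    pial_amplitude_um: float = 300.0
    pial_period_um: float = 4000.0
    margin_um: float = 200.0
    resolution_um: float = 50.0
    # iron process: depth decay x multifocal lateral modulation
    iron_expected: float = 12000.0
    iron_decay_um: float = 500.0
    iron_foci_per_mm: float = 0.8
    iron_focus_width_um: tuple[float, float] = (150.0, 400.0)
    iron_focus_lognorm_sd: float = 1.5
    iron_background: float = 0.02
    # GFAP process (per 500 um heat-map pixel)
    gfap_baseline_per_pixel: tuple[float, ...] = (0.3, 0.2, 0.1, 0.05, 0.05)
    gfap_gain: float = 1.0
    gfap_scale_mode: str = "self"  # "self": solve the median-consistent scale
    planted_coefficients: tuple[float, ...] = (0.55, 0.25, 0.15, 0.05)
    # CD68 process
    cd68_expected: float = 6000.0
    # misalignment warp between adjacent sections (pinned at the deep edge)
    warp_translation_um: tuple[float, float] = (200.0, 120.0)
    warp_nonrigid_amplitude_um: float = 100.0
    warp_nonrigid_period_um: float = 3000.0
    warp_taper_um: float = 1500.0
    # macrohemorrhage scenario
    macro_multiplier: float = 20.0
    macro_radius_um: float = 1000.0
    macro_center_um: Optional[tuple[float, float]] = None
    macro_cd68_gain: float = 1.0
    # heat-map scale at which the GFAP response is planted
    pixel_size_um: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.planted_coefficients, float)
        h = np.round(c * 100).astype(int)
        if h.sum() != 100 or np.any(np.diff(h) > 0) or np.any(h < 0):
            raise ValueError(
                "planted coefficients must be non-increasing, non-negative "
                "hundredths summing to 1.00"
            )
        if any(v < 0 for v in (self.iron_expected, self.cd68_expected, self.gfap_gain)):
            raise ValueError("intensities and gains must be non-negative")


@dataclass
class SectionGroundTruth:
    planted_coefficients: tuple[float, ...]
    planted_scale: float  # response scale B of the GFAP process
    iron_expected: float
    gfap_expected: float
    cd68_expected: float
    warp: Optional[dict]
    pial_rows: np.ndarray  # per-column raster row of the pial surface
    macro: bool = False


# ------------------------------------------------------------------ geometry


@dataclass
class Geometry:
    mask: np.ndarray
    resolution_um: float
    depth: np.ndarray  # μm from pial surface, NaN outside
    pial_rows: np.ndarray


def make_geometry(config: SyntheticConfig, case_idx: int, region_idx: int) -> Geometry:
    """Cortical ribbon mask for one sampling site (deterministic)."""
    res = config.resolution_um
    n_cols = int(round(config.width_um / res))
    n_rows = int(round((config.margin_um + config.pial_amplitude_um + config.depth_um) / res))
    rng = np.random.default_rng([config.seed, case_idx, region_idx, 7])
    phase = rng.uniform(0, 2 * np.pi)
    x = (np.arange(n_cols) + 0.5) * res
    pial_y = config.margin_um + config.pial_amplitude_um * 0.5 * (
        1 + np.sin(2 * np.pi * x / config.pial_period_um + phase)
    )
    rows = np.arange(n_rows)[:, None] * res
    mask = rows >= pial_y[None, :]
    depth = depth_map(mask, res)
    pial_rows = np.ceil(pial_y / res).astype(int)
    return Geometry(mask, res, depth, pial_rows)


# -------------------------------------------------------------- point drawing


def _draw_points_from_cell_weights(
    geom: Geometry, weights: np.ndarray, expected_total: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts per mask cell with E[total] as configured; uniform jitter."""
    if expected_total > _MAX_EXPECTED:
        raise ValueError(f"expected count {expected_total:.3g} exceeds desk-scale guard")
    w = np.where(geom.mask, weights, 0.0)
    total_w = w.sum()
    if expected_total <= 0 or total_w <= 0:
        return np.empty((0, 2))
    lam = w * (expected_total / total_w)
    counts = rng.poisson(lam)
    r, c = np.nonzero(counts)
    reps = counts[r, c]
    rr = np.repeat(r, reps).astype(float)
    cc = np.repeat(c, reps).astype(float)
    n = rr.size
    x = (cc + rng.uniform(0, 1, n)) * geom.resolution_um
    y = (rr + rng.uniform(0, 1, n)) * geom.resolution_um
    return np.column_stack([x, y])


def iron_weight_field(
    geom: Geometry, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Unnormalized iron intensity: depth decay × multifocal modulation.

    The lateral modulation is a small background plus Gaussian foci with
    lognormal amplitudes scattered along the surface coordinate,
    emulating the patchy, sulcus-centred distribution of siderosis.
    """
    with np.errstate(invalid="ignore"):
        w = np.exp(-np.nan_to_num(geom.depth, nan=np.inf) / config.iron_decay_um)
    nc = geom.mask.shape[1]
    x = (np.arange(nc) + 0.5) * geom.resolution_um
    f = np.full(nc, config.iron_background)
    n_foci = max(int(rng.poisson(config.iron_foci_per_mm * x[-1] / 1000.0)), 1)
    for _ in range(n_foci):
        c = rng.uniform(0, x[-1])
        s = rng.uniform(*config.iron_focus_width_um)
        a = rng.lognormal(0.0, config.iron_focus_lognorm_sd)
        f += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    return np.where(geom.mask, w * f[None, :], 0.0)


def _focus_mask(geom: Geometry, focus: tuple[float, float, float]) -> np.ndarray:
    fx, fy, rad = focus
    res = geom.resolution_um
    yy = (np.arange(geom.mask.shape[0]) + 0.5) * res
    xx = (np.arange(geom.mask.shape[1]) + 0.5) * res
    return (yy[:, None] - fy) ** 2 + (xx[None, :] - fx) ** 2 <= rad**2


def sample_iron(
    geom: Geometry,
    config: SyntheticConfig,
    rng: np.random.Generator,
    focus: Optional[tuple[float, float, float, float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iron points for one section.

    ``focus`` = (x, y, radius, multiplier) multiplies intensity inside a
    macrohemorrhage focus.  Returns (points, per-cell expected counts,
    per-cell expected counts without the focus) — the last feeds the
    macrohemorrhage CD68 response, which is tied to the *excess* iron.
    """
    w0 = iron_weight_field(geom, config, rng)
    w = w0
    if focus is not None:
        fx, fy, rad, mult = focus
        inside = _focus_mask(geom, (fx, fy, rad))
        w = w0 * np.where(inside, mult, 1.0)
    total = config.iron_expected
    lam = w * (total / w.sum()) if w.sum() > 0 else w
    lam0 = w0 * (total / w0.sum()) if w0.sum() > 0 else w0
    pts = _draw_points_from_cell_weights(geom, w, total, rng)
    return pts, lam, lam0


def _layer_index_map(geom: Geometry, thickness_um: float = 1000.0) -> np.ndarray:
    """0-based layer index per mask cell (clipped to the last baseline layer)."""
    with np.errstate(invalid="ignore"):
        li = np.floor(np.nan_to_num(geom.depth, nan=0.0) / thickness_um).astype(int)
    return li


def _place_counts_in_pixels(
    geom: Geometry,
    grid,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place given per-pixel counts uniformly over the in-cortex mask
    cells inside each heat-map pixel."""
    res = geom.resolution_um
    nr, nc = geom.mask.shape
    r_idx = np.floor((np.arange(nr) * res - grid.origin_y) / grid.cell_size_um).astype(int)
    c_idx = np.floor((np.arange(nc) * res - grid.origin_x) / grid.cell_size_um).astype(int)
    pts = []
    counts = np.nan_to_num(counts, nan=0.0).astype(int)
    for (pi, pj) in np.argwhere(counts > 0):
        n = counts[pi, pj]
        rows = np.nonzero(r_idx == pi)[0]
        cols = np.nonzero(c_idx == pj)[0]
        sub = geom.mask[np.ix_(rows, cols)]
        rr, cc = np.nonzero(sub)
        if rr.size == 0:
            continue
        pick = rng.integers(0, rr.size, n)
        x = (cols[cc[pick]] + rng.uniform(0, 1, n)) * res
        y = (rows[rr[pick]] + rng.uniform(0, 1, n)) * res
        pts.append(np.column_stack([x, y]))
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def _pixel_baseline(iron_heat, geom: Geometry, config: SyntheticConfig) -> np.ndarray:
    """Per-pixel GFAP baseline by the depth layer of each heat pixel."""
    from .spatial import _aggregate_to_grid

    grid = iron_heat.grid
    depth = np.nan_to_num(geom.depth, nan=0.0) * geom.mask
    num = _aggregate_to_grid(depth, geom.resolution_um, grid)
    den = _aggregate_to_grid(geom.mask.astype(float), geom.resolution_um, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_depth = np.where(den > 0, num / den, 0.0)
    base_by_layer = np.asarray(config.gfap_baseline_per_pixel, float)
    li = np.clip((mean_depth // 1000.0).astype(int), 0, base_by_layer.size - 1)
    return np.where(iron_heat.valid, base_by_layer[li], 0.0)


def plant_gfap(
    iron_heat, geom: Geometry, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Realized per-pixel GFAP counts: baseline + planted ring response.

    Expectation per valid pixel is baseline(layer) + B * sum_k C*_k *
    (ring-k mean of the realized iron heat map); pixels with an
    undefined ring receive baseline only.  In the default ``self`` mode
    the response scale B is solved so that the analysis's median-ratio
    scale factor, evaluated on the realized counts, equals B — the
    condition under which the ring fit's estimand is exactly C*.  Counts
    are Poisson, realized through fixed uniform quantiles so the scale
    iteration and the final draw are coherent and seed-deterministic.

    Returns (counts, expectation, response scale).
    """
    from scipy import stats as sps

    cstar = np.asarray(config.planted_coefficients, float)
    n_rings = cstar.size - 1
    means, _ = ring_counts(iron_heat, n_rings)
    defined = iron_heat.valid & np.all(np.isfinite(means), axis=0)
    response = np.where(
        defined, np.tensordot(cstar, np.nan_to_num(means, nan=0.0), axes=(0, 0)), 0.0
    )
    baseline = _pixel_baseline(iron_heat, geom, config)
    u = rng.uniform(size=iron_heat.counts.shape)

    def realize(lam: np.ndarray) -> np.ndarray:
        total = float(lam.sum())
        if total > _MAX_EXPECTED:
            raise ValueError(f"expected count {total:.3g} exceeds desk-scale guard")
        return sps.poisson.ppf(u, lam)

    gain = config.gfap_gain
    iron_nz = iron_heat.counts[iron_heat.valid & (iron_heat.counts >= 1)]
    scale = gain
    if (
        config.gfap_scale_mode == "self"
        and gain > 0
        and response.sum() > 0
        and iron_nz.size > 0
    ):
        med_iron = float(np.median(iron_nz))
        for _ in range(30):
            counts = realize(baseline + scale * response)
            nz = counts[iron_heat.valid & (counts >= 1)]
            if nz.size == 0:
                break
            scale = 0.7 * scale + 0.3 * float(np.median(nz)) / med_iron
    lam = baseline + scale * response
    counts = realize(lam)
    return counts, lam, float(scale)


# ------------------------------------------------------------------ warping


def warp_params(config: SyntheticConfig, case_idx: int, region_idx: int, stain: str) -> dict:
    rng = np.random.default_rng(
        [config.seed, case_idx, region_idx, 11, 1 if stain == "GFAP" else 2]
    )
    return {
        "translation_um": (
            config.warp_translation_um[0] * rng.uniform(-1, 1),
            config.warp_translation_um[1] * rng.uniform(-1, 1),
        ),
        "amplitude_um": config.warp_nonrigid_amplitude_um,
        "period_um": config.warp_nonrigid_period_um,
        "phase": (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
        "taper_um": config.warp_taper_um,
    }


def _warp_S(params: dict, extent_um: tuple[float, float]):
    """S maps marker-frame coordinates to iron-frame coordinates.

    The displacement (translation + sinusoid) is windowed to vanish at
    the left, right and deep raster edges, so the warped tissue never
    leaves the frame and the deep mounting edge stays put.
    """
    t = np.asarray(params["translation_um"], float)
    a = params["amplitude_um"]
    P = params["period_um"]
    ph = params["phase"]
    taper = params.get("taper_um", 1500.0)
    W, H = extent_um

    def S(xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        x, y = xy[..., 0], xy[..., 1]
        win = (
            np.clip(x / taper, 0, 1)
            * np.clip((W - x) / taper, 0, 1)
            * np.clip((H - y) / taper, 0, 1)
        )
        ux = (t[0] + a * np.sin(2 * np.pi * y / P + ph[0])) * win
        uy = (t[1] + a * np.cos(2 * np.pi * x / P + ph[1])) * win
        return np.stack([x + ux, y + uy], axis=-1)

    return S


def _invert_S(S, xy: np.ndarray, iters: int = 8) -> np.ndarray:
    """Fixed-point inverse of a near-identity smooth warp."""
    q = np.asarray(xy, float).copy()
    for _ in range(iters):
        q = q - (S(q) - xy)
    return q


def apply_misalignment(
    section: SectionDetections, params: dict
) -> SectionDetections:
    """Produce the 'adjacent section' view: mask and points under the warp."""
    res = section.mask_resolution_um
    mask = section.cortex_mask
    extent = (mask.shape[1] * res, mask.shape[0] * res)
    S = _warp_S(params, extent)
    nr, nc = mask.shape
    xs = (np.arange(nc) + 0.5) * res
    ys = (np.arange(nr) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    src = S(np.stack([gx, gy], axis=-1))
    ci = np.floor(src[..., 0] / res).astype(int)
    ri = np.floor(src[..., 1] / res).astype(int)
    ok = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
    warped_mask = np.zeros_like(mask)
    warped_mask[ok] = mask[ri[ok], ci[ok]]
    pts = section.objects
    if pts.shape[0]:
        pts = _invert_S(S, pts)
    return SectionDetections(
        section.case_id,
        section.region,
        section.stain,
        pts,
        warped_mask,
        res,
        section.group,
    )


# ------------------------------------------------------------------- cohort


@dataclass
class Cohort:
    sections: list
    cases: pd.DataFrame
    ground_truth: dict
    config: SyntheticConfig

    def get(self, case_id: str, region: str, stain: str) -> SectionDetections:
        for s in self.sections:
            if s.key == (case_id, region, stain):
                return s
        raise KeyError((case_id, region, stain))


def _case_id(i: int) -> str:
    return f"case{i + 1:02d}"


def generate_section_triplet(
    config: SyntheticConfig,
    case_idx: int,
    region_idx: int,
    macro: bool = False,
    misalign: bool = True,
) -> tuple[list[SectionDetections], SectionGroundTruth]:
    """Iron, GFAP and CD68 sections for one sampling site.

    The three stains share the site's geometry; the GFAP expectation is
    planted on the realized iron heat map; marker sections are then
    misaligned by a smooth warp (if configured) to emulate adjacent
    tissue sections.
    """
    region = config.regions[region_idx]
    case_id = _case_id(case_idx)
    geom = make_geometry(config, case_idx, region_idx)
    group = "macrohemorrhage" if macro else "cSS"

    rng_iron = np.random.default_rng([config.seed, case_idx, region_idx, 1])
    focus = None
    if macro:
        if config.macro_center_um is None:
            fx = config.width_um / 2.0
            fy = config.margin_um + config.pial_amplitude_um / 2.0 + 1500.0
        else:
            fx, fy = config.macro_center_um
        ci = int(fx / geom.resolution_um)
        ri = int(fy / geom.resolution_um)
        if not (
            0 <= ri < geom.mask.shape[0]
            and 0 <= ci < geom.mask.shape[1]
            and geom.mask[ri, ci]
        ):
            raise ValueError("macrohemorrhage focus lies outside the cortex")
        focus = (fx, fy, config.macro_radius_um, config.macro_multiplier)
    iron_pts, iron_lam, iron_lam0 = sample_iron(geom, config, rng_iron, focus=focus)
    iron_sec = SectionDetections(
        case_id, region, "iron", iron_pts, geom.mask, geom.resolution_um, group
    )

    iron_heat = bin_heatmap(iron_sec, config.pixel_size_um)
    rng_gfap = np.random.default_rng([config.seed, case_idx, region_idx, 2])
    gfap_counts, gfap_lam, gfap_scale = plant_gfap(iron_heat, geom, config, rng_gfap)
    gfap_pts = _place_counts_in_pixels(geom, iron_heat.grid, gfap_counts, rng_gfap)
    gfap_sec = SectionDetections(
        case_id, region, "GFAP", gfap_pts, geom.mask.copy(), geom.resolution_um, group
    )

    rng_cd68 = np.random.default_rng([config.seed, case_idx, region_idx, 3])
    cd68_lam_cells = np.where(geom.mask, 1.0, 0.0)
    cd68_total = config.cd68_expected
    lam = cd68_lam_cells * (cd68_total / cd68_lam_cells.sum())
    if macro and focus is not None:
        # response tied to the *excess* focal iron: zero when multiplier == 1
        excess = np.clip(iron_lam - iron_lam0, 0.0, None)
        lam = lam + config.macro_cd68_gain * excess
    cd68_pts = _draw_points_from_cell_weights(geom, lam, float(lam.sum()), rng_cd68)
    cd68_total_expected = float(lam.sum())
    cd68_sec = SectionDetections(
        case_id, region, "CD68", cd68_pts, geom.mask.copy(), geom.resolution_um, group
    )

    warps = None
    if misalign and (
        config.warp_nonrigid_amplitude_um > 0 or any(config.warp_translation_um)
    ):
        warps = {}
        for sec in (gfap_sec, cd68_sec):
            params = warp_params(config, case_idx, region_idx, sec.stain)
            warps[sec.stain] = params
        gfap_sec = apply_misalignment(gfap_sec, warps["GFAP"])
        cd68_sec = apply_misalignment(cd68_sec, warps["CD68"])

    gt = SectionGroundTruth(
        config.planted_coefficients,
        gfap_scale,
        float(iron_lam.sum()),
        float(np.nansum(gfap_lam)),
        cd68_total_expected,
        warps,
        geom.pial_rows,
        macro,
    )
    return [iron_sec, gfap_sec, cd68_sec], gt


def generate_cohort(
    config: SyntheticConfig,
    misalign: bool = True,
    macro_sites: tuple[tuple[int, int], ...] = (),
) -> Cohort:
    """Full cohort: n_cases × regions × 3 stains.

    ``macro_sites`` lists (case_idx, region_idx) pairs generated under
    the macrohemorrhage scenario.
    """
    sections = []
    gts = {}
    for ci in range(config.n_cases):
        for ri in range(len(config.regions)):
            macro = (ci, ri) in macro_sites
            triplet, gt = generate_section_triplet(config, ci, ri, macro, misalign)
            sections.extend(triplet)
            gts[f"{_case_id(ci)}/{config.regions[ri]}"] = gt
    rng = np.random.default_rng([config.seed, 999])
    cases = pd.DataFrame(
        {
            "case_id": [_case_id(i) for i in range(config.n_cases)],
            "age": rng.integers(64, 89, config.n_cases),
            "sex": np.where(rng.uniform(size=config.n_cases) < 0.3, "F", "M"),
        }
    )
    return Cohort(sections, cases, gts, config)


def cohort_table(cohort: Cohort) -> pd.DataFrame:
    """Whole-section density table feeding the mixed-model stage.

    One row per sampling site with iron/GFAP/CD68 densities (objects per
    mm² of cortex) joined with the case's age and sex.
    """
    rows = {}
    for s in cohort.sections:
        key = (s.case_id, s.region)
        rows.setdefault(key, {})[s.stain] = s.n_objects / s.cortex_area_mm2()
    recs = [
        {
            "case_id": c,
            "region": r,
            "iron_density": v.get("iron", np.nan),
            "gfap_density": v.get("GFAP", np.nan),
            "cd68_density": v.get("CD68", np.nan),
        }
        for (c, r), v in rows.items()
    ]
    df = pd.DataFrame(recs)
    return df.merge(cohort.cases, on="case_id", how="left")
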