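"""End-to-end orchestration: co-registration with exclusion bookkeeping,
layer profiles, heat maps, category profiles, ring fits and statistics.

Each stage is a function over in-memory sections so it can be driven
either programmatically or from the command line.  Exclusions are
recorded once per section per stage; the bookkeeping identity
(sections in) = (analyzed) + (excluded) holds per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import rings as ringsmod
from . import stats as statsmod
from .geometry import mask_grid, rasterize_objects
from .registration import register_sections, warp_counts
from .geometry import split_edge_inner
from .spatial import (
    bin_heatmap,
    category_design,
    category_profile,
    layer_densities,
    lobe_design,
    lobe_summary,
)
from .types import ExclusionLog, HeatMap, SectionDetections


def group_by_site(sections) -> dict:
    """{(case_id, region): {stain: section}}"""
    sites: dict = {}
    for s in sections:
        sites.setdefault((s.case_id, s.region), {})[s.stain] = s
    return sites


@dataclass
class RegisteredSite:
    iron: SectionDetections
    marker_counts: dict  # stain -> count matrix (iron mask grid) or None
    qualities: dict


def coregister_cohort(
    sections,
    log: ExclusionLog,
    dice_threshold: float = 0.90,
    nonrigid: bool = True,
) -> dict:
    """Register marker sections onto their iron section, warping counts.

    Marker sections that fail to co-register (Dice below threshold) are
    excluded and logged; sections whose iron mask is unusable exclude
    the whole site from iron-marker comparisons.
    """
    sites = group_by_site(sections)
    out = {}
    for key, stains in sorted(sites.items()):
        iron = stains.get("iron")
        if iron is None or not iron.mask_usable:
            for st, sec in stains.items():
                log.exclude(key[0], key[1], st, "poor_tissue_detection", "coregistration")
            continue
        marker_counts = {}
        qualities = {}
        for st in ("GFAP", "CD68"):
            sec = stains.get(st)
            if sec is None:
                continue
            if not sec.mask_usable:
                log.exclude(key[0], key[1], st, "poor_tissue_detection", "coregistration")
                continue
            identical = (
                sec.cortex_mask.shape == iron.cortex_mask.shape
                and bool(np.array_equal(sec.cortex_mask, iron.cortex_mask))
            )
            if identical:
                # perfectly aligned adjacent sections: nothing to undo
                cm, _ = rasterize_objects(sec.objects, mask_grid(iron.cortex_mask, iron.mask_resolution_um))
                marker_counts[st] = cm
                qualities[st] = 1.0
                continue
            tp = register_sections(iron, sec, dice_threshold=dice_threshold, nonrigid=nonrigid)
            qualities[st] = tp.quality
            if tp.failed:
                log.exclude(key[0], key[1], st, "coregistration_failure", "coregistration")
                continue
            cm, _ = rasterize_objects(
                sec.objects, mask_grid(sec.cortex_mask, sec.mask_resolution_um)
            )
            warped, _ = warp_counts(cm, tp, fixed_shape=iron.cortex_mask.shape)
            marker_counts[st] = warped
        out[key] = RegisteredSite(iron, marker_counts, qualities)
    return out


def layer_profiles(
    registered: dict, thickness_um: float = 1000.0, n_layers: int = 5
) -> pd.DataFrame:
    """Per-section per-layer densities for iron and co-registered markers."""
    from .geometry import make_layer_masks

    rows = []
    for (case_id, region), site in sorted(registered.items()):
        iron = site.iron
        layers = make_layer_masks(
            iron.cortex_mask, iron.mask_resolution_um, thickness_um, n_layers
        )
        prof = layer_densities(iron, layers=layers)
        rows.extend(
            (case_id, region, "iron", k + 1, prof.densities[k], prof.areas_mm2[k])
            for k in range(n_layers)
        )
        for st, cm in site.marker_counts.items():
            prof = layer_densities(iron, layers=layers, counts=cm.values)
            rows.extend(
                (case_id, region, st, k + 1, prof.densities[k], prof.areas_mm2[k])
                for k in range(n_layers)
            )
    return pd.DataFrame(
        rows, columns=["case_id", "region", "stain", "layer", "density", "area_mm2"]
    )


def layer_design(profiles: pd.DataFrame, stain: str) -> pd.DataFrame:
    """Blocks = brains, treatments = layers 1..5 (brain mean over regions)."""
    sub = profiles[profiles["stain"] == stain]
    return sub.pivot_table(index="case_id", columns="layer", values="density")


def heatmap_pairs(
    registered: dict,
    stain: str,
    pixel_size_um: float = 500.0,
    restrict: Optional[str] = None,
    edge_depth_um: float = 1000.0,
) -> list[tuple[HeatMap, HeatMap]]:
    """Co-registered (iron, marker) heat-map pairs on the iron grid.

    ``restrict``: None for whole cortex, 'edge' for the outermost band,
    'inner' for the cortex without it.
    """
    pairs = []
    for (case_id, region), site in sorted(registered.items()):
        cm = site.marker_counts.get(stain)
        if cm is None:
            continue
        iron = site.iron
        rmask = None
        if restrict is not None:
            edge, inner = split_edge_inner(
                iron.cortex_mask, iron.mask_resolution_um, edge_depth_um
            )
            rmask = edge if restrict == "edge" else inner
        ih = bin_heatmap(iron, pixel_size_um, restrict_mask=rmask)
        mh = bin_heatmap(iron, pixel_size_um, restrict_mask=rmask, counts=cm.values)
        mh.stain = stain
        pairs.append((ih, mh))
    return pairs


def ring_stage(
    registered: dict,
    stain: str = "GFAP",
    max_rings: int = 3,
    pixel_size_um: float = 500.0,
    log: Optional[ExclusionLog] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    pairs = heatmap_pairs(registered, stain, pixel_size_um)
    table, skipped = ringsmod.compare_ring_models(pairs, max_rings, **fit_kwargs)
    if log is not None:
        for case_id, region, st in skipped:
            log.exclude(case_id, region, st, "poor_object_detection", "ring_fit")
    return table


def ring_designs(table: pd.DataFrame, max_rings: Optional[int] = None):
    """Brain-level designs for the ring-count and coefficient comparisons."""
    if max_rings is None:
        max_rings = int(table["n_rings"].max())
    resid = table.pivot_table(
        index="case_id", columns="n_rings", values="residual", aggfunc="mean"
    )
    full = table[table["n_rings"] == max_rings]
    coef = full.groupby("case_id")[[f"c{k}" for k in range(max_rings + 1)]].mean()
    return resid, coef


def stats_stage(
    registered: dict,
    cases: pd.DataFrame,
    profiles: Optional[pd.DataFrame] = None,
    ring_table: Optional[pd.DataFrame] = None,
    pixel_size_um: float = 500.0,
    lme: bool = True,
) -> dict:
    """The inferential layer over the pipeline outputs."""
    results: dict = {}
    if profiles is not None:
        for stain in ("iron", "GFAP", "CD68"):
            design = layer_design(profiles, stain).dropna()
            if design.shape[0] >= 2 and design.shape[1] >= 2:
                fr = statsmod.friedman_kendall(design)
                post = statsmod.conover_posthoc(design, labels=list(design.columns))
                results[f"layers_{stain}"] = {"friedman": fr, "posthoc": post}
    for stain in ("GFAP", "CD68"):
        pairs = heatmap_pairs(registered, stain, pixel_size_um)
        if not pairs:
            continue
        prof = category_profile(pairs, grouping="brain")
        design = category_design(prof)
        sm = statsmod.skillings_mack(design.to_numpy(float))
        results[f"categories_{stain}"] = {"profile": prof, "skillings_mack": sm}
    if ring_table is not None and len(ring_table):
        resid, coef = ring_designs(ring_table)
        if resid.dropna().shape[0] >= 3:
            results["ring_residuals"] = statsmod.rm_anova_tukey(
                resid.dropna(), labels=list(resid.columns)
            )
        if coef.dropna().shape[0] >= 3:
            results["ring_coefficients"] = statsmod.rm_anova_tukey(
                coef.dropna(), labels=list(coef.columns)
            )
    if lme and cases is not None and len(cases):
        table = _site_density_table(registered, cases)
        for stain, col in (("GFAP", "gfap_density"), ("CD68", "cd68_density")):
            sub = table.dropna(subset=[col])
            if sub["case_id"].nunique() >= 5:
                results[f"lme_{stain}"] = statsmod.lme_compare(sub, col)
    sections = [site.iron for site in registered.values()]
    results["lobes"] = lobe_summary(sections)
    return results


def _site_density_table(registered: dict, cases: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (case_id, region), site in sorted(registered.items()):
        iron = site.iron
        area = iron.cortex_area_mm2()
        rec = {
            "case_id": case_id,
            "region": region,
            "iron_density": iron.n_objects / area,
            "gfap_density": np.nan,
            "cd68_density": np.nan,
        }
        for st, col in (("GFAP", "gfap_density"), ("CD68", "cd68_density")):
            cm = site.marker_counts.get(st)
            if cm is not None:
                rec[col] = cm.total / area
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df.merge(cases, on="case_id", how="left")
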