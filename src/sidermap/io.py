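"""Readers and writers for detection tables, masks, heat maps and results.

A cohort directory holds:

    detections.csv   case_id, region, stain, x_um, y_um  (one row per object)
    sections.csv     case_id, region, stain, mask_file, resolution_um, group
    masks/*.png      single-channel cortex masks (nonzero = in cortex)
    cases.csv        case_id, age, sex
    ground_truth.json  (synthetic cohorts only; never read by analyses)

Sections listed in the manifest with no detection rows are real data
with zero objects, not errors.  Stain and region vocabularies are
closed; unknown values are rejected by name.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .types import (
    REGIONS,
    STAINS,
    ExclusionLog,
    GridSpec,
    HeatMap,
    SectionDetections,
)

_DETECTION_COLUMNS = ("case_id", "region", "stain", "x_um", "y_um")
_SECTION_COLUMNS = ("case_id", "region", "stain", "mask_file", "resolution_um")


class SchemaError(ValueError):
    """A table does not match the expected column schema or vocabulary."""


def read_mask(path, binarize: Optional[str] = "nonzero") -> np.ndarray:
    """Read a single-channel mask image; nonzero means in-cortex.

    Multi-channel images are rejected unless a binarization rule is
    declared (``'any'``: any channel nonzero).
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if binarize == "any":
            arr = arr.any(axis=-1)
        else:
            raise ValueError(
                f"mask {path} has {arr.shape[-1]} channels and no declared "
                "binarization rule (use binarize='any')"
            )
    elif arr.ndim != 2:
        raise ValueError(f"mask {path} is not a 2-D image")
    return arr.astype(bool)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_detections(
    detections_path,
    sections_path,
    masks_dir=None,
) -> list[SectionDetections]:
    """Parse a cohort's detection table + section manifest into sections.

    Raises :class:`SchemaError` on a missing column or an unknown
    region/stain value, and a parse error naming the row for a
    non-numeric coordinate.
    """
    det = pd.read_csv(detections_path, dtype={"case_id": str})
    missing = [c for c in _DETECTION_COLUMNS if c not in det.columns]
    if missing:
        raise SchemaError(f"detections table lacks columns {missing}")
    man = pd.read_csv(sections_path, dtype={"case_id": str})
    missing = [c for c in _SECTION_COLUMNS if c not in man.columns]
    if missing:
        raise SchemaError(f"section manifest lacks columns {missing}")
    for frame, label in ((det, "detections"), (man, "manifest")):
        bad_r = set(frame["region"]) - set(REGIONS)
        if bad_r:
            raise SchemaError(f"unknown region value(s) {sorted(bad_r)} in {label}")
        bad_s = set(frame["stain"]) - set(STAINS)
        if bad_s:
            raise SchemaError(f"unknown stain value(s) {sorted(bad_s)} in {label}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(det[col], errors="coerce")
        bad = det.index[vals.isna() & det[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric coordinate in column {col!r} at row {int(bad[0])}"
            )
        if det[col].isna().any():
            raise SchemaError(f"missing coordinate in column {col!r}")
        det[col] = vals
    base = Path(masks_dir) if masks_dir is not None else Path(sections_path).parent
    sections = []
    grouped = det.groupby(["case_id", "region", "stain"])
    for row in man.itertuples(index=False):
        key = (row.case_id, row.region, row.stain)
        try:
            objs = grouped.get_group(key)[["x_um", "y_um"]].to_numpy(float)
        except KeyError:
            objs = np.empty((0, 2))
        mask = read_mask(base / row.mask_file)
        group = getattr(row, "group", "cSS")
        sections.append(
            SectionDetections(
                row.case_id, row.region, row.stain, objs, mask,
                float(row.resolution_um), group,
            )
        )
    return sections


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort in the exact formats the readers consume."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    det_rows = []
    man_rows = []
    for s in cohort.sections:
        mask_file = f"masks/{s.case_id}_{s.region}_{s.stain}.png"
        write_mask(out / mask_file, s.cortex_mask)
        man_rows.append(
            (s.case_id, s.region, s.stain, mask_file, s.mask_resolution_um, s.group)
        )
        for x, y in s.objects:
            det_rows.append((s.case_id, s.region, s.stain, x, y))
    pd.DataFrame(det_rows, columns=list(_DETECTION_COLUMNS)).to_csv(
        out / "detections.csv", index=False
    )
    pd.DataFrame(
        man_rows, columns=list(_SECTION_COLUMNS) + ["group"]
    ).to_csv(out / "sections.csv", index=False)
    cohort.cases.to_csv(out / "cases.csv", index=False)
    gt = {
        key: {
            "planted_coefficients": list(v.planted_coefficients),
            "planted_scale": v.planted_scale,
            "iron_expected": v.iron_expected,
            "gfap_expected": v.gfap_expected,
            "cd68_expected": v.cd68_expected,
            "warp": _jsonable(v.warp),
            "macro": v.macro,
        }
        for key, v in cohort.ground_truth.items()
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    return out


def read_cohort(cohort_dir) -> tuple[list[SectionDetections], pd.DataFrame]:
    base = Path(cohort_dir)
    sections = read_detections(base / "detections.csv", base / "sections.csv", base)
    cases_path = base / "cases.csv"
    cases = pd.read_csv(cases_path, dtype={"case_id": str}) if cases_path.exists() else pd.DataFrame()
    return sections, cases


def _jsonable(obj):
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ------------------------------------------------------------------ heat maps


def write_heatmap(heat: HeatMap, prefix) -> tuple[Path, Path]:
    """Dense matrix CSV plus long-format (pixel_i, pixel_j, count, valid).

    The dense file carries the grid metadata in a comment header so a
    round-trip read restores an equal object.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dense = prefix.with_suffix(".matrix.csv")
    g = heat.grid
    header = (
        f"# case_id={heat.case_id} region={heat.region} stain={heat.stain} "
        f"origin_x={g.origin_x} origin_y={g.origin_y} "
        f"cell_size_um={g.cell_size_um} n_outside={heat.n_outside_grid}\n"
    )
    with open(dense, "w") as fh:
        fh.write(header)
        np.savetxt(fh, heat.counts, delimiter=",", fmt="%.12g")
    long = prefix.with_suffix(".long.csv")
    ii, jj = np.meshgrid(range(g.n_rows), range(g.n_cols), indexing="ij")
    pd.DataFrame(
        {
            "pixel_i": ii.ravel(),
            "pixel_j": jj.ravel(),
            "count": heat.counts.ravel(),
            "valid": heat.valid.ravel().astype(int),
        }
    ).to_csv(long, index=False)
    return dense, long


def read_heatmap(prefix) -> HeatMap:
    prefix = Path(prefix)
    dense = prefix.with_suffix(".matrix.csv")
    with open(dense) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        counts = np.loadtxt(fh, delimiter=",", ndmin=2)
    long = pd.read_csv(prefix.with_suffix(".long.csv"))
    valid = np.zeros(counts.shape, dtype=bool)
    valid[long["pixel_i"], long["pixel_j"]] = long["valid"].astype(bool)
    grid = GridSpec(
        float(meta["origin_x"]),
        float(meta["origin_y"]),
        float(meta["cell_size_um"]),
        counts.shape[0],
        counts.shape[1],
    )
    return HeatMap(
        counts,
        valid,
        grid,
        meta["case_id"],
        meta["region"],
        meta["stain"],
        int(meta["n_outside"]),
    )


# ------------------------------------------------------------------- results


def write_records(records: Iterable[dict], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump([_jsonable(r) for r in records], fh, indent=1)
    return path


def read_records(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def write_exclusions(log: ExclusionLog, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (r.case_id, r.region, r.stain, r.reason, r.stage)
            for r in log
        ],
        columns=["case_id", "region", "stain", "reason", "stage"],
    ).to_csv(path, index=False)
    return path


def read_exclusions(path) -> ExclusionLog:
    df = pd.read_csv(path, dtype={"case_id": str})
    log = ExclusionLog()
    for row in df.itertuples(index=False):
        log.exclude(row.case_id, row.region, row.stain, row.reason, row.stage)
    return log


# -------------------------------------------------------------------- config


DEFAULT_SETTINGS = {
    "pixel_size_um": 500.0,
    "edge_pixel_size_um": 250.0,
    "layer_thickness_um": 1000.0,
    "n_layers": 5,
    "n_rings": 3,
    "dice_threshold": 0.90,
    "min_fit_pixels": 10,
    "residual_mode": "multiply",
    "error_mode": "mean",
    "seed": 0,
}


def load_config(path) -> dict:
    """YAML pipeline settings merged over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_SETTINGS) - {"cohort_dir", "out_dir", "simulate"}
    if unknown:
        raise SchemaError(f"unknown configuration keys {sorted(unknown)}")
    cfg = dict(DEFAULT_SETTINGS)
    cfg.update(user)
    return cfg
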