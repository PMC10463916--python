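import numpy as np
import pytest

from sidermap.simulate import SyntheticConfig, generate_section_triplet
from sidermap.types import GridSpec, HeatMap, SectionDetections


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale study conditions for fast unit tests."""
    return SyntheticConfig(
        n_cases=3,
        width_um=8000.0,
        iron_expected=3000.0,
        cd68_expected=1500.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def triplet(small_config):
    """One aligned iron/GFAP/CD68 triplet."""
    sections, gt = generate_section_triplet(small_config, 0, 0, misalign=False)
    return sections, gt


def flat_ribbon_section(
    depth_um=5000.0,
    width_um=4000.0,
    res=50.0,
    objects=None,
    margin_rows=1,
    case_id="caseA",
    region="frontal",
    stain="iron",
):
    """Rectangular ribbon with a flat pial surface below `margin_rows` of
    background; deep side touches the raster edge."""
    n_rows = int(depth_um / res) + margin_rows
    n_cols = int(width_um / res)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    mask[margin_rows:, :] = True
    if objects is None:
        objects = np.empty((0, 2))
    return SectionDetections(case_id, region, stain, objects, mask, res)


def heatmap_from_counts(counts, valid=None, pixel=500.0, stain="iron"):
    counts = np.asarray(counts, dtype=float)
    if valid is None:
        valid = np.ones_like(counts, dtype=bool)
    grid = GridSpec(0.0, 0.0, pixel, counts.shape[0], counts.shape[1])
    return HeatMap(counts, np.asarray(valid, bool), grid, "caseA", "frontal", stain)
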