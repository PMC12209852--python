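import numpy as np
import pandas as pd
import pytest

from adpn.synthetic import SimConfig, build_atlas, simulate_roi_cohort
from adpn.volumes import Atlas, Volume


@pytest.fixture(scope="session")
def tiny_atlas() -> Atlas:
    """Small parcellation shared by fast unit tests."""
    return build_atlas((16, 16, 16), 6, seed=3, voxel_size_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def two_region_atlas() -> Atlas:
    """Hand-built 1x1x5 grid: region 1 = 3 voxels, region 2 = 2 voxels."""
    labels = np.array([[[1, 1, 1, 2, 2]]], dtype=np.int32)
    regions = pd.DataFrame({"region_id": [1, 2], "name": ["a", "b"],
                            "abbreviation": ["A", "B"], "is_reference": [True, False]})
    return Atlas(labels=labels, regions=regions, reference_ids=frozenset({1}),
                 voxel_size_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def roi_cohort():
    """Region-level default-condition cohort reused across statistics tests."""
    cfg = SimConfig(n_subjects={"HEC": 200, "AD+P": 120, "AD-P": 120},
                    n_longitudinal={}, seed=42)
    roi, manifest, gt, atlas, specs = simulate_roi_cohort(cfg)
    return {"roi": roi, "manifest": manifest, "gt": gt, "atlas": atlas,
            "specs": specs, "config": cfg}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_volume(rng, shape=(12, 12, 12), voxel=(2.0, 2.0, 2.0)) -> Volume:
    return Volume(rng.uniform(0.5, 1.5, size=shape), voxel)
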