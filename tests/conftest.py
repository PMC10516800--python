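import numpy as np
import pytest

from metaconn.registry import ROI, ROIRegistry, default_registry
from metaconn.simulate import CovarianceSpec, GroupSpec, generate_group
from metaconn.uptake import UptakeTable


@pytest.fixture(scope="session")
def registry176():
    return default_registry()


def make_small_registry(sizes: dict[str, int]) -> ROIRegistry:
    """Tiny registry with the given per-structure sizes."""
    rois = []
    for structure, k in sizes.items():
        for i in range(k):
            rois.append(ROI(f"{structure}_{i}", structure, structure,
                            f"{structure}.{i}", -float(i)))
    return ROIRegistry(rois)


@pytest.fixture
def small_registry():
    return make_small_registry({"CP": 4, "TH": 4})


def make_table(values, group="g", registry=None) -> UptakeTable:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    roi_ids = (tuple(registry.roi_ids) if registry is not None
               else tuple(f"roi{j}" for j in range(p)))
    return UptakeTable(group, tuple(f"s{i}" for i in range(n)), roi_ids, values)


def correlated_pair_table(n=10, r=0.9, seed=0, extra_rois=0):
    """n-subject table whose first two ROIs target correlation r; any extra
    ROIs are independent noise."""
    rng = np.random.default_rng(seed)
    p = 2 + extra_rois
    cov = np.eye(p)
    cov[0, 1] = cov[1, 0] = r
    values = 100.0 + 5.0 * rng.multivariate_normal(np.zeros(p), cov, size=n,
                                                   method="eigh")
    return make_table(values)


def grouped_table(registry, n=10, within_r=0.0, planted=(), seed=0,
                  name="group"):
    cov = CovarianceSpec(
        roi_count=len(registry),
        block_assignment=tuple(r.structure for r in registry),
        within_block_r=within_r,
        planted_edges=tuple(planted),
    )
    return generate_group(GroupSpec(name, cov, n_subjects=n, seed=seed), registry)
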