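import numpy as np
import pytest

from rcbp.synthetic import PlantedDesign, materialize_connectivity_dataset
from rcbp.types import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_design():
    """Small planted cohort: 120 voxels, 3 parcels, 6 subjects."""
    return PlantedDesign(roi_shape=(6, 5, 4), k_true=3, n_subjects=6,
                         n_targets=40, seed=7)


def as_matrix(values):
    """Wrap a raw array in a ConnectivityMatrix with a synthetic voxel index."""
    values = np.atleast_2d(np.asarray(values, float))
    idx = np.c_[np.arange(values.shape[0]),
                np.zeros((values.shape[0], 2), dtype=int)]
    return ConnectivityMatrix(values=values, voxel_index=idx)


@pytest.fixture
def small_project(tmp_path, tiny_design):
    """A created, runnable precomputed-connectivity project."""
    from rcbp.config import example_config
    from rcbp.workflow import create_project

    paths = materialize_connectivity_dataset(tiny_design, tmp_path / "data")
    cfg = example_config("connectivity")
    cfg.participants = str(paths["participants"])
    cfg.roi_mask = str(paths["roi_mask"])
    cfg.connectivity = str(paths["connectivity_template"])
    cfg.voxel_index = str(paths["voxel_index"])
    cfg.clustering.k_range = [2, 3]
    cfg.clustering.n_init = 8
    cfg.clustering.max_iter = 300
    cfg_path = tmp_path / "config.yaml"
    cfg.to_yaml(cfg_path)
    project = tmp_path / "project"
    create_project(cfg_path, project)
    return {"project": project, "config": cfg_path, "paths": paths,
            "design": tiny_design}
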