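"""Shared fixtures: small synthetic tables, toy scenes, trained models.

The heavyweight fixtures (the n = 2x10^5 reference training run and the
scene-feature classifier) are session-scoped so the expensive work happens
once per test run.
"""

import numpy as np
import pytest

from solventscope.structures import find_difference_peaks, make_pseudoinverse
from solventscope.synthetic import (SceneConfig, make_scene, reference_dataset,
                                    sample_features, scene_reference_model)
from solventscope.training import train


@pytest.fixture(scope="session")
def ref_df():
    """The reference synthetic training table (n = 2x10^5, seed 1)."""
    return reference_dataset(seed=1)


@pytest.fixture(scope="session")
def ref_model(ref_df):
    return train(ref_df, seed=1)


@pytest.fixture(scope="session")
def small_df():
    """A small table for quick training-path tests."""
    return sample_features(20_000, seed=42)


@pytest.fixture(scope="session")
def small_model(small_df):
    return train(small_df, seed=42)


@pytest.fixture(scope="session")
def scene_model():
    """Classifier trained on scene-extracted (physical-unit) features."""
    return scene_reference_model(seed=0)


def _scene_fixture(cfg):
    structure, two_fofc, fofc, truth = make_scene(cfg)
    grids = {"two_fofc": two_fofc, "fofc": fofc,
             "pseudoinverse_two_fofc": make_pseudoinverse(two_fofc),
             "pseudoinverse_fofc": make_pseudoinverse(fofc)}
    peaks = find_difference_peaks(fofc, 3.0, resolution=cfg.resolution)
    # order peaks by distance to the nearest truth site
    txyz = truth[["x", "y", "z"]].to_numpy()
    peaks.sort(key=lambda p: np.min(np.linalg.norm(txyz - p.coordinate, axis=1)))
    return {"structure": structure, "grids": grids, "peaks": peaks,
            "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def water_scene():
    """One water in a quiet cell, with all four map kinds."""
    return _scene_fixture(SceneConfig(n_waters=1, n_sulfates=0, seed=5))


@pytest.fixture(scope="session")
def sulfate_scene():
    """One sulfate at the same random layout (paired with water_scene)."""
    return _scene_fixture(SceneConfig(n_waters=0, n_sulfates=1, seed=5))
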