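"""Shared fixtures: small synthetic scenes and fully prepared datasets.

Everything is generated at test time from fixed seeds; module-scoped
fixtures keep the heavier pipeline runs to one per session.
"""

import numpy as np
import pandas as pd
import pytest

import lurtransfer as lt
from lurtransfer import data_prep
from lurtransfer.evaluation import PreparedData


def run_pipeline(seed: int, shift: lt.ShiftConfig | None = None,
                 scene_config: lt.SceneConfig | None = None) -> PreparedData:
    """Generate a scene + campaign + network and push them through data_prep."""
    scene = lt.generate_scene(scene_config, seed=seed)
    shift = shift or lt.ShiftConfig()
    obs, ref = lt.generate_mobile_campaign(scene, shift, seed=seed + 100)
    obs = data_prep.temporal_correct(obs, ref)
    snapped = data_prep.snap_to_segments(obs, scene.segments)
    snapped = snapped.dropna(subset=["segment_id"])
    agg = data_prep.aggregate_segments(snapped).set_index("segment_id")
    y = agg["mean_conc"].reindex(scene.X.index)
    sites = data_prep.match_sites_to_segments(
        lt.generate_longterm_network(scene, shift, seed=seed + 200),
        scene.segments,
    )
    data = PreparedData(scene.X, y, sites, scene.directions)
    data.scene = scene  # tests may need the ground truth
    return data


@pytest.fixture(scope="session")
def shifted_data() -> PreparedData:
    """Default-shift scene pushed through the full preparation pipeline."""
    return run_pipeline(seed=0)


@pytest.fixture(scope="session")
def small_scene() -> lt.Scene:
    return lt.generate_scene(lt.SceneConfig(grid_n=5, street_length=400.0), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
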