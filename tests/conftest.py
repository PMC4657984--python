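import datetime as dt

import numpy as np
import pytest

from phenocrown import (
    MetricConfig,
    SceneConfig,
    SurveyLayer,
    build_feature_table,
    generate_world,
    make_phenology,
)
from phenocrown.geodata import GridTransform


def make_layer(
    bands,
    survey_id="s01",
    camera="RGB",
    gsd=0.20,
    x_origin=0.0,
    y_origin=None,
    nodata=None,
):
    """Wrap a (3, rows, cols) array into a SurveyLayer with a simple grid."""
    bands = np.asarray(bands)
    rows = bands.shape[1]
    if y_origin is None:
        y_origin = rows * gsd
    return SurveyLayer(
        survey_id=survey_id,
        date=dt.date(2021, 5, 28),
        season="spring",
        gdd=250.0,
        camera=camera,
        bands=bands,
        transform=GridTransform(x_origin=x_origin, y_origin=y_origin, gsd=gsd),
        nodata=nodata,
    )


@pytest.fixture(scope="session")
def planted_world():
    """Small planted-optimum world: 4 dates, 12 crowns/species."""
    phenology = make_phenology("planted_optimum", 7, n_dates=4)
    config = SceneConfig(
        n_crowns_per_species=12,
        grid_size=(240, 240),
        seed=7,
        crown_radius_range=(1.2, 1.8),
        preset="planted_optimum",
    )
    crowns, layers = generate_world(phenology, config)
    return phenology, config, crowns, layers


@pytest.fixture(scope="session")
def planted_table(planted_world):
    _, _, crowns, layers = planted_world
    return build_feature_table(layers, crowns, MetricConfig())


@pytest.fixture(scope="session")
def separable_table():
    """Single-date separable world with enough crowns for small RF runs."""
    phenology = make_phenology("separable_world", 2, n_dates=1)
    config = SceneConfig(
        n_crowns_per_species=14,
        grid_size=(260, 260),
        seed=3,
        crown_radius_range=(1.2, 1.8),
    )
    crowns, layers = generate_world(phenology, config)
    return build_feature_table(layers, crowns, MetricConfig())


@pytest.fixture(scope="session")
def small_null_table():
    """Small null world (identical species distributions) for chance-band checks."""
    phenology = make_phenology("null_world", 5, n_dates=1)
    config = SceneConfig(
        n_crowns_per_species=20,
        grid_size=(300, 300),
        seed=11,
        crown_radius_range=(1.2, 1.8),
    )
    crowns, layers = generate_world(phenology, config)
    return build_feature_table(layers, crowns, MetricConfig())
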