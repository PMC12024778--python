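import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import Point, box

from melliflow.landscape import LUU, Landscape
from melliflow.synthetic import GeneratorConfig, generate_landscape, generate_survey

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_landscape(default_config) -> Landscape:
    return generate_landscape(default_config)


@pytest.fixture(scope="session")
def default_survey(default_landscape, default_config):
    return generate_survey(default_landscape, default_config)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast, scaled-down mosaic for pipeline-level tests."""
    return GeneratorConfig(
        total_area_ha=60.0,
        lus_shares={
            "forest": 0.4,
            "grassland": 0.3,
            "habitation": 0.1,
            "wasteland": 0.1,
            "orchard": 0.05,
            "riparian": 0.05,
        },
        lus_patch_counts={
            "forest": 4,
            "grassland": 8,
            "habitation": 3,
            "wasteland": 4,
            "orchard": 6,
            "riparian": 2,
        },
        species_pool_size=40,
        community_size_by_lus={
            "forest": 20, "grassland": 25, "wasteland": 15,
            "riparian": 18, "orchard": 12, "maize": 8,
        },
        plot_spacing=60.0,
        accessibility=1.0,
        rng_seed=7,
    )


def grid_box_landscape(rng: np.random.Generator, n: int, labels=("forest", "grassland")):
    """n non-overlapping rectangular patches on a jittered grid (test helper)."""
    side = int(np.ceil(np.sqrt(n)))
    cells = rng.permutation(side * side)[:n]
    luus = []
    for k, c in enumerate(cells):
        i, j = divmod(int(c), side)
        x0, y0 = i * 100.0, j * 100.0
        w = rng.uniform(20.0, 80.0)
        h = rng.uniform(20.0, 80.0)
        ox = rng.uniform(0.0, 100.0 - w)
        oy = rng.uniform(0.0, 100.0 - h)
        lus = labels[int(rng.integers(len(labels)))]
        luus.append(LUU(f"B{k:03d}", lus, box(x0 + ox, y0 + oy, x0 + ox + w, y0 + oy + h)))
    return Landscape(luus, apiary=Point(side * 50.0, side * 50.0))
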