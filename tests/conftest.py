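import numpy as np
import pytest

import treegrid as tg


@pytest.fixture
def small_db():
    """Hand-built four-species database with known bounds and taxonomy."""
    entries = [
        tg.SpeciesTrait(
            name="Ficus religiosa",
            genus="Ficus",
            family="Moraceae",
            tree_height=30.0,
            canopy_width=20.0,
            leaf_area_index=6.0,
            faunal_groups=frozenset({"birds", "pollinators", "insects"}),
            services=frozenset(
                {"air quality", "biodiversity support", "bird feeding", "carbon sequestration",
                 "pollination", "runoff reduction", "uhi mitigation"}
            ),
        ),
        tg.SpeciesTrait(
            name="Azadirachta indica",
            genus="Azadirachta",
            family="Meliaceae",
            tree_height=20.0,
            canopy_width=15.0,
            leaf_area_index=4.0,
            faunal_groups=frozenset({"birds", "insects"}),
            services=frozenset({"air quality", "pest suppression", "uhi mitigation", "erosion control"}),
        ),
        tg.SpeciesTrait(
            name="Cassia fistula",
            genus="Cassia",
            family="Fabaceae",
            tree_height=10.0,
            canopy_width=8.0,
            leaf_area_index=3.0,
            faunal_groups=frozenset({"pollinators"}),
            services=frozenset({"pollination", "biodiversity support"}),
        ),
        tg.SpeciesTrait(
            name="Dalbergia sissoo",
            genus="Dalbergia",
            family="Fabaceae",
            tree_height=25.0,
            canopy_width=12.0,
            leaf_area_index=5.0,
            faunal_groups=frozenset(),
            services=frozenset({"carbon sequestration", "erosion control", "air quality"}),
        ),
    ]
    return tg.TraitDatabase(entries)


@pytest.fixture
def synth_db():
    return tg.gen_species_db(tg.SynthConfig(seed=11, n_species=24))


@pytest.fixture
def lst_grid():
    return tg.gen_lst_raster(tg.SynthConfig(seed=11, raster_shape=(48, 48)))


@pytest.fixture
def raster_polygon(lst_grid):
    """Square polygon centered on and contained in the fixture raster."""
    nr, nc = lst_grid.shape
    c = lst_grid.pixel_center(nr // 2, nc // 2)
    side = 0.8 * min(nr, nc) * lst_grid.pixel_size * 111_194.93
    return tg.square_polygon(c.latitude, c.longitude, side)


@pytest.fixture
def square_1km():
    return tg.square_polygon(30.3, 78.0, 1000.0)


def pairwise_overlap_audit(layout):
    """O(n²) oracle: no two canopies intersect (strict center-distance rule)."""
    trees = layout.trees
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            d = tg.haversine(trees[i].location, trees[j].location)
            if d < (trees[i].diameter + trees[j].diameter) / 2.0:
                return False
    return True
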