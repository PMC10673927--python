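import dendropy
import numpy as np
import pytest

from elasmodiv import synthetic
from elasmodiv.core import GridSpec, SpeciesTraitRecord, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def make_record(sid, size=100.0, habitat=("coastal",), terrestriality=("marine",),
                vertical="benthic", diet=("fish",), feeding="macropredator",
                thermo="ectothermic", iucn="LC", superorder="Selachii",
                order="Order01", family="Family01"):
    return SpeciesTraitRecord(
        species_id=sid, superorder=superorder, order=order, family=family,
        traits={
            "max_size": size,
            "habitat": frozenset(habitat),
            "terrestriality": frozenset(terrestriality),
            "vertical_position": vertical,
            "diet": frozenset(diet),
            "feeding": feeding,
            "thermoregulation": thermo,
        },
        iucn=iucn,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(
        n_species=60, n_trees=3, seed=11,
        grid=GridSpec(cell_size=1.0, lon_min=-20.0, lon_max=20.0,
                      lat_min=-30.0, lat_max=30.0),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synthetic.make_bundle(small_config)


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):0.5,C:2); rooted, hand-checkable branch lengths."""
    return dendropy.Tree.get(data="((A:1,B:1):0.5,C:2);", schema="newick")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
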