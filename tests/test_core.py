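"""Schema, readers/writers, grid geometry and pool filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elasmodiv.core import (
    ElasmodivError,
    GridSpec,
    IUCN100_MOOERS2008,
    OccurrenceGrid,
    ValidationError,
    filter_analysis_pool,
    read_occurrences,
    read_trait_table,
    write_occurrences,
    write_trait_table,
)

TRAIT_CSV = """species_id,superorder,order,family,max_size,habitat,terrestriality,vertical_position,diet,feeding,thermoregulation,iucn
spA,Selachii,Order01,Family01,120,coastal,marine,benthic,fish;invertebrates,macropredator,ectothermic,LC
spB,Batoidea,Order02,Family02,35.5,coastal;oceanic,marine;freshwater,benthopelagic,invertebrates,macropredator,ectothermic,EN
spC,Selachii,Order01,Family01,900,oceanic,marine,pelagic,plankton,filter_feeder,mesothermic,
"""


def test_trait_table_parsing_and_round_trip(tmp_path):
    src = tmp_path / "traits.csv"
    src.write_text(TRAIT_CSV)
    records = read_trait_table(src)
    assert len(records) == 3
    assert records[0].traits["diet"] == frozenset({"fish", "invertebrates"})
    assert records[1].traits["habitat"] == frozenset({"coastal", "oceanic"})
    assert records[2].iucn is None and records[2].traits["max_size"] == 900.0

    dst = tmp_path / "roundtrip.csv"
    write_trait_table(records, dst)
    again = read_trait_table(dst)
    for a, b in zip(records, again):
        assert a.species_id == b.species_id
        assert a.traits == b.traits
        assert a.iucn == b.iucn


@pytest.mark.parametrize("mutation, message", [
    (("spC", "spA"), "duplicate"),                       # duplicate id
    (("pelagic", "abyssal"), "abyssal"),                 # unknown category
    (("900", "-3"), "finite and > 0"),                   # bad size
])
def test_trait_table_rejects_bad_rows(tmp_path, mutation, message):
    old, new = mutation
    src = tmp_path / "bad.csv"
    src.write_text(TRAIT_CSV.replace(old, new))
    with pytest.raises(ValidationError, match=message):
        read_trait_table(src)


class TestGridSpec:
    def test_cell_assignment_is_total_and_half_open(self):
        spec = GridSpec()
        assert spec.cell_index(10.2, -5.1) == (380, 169)
        # boundary coordinate belongs to the cell to its east/north
        assert spec.cell_index(0.0, 0.0) == (360, 180)
        assert spec.cell_index(-0.0001, -0.0001) == (359, 179)
        # top edge folds into the last cell rather than falling out
        assert spec.cell_index(180.0, 90.0) == (719, 359)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            GridSpec().cell_index(200.0, 0.0)

    def test_every_coordinate_maps_to_exactly_one_cell(self, rng):
        spec = GridSpec(cell_size=1.0, lon_min=-10, lon_max=10, lat_min=-5, lat_max=5)
        for lon, lat in zip(rng.uniform(-10, 10, 200), rng.uniform(-5, 5, 200)):
            col, row = spec.cell_index(lon, lat)
            west = spec.lon_min + col * spec.cell_size
            south = spec.lat_min + row * spec.cell_size
            assert west <= lon < west + spec.cell_size
            assert south <= lat < south + spec.cell_size

    def test_cell_id_round_trip(self):
        spec = GridSpec()
        assert spec.parse_cell_id(spec.cell_id(380, 169)) == (380, 169)

    @settings(derandomize=True, max_examples=200)
    @given(lon=st.floats(-180, 180, exclude_max=True, allow_nan=False),
           lat=st.floats(-90, 90, exclude_max=True, allow_nan=False))
    def test_half_open_convention_holds_for_arbitrary_coordinates(self, lon, lat):
        # exact on representable cell boundaries; elsewhere within one
        # floating-point rounding of the boundary
        spec = GridSpec()
        col, row = spec.cell_index(lon, lat)
        west = spec.lon_min + col * spec.cell_size
        south = spec.lat_min + row * spec.cell_size
        eps = 1e-9
        assert west - eps <= lon < west + spec.cell_size + eps
        assert south - eps <= lat < south + spec.cell_size + eps
        assert 0 <= col < spec.n_cols and 0 <= row < spec.n_rows

    @settings(derandomize=True, max_examples=100)
    @given(col=st.integers(0, 719), row=st.integers(0, 359))
    def test_cell_boundaries_map_exactly_to_their_own_cell(self, col, row):
        spec = GridSpec()
        west = spec.lon_min + col * spec.cell_size
        south = spec.lat_min + row * spec.cell_size
        assert spec.cell_index(west, south) == (col, row)


def test_read_occurrences_collapses_duplicates(tmp_path):
    src = tmp_path / "occ.csv"
    src.write_text("species_id,lon,lat\nspA,10.2,-5.1\nspA,10.3,-5.2\nspB,0.0,0.0\n")
    grid = read_occurrences(src, GridSpec())
    assert grid.presence.sum() == 2  # spA twice in one 0.5-degree cell
    col, row = grid.spec.cell_index(10.2, -5.1)
    assert grid.presence[grid.spec.flat_index(col, row), grid.species.index("spA")]


def test_read_occurrences_bounds_error(tmp_path):
    src = tmp_path / "occ.csv"
    src.write_text("species_id,lon,lat\nspA,200,0\n")
    with pytest.raises(ValidationError):
        read_occurrences(src, GridSpec())


def test_occurrence_write_read_round_trip(tmp_path, small_bundle):
    path = tmp_path / "occ.csv"
    write_occurrences(small_bundle.grid, path)
    again = read_occurrences(path, small_bundle.grid.spec)
    assert again.species == sorted(small_bundle.grid.species)
    reordered = small_bundle.grid.subset_species(again.species)
    assert np.array_equal(again.presence, reordered.presence)


def test_unknown_species_dropped_with_warning(tmp_path, caplog):
    src = tmp_path / "occ.csv"
    src.write_text("species_id,lon,lat\nspA,1,1\nghost,2,2\n")
    grid = read_occurrences(src, GridSpec(), known_species=["spA"])
    assert grid.species == ["spA"]


class TestPoolFilter:
    def _grid(self, spec, placements):
        species = sorted({s for s, _ in placements})
        presence = np.zeros((spec.n_cells, len(species)), dtype=bool)
        for s, flat in placements:
            presence[flat, species.index(s)] = True
        return OccurrenceGrid(spec, species, presence)

    def test_exclusively_freshwater_dropped_but_mixed_kept(self, record_factory):
        spec = GridSpec(cell_size=1.0, lon_min=0, lon_max=5, lat_min=0, lat_max=1)
        recs = [
            record_factory("fw", terrestriality=("freshwater",)),
            record_factory("mix", terrestriality=("marine", "freshwater")),
            record_factory("m1"), record_factory("m2"), record_factory("m3"),
        ]
        placements = [(r.species_id, 0) for r in recs]
        result = filter_analysis_pool(recs, self._grid(spec, placements))
        kept = {r.species_id for r in result.records}
        assert "fw" not in kept and "mix" in kept
        assert result.drop_counts["freshwater_only"] == 1

    def test_sparse_cell_excluded_but_species_retained_elsewhere(self, record_factory):
        # cell 0 holds 5 species, cell 1 holds 3 of them: cell 1 is excluded
        # from FRic but its species survive through cell 0
        spec = GridSpec(cell_size=1.0, lon_min=0, lon_max=5, lat_min=0, lat_max=1)
        recs = [record_factory(f"s{i}") for i in range(5)]
        placements = [(f"s{i}", 0) for i in range(5)] + [(f"s{i}", 1) for i in range(3)]
        result = filter_analysis_pool(recs, self._grid(spec, placements))
        assert len(result.records) == 5
        assert result.excluded_cells[1] and not result.excluded_cells[0]

    def test_species_only_in_sparse_cells_dropped(self, record_factory):
        spec = GridSpec(cell_size=1.0, lon_min=0, lon_max=5, lat_min=0, lat_max=1)
        recs = [record_factory(f"s{i}") for i in range(4)] + [record_factory("lonely")]
        placements = [(f"s{i}", 0) for i in range(4)] + [("lonely", 1)]
        result = filter_analysis_pool(recs, self._grid(spec, placements))
        assert {r.species_id for r in result.records} == {f"s{i}" for i in range(4)}
        assert result.drop_counts["only_in_sparse_cells"] == 1
        # invariant: no all-false species column remains
        assert result.grid.presence.any(axis=0).all()

    def test_idempotent(self, small_bundle):
        first = filter_analysis_pool(small_bundle.records, small_bundle.grid)
        second = filter_analysis_pool(first.records, first.grid)
        assert [r.species_id for r in first.records] == [r.species_id for r in second.records]
        assert np.array_equal(first.grid.presence, second.grid.presence)
        assert np.array_equal(first.excluded_cells, second.excluded_cells)

    def test_empty_pool_raises(self, record_factory):
        spec = GridSpec(cell_size=1.0, lon_min=0, lon_max=2, lat_min=0, lat_max=1)
        recs = [record_factory("fw", terrestriality=("freshwater",))]
        grid = self._grid(spec, [("fw", 0)])
        with pytest.raises(ElasmodivError):
            filter_analysis_pool(recs, grid)


def test_extinction_probability_preset_is_monotone():
    probs = [IUCN100_MOOERS2008[c] for c in ("LC", "NT", "VU", "EN", "CR")]
    assert probs == sorted(probs)
    assert all(0 <= p <= 1 for p in probs)
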