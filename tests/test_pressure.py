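"""Fishing index, kriging interpolation and MPA gap analysis."""

import numpy as np
import pandas as pd
import pytest

from elasmodiv.core import ElasmodivError, GridSpec, ValidationError
from elasmodiv.pressure import (
    DEFAULT_GEAR_LIST,
    EffortGrid,
    cumulative_protection_curve,
    filter_mpas,
    fishing_index,
    krige_to_grid,
    mpa_cell_set,
    protection_overlap,
)

SPEC1 = GridSpec(cell_size=1.0, lon_min=0, lon_max=10, lat_min=0, lat_max=10)


class TestFishingIndex:
    def test_hours_summed_per_cell(self):
        records = pd.DataFrame({
            "cell_id": ["0:0", "0:0"],
            "gear": ["trawlers", "drifting_longlines"],
            "hours": [3.0, 2.0],
        })
        grid = fishing_index(records, SPEC1)
        assert grid.hours[SPEC1.flat_index(0, 0)] == pytest.approx(5.0)

    def test_non_target_gear_excluded(self):
        records = pd.DataFrame({
            "cell_id": ["0:0", "0:0"],
            "gear": ["trawlers", "squid_jigger"],
            "hours": [3.0, 100.0],
        })
        grid = fishing_index(records, SPEC1)
        assert grid.hours[SPEC1.flat_index(0, 0)] == pytest.approx(3.0)
        assert "squid_jigger" not in DEFAULT_GEAR_LIST

    def test_empty_records_give_zero_grid(self):
        grid = fishing_index(pd.DataFrame(columns=["cell_id", "gear", "hours"]), SPEC1)
        assert grid.hours.sum() == 0.0 and not grid.has_data.any()

    def test_negative_hours_rejected(self):
        records = pd.DataFrame({"cell_id": ["0:0"], "gear": ["trawlers"], "hours": [-1.0]})
        with pytest.raises(ValidationError):
            fishing_index(records, SPEC1)

    def test_additive_over_record_unions(self, rng):
        def recs(seed):
            r = np.random.default_rng(seed)
            return pd.DataFrame({
                "cell_id": [f"{int(c)}:{int(q)}" for c, q in
                            zip(r.integers(0, 10, 20), r.integers(0, 10, 20))],
                "gear": r.choice(DEFAULT_GEAR_LIST, 20),
                "hours": r.uniform(0, 10, 20),
            })
        a, b = recs(1), recs(2)
        combined = fishing_index(pd.concat([a, b]), SPEC1)
        separate = fishing_index(a, SPEC1).hours + fishing_index(b, SPEC1).hours
        assert np.allclose(combined.hours, separate)


class TestKriging:
    def _effort(self, values, has=None):
        has = np.ones(SPEC1.n_cells, bool) if has is None else has
        return EffortGrid(SPEC1, values, has, DEFAULT_GEAR_LIST)

    def test_constant_field_interpolates_to_constant(self):
        coarse = self._effort(np.full(SPEC1.n_cells, 7.0))
        target = GridSpec(cell_size=0.5, lon_min=0, lon_max=10, lat_min=0, lat_max=10)
        fine = krige_to_grid(coarse, target, radius=3.0)
        assert np.allclose(fine.hours[~np.isnan(fine.hours)], 7.0, atol=1e-6)

    def test_prediction_at_data_location_returns_datum(self, rng):
        values = rng.uniform(0, 100, SPEC1.n_cells)
        coarse = self._effort(values)
        fine = krige_to_grid(coarse, SPEC1, radius=3.0)  # same grid: co-located
        ok = ~np.isnan(fine.hours)
        assert np.allclose(fine.hours[ok], values[ok], atol=1e-5)

    def test_sparse_neighbourhood_left_na(self):
        has = np.zeros(SPEC1.n_cells, bool)
        has[:3] = True  # only 3 data cells anywhere
        coarse = self._effort(np.ones(SPEC1.n_cells), has)
        fine = krige_to_grid(coarse, SPEC1, radius=3.0, min_neighbors=5)
        assert np.isnan(fine.hours).all()

    def test_predictions_non_negative(self, rng):
        values = rng.exponential(10, SPEC1.n_cells)
        fine = krige_to_grid(self._effort(values),
                             GridSpec(cell_size=0.5, lon_min=0, lon_max=10,
                                      lat_min=0, lat_max=10), radius=3.0)
        ok = ~np.isnan(fine.hours)
        assert (fine.hours[ok] >= 0).all()

    def test_kriging_beats_idw_on_smooth_field(self):
        # hold out cells from a smooth field; kriging should not lose to
        # inverse-distance weighting on average
        from elasmodiv.pressure import _idw
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            lon, lat = SPEC1.centers()
            field = 50 + 30 * np.sin(lon / 3.0) * np.cos(lat / 3.0) + rng.normal(0, 2, SPEC1.n_cells)
            field = np.clip(field, 0, None)
            held = rng.choice(SPEC1.n_cells, 20, replace=False)
            has = np.ones(SPEC1.n_cells, bool)
            has[held] = False
            coarse = EffortGrid(SPEC1, field, has, DEFAULT_GEAR_LIST)
            fine = krige_to_grid(coarse, SPEC1, radius=3.0)
            pts = np.column_stack([lon[has], lat[has]])
            krig_err, idw_err = [], []
            for c in held:
                if np.isnan(fine.hours[c]):
                    continue
                d0 = np.sqrt((pts[:, 0] - lon[c]) ** 2 + (pts[:, 1] - lat[c]) ** 2)
                near = d0 <= 3.0
                idw_pred = _idw(d0[near], field[has][near])
                krig_err.append((fine.hours[c] - field[c]) ** 2)
                idw_err.append((idw_pred - field[c]) ** 2)
            if np.sqrt(np.mean(krig_err)) <= np.sqrt(np.mean(idw_err)):
                wins += 1
        assert wins >= 4


MPA_TABLE = pd.DataFrame({
    "mpa_id": ["m1", "m1", "m2", "m3", "m4"],
    "category": ["Ia", "Ia", "IV", "II", "Ib"],
    "designation": ["Marine Reserve", "Marine Reserve", "Marine Reserve",
                    "Seabird Sanctuary", "No-Take Zone"],
    "cell_id": ["0:0", "0:1", "1:1", "2:2", "3:3"],
})


class TestMpaFiltering:
    def test_partial_protection_categories_removed(self):
        kept, removed = filter_mpas(MPA_TABLE)
        assert "m2" not in set(kept["mpa_id"])
        assert removed["category"] == 1

    def test_decoy_designation_removed_even_in_category_ii(self):
        kept, _ = filter_mpas(MPA_TABLE)
        assert "m3" not in set(kept["mpa_id"])

    def test_neutral_fully_protected_kept(self):
        kept, _ = filter_mpas(MPA_TABLE)
        assert {"m1", "m4"} == set(kept["mpa_id"])

    def test_idempotent_and_order_invariant(self):
        once, _ = filter_mpas(MPA_TABLE)
        twice, removed2 = filter_mpas(once)
        pd.testing.assert_frame_equal(once, twice)
        assert removed2 == {"category": 0, "designation": 0}
        shuffled, _ = filter_mpas(MPA_TABLE.iloc[::-1].reset_index(drop=True))
        assert set(shuffled["cell_id"]) == set(once["cell_id"])

    def test_unknown_category_rejected(self):
        bad = MPA_TABLE.assign(category=["Ia", "Ia", "VII", "II", "Ib"])
        with pytest.raises(ValidationError):
            filter_mpas(bad)


class TestProtectionOverlap:
    def test_full_coverage(self):
        out = protection_overlap({"a", "b"}, {"a", "b", "c"})
        assert out["pct_hotspot_inside_mpa"] == 100.0

    def test_disjoint_masks(self):
        out = protection_overlap({"a", "b"}, {"c"})
        assert out["pct_hotspot_inside_mpa"] == 0.0
        assert out["pct_hotspot_outside_mpa"] == 100.0

    def test_quarter_inside(self):
        hs = {f"h{i}" for i in range(20)}
        prot = {f"h{i}" for i in range(5)} | {"x"}
        out = protection_overlap(hs, prot)
        assert out["pct_hotspot_inside_mpa"] == pytest.approx(25.0)
        assert out["pct_hotspot_outside_mpa"] == pytest.approx(75.0)

    def test_percentages_sum_to_100(self, rng):
        hs = {f"c{i}" for i in rng.choice(100, 30, replace=False)}
        prot = {f"c{i}" for i in rng.choice(100, 40, replace=False)}
        out = protection_overlap(hs, prot)
        assert out["pct_hotspot_inside_mpa"] + out["pct_hotspot_outside_mpa"] == pytest.approx(100.0)

    def test_empty_hotspots_rejected(self):
        with pytest.raises(ElasmodivError):
            protection_overlap(set(), {"a"})


class TestCumulativeCurve:
    def test_single_protected_cell(self):
        curve = cumulative_protection_curve(pd.Series({"a": 5.0}), {"a"})
        assert len(curve) == 1 and curve["cumulative_pct_protected"].iloc[0] == 100.0

    def test_three_cells_cumulative_percentages(self):
        values = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 9.0})
        curve = cumulative_protection_curve(values, {"a", "b", "c"})
        assert curve["value"].tolist() == [1.0, 2.0, 3.0]
        assert curve["cumulative_pct_protected"].tolist() == pytest.approx([100 / 3, 200 / 3, 100.0])

    def test_curve_non_decreasing(self, rng):
        values = pd.Series(rng.uniform(0, 10, 50), index=[f"c{i}" for i in range(50)])
        curve = cumulative_protection_curve(values, set(values.index[::2]))
        assert (np.diff(curve["value"]) >= 0).all()
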