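"""Synthetic-data generator: determinism and statistical structure."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elasmodiv import synthetic
from elasmodiv.core import ElasmodivError, GridSpec, read_trait_table
from elasmodiv.functional_space import trait_gower_matrix
from elasmodiv.synthetic import (
    SimulationConfig,
    StatusCoupling,
    assign_statuses,
    generate_fishing,
    generate_mpas,
    generate_ranges,
    generate_tree,
    inject_missingness,
    make_benchmark,
    simulate_traits,
)


class TestTrees:
    def test_two_species_is_a_cherry(self):
        tree = generate_tree(2, seed=0)
        assert len(tree.leaf_nodes()) == 2

    def test_seed_reproducibility(self):
        a = generate_tree(50, seed=9).as_string(schema="newick")
        b = generate_tree(50, seed=9).as_string(schema="newick")
        assert a == b

    def test_tip_count_and_positive_length(self):
        tree = generate_tree(100, seed=1)
        assert len(tree.leaf_nodes()) == 100
        assert tree.length() > 0

    def test_n_below_two_rejected(self):
        with pytest.raises(ElasmodivError):
            generate_tree(1)


class TestTraits:
    def test_zero_transition_rate_keeps_root_state(self):
        tree = generate_tree(20, seed=2)
        recs = simulate_traits(tree, mk_rate=0.0, bm_sigma2=0.1, seed=3)
        assert len({r.traits["vertical_position"] for r in recs}) == 1
        assert len({r.traits["feeding"] for r in recs}) == 1

    def test_seed_reproducibility(self):
        tree = generate_tree(15, seed=4)
        a = simulate_traits(tree, seed=5)
        b = simulate_traits(tree, seed=5)
        assert all(x.traits == y.traits for x, y in zip(a, b))

    def test_phylogenetic_signal_in_cherries(self):
        # sister tips should be more similar than random pairs under
        # conservative evolution
        tree = generate_tree(80, seed=6)
        recs = simulate_traits(tree, bm_sigma2=0.3, mk_rate=0.4, seed=7)
        d = trait_gower_matrix(recs)
        idx = {s: i for i, s in enumerate(d.species)}
        cherry_d = []
        for node in tree.postorder_internal_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                cherry_d.append(d.values[idx[kids[0].taxon.label], idx[kids[1].taxon.label]])
        iu = np.triu_indices(len(d.species), k=1)
        assert np.mean(cherry_d) < d.values[iu].mean()

    def test_multichoice_always_non_empty(self):
        tree = generate_tree(60, seed=8)
        recs = simulate_traits(tree, mk_rate=2.0, seed=9)
        for r in recs:
            for name in ("habitat", "terrestriality", "diet"):
                assert len(r.traits[name]) >= 1


class TestStatuses:
    def test_zero_coupling_zero_base_rate_all_non_threatened(self, small_bundle):
        recs, _ = assign_statuses(small_bundle.records_true,
                                  StatusCoupling(0, 0, 0, 0), base_rate=0.0, seed=1)
        assert all(r.iucn in ("LC", "NT") for r in recs)

    def test_size_coupling_induces_positive_correlation(self):
        tree = generate_tree(500, seed=10)
        base = simulate_traits(tree, seed=11)
        recs, truth = assign_statuses(base, StatusCoupling(size=2.0, coastal=0, freshwater=0,
                                                           plankton=0),
                                      base_rate=0.4, seed=12)
        logsize = np.array([np.log10(r.traits["max_size"]) for r in recs])
        threatened = np.array([truth[r.species_id] in ("VU", "EN", "CR") for r in recs])
        r, _ = stats.pointbiserialr(threatened, logsize)
        assert r > 0

    def test_dd_fraction_binomial_expectation(self):
        tree = generate_tree(1000, seed=13)
        base = simulate_traits(tree, seed=14)
        recs, _ = assign_statuses(base, dd_ne_fraction=0.15, seed=15)
        n_dd = sum(1 for r in recs if r.iucn in ("DD", "NE"))
        sigma = np.sqrt(1000 * 0.15 * 0.85)
        assert abs(n_dd - 150) <= 3 * sigma

    def test_truth_precedes_dd_relabelling(self, small_bundle):
        assert set(small_bundle.status_truth.unique()) <= {"LC", "NT", "VU", "EN", "CR"}


class TestMissingness:
    def test_zero_rate_is_identity(self, small_bundle):
        recs, truth = inject_missingness(small_bundle.records_true, {"diet": 0.0}, seed=1)
        assert truth.empty
        assert all(r.traits == o.traits for r, o in zip(recs, small_bundle.records_true))

    def test_rate_matches_binomial_expectation(self):
        tree = generate_tree(1000, seed=16)
        base = simulate_traits(tree, seed=17)
        recs, truth = inject_missingness(base, {"diet": 0.35}, seed=18)
        n_missing = sum(1 for r in recs if r.traits["diet"] is None)
        sigma = np.sqrt(1000 * 0.35 * 0.65)
        assert abs(n_missing - 350) <= 3 * sigma

    def test_truth_table_reconstructs_original_exactly(self, small_bundle):
        recs, truth = inject_missingness(small_bundle.records_true,
                                         {"diet": 0.3, "max_size": 0.2}, seed=19)
        originals = {r.species_id: r for r in small_bundle.records_true}
        for sid, row in truth.iterrows():
            for var, val in row.dropna().items():
                assert originals[sid].traits[var] == val
        for r in recs:
            for var in ("diet", "max_size"):
                if r.traits[var] is None:
                    assert pd.notna(truth.loc[r.species_id, var])


class TestRanges:
    SPEC = GridSpec(cell_size=1.0, lon_min=-30, lon_max=30, lat_min=-60, lat_max=60)

    def test_zero_sigma_gives_identical_range_sizes(self, small_bundle):
        grid = generate_ranges(small_bundle.records_true, self.SPEC,
                               range_mu=np.log(50), range_sigma=0.0, seed=1)
        counts = grid.presence.sum(axis=0)
        assert len(set(counts.tolist())) == 1

    def test_zero_gradient_centroids_uniform(self):
        tree = generate_tree(2000, seed=20)
        recs = [type("R", (), {"species_id": f"sp{i}"})() for i in range(2000)]
        grid = generate_ranges(recs, self.SPEC, gradient=0.0,
                               range_mu=0.0, range_sigma=0.0, seed=21)
        _, lat = self.SPEC.centers()
        lats = [lat[grid.presence[:, j]].mean() for j in range(2000)]
        u = (np.array(lats) - self.SPEC.lat_min) / (self.SPEC.lat_max - self.SPEC.lat_min)
        _, p = stats.kstest(u, "uniform")
        assert p > 0.01

    def test_equatorial_richness_peak_under_default_gradient(self, small_bundle):
        grid = small_bundle.grid
        sr = grid.species_richness()
        _, lat = grid.spec.centers()
        tropics = sr[np.abs(lat) < 15].mean()
        poles = sr[np.abs(lat) > 25].mean()
        assert tropics > poles


class TestFishingAndMpas:
    SPEC = GridSpec(cell_size=1.0, lon_min=0, lon_max=50, lat_min=0, lat_max=50)

    def test_zero_coverage_empty_table(self):
        assert generate_mpas(self.SPEC, coverage=0.0, seed=1).empty

    def test_coverage_fraction_approximate(self):
        spec = GridSpec(cell_size=1.0, lon_min=0, lon_max=100, lat_min=0, lat_max=100)
        mpas = generate_mpas(spec, coverage=0.1, seed=2)
        covered = mpas["cell_id"].nunique()
        sigma = np.sqrt(10000 * 0.1 * 0.9)
        assert abs(covered - 1000) <= 3 * sigma

    def test_fishing_non_negative_and_all_cells_recorded(self):
        effort = generate_fishing(self.SPEC, autocorr_length=2.0, seed=3)
        assert (effort["hours"] >= 0).all()
        assert effort["cell_id"].nunique() == self.SPEC.n_cells

    def test_no_autocorrelation_gives_moran_i_near_null(self):
        effort = generate_fishing(self.SPEC, autocorr_length=0.0, seed=4)
        from elasmodiv.pressure import fishing_index
        grid = fishing_index(effort, self.SPEC)
        field = np.log1p(grid.hours).reshape(self.SPEC.n_rows, self.SPEC.n_cols)
        # Moran's I with rook neighbours
        z = field - field.mean()
        num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
        w_total = z[:, :-1].size + z[:-1, :].size
        moran = (field.size / w_total) * num / (z ** 2).sum()
        # permutation null
        rng = np.random.default_rng(0)
        null = []
        flat = z.ravel()
        for _ in range(200):
            s = rng.permutation(flat).reshape(field.shape)
            n2 = (s[:, :-1] * s[:, 1:]).sum() + (s[:-1, :] * s[1:, :]).sum()
            null.append((field.size / w_total) * n2 / (s ** 2).sum())
        assert abs(moran - np.mean(null)) <= 3 * np.std(null)

    def test_autocorrelated_field_has_positive_moran_i(self):
        effort = generate_fishing(self.SPEC, autocorr_length=3.0, seed=5)
        from elasmodiv.pressure import fishing_index
        grid = fishing_index(effort, self.SPEC)
        field = np.log1p(grid.hours).reshape(self.SPEC.n_rows, self.SPEC.n_cols)
        z = field - field.mean()
        num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
        w_total = z[:, :-1].size + z[:-1, :].size
        moran = (field.size / w_total) * num / (z ** 2).sum()
        assert moran > 0.3


class TestBenchmark:
    def test_bundle_files_written_and_reproducible(self, tmp_path, small_config):
        out1 = make_benchmark(small_config, tmp_path / "b1")
        out2 = make_benchmark(small_config, tmp_path / "b2")
        for name in ("traits.csv", "occurrences.csv", "fishing_effort.csv",
                     "mpas.csv", "manifest.json"):
            assert (out1 / name).exists()
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name
        trees = sorted((out1 / "trees").glob("*.nwk"))
        assert len(trees) == small_config.n_trees
        manifest = json.loads((out1 / "manifest.json").read_text())
        assert manifest["seed"] == small_config.seed

    def test_trait_csv_row_count(self, tmp_path):
        cfg = SimulationConfig(n_species=20, n_trees=2, seed=1,
                               grid=GridSpec(cell_size=1.0, lon_min=0, lon_max=10,
                                             lat_min=0, lat_max=10))
        out = make_benchmark(cfg, tmp_path / "b")
        assert len(read_trait_table(out / "traits.csv")) == 20

    def test_refuses_to_overwrite_without_force(self, tmp_path, small_config):
        out = make_benchmark(small_config, tmp_path / "b")
        with pytest.raises(ElasmodivError):
            make_benchmark(small_config, out)
        make_benchmark(small_config, out, force=True)

    def test_status_coupling_recoverable_by_logistic_fit(self):
        # the configured threat coupling signs should be recovered by a
        # logistic regression on a larger simulation
        from sklearn.linear_model import LogisticRegression
        tree = generate_tree(800, seed=30)
        base = simulate_traits(tree, seed=31)
        recs, truth = assign_statuses(
            base, StatusCoupling(size=1.0, coastal=1.0, freshwater=1.0, plankton=1.0),
            base_rate=0.35, seed=32)
        X = np.column_stack([
            stats.zscore([np.log10(r.traits["max_size"]) for r in recs]),
            [("coastal" in r.traits["habitat"]) for r in recs],
            [("freshwater" in r.traits["terrestriality"]) for r in recs],
            [("plankton" in r.traits["diet"]) for r in recs],
        ]).astype(float)
        y = np.array([truth[r.species_id] in ("VU", "EN", "CR") for r in recs])
        coefs = LogisticRegression(max_iter=1000).fit(X, y).coef_[0]
        assert (coefs > 0).all()
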