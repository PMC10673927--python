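"""Synthetic data with the statistical structure the analysis assumes.

The generator produces everything the pipeline consumes: a birth-death
tree sample, clade-conserved mixed-type traits (Brownian motion for
log body size, Mk processes for the categorical traits), IUCN statuses
coupled to size / coastal habitat / freshwater incursion / plankton
diet through a logistic model, missing-completely-at-random trait
masking with a hidden truth table, latitudinally graded contiguous
species ranges with lognormal sizes, a spatially autocorrelated
fishing-effort surface, and a patchy MPA table with decoy
designations.  Everything is deterministic under the master seed; each
generator draws from its own spawned substream so adding one does not
shift the others.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    ElasmodivError,
    GridSpec,
    OccurrenceGrid,
    SpeciesTraitRecord,
    TraitSchema,
    default_schema,
    write_occurrences,
    write_trait_table,
)

DECOY_DESIGNATIONS = (
    "Seabird Sanctuary",
    "Important Bird Area Reserve",
    "Sea Turtle Nesting Refuge",
    "Seal Haul-out Protected Area",
    "Coastal Flora Conservation Zone",
)
TARGET_DESIGNATIONS = (
    "Marine National Park",
    "No-Take Marine Reserve",
    "Marine Nature Reserve",
    "Strict Marine Sanctuary",
    "Marine Protected Area",
)
NON_TARGET_GEARS = ("squid_jigger", "fixed_gear", "dredge_fishing")


@dataclass(frozen=True)
class StatusCoupling:
    """Log-odds of being threatened per unit covariate."""

    size: float = 0.8          # per SD of log10 max size
    coastal: float = 0.7       # coastal habitat indicator
    freshwater: float = 0.9    # freshwater incursion indicator
    plankton: float = 0.8      # planktivorous diet indicator


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 300
    n_trees: int = 10
    birth_rate: float = 1.0
    bm_sigma2: float = 0.5       # Brownian variance of log10 size over one tree height
    mk_rate: float = 0.7         # Mk transitions per tree height
    coupling: StatusCoupling = StatusCoupling()
    base_threat_rate: float = 0.37   # marginal threatened fraction (378/1015)
    threatened_proportions: tuple[float, float, float] = (0.45, 0.35, 0.20)  # VU, EN, CR
    non_threatened_proportions: tuple[float, float] = (0.8, 0.2)             # LC, NT
    dd_ne_fraction: float = 0.17
    missing_rates: Mapping[str, float] = field(default_factory=lambda: {
        "habitat": 0.007, "terrestriality": 0.001, "diet": 0.35, "max_size": 0.001,
    })
    grid: GridSpec = GridSpec(cell_size=0.5, lon_min=-30.0, lon_max=30.0,
                              lat_min=-60.0, lat_max=60.0)
    richness_gradient: float = 4.0
    range_mu: float = 6.0        # lognormal log-mean of range size in cells
    range_sigma: float = 1.0
    fishing_autocorr: float = 2.0  # gaussian smoothing length, in 1-degree cells
    fishing_mean_hours: float = 200.0
    mpa_coverage: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ElasmodivError("n_species must be at least 2")
        if not 0 <= self.mpa_coverage <= 1:
            raise ElasmodivError("mpa_coverage must lie in [0,1]")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ElasmodivError(f"missing rate for {name} outside [0,1]")


def _sub_seeds(master: int, n: int) -> list[int]:
    """Splittable per-generator substreams derived from the master seed."""
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def generate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_species`` extant tips.

    Tips are relabelled sp0001..spNNNN in a deterministic traversal
    order so the same seed yields byte-identical newick strings.
    """
    if n_species < 2:
        raise ElasmodivError("need at least 2 species")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=random.Random(seed),
    )
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:04d}")
    tree.taxon_namespace = taxa
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def _simulate_bm(tree: dendropy.Tree, root_value: float, sigma2_per_height: float,
                 rng: np.random.Generator) -> dict[str, float]:
    h = tree_height(tree)
    rate = sigma2_per_height / max(h, 1e-12)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            t = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(rate * t))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def _mk_transition(state: int, k: int, rate: float, t: float,
                   rng: np.random.Generator) -> int:
    # symmetric k-state Mk: P(stay) = 1/k + (1 - 1/k) exp(-k * alpha * t)
    # with alpha the per-pair rate; `rate` is the total leaving rate.
    if k == 1 or rate == 0.0 or t == 0.0:
        return state
    alpha = rate / (k - 1)
    p_stay = 1.0 / k + (1.0 - 1.0 / k) * np.exp(-k * alpha * t)
    if rng.random() < p_stay:
        return state
    others = [s for s in range(k) if s != state]
    return others[rng.integers(len(others))]


def _simulate_mk(tree: dendropy.Tree, k: int, rate_per_height: float,
                 rng: np.random.Generator, root_state: int | None = None) -> dict[str, int]:
    h = tree_height(tree)
    rate = rate_per_height / max(h, 1e-12)
    states: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_state if root_state is not None else int(rng.integers(k))
        else:
            t = node.edge.length or 0.0
            states[id(node)] = _mk_transition(states[id(node.parent_node)], k, rate, t, rng)
        if node.is_leaf():
            out[node.taxon.label] = states[id(node)]
    return out


def _clade_groups(tree: dendropy.Tree, depth_fraction: float, prefix: str) -> dict[str, str]:
    """Group tips by the clade their lineage belongs to at a given depth."""
    h = tree_height(tree)
    cut = depth_fraction * h
    groups: dict[str, str] = {}
    counter = [0]

    def assign(node, label):
        for leaf in node.leaf_iter():
            groups[leaf.taxon.label] = label

    def walk(node, depth):
        child_depth_ok = depth >= cut
        if node.is_leaf() or child_depth_ok:
            counter[0] += 1
            assign(node, f"{prefix}{counter[0]:02d}")
            return
        for ch in node.child_nodes():
            walk(ch, depth + (ch.edge.length or 0.0))

    for ch in tree.seed_node.child_nodes():
        walk(ch, ch.edge.length or 0.0)
    if not groups:  # degenerate: single tip
        assign(tree.seed_node, f"{prefix}01")
    return groups


def simulate_traits(tree: dendropy.Tree, schema: TraitSchema | None = None,
                    bm_sigma2: float = 0.5, mk_rate: float = 0.7,
                    seed: int = 0) -> list[SpeciesTraitRecord]:
    """Complete (no missingness) trait records for every tip.

    Continuous size evolves by Brownian motion on the log10 scale and
    is exponentiated; nominal and binary traits follow a symmetric Mk
    process; each multichoice category follows its own two-state Mk
    with at least one category forced present.  Taxonomy (superorder /
    order / family) is read off the clade structure of the tree.
    """
    schema = schema or default_schema()
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 4:
        raise ElasmodivError("need at least 4 tips to simulate traits")
    rng = np.random.default_rng(seed)

    log_size = _simulate_bm(tree, root_value=2.0, sigma2_per_height=bm_sigma2, rng=rng)

    trait_values: dict[str, dict[str, object]] = {}
    for tdef in schema:
        if tdef.kind == "continuous":
            trait_values[tdef.name] = {t: float(10.0 ** log_size[t]) for t in tips}
        elif tdef.kind in ("nominal", "binary"):
            k = len(tdef.categories)
            states = _simulate_mk(tree, k, mk_rate, rng)
            trait_values[tdef.name] = {t: tdef.categories[states[t]] for t in tips}
        else:  # multichoice: independent presence/absence Mk per category
            per_cat = {}
            for cat in tdef.categories:
                root = 1 if rng.random() < 0.6 else 0
                per_cat[cat] = _simulate_mk(tree, 2, mk_rate, rng, root_state=root)
            sets = {}
            for t in tips:
                present = frozenset(c for c in tdef.categories if per_cat[c][t] == 1)
                if not present:
                    present = frozenset({tdef.categories[rng.integers(len(tdef.categories))]})
                sets[t] = present
            trait_values[tdef.name] = sets

    # clade-structured taxonomy
    basal = tree.seed_node.child_nodes()
    superorder = {}
    for i, clade in enumerate(basal):
        name = "Selachii" if i % 2 == 0 else "Batoidea"
        for leaf in clade.leaf_iter():
            superorder[leaf.taxon.label] = name
    orders = _clade_groups(tree, 0.25, "Order")
    families = _clade_groups(tree, 0.5, "Family")

    records = []
    for t in tips:
        records.append(SpeciesTraitRecord(
            species_id=t,
            superorder=superorder.get(t, "Selachii"),
            order=orders[t],
            family=families[t],
            traits={name: trait_values[name][t] for name in schema.names},
        ))
    return records


# ---------------------------------------------------------------------------
# Statuses and missingness
# ---------------------------------------------------------------------------


def assign_statuses(records: Sequence[SpeciesTraitRecord],
                    coupling: StatusCoupling = StatusCoupling(),
                    base_rate: float = 0.3,
                    threatened_proportions: Sequence[float] = (0.45, 0.35, 0.20),
                    non_threatened_proportions: Sequence[float] = (0.8, 0.2),
                    dd_ne_fraction: float = 0.0,
                    seed: int = 0) -> tuple[list[SpeciesTraitRecord], pd.Series]:
    """Fill IUCN statuses from a logistic threat model on four covariates.

    Threat log-odds increase with standardised log size, coastal
    habitat, freshwater incursion, and plankton diet.  Threatened
    species draw VU/EN/CR and the rest LC/NT by the configured
    proportions; ``dd_ne_fraction`` of species are then relabelled
    DD or NE.  Returns the records plus the pre-relabelling truth.
    """
    rng = np.random.default_rng(seed)
    logsize = np.array([np.log10(r.traits["max_size"]) for r in records])
    z = (logsize - logsize.mean()) / (logsize.std() or 1.0)
    # indicators are centred so base_rate is (approximately) the
    # marginal probability of being threatened, not the probability at
    # the all-zero covariate profile
    coastal = np.array([("coastal" in r.traits["habitat"]) for r in records], dtype=float)
    fresh = np.array([("freshwater" in r.traits["terrestriality"]) for r in records], dtype=float)
    plank = np.array([("plankton" in r.traits["diet"]) for r in records], dtype=float)
    coastal -= coastal.mean()
    fresh -= fresh.mean()
    plank -= plank.mean()
    if base_rate <= 0.0:
        p = np.zeros(len(records))
    elif base_rate >= 1.0:
        p = np.ones(len(records))
    else:
        logit = np.log(base_rate / (1 - base_rate))
        eta = (logit + coupling.size * z + coupling.coastal * coastal
               + coupling.freshwater * fresh + coupling.plankton * plank)
        p = 1.0 / (1.0 + np.exp(-eta))
    threatened = rng.random(len(records)) < p
    out = []
    truth = {}
    for i, rec in enumerate(records):
        if threatened[i]:
            cat = rng.choice(["VU", "EN", "CR"], p=np.asarray(threatened_proportions))
        else:
            cat = rng.choice(["LC", "NT"], p=np.asarray(non_threatened_proportions))
        truth[rec.species_id] = cat
        new = dataclasses.replace(rec, iucn=str(cat), imputed_fields=set(rec.imputed_fields))
        out.append(new)
    if dd_ne_fraction > 0:
        mask = rng.random(len(out)) < dd_ne_fraction
        for i, rec in enumerate(out):
            if mask[i]:
                rec.iucn = "DD" if rng.random() < 0.8 else "NE"
    return out, pd.Series(truth, name="iucn_true")


def inject_missingness(records: Sequence[SpeciesTraitRecord],
                       rates: Mapping[str, float],
                       seed: int = 0,
                       schema: TraitSchema | None = None
                       ) -> tuple[list[SpeciesTraitRecord], pd.DataFrame]:
    """Mask trait values completely at random at the given per-trait rates.

    Returns the masked records and a truth table holding the removed
    values (rows = species with at least one masked cell), so recovery
    error can be computed exactly.
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    out = []
    truth_rows: dict[str, dict[str, object]] = {}
    for rec in records:
        new_traits = dict(rec.traits)
        for name, rate in rates.items():
            if rate > 0 and new_traits.get(name) is not None and rng.random() < rate:
                truth_rows.setdefault(rec.species_id, {})[name] = new_traits[name]
                new_traits[name] = None
        out.append(dataclasses.replace(rec, traits=new_traits,
                                       imputed_fields=set(rec.imputed_fields)))
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    return out, truth


# ---------------------------------------------------------------------------
# Ranges, fishing, MPAs
# ---------------------------------------------------------------------------


def generate_ranges(records: Sequence[SpeciesTraitRecord], spec: GridSpec,
                    gradient: float = 4.0, range_mu: float = 6.0,
                    range_sigma: float = 1.0, seed: int = 0) -> OccurrenceGrid:
    """Contiguous rectangular ranges around latitudinally graded centroids.

    Centroid latitude density is proportional to
    ``exp(-gradient * (lat / lat_half_span)^2)`` (uniform when the
    gradient is 0), producing an equatorial richness peak.  Range area
    in cells is lognormal(mu, sigma), capped at the grid size; the
    block is shifted, not clipped, at the grid edge so the realised
    cell count is exact.
    """
    rng = np.random.default_rng(seed)
    n_cols, n_rows = spec.n_cols, spec.n_rows
    half_span = (spec.lat_max - spec.lat_min) / 2.0
    mid = (spec.lat_max + spec.lat_min) / 2.0
    presence = np.zeros((spec.n_cells, len(records)), dtype=bool)
    for j, rec in enumerate(records):
        # rejection-sample the centroid latitude
        while True:
            lat = rng.uniform(spec.lat_min, spec.lat_max)
            if gradient <= 0 or rng.random() < np.exp(-gradient * ((lat - mid) / half_span) ** 2):
                break
        lon = rng.uniform(spec.lon_min, spec.lon_max)
        col0, row0 = spec.cell_index(lon, min(lat, np.nextafter(spec.lat_max, -np.inf)))
        area = int(np.clip(np.round(rng.lognormal(range_mu, range_sigma)), 1, spec.n_cells))
        width = min(int(np.ceil(np.sqrt(area))), n_cols)
        height = int(np.ceil(area / width))
        if height > n_rows:
            height = n_rows
            width = min(int(np.ceil(area / height)), n_cols)
            area = min(area, width * height)
        left = int(np.clip(col0 - width // 2, 0, n_cols - width))
        bottom = int(np.clip(row0 - height // 2, 0, n_rows - height))
        placed = 0
        for r in range(bottom, bottom + height):
            for c in range(left, left + width):
                if placed >= area:
                    break
                presence[spec.flat_index(c, r), j] = True
                placed += 1
    return OccurrenceGrid(spec, [r.species_id for r in records], presence)


def fishing_grid_spec(analysis: GridSpec) -> GridSpec:
    """The 1-degree native grid matching an analysis grid's extent."""
    return GridSpec(cell_size=1.0, lon_min=analysis.lon_min, lon_max=analysis.lon_max,
                    lat_min=analysis.lat_min, lat_max=analysis.lat_max)


def generate_fishing(spec: GridSpec, autocorr_length: float = 2.0,
                     mean_hours: float = 200.0, seed: int = 0,
                     years: tuple[int, int] = (2012, 2020)) -> pd.DataFrame:
    """Autocorrelated 1-degree effort records (cell, gear, hours, year).

    The latent field is exponentiated smoothed Gaussian noise, so
    effort is non-negative and spatially autocorrelated with
    correlation length ``autocorr_length`` (0 gives white noise).  Each
    cell's hours are split across 1-3 target gears plus an occasional
    non-target gear record to exercise the gear filter.
    """
    from .pressure import DEFAULT_GEAR_LIST

    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(spec.n_rows, spec.n_cols))
    if autocorr_length > 0:
        smooth = gaussian_filter(noise, sigma=autocorr_length, mode="wrap")
        smooth *= noise.std() / max(smooth.std(), 1e-12)
    else:
        smooth = noise
    field_hours = mean_hours * np.exp(smooth - smooth.var() / 2.0)
    rows = []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            total = field_hours[r, c]
            n_gears = int(rng.integers(1, 4))
            gears = rng.choice(DEFAULT_GEAR_LIST, size=n_gears, replace=False)
            shares = rng.dirichlet(np.ones(n_gears))
            for g, s in zip(gears, shares):
                rows.append({
                    "cell_id": spec.cell_id(c, r), "gear": str(g),
                    "hours": float(total * s), "year": int(rng.integers(*years)),
                })
            if rng.random() < 0.2:
                rows.append({
                    "cell_id": spec.cell_id(c, r),
                    "gear": str(rng.choice(NON_TARGET_GEARS)),
                    "hours": float(rng.exponential(mean_hours / 10)),
                    "year": int(rng.integers(*years)),
                })
    return pd.DataFrame(rows)


def generate_mpas(spec: GridSpec, coverage: float = 0.06, seed: int = 0) -> pd.DataFrame:
    """Patchy MPA table covering about ``coverage`` of the grid cells.

    Rectangular patches with categories across Ia-VI and designation
    strings that include decoy non-target designations (seabird
    reserves and the like) so the designation filter has work to do.
    """
    from .pressure import MPA_CATEGORIES

    rng = np.random.default_rng(seed)
    target = int(round(coverage * spec.n_cells))
    covered: set[int] = set()
    rows = []
    mpa_counter = 0
    while len(covered) < target:
        mpa_counter += 1
        w = int(rng.integers(1, 6))
        h = int(rng.integers(1, 6))
        left = int(rng.integers(0, max(spec.n_cols - w, 1)))
        bottom = int(rng.integers(0, max(spec.n_rows - h, 1)))
        category = str(rng.choice(MPA_CATEGORIES))
        if rng.random() < 0.15:
            designation = str(rng.choice(DECOY_DESIGNATIONS))
        else:
            designation = str(rng.choice(TARGET_DESIGNATIONS))
        mpa_id = f"MPA{mpa_counter:04d}"
        for r in range(bottom, bottom + h):
            for c in range(left, left + w):
                flat = spec.flat_index(c, r)
                covered.add(flat)
                rows.append({
                    "mpa_id": mpa_id, "category": category,
                    "designation": designation, "cell_id": spec.cell_id(c, r),
                })
        if len(covered) >= target:
            break
    return pd.DataFrame(rows, columns=["mpa_id", "category", "designation", "cell_id"])


# ---------------------------------------------------------------------------
# Benchmark bundle
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkBundle:
    config: SimulationConfig
    records: list[SpeciesTraitRecord]        # with missingness + DD/NE
    records_true: list[SpeciesTraitRecord]   # complete truth
    status_truth: pd.Series
    missing_truth: pd.DataFrame
    trees: list[dendropy.Tree]
    grid: OccurrenceGrid
    fishing: pd.DataFrame
    mpas: pd.DataFrame


def make_bundle(config: SimulationConfig | None = None) -> BenchmarkBundle:
    """Generate the full synthetic benchmark in memory."""
    config = config or SimulationConfig()
    seeds = _sub_seeds(config.seed, 8)
    trees = [generate_tree(config.n_species, config.birth_rate, seed=seeds[0] + i)
             for i in range(config.n_trees)]
    records_complete = simulate_traits(trees[0], bm_sigma2=config.bm_sigma2,
                                       mk_rate=config.mk_rate, seed=seeds[1])
    records_true, status_truth = assign_statuses(
        records_complete, config.coupling, config.base_threat_rate,
        config.threatened_proportions, config.non_threatened_proportions,
        dd_ne_fraction=0.0, seed=seeds[2],
    )
    with_dd, _ = assign_statuses(
        records_complete, config.coupling, config.base_threat_rate,
        config.threatened_proportions, config.non_threatened_proportions,
        dd_ne_fraction=config.dd_ne_fraction, seed=seeds[2],
    )
    records, missing_truth = inject_missingness(with_dd, config.missing_rates, seed=seeds[3])
    grid = generate_ranges(records_true, config.grid, config.richness_gradient,
                           config.range_mu, config.range_sigma, seed=seeds[4])
    fishing = generate_fishing(fishing_grid_spec(config.grid), config.fishing_autocorr,
                               config.fishing_mean_hours, seed=seeds[5])
    mpas = generate_mpas(config.grid, config.mpa_coverage, seed=seeds[6])
    return BenchmarkBundle(config, records, records_true, status_truth,
                           missing_truth, trees, grid, fishing, mpas)


def make_benchmark(config: SimulationConfig | None = None,
                   out_dir: str | Path = "benchmark", force: bool = False) -> Path:
    """Write a complete benchmark directory in the pipeline's file formats."""
    config = config or SimulationConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ElasmodivError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_bundle(config)
    write_trait_table(bundle.records, out / "traits.csv")
    write_trait_table(bundle.records_true, out / "traits_true.csv")
    bundle.missing_truth.to_csv(out / "missing_truth.csv", index_label="species_id")
    bundle.status_truth.to_csv(out / "status_truth.csv", index_label="species_id")
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for i, tree in enumerate(bundle.trees):
        tree.write(path=str(tree_dir / f"tree_{i + 1:03d}.nwk"), schema="newick")
    write_occurrences(bundle.grid, out / "occurrences.csv")
    bundle.fishing.to_csv(out / "fishing_effort.csv", index=False)
    bundle.mpas.to_csv(out / "mpas.csv", index=False)
    manifest = {
        "seed": config.seed,
        "n_species": config.n_species,
        "n_trees": config.n_trees,
        "grid": dataclasses.asdict(config.grid),
        "missing_rates": dict(config.missing_rates),
        "coupling": dataclasses.asdict(config.coupling),
        "base_threat_rate": config.base_threat_rate,
        "dd_ne_fraction": config.dd_ne_fraction,
        "richness_gradient": config.richness_gradient,
        "range_lognormal": [config.range_mu, config.range_sigma],
        "fishing_autocorr": config.fishing_autocorr,
        "mpa_coverage": config.mpa_coverage,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
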