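"""Domain types and I/O for the elasmobranch diversity pipeline.

The pipeline works from five inputs: a species trait table (seven
mixed-type traits plus IUCN status), a sample of phylogenies, species
presence on a regular longitude/latitude grid, gridded fishing-effort
records, and a marine-protected-area table.  This module owns the trait
schema, the grid geometry, the record containers, the CSV/newick
readers and writers, and the analysis-pool filter applied before any
metric is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MULTICHOICE_DELIMITER = ";"

IUCN_CODES = ("LC", "NT", "VU", "EN", "CR", "DD", "NE")
#: Categories carrying an assessed extinction risk, in increasing severity.
IUCN_RANKED = ("LC", "NT", "VU", "EN", "CR")
THREATENED = frozenset({"VU", "EN", "CR"})
NON_THREATENED = frozenset({"LC", "NT"})

SUPERORDERS = ("Selachii", "Batoidea")


class ElasmodivError(Exception):
    """Base class for pipeline errors."""


class ValidationError(ElasmodivError):
    """Raised when an input file or record violates the schema."""


# ---------------------------------------------------------------------------
# Trait schema
# ---------------------------------------------------------------------------

TRAIT_KINDS = ("continuous", "nominal", "multichoice", "binary")


@dataclass(frozen=True)
class TraitDef:
    """Definition of a single trait column.

    ``transform`` currently supports ``None`` or ``"log10"`` and applies
    only to continuous traits (before range normalisation in the Gower
    computation).
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    transform: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ValidationError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if self.kind != "continuous" and not self.categories:
            raise ValidationError(f"trait {self.name!r}: category set must be non-empty")
        if self.kind == "binary" and len(self.categories) != 2:
            raise ValidationError(f"binary trait {self.name!r} needs exactly 2 categories")


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of trait definitions."""

    traits: tuple[TraitDef, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate trait names in schema")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    def __getitem__(self, name: str) -> TraitDef:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def __iter__(self):
        return iter(self.traits)


def default_schema() -> TraitSchema:
    """The seven-trait elasmobranch schema.

    Maximum body size (total length or disc width, cm), habitat
    (coastal/oceanic, possibly both), terrestriality (marine, brackish
    and/or freshwater occurrence), vertical position in the water
    column, diet (one or more of four prey classes), feeding mechanism,
    and thermoregulation.
    """
    return TraitSchema(
        traits=(
            TraitDef("max_size", "continuous", transform="log10"),
            TraitDef("habitat", "multichoice", ("coastal", "oceanic")),
            TraitDef("terrestriality", "multichoice", ("marine", "brackish", "freshwater")),
            TraitDef("vertical_position", "nominal", ("benthic", "benthopelagic", "pelagic")),
            TraitDef("diet", "multichoice", ("high_vertebrates", "fish", "invertebrates", "plankton")),
            TraitDef("feeding", "binary", ("macropredator", "filter_feeder")),
            TraitDef("thermoregulation", "binary", ("ectothermic", "mesothermic")),
        )
    )


# ---------------------------------------------------------------------------
# Species records
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTraitRecord:
    species_id: str
    superorder: str
    order: str
    family: str
    traits: dict  # trait name -> float | str | frozenset | None
    iucn: str | None = None
    imputed_fields: set = field(default_factory=set)

    def validate(self, schema: TraitSchema, context: str = "") -> None:
        for tdef in schema:
            value = self.traits.get(tdef.name)
            if value is None:
                continue
            where = f"{context}species {self.species_id!r}, column {tdef.name!r}"
            if tdef.kind == "continuous":
                if not np.isfinite(value) or value <= 0:
                    raise ValidationError(f"{where}: continuous value must be finite and > 0, got {value!r}")
            elif tdef.kind == "multichoice":
                if not isinstance(value, frozenset) or not value:
                    raise ValidationError(f"{where}: multichoice value must be a non-empty set")
                bad = value - set(tdef.categories)
                if bad:
                    raise ValidationError(f"{where}: unknown category token(s) {sorted(bad)}")
            else:  # nominal / binary
                if value not in tdef.categories:
                    raise ValidationError(f"{where}: unknown category token {value!r}")
        if self.iucn is not None and self.iucn not in IUCN_CODES:
            raise ValidationError(
                f"{context}species {self.species_id!r}: IUCN code {self.iucn!r} not in {IUCN_CODES}"
            )

    @property
    def is_threatened(self) -> bool | None:
        if self.iucn in THREATENED:
            return True
        if self.iucn in NON_THREATENED:
            return False
        return None


def _format_value(tdef: TraitDef, value) -> str:
    if value is None:
        return ""
    if tdef.kind == "multichoice":
        return MULTICHOICE_DELIMITER.join(sorted(value))
    return str(value)


def _parse_value(tdef: TraitDef, raw: str, where: str):
    raw = raw.strip()
    if raw == "" or raw.lower() in {"na", "nan"}:
        return None
    if tdef.kind == "continuous":
        try:
            return float(raw)
        except ValueError as exc:
            raise ValidationError(f"{where}: cannot parse {raw!r} as a number") from exc
    if tdef.kind == "multichoice":
        return frozenset(tok.strip() for tok in raw.split(MULTICHOICE_DELIMITER) if tok.strip())
    return raw


TRAIT_TABLE_COLUMNS = (
    "species_id",
    "superorder",
    "order",
    "family",
    "max_size",
    "habitat",
    "terrestriality",
    "vertical_position",
    "diet",
    "feeding",
    "thermoregulation",
    "iucn",
)


def read_trait_table(path: str | Path, schema: TraitSchema | None = None) -> list[SpeciesTraitRecord]:
    """Read a species trait CSV into validated records.

    Multichoice cells are ``;``-separated token sets; empty cells are
    missing values.  Duplicate species ids and unknown category tokens
    raise :class:`ValidationError` naming the offending row/column.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in ("species_id", "superorder", "order", "family") + schema.names if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing column(s) {missing_cols}")
    records: list[SpeciesTraitRecord] = []
    seen: set[str] = set()
    imputed_col = "imputed_fields" if "imputed_fields" in df.columns else None
    for i, row in df.iterrows():
        sid = row["species_id"].strip()
        if not sid:
            raise ValidationError(f"{path} row {i}: empty species_id")
        if sid in seen:
            raise ValidationError(f"{path} row {i}: duplicate species_id {sid!r}")
        seen.add(sid)
        where = f"{path} row {i}"
        traits = {t.name: _parse_value(t, row[t.name], f"{where}, column {t.name!r}") for t in schema}
        iucn = row.get("iucn", "").strip() or None
        imputed: set[str] = set()
        if imputed_col and row[imputed_col].strip():
            imputed = set(row[imputed_col].split(MULTICHOICE_DELIMITER))
        rec = SpeciesTraitRecord(
            species_id=sid,
            superorder=row["superorder"].strip(),
            order=row["order"].strip(),
            family=row["family"].strip(),
            traits=traits,
            iucn=iucn,
            imputed_fields=imputed,
        )
        rec.validate(schema, context=f"{where}: ")
        records.append(rec)
    return records


def write_trait_table(records: Sequence[SpeciesTraitRecord], path: str | Path,
                      schema: TraitSchema | None = None) -> None:
    schema = schema or default_schema()
    rows = []
    for rec in records:
        row = {
            "species_id": rec.species_id,
            "superorder": rec.superorder,
            "order": rec.order,
            "family": rec.family,
            "iucn": rec.iucn or "",
            "imputed_fields": MULTICHOICE_DELIMITER.join(sorted(rec.imputed_fields)),
        }
        for tdef in schema:
            row[tdef.name] = _format_value(tdef, rec.traits.get(tdef.name))
        rows.append(row)
    cols = list(TRAIT_TABLE_COLUMNS) + ["imputed_fields"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Extinction probabilities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtinctionProbabilityMap:
    """IUCN category -> probability of extinction over a 100-year horizon."""

    probabilities: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        for cat in IUCN_RANKED:
            if cat not in probs:
                raise ValidationError(f"extinction-probability map missing category {cat}")
            p = probs[cat]
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability for {cat} outside [0,1]: {p}")
        ranked = [probs[c] for c in IUCN_RANKED]
        if any(a > b for a, b in zip(ranked, ranked[1:])):
            raise ValidationError("extinction probabilities must be non-decreasing LC<=NT<=VU<=EN<=CR")

    def __getitem__(self, category: str) -> float:
        try:
            return self.probabilities[category]
        except KeyError as exc:
            raise ValidationError(
                f"no extinction probability for IUCN category {category!r}; "
                "DD/NE statuses must be imputed before scoring"
            ) from exc

    def for_records(self, records: Sequence[SpeciesTraitRecord]) -> pd.Series:
        return pd.Series({r.species_id: self[r.iucn] for r in records}, name="GE")


#: 100-year extinction probabilities per IUCN category (the "IUCN100"
#: transformation commonly used with the HED/EDGE family of metrics).
IUCN100_MOOERS2008 = ExtinctionProbabilityMap(
    probabilities={"LC": 0.001, "NT": 0.01, "VU": 0.1, "EN": 0.667, "CR": 0.999},
    name="IUCN100-Mooers2008",
)

EXTINCTION_PROBABILITY_PRESETS = {"IUCN100-Mooers2008": IUCN100_MOOERS2008}


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------


def read_trees(paths: Iterable[str | Path]) -> list[dendropy.Tree]:
    """Read newick tree files (each file may hold one or more trees)."""
    trees: list[dendropy.Tree] = []
    for path in paths:
        tl = dendropy.TreeList.get(path=str(path), schema="newick")
        trees.extend(tl)
    if not trees:
        raise ValidationError("no trees found")
    for tree in trees:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValidationError("tree has duplicate tip labels")
    return trees


def tree_tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Grid geometry and occurrences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat lattice with half-open cells.

    Cells are ``[west, east) x [south, north)``; the cell id is the
    integer pair ``(col, row)`` counted from the (lon_min, lat_min)
    origin, serialised as ``"col:row"`` in CSV files.
    """

    cell_size: float = 0.5
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        for span in (self.lon_max - self.lon_min, self.lat_max - self.lat_min):
            if span <= 0 or abs(span / self.cell_size - round(span / self.cell_size)) > 1e-9:
                raise ValidationError("grid extent must be a positive whole number of cells")

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a coordinate to its (col, row) cell; total and deterministic."""
        if not (self.lon_min <= lon < self.lon_max) and lon != self.lon_max:
            raise ValidationError(f"longitude {lon} outside [{self.lon_min}, {self.lon_max})")
        if not (self.lat_min <= lat < self.lat_max) and lat != self.lat_max:
            raise ValidationError(f"latitude {lat} outside [{self.lat_min}, {self.lat_max})")
        col = min(int((lon - self.lon_min) / self.cell_size), self.n_cols - 1)
        row = min(int((lat - self.lat_min) / self.cell_size), self.n_rows - 1)
        return col, row

    def flat_index(self, col: int, row: int) -> int:
        return row * self.n_cols + col

    def cell_center(self, col: int, row: int) -> tuple[float, float]:
        return (
            self.lon_min + (col + 0.5) * self.cell_size,
            self.lat_min + (row + 0.5) * self.cell_size,
        )

    def cell_id(self, col: int, row: int) -> str:
        return f"{col}:{row}"

    def parse_cell_id(self, cell_id: str) -> tuple[int, int]:
        try:
            col_s, row_s = cell_id.split(":")
            col, row = int(col_s), int(row_s)
        except ValueError as exc:
            raise ValidationError(f"malformed cell id {cell_id!r} (expected 'col:row')") from exc
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValidationError(f"cell id {cell_id!r} outside grid")
        return col, row

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centre arrays aligned with flat cell indices."""
        cols = np.arange(self.n_cells) % self.n_cols
        rows = np.arange(self.n_cells) // self.n_cols
        return (
            self.lon_min + (cols + 0.5) * self.cell_size,
            self.lat_min + (rows + 0.5) * self.cell_size,
        )


@dataclass
class OccurrenceGrid:
    """Boolean presence matrix (flat cells x species) on a GridSpec."""

    spec: GridSpec
    species: list[str]
    presence: np.ndarray  # bool, shape (n_cells, n_species)

    def __post_init__(self) -> None:
        if self.presence.shape != (self.spec.n_cells, len(self.species)):
            raise ValidationError("presence matrix shape does not match grid/species")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species in occurrence grid")
        self.presence = self.presence.astype(bool)

    def species_richness(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def occupied_cells(self) -> np.ndarray:
        return np.flatnonzero(self.presence.any(axis=1))

    def subset_species(self, keep: Sequence[str]) -> "OccurrenceGrid":
        idx = [self.species.index(s) for s in keep]
        return OccurrenceGrid(self.spec, list(keep), self.presence[:, idx].copy())

    def species_cell_count(self) -> pd.Series:
        return pd.Series(self.presence.sum(axis=0), index=self.species, name="range_cells")

    def species_centroid_latitude(self) -> pd.Series:
        _, lat = self.spec.centers()
        out = {}
        for j, sp in enumerate(self.species):
            cells = self.presence[:, j]
            out[sp] = float(lat[cells].mean()) if cells.any() else np.nan
        return pd.Series(out, name="centroid_lat")


def read_occurrences(path: str | Path, spec: GridSpec,
                     known_species: Sequence[str] | None = None,
                     drop_unknown: bool = True) -> OccurrenceGrid:
    """Long-format occurrence CSV -> OccurrenceGrid.

    Accepts either (species_id, lon, lat) or (species_id, cell_id)
    columns.  Repeated presences collapse; species not in
    ``known_species`` are dropped with a warning (or raise if
    ``drop_unknown`` is false).
    """
    df = pd.read_csv(path, dtype={"species_id": str})
    if "species_id" not in df.columns:
        raise ValidationError(f"{path}: missing species_id column")
    if known_species is not None:
        unknown = sorted(set(df["species_id"]) - set(known_species))
        if unknown:
            msg = f"{path}: {len(unknown)} species not in trait table (e.g. {unknown[:3]})"
            if not drop_unknown:
                raise ValidationError(msg)
            logger.warning("%s; dropping", msg)
            df = df[~df["species_id"].isin(unknown)]
    species = sorted(df["species_id"].unique())
    presence = np.zeros((spec.n_cells, len(species)), dtype=bool)
    sp_index = {s: j for j, s in enumerate(species)}
    if {"lon", "lat"} <= set(df.columns):
        for sid, lon, lat in df[["species_id", "lon", "lat"]].itertuples(index=False):
            col, row = spec.cell_index(float(lon), float(lat))
            presence[spec.flat_index(col, row), sp_index[sid]] = True
    elif "cell_id" in df.columns:
        for sid, cid in df[["species_id", "cell_id"]].itertuples(index=False):
            col, row = spec.parse_cell_id(str(cid))
            presence[spec.flat_index(col, row), sp_index[sid]] = True
    else:
        raise ValidationError(f"{path}: need (lon, lat) or cell_id columns")
    return OccurrenceGrid(spec, species, presence)


def write_occurrences(grid: OccurrenceGrid, path: str | Path) -> None:
    cells, species_idx = np.nonzero(grid.presence)
    n_cols = grid.spec.n_cols
    rows = {
        "species_id": [grid.species[j] for j in species_idx],
        "cell_id": [grid.spec.cell_id(int(c % n_cols), int(c // n_cols)) for c in cells],
    }
    pd.DataFrame(rows).sort_values(["species_id", "cell_id"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis-pool filtering
# ---------------------------------------------------------------------------


@dataclass
class PoolFilterResult:
    records: list[SpeciesTraitRecord]
    grid: OccurrenceGrid
    excluded_cells: np.ndarray  # bool per flat cell: SR < threshold, excluded from FRic
    drop_counts: dict[str, int]


def filter_analysis_pool(records: Sequence[SpeciesTraitRecord],
                         grid: OccurrenceGrid,
                         trees: Sequence[dendropy.Tree] | None = None,
                         min_cell_richness: int = 4) -> PoolFilterResult:
    """Restrict the species pool to the analysable intersection.

    Drops exclusively freshwater species, species missing from the grid
    or from any supplied tree, and species present only in cells below
    the richness threshold; those cells are flagged as excluded from
    hull-based richness.  Iterates to a fixed point so the operation is
    idempotent.
    """
    drop_counts = {"freshwater_only": 0, "not_on_grid": 0, "not_on_tree": 0,
                   "only_in_sparse_cells": 0}
    by_id = {r.species_id: r for r in records}

    keep: list[str] = []
    tree_tips: set[str] | None = None
    if trees:
        tree_tips = set.intersection(*(tree_tip_labels(t) for t in trees))
    grid_species = set(grid.species)
    for rec in records:
        terr = rec.traits.get("terrestriality")
        if terr is not None and terr == frozenset({"freshwater"}):
            drop_counts["freshwater_only"] += 1
            continue
        if rec.species_id not in grid_species:
            drop_counts["not_on_grid"] += 1
            logger.warning("species %s absent from grid; dropped", rec.species_id)
            continue
        if tree_tips is not None and rec.species_id not in tree_tips:
            drop_counts["not_on_tree"] += 1
            continue
        keep.append(rec.species_id)

    sub = grid.subset_species(keep)
    # fixed point: excluding sparse cells can orphan species, which can
    # thin further cells below the threshold
    while True:
        sr = sub.presence.sum(axis=1)
        excluded = (sr > 0) & (sr < min_cell_richness)
        reachable = sub.presence[~excluded].any(axis=0)
        if reachable.all():
            break
        dropped = int((~reachable).sum())
        drop_counts["only_in_sparse_cells"] += dropped
        keep = [s for s, ok in zip(sub.species, reachable) if ok]
        sub = sub.subset_species(keep)
    if not keep:
        raise ElasmodivError("analysis pool empty after filtering")
    sr = sub.presence.sum(axis=1)
    excluded = (sr > 0) & (sr < min_cell_richness)
    return PoolFilterResult(
        records=[replace(by_id[s]) for s in sub.species],
        grid=sub,
        excluded_cells=excluded,
        drop_counts=drop_counts,
    )
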