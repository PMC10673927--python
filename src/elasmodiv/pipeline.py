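"""End-to-end orchestration: impute -> space -> scores -> phylo ->
spatial -> hotspots/congruence -> pressure/protection.

`run_all` drives the whole analysis from a directory in the benchmark
layout (traits.csv, trees/*.nwk, occurrences.csv, fishing_effort.csv,
mpas.csv) and writes every intermediate table plus a machine-readable
summary JSON.  `summarize_by_group` and `reproduce_from_trait_table`
expose the species-level headline numbers (group convex-hull richness,
inertia fraction, group counts) on their own.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import imputation, pressure, spatial
from .core import (
    ElasmodivError,
    EXTINCTION_PROBABILITY_PRESETS,
    ExtinctionProbabilityMap,
    GridSpec,
    OccurrenceGrid,
    SpeciesTraitRecord,
    THREATENED,
    default_schema,
    filter_analysis_pool,
    read_occurrences,
    read_trait_table,
    read_trees,
)
from .functional_space import inertia_explained, pcoa, space_quality_msd, trait_gower_matrix
from .hotspots import congruence_test, detect_hotspots
from .phylo_scores import phylo_score_table
from .species_scores import functional_richness, species_score_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str = "benchmark"
    output_dir: str = "run"
    axes: int = 3
    fun_k: int = 5
    hotspot_q: tuple[float, ...] = (0.025, 0.05, 0.10)
    n_perm: int = 999
    imputation_reps: int = 10
    rf_trees: int = 100
    predictors: str = "all"
    probability_map: str = "IUCN100-Mooers2008"
    min_cell_richness: int = 4
    kriging_radius: float = 3.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "hotspot_q" in data:
            data["hotspot_q"] = tuple(data["hotspot_q"])
        return cls(**data)

    def resolve_probability_map(self) -> ExtinctionProbabilityMap:
        try:
            return EXTINCTION_PROBABILITY_PRESETS[self.probability_map]
        except KeyError as exc:
            raise ElasmodivError(
                f"unknown extinction-probability map {self.probability_map!r}; "
                f"presets: {sorted(EXTINCTION_PROBABILITY_PRESETS)}"
            ) from exc


def summarize_by_group(space, score_table: pd.DataFrame,
                       records: Sequence[SpeciesTraitRecord],
                       grouping: str = "order") -> pd.DataFrame:
    """Per-group species count, FRic (% of pool hull) and FUn/FSp/FUSE
    summaries.  ``grouping`` is superorder | order | threat_status."""
    if grouping == "threat_status":
        def key(rec):
            t = rec.is_threatened
            if t is None:
                return "unassessed"
            return "threatened" if t else "non_threatened"
    elif grouping in ("superorder", "order", "family"):
        def key(rec):
            return getattr(rec, grouping)
    else:
        raise ElasmodivError(f"unknown grouping {grouping!r}")
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec.species_id)
    rows = []
    for name, members in sorted(groups.items()):
        fr = functional_richness(space, members)
        sub = score_table.loc[score_table.index.intersection(members)]
        rows.append({
            "group": name,
            "n_species": len(members),
            "FRic": fr.percent if fr.percent is not None else np.nan,
            "FRic_reason": fr.reason or "",
            "FUn_mean": sub["FUn"].mean(),
            "FUn_median": sub["FUn"].median(),
            "FSp_mean": sub["FSp"].mean(),
            "FSp_median": sub["FSp"].median(),
            "FUSE_mean": sub["FUSE"].mean() if "FUSE" in sub else np.nan,
            "FUSE_median": sub["FUSE"].median() if "FUSE" in sub else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")


def reproduce_from_trait_table(path: str | Path, axes: int = 3,
                               pext: ExtinctionProbabilityMap | None = None) -> dict:
    """Species-level headline numbers from a completed trait table.

    Builds the Gower dissimilarity and PCoA space from an imputed
    trait CSV and reports the retained-axis inertia fraction, group
    counts and group FRic percentages (superorders, orders, threat
    classes).  This is the analysis surface to compare against
    published species-level values when the corresponding trait table
    is supplied.
    """
    records = read_trait_table(path)
    missing = [r.species_id for r in records
               if any(r.traits.get(n) is None for n in default_schema().names)]
    if missing:
        raise ElasmodivError(f"trait table has missing values (e.g. {missing[:3]}); impute first")
    dissim = trait_gower_matrix(records)
    space_full = pcoa(dissim)
    space = space_full.subspace(min(axes, space_full.n_axes))
    inertia = inertia_explained(space_full, min(axes, space_full.n_axes))
    pext = pext or EXTINCTION_PROBABILITY_PRESETS["IUCN100-Mooers2008"]
    assessed = all(r.iucn in ("LC", "NT", "VU", "EN", "CR") for r in records)
    score = species_score_table(space, records, pext) if assessed else pd.DataFrame(
        {"FUn": [], "FSp": [], "FUSE": []})
    out = {
        "n_species": len(records),
        "inertia_pct": 100.0 * inertia,
        "msd": space_quality_msd(dissim, space_full, dims=(2, 3, 4, 5, 6)),
        "superorder": summarize_by_group(space, score, records, "superorder"),
        "order": summarize_by_group(space, score, records, "order"),
        "threat_status": summarize_by_group(space, score, records, "threat_status"),
    }
    return out


def _cell_series(table: pd.DataFrame, column: str) -> pd.Series:
    return table[column].astype(float)


CONGRUENCE_PAIRS = (
    ("FRic", "SR"),
    ("SR", "PD_mean"),
    ("FUn_local", "PUn"),
    ("top25_FUSE", "top25_EDGE2"),
)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage and write a run directory.

    Any stage failure is re-raised with the stage name attached so the
    offending input is identifiable.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inp = Path(config.input_dir)
    rng_seed = config.seed
    pext = config.resolve_probability_map()
    summary: dict = {"config": dataclasses.asdict(config)}
    stage = "inputs"
    try:
        records = read_trait_table(inp / "traits.csv")
        tree_paths = sorted((inp / "trees").glob("*.nwk"))
        if not tree_paths:
            raise ElasmodivError(f"no newick trees under {inp / 'trees'}")
        trees = read_trees(tree_paths)
        # grid spec from manifest when present, else global half-degree
        manifest_path = inp / "manifest.json"
        if manifest_path.exists():
            g = json.loads(manifest_path.read_text())["grid"]
            spec = GridSpec(**g)
        else:
            spec = GridSpec()
        grid = read_occurrences(inp / "occurrences.csv", spec,
                                known_species=[r.species_id for r in records])

        stage = "pool_filtering"
        pool = filter_analysis_pool(records, grid, trees,
                                    min_cell_richness=config.min_cell_richness)
        summary["pool"] = {"n_species": len(pool.records),
                           "drop_counts": pool.drop_counts,
                           "n_excluded_cells": int(pool.excluded_cells.sum())}
        pool_ids = {r.species_id for r in pool.records}
        for tree in trees:
            tree.retain_taxa_with_labels(pool_ids)

        stage = "imputation"
        needs = any(
            any(r.traits.get(n) is None for n in default_schema().names)
            or r.iucn not in ("LC", "NT", "VU", "EN", "CR")
            for r in pool.records
        )
        if needs:
            result = imputation.impute_multiple(
                pool.records, n_reps=config.imputation_reps,
                predictors=config.predictors, grid=pool.grid,
                n_trees=config.rf_trees, seed=rng_seed)
            completed = result.completed
            summary["imputation"] = {"replicates": result.n_replicates,
                                     "iterations": result.iteration_counts,
                                     "predictors": result.predictors}
        else:
            completed = list(pool.records)
            summary["imputation"] = {"replicates": 0, "note": "no missing values"}
        from .core import write_trait_table
        write_trait_table(completed, out / "traits_imputed.csv")

        stage = "functional_space"
        dissim = trait_gower_matrix(completed)
        space_full = pcoa(dissim)
        space = space_full.subspace(config.axes)
        inertia = inertia_explained(space_full, config.axes)
        msd = space_quality_msd(dissim, space_full)
        dissim.to_frame().to_csv(out / "dissimilarity.csv")
        space.coords_frame().to_csv(out / "coordinates.csv")
        summary["functional_space"] = {
            "axes": config.axes,
            "inertia_pct": 100.0 * inertia,
            "msd": {str(k): v for k, v in msd.items()},
            "correction": space.correction,
        }

        stage = "species_scores"
        scores = species_score_table(space, completed, pext, k=config.fun_k)
        scores.to_csv(out / "species_scores.csv")
        for grouping in ("superorder", "order", "threat_status"):
            tbl = summarize_by_group(space, scores, completed, grouping)
            tbl.to_csv(out / f"summary_{grouping}.csv")
            summary[f"fric_{grouping}"] = tbl["FRic"].round(4).to_dict()
            summary[f"n_{grouping}"] = tbl["n_species"].to_dict()

        stage = "phylo_scores"
        pmap = {r.species_id: pext[r.iucn] for r in completed}
        phylo = phylo_score_table(trees, pmap)
        phylo.to_csv(out / "phylo_scores.csv")

        stage = "spatial_metrics"
        cells = spatial.cell_metrics(pool.grid, space, scores, phylo, trees,
                                     excluded_cells=pool.excluded_cells,
                                     min_fric_richness=config.min_cell_richness)
        cells.to_csv(out / "cell_metrics.csv", index_label="cell_id")

        stage = "hotspots_congruence"
        q0 = config.hotspot_q[0]
        congruence: dict[str, dict] = {}
        for a, b in CONGRUENCE_PAIRS:
            if a not in cells.columns or b not in cells.columns:
                continue
            res = congruence_test(_cell_series(cells, a), _cell_series(cells, b),
                                  q=q0, n_perm=config.n_perm, seed=rng_seed)
            congruence[f"{a}_vs_{b}"] = res.to_dict()
        summary["congruence"] = congruence

        stage = "fishing_pressure"
        fishing_records = pd.read_csv(inp / "fishing_effort.csv")
        coarse_spec = GridSpec(cell_size=1.0, lon_min=spec.lon_min, lon_max=spec.lon_max,
                               lat_min=spec.lat_min, lat_max=spec.lat_max)
        coarse = pressure.fishing_index(fishing_records, coarse_spec)
        fine = pressure.krige_to_grid(coarse, spec, radius=config.kriging_radius)
        fine.to_series().to_csv(out / "fishing_index.csv", header=True)
        fishing_series = fine.to_series().reindex(cells.index)

        stage = "protection"
        mpas_raw = pd.read_csv(inp / "mpas.csv")
        mpas, removed = pressure.filter_mpas(mpas_raw)
        protected = pressure.mpa_cell_set(mpas)
        protection: dict[str, dict] = {}
        hotspot_rows = []
        for metric in ("FRic", "SR", "FUn_local", "FSp_mean", "PUn", "top25_FUSE", "top25_EDGE2"):
            if metric not in cells.columns:
                continue
            try:
                mask = detect_hotspots(_cell_series(cells, metric), q=q0)
            except ElasmodivError:
                continue
            hs = set(mask.hotspot_cells())
            protection[metric] = pressure.protection_overlap(hs, protected)
            protection[metric]["n_hotspots"] = mask.n_hotspots
            for cid in hs:
                hotspot_rows.append({"metric": metric, "cell_id": cid})
        try:
            fmask = detect_hotspots(fishing_series.dropna(), q=q0)
            protection["fishing"] = {"n_hotspots": fmask.n_hotspots}
        except ElasmodivError:
            pass
        pd.DataFrame(hotspot_rows).to_csv(out / "hotspot_cells.csv", index=False)
        curve = pressure.cumulative_protection_curve(_cell_series(cells, "SR"), protected)
        curve.to_csv(out / "protection_curve_SR.csv", index=False)
        summary["protection"] = protection
        summary["mpa_filtering"] = removed
    except Exception as exc:
        raise ElasmodivError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj
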