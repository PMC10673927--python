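"""Iterative random-forest imputation of missing traits and IUCN status.

Re-implementation of the missForest procedure: missing cells start at
the column mean/mode, then variables are revisited in order of
increasing missingness, each fitted with a random forest (100 trees)
on the currently completed data and re-predicted, until the change in
imputed values first increases (tracked separately for continuous and
categorical variables) or an iteration cap is reached.  The run is
repeated (ten times by default) and replicates are aggregated by the
modal value (median for the continuous trait).

Predictor sets mirror the three configurations used for elasmobranch
traits: traits + taxonomy, geography + taxonomy, or all of the above
(the pipeline default).  Taxonomy enters as one-hot family indicators;
geography as range size (cells) and range centroid latitude.
DD and NE statuses are treated as missing and imputed on the 5-level
LC/NT/VU/EN/CR scale.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .core import (
    MULTICHOICE_DELIMITER,
    ElasmodivError,
    IUCN_RANKED,
    OccurrenceGrid,
    SpeciesTraitRecord,
    TraitSchema,
    default_schema,
)

logger = logging.getLogger(__name__)

PREDICTOR_SETS = ("traits", "geo", "all")


def _to_cell(tdef_kind: str, value):
    if value is None:
        return np.nan
    if tdef_kind == "multichoice":
        return MULTICHOICE_DELIMITER.join(sorted(value))
    if tdef_kind == "continuous":
        return float(value)
    return value


def _from_cell(tdef_kind: str, value):
    if tdef_kind == "multichoice":
        return frozenset(str(value).split(MULTICHOICE_DELIMITER))
    if tdef_kind == "continuous":
        return float(value)
    return value


def records_to_frame(records: Sequence[SpeciesTraitRecord],
                     schema: TraitSchema) -> pd.DataFrame:
    """Records -> imputation frame; multichoice sets become combination
    labels and DD/NE statuses become NaN."""
    rows = {}
    for rec in records:
        row = {t.name: _to_cell(t.kind, rec.traits.get(t.name)) for t in schema}
        row["iucn"] = rec.iucn if rec.iucn in IUCN_RANKED else np.nan
        row["family"] = rec.family
        row["order"] = rec.order
        row["superorder"] = rec.superorder
        rows[rec.species_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def frame_to_records(frame: pd.DataFrame, records: Sequence[SpeciesTraitRecord],
                     schema: TraitSchema) -> list[SpeciesTraitRecord]:
    """Write completed frame values back into copies of the records,
    tagging the cells that were filled in ``imputed_fields``."""
    out = []
    for rec in records:
        row = frame.loc[rec.species_id]
        traits = dict(rec.traits)
        imputed = set(rec.imputed_fields)
        for tdef in schema:
            if traits.get(tdef.name) is None:
                traits[tdef.name] = _from_cell(tdef.kind, row[tdef.name])
                imputed.add(tdef.name)
        iucn = rec.iucn
        if iucn not in IUCN_RANKED:
            iucn = str(row["iucn"])
            imputed.add("iucn")
        out.append(dataclasses.replace(rec, traits=traits, iucn=iucn,
                                       imputed_fields=imputed))
    return out


@dataclass
class ImputationResult:
    completed: list[SpeciesTraitRecord]
    replicates: list[pd.DataFrame]
    iteration_counts: list[int]
    convergence: list[dict[str, float]]
    predictors: str

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass
class ImputationErrorReport:
    error_percent: dict[str, float]   # categorical variables, 0..100 (NaN when none imputed)
    nrmse: dict[str, float]           # continuous variables
    masked_counts: dict[str, int]
    seed: int = 0


def _geography_columns(records: Sequence[SpeciesTraitRecord],
                       grid: OccurrenceGrid) -> pd.DataFrame:
    cells = grid.species_cell_count()
    lats = grid.species_centroid_latitude()
    ids = [r.species_id for r in records]
    geo = pd.DataFrame({
        "range_cells": cells.reindex(ids),
        "centroid_lat": lats.reindex(ids),
    }, index=ids)
    return geo.fillna(geo.median())


def _encode(frame: pd.DataFrame, continuous: set[str],
            multichoice: Mapping[str, Sequence[str]] = {}) -> pd.DataFrame:
    """One-hot encoding for forests; multichoice columns become
    per-category membership indicators (not combination dummies) so
    category-level signal is directly visible to the trees."""
    parts = []
    for col in frame.columns:
        if col in continuous:
            parts.append(frame[[col]].astype(float))
        elif col in multichoice:
            tokens = frame[col].astype(str).str.split(MULTICHOICE_DELIMITER)
            for cat in multichoice[col]:
                parts.append(tokens.apply(lambda s: float(cat in s)).rename(f"{col}__{cat}"))
        else:
            parts.append(pd.get_dummies(frame[col].astype(str), prefix=col, dtype=float))
    return pd.concat(parts, axis=1)


def impute_once(records: Sequence[SpeciesTraitRecord],
                predictors: str = "all",
                grid: OccurrenceGrid | None = None,
                n_trees: int = 100,
                seed: int = 0,
                max_iter: int = 10,
                schema: TraitSchema | None = None) -> tuple[pd.DataFrame, int, dict[str, float]]:
    """One missForest pass; returns (completed frame, iterations, deltas).

    The frame holds trait columns plus ``iucn``; observed cells are
    never altered.  With no missing values the input frame is returned
    unchanged after zero iterations.
    """
    if predictors not in PREDICTOR_SETS:
        raise ElasmodivError(f"predictors must be one of {PREDICTOR_SETS}")
    if predictors in ("geo", "all") and grid is None:
        raise ElasmodivError("geography predictors requested but no occurrence grid given")
    schema = schema or default_schema()
    if len(records) < 20:
        logger.warning("imputing with only %d records; fits may be unstable", len(records))
    frame = records_to_frame(records, schema)
    continuous = {t.name for t in schema if t.kind == "continuous"}
    impute_cols = [c for c in list(schema.names) + ["iucn"] if frame[c].isna().any()]
    for col in impute_cols:
        if frame[col].isna().all():
            raise ElasmodivError(f"variable {col!r} missing in every row; cannot impute")
    if not impute_cols:
        return frame.drop(columns=["family", "order", "superorder"]), 0, {}

    target_cols = list(schema.names) + ["iucn"]
    if predictors == "geo":
        # geography + taxonomy only: trait columns are not predictors
        predictor_pool = ["family", "superorder"]
    else:
        predictor_pool = target_cols + ["family", "superorder"]
    work = frame.copy()
    if predictors in ("geo", "all"):
        geo = _geography_columns(records, grid)
        work = pd.concat([work, geo], axis=1)
        predictor_pool = predictor_pool + list(geo.columns)
        continuous_pred = continuous | set(geo.columns)
    else:
        continuous_pred = set(continuous)

    multichoice = {t.name: t.categories for t in schema if t.kind == "multichoice"}
    missing_mask = {c: frame[c].isna().values for c in impute_cols}
    # initialise with column mean / mode
    for col in impute_cols:
        if col in continuous:
            work.loc[missing_mask[col], col] = frame[col].mean()
        else:
            work.loc[missing_mask[col], col] = frame[col].mode().iloc[0]
    order = sorted(impute_cols, key=lambda c: missing_mask[c].sum())

    rng = np.random.default_rng(seed)
    prev = work.copy()
    best = work.copy()
    last_cont, last_cat = np.inf, np.inf
    deltas: dict[str, float] = {}
    iters = 0
    for iteration in range(max_iter):
        iters = iteration + 1
        for col in order:
            mask = missing_mask[col]
            feats = [c for c in predictor_pool if c != col]
            X = _encode(work[feats], continuous_pred, multichoice)
            rf_seed = int(rng.integers(2 ** 31))
            if col in continuous:
                model = RandomForestRegressor(n_estimators=n_trees, random_state=rf_seed,
                                              n_jobs=1)
                model.fit(X[~mask], work.loc[~mask, col].astype(float))
                work.loc[mask, col] = model.predict(X[mask])
            else:
                model = RandomForestClassifier(n_estimators=n_trees, random_state=rf_seed,
                                               n_jobs=1)
                model.fit(X[~mask], work.loc[~mask, col].astype(str))
                work.loc[mask, col] = model.predict(X[mask])
        # convergence deltas over imputed cells
        cont_num = cont_den = 0.0
        cat_changes = cat_total = 0
        for col in order:
            mask = missing_mask[col]
            if col in continuous:
                new = work.loc[mask, col].astype(float).values
                old = prev.loc[mask, col].astype(float).values
                cont_num += float(np.sum((new - old) ** 2))
                cont_den += float(np.sum(new ** 2))
            else:
                cat_changes += int((work.loc[mask, col] != prev.loc[mask, col]).sum())
                cat_total += int(mask.sum())
        d_cont = cont_num / cont_den if cont_den > 0 else 0.0
        d_cat = cat_changes / cat_total if cat_total > 0 else 0.0
        deltas = {"continuous": d_cont, "categorical": d_cat}
        worse_cont = cont_den > 0 and d_cont > last_cont
        worse_cat = cat_total > 0 and d_cat > last_cat
        if (worse_cont or cont_den == 0) and (worse_cat or cat_total == 0) and iteration > 0:
            work = prev  # missForest returns the previous iterate
            break
        best = work.copy()
        prev = work.copy()
        last_cont, last_cat = d_cont, d_cat
        if d_cont == 0.0 and d_cat == 0.0:
            break
    completed = best[target_cols].copy()
    return completed, iters, deltas


def impute_multiple(records: Sequence[SpeciesTraitRecord],
                    n_reps: int = 10,
                    predictors: str = "all",
                    grid: OccurrenceGrid | None = None,
                    n_trees: int = 100,
                    seed: int = 0,
                    max_iter: int = 10,
                    schema: TraitSchema | None = None) -> ImputationResult:
    """Repeat the imputation and aggregate replicates by modal value."""
    if n_reps < 1:
        raise ElasmodivError("n_reps must be at least 1")
    schema = schema or default_schema()
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    replicates, iter_counts, convergence = [], [], []
    for child in seeds:
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        frame, iters, deltas = impute_once(records, predictors, grid, n_trees,
                                           seed=rep_seed, max_iter=max_iter, schema=schema)
        replicates.append(frame)
        iter_counts.append(iters)
        convergence.append(deltas)
    result = ImputationResult(completed=[], replicates=replicates,
                              iteration_counts=iter_counts,
                              convergence=convergence, predictors=predictors)
    result.completed = aggregate_modal(result, records, schema)
    return result


def aggregate_modal(result: ImputationResult,
                    records: Sequence[SpeciesTraitRecord],
                    schema: TraitSchema | None = None) -> list[SpeciesTraitRecord]:
    """Modal aggregation across replicates (median for continuous).

    Categorical ties break to the lexicographically smallest label,
    logged.  Invariant to replicate order.
    """
    schema = schema or default_schema()
    continuous = {t.name for t in schema if t.kind == "continuous"}
    base = result.replicates[0]
    agg = base.copy()
    for col in base.columns:
        stack = pd.concat([rep[col] for rep in result.replicates], axis=1)
        if col in continuous:
            agg[col] = stack.astype(float).median(axis=1)
        else:
            def modal(row):
                counts = Counter(row)
                top = max(counts.values())
                winners = sorted(k for k, v in counts.items() if v == top)
                if len(winners) > 1:
                    logger.info("modal tie %s -> %s", winners, winners[0])
                return winners[0]
            agg[col] = stack.apply(modal, axis=1)
    return frame_to_records(agg, records, schema)


def evaluate_imputation_error(complete_records: Sequence[SpeciesTraitRecord],
                              mask_rates: Mapping[str, float],
                              predictors: str = "all",
                              grid: OccurrenceGrid | None = None,
                              n_reps: int = 10,
                              n_trees: int = 100,
                              seed: int = 0,
                              schema: TraitSchema | None = None) -> ImputationErrorReport:
    """Mask known values, re-impute, and score recovery against truth.

    Categorical error is ``incorrect / total imputed * 100``;
    continuous error is the NRMSE (RMSE over the truth's standard
    deviation).  Variables with nothing masked report NaN.
    """
    from .synthetic import inject_missingness

    schema = schema or default_schema()
    frame_true = records_to_frame(complete_records, schema)
    if frame_true[list(schema.names)].isna().any().any():
        raise ElasmodivError("complete_records must have no missing trait values")
    masked, truth = inject_missingness(complete_records, mask_rates,
                                       seed=seed, schema=schema)
    for var, rate in mask_rates.items():
        if rate > 0 and var in truth.columns and truth[var].notna().sum() == len(complete_records):
            raise ElasmodivError(f"mask removed every value of {var!r}")
    result = impute_multiple(masked, n_reps=n_reps, predictors=predictors,
                             grid=grid, n_trees=n_trees, seed=seed, schema=schema)
    completed = {r.species_id: r for r in result.completed}
    continuous = {t.name for t in schema if t.kind == "continuous"}
    errors: dict[str, float] = {}
    nrmse: dict[str, float] = {}
    counts: dict[str, int] = {}
    for var in mask_rates:
        if var not in truth.columns:
            errors[var] = float("nan")
            counts[var] = 0
            continue
        cells = truth[var].dropna()
        counts[var] = len(cells)
        if len(cells) == 0:
            errors[var] = float("nan")
            continue
        if var in continuous:
            pred = np.array([completed[s].traits[var] for s in cells.index], dtype=float)
            true = cells.astype(float).values
            sd = frame_true[var].astype(float).std()
            nrmse[var] = float(np.sqrt(np.mean((pred - true) ** 2)) / (sd or 1.0))
        else:
            wrong = 0
            for s, tv in cells.items():
                pv = completed[s].traits[var]
                if pv != tv:
                    wrong += 1
            errors[var] = 100.0 * wrong / len(cells)
    return ImputationErrorReport(error_percent=errors, nrmse=nrmse,
                                 masked_counts=counts, seed=seed)
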