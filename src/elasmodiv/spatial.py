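"""Assemblage-level (per grid cell) diversity metrics.

For every occupied cell the table reports species richness, convex-hull
functional richness as a percentage of the global pool hull (NA below
four species or for degenerate assemblages), local and global
functional uniqueness (nearest neighbour, NN=1), mean functional
specialization, Faith PD and phylogenetic uniqueness (MNTD) averaged
over the tree sample, and counts of resident species in the global top
quartile of the species-level scores.  Identical assemblages in
different cells are computed once and cached.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ElasmodivError, OccurrenceGrid
from .functional_space import FunctionalSpace
from .species_scores import hull_volume

logger = logging.getLogger(__name__)


def _edge_structure(tree: dendropy.Tree, species: Sequence[str]):
    """Edge lengths and edge-by-species tip incidence for fast PD."""
    index = {s: j for j, s in enumerate(species)}
    lengths: list[float] = []
    masks: list[np.ndarray] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(len(species), dtype=bool)
            j = index.get(node.taxon.label)
            if j is not None:
                mask[j] = True
            node._mask = mask
        else:
            node._mask = np.logical_or.reduce([ch._mask for ch in node.child_nodes()])
        if node.parent_node is not None:
            lengths.append(node.edge.length or 0.0)
            masks.append(node._mask)
    return np.asarray(lengths), np.asarray(masks)


def pd_per_cell(tree: dendropy.Tree, grid: OccurrenceGrid,
                cells: np.ndarray) -> np.ndarray:
    """Faith PD (rooted) for each listed flat cell index, vectorised."""
    lengths, masks = _edge_structure(tree, grid.species)
    pres = grid.presence[cells]  # (n_cells, n_species)
    out = np.empty(len(cells))
    chunk = 4096
    for start in range(0, len(cells), chunk):
        block = pres[start:start + chunk]
        spans = masks.astype(np.float32) @ block.T.astype(np.float32) > 0.5
        out[start:start + chunk] = lengths @ spans
    return out


def _mntd_from_matrix(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def top_quartile_counts(grid: OccurrenceGrid, scores: pd.Series,
                        cells: np.ndarray, quantile: float = 0.75) -> np.ndarray:
    """Per-cell count of resident species in the global top quartile.

    Membership is ``score >= empirical q-quantile``; boundary ties are
    included (and logged when they inflate membership past the nominal
    fraction).
    """
    aligned = scores.reindex(grid.species)
    if aligned.isna().any():
        raise ElasmodivError("scores do not cover all gridded species")
    threshold = float(np.quantile(aligned.values, quantile))
    members = (aligned.values >= threshold)
    nominal = int(np.ceil((1 - quantile) * len(aligned)))
    if members.sum() > nominal:
        logger.info("top-quartile ties: %d members vs nominal %d", members.sum(), nominal)
    return grid.presence[cells][:, members].sum(axis=1)


def fric_sr_residuals(table: pd.DataFrame, y: str = "FRic", x: str = "SR") -> pd.Series:
    """OLS residuals of one cell metric on another (NA propagated)."""
    ok = table[y].notna() & table[x].notna()
    if ok.sum() < 3:
        raise ElasmodivError("need at least 3 cells with defined values for the regression")
    xs = table.loc[ok, x].astype(float).values
    ys = table.loc[ok, y].astype(float).values
    if np.ptp(xs) == 0:
        raise ElasmodivError(f"zero variance in {x}; regression undefined")
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = pd.Series(np.nan, index=table.index, name=f"{y}_{x}_residual")
    resid[ok] = ys - (intercept + slope * xs)
    return resid


def cell_metrics(grid: OccurrenceGrid,
                 space: FunctionalSpace,
                 score_table: pd.DataFrame,
                 phylo_table: pd.DataFrame | None = None,
                 trees: Sequence[dendropy.Tree] | None = None,
                 patristic: Sequence[np.ndarray] | None = None,
                 excluded_cells: np.ndarray | None = None,
                 min_fric_richness: int = 4) -> pd.DataFrame:
    """Compute the full per-cell metric table over occupied cells.

    ``patristic`` may carry precomputed per-tree patristic matrices
    aligned with ``grid.species`` (they are derived from ``trees``
    otherwise).  Cells flagged in ``excluded_cells`` (richness below
    the FRic threshold at pool-filtering time) get FRic = NA.
    """
    if grid.presence.size == 0 or not grid.occupied_cells().size:
        raise ElasmodivError("empty occurrence grid")
    sp_order = {s: i for i, s in enumerate(space.species)}
    try:
        col_of = np.array([sp_order[s] for s in grid.species])
    except KeyError as exc:
        raise ElasmodivError(f"gridded species {exc.args[0]!r} not in functional space") from exc
    coords = space.coordinates[col_of]  # aligned with grid.species

    cells = grid.occupied_cells()
    pres = grid.presence[cells]
    sr = pres.sum(axis=1)

    pool_vol = hull_volume(space.coordinates)
    if pool_vol is None or pool_vol <= 0:
        raise ElasmodivError("global pool hull is degenerate")

    # species-level quantities aligned with grid.species
    fsp = score_table["FSp"].reindex(grid.species).values
    trait_D = cdist(coords, coords)
    np.fill_diagonal(trait_D, np.inf)
    global_nn1 = trait_D.min(axis=1)

    n_cells = len(cells)
    fric = np.full(n_cells, np.nan)
    fric_reason = np.array([""] * n_cells, dtype=object)
    fun_local = np.full(n_cells, np.nan)

    hull_cache: dict[bytes, tuple[float | None, str]] = {}
    fun_cache: dict[bytes, float] = {}
    for i in range(n_cells):
        row = pres[i]
        key = row.tobytes()
        # FRic
        if excluded_cells is not None and excluded_cells[cells[i]]:
            fric_reason[i] = "excluded_SR_lt_threshold"
        elif sr[i] < min_fric_richness:
            fric_reason[i] = "SR<4"
        else:
            if key not in hull_cache:
                pts = coords[row]
                if pts.shape[0] < space.n_axes + 1:
                    hull_cache[key] = (None, "too_few_species")
                else:
                    vol = hull_volume(pts)
                    hull_cache[key] = (vol, "" if vol is not None else "degenerate")
            vol, reason = hull_cache[key]
            if vol is None:
                fric_reason[i] = reason
            else:
                fric[i] = 100.0 * vol / pool_vol
        # local FUn (NN=1 within the assemblage)
        if sr[i] >= 2:
            if key not in fun_cache:
                idx = np.flatnonzero(row)
                sub = trait_D[np.ix_(idx, idx)]
                fun_cache[key] = float(sub.min(axis=1).mean())
            fun_local[i] = fun_cache[key]

    table = pd.DataFrame(index=[grid.spec.cell_id(int(c % grid.spec.n_cols),
                                                  int(c // grid.spec.n_cols))
                                for c in cells])
    lon, lat = grid.spec.centers()
    table["lon_center"] = lon[cells]
    table["lat_center"] = lat[cells]
    table["SR"] = sr
    table["FRic"] = fric
    table["FRic_reason"] = fric_reason
    table["FUn_local"] = fun_local
    with np.errstate(invalid="ignore"):
        table["FUn_global"] = (pres @ global_nn1) / sr
        table["FSp_mean"] = (pres @ fsp) / sr

    if trees:
        pd_stack = np.stack([pd_per_cell(t, grid, cells) for t in trees])
        table["PD_mean"] = pd_stack.mean(axis=0)
        if patristic is None:
            from .phylo_scores import patristic_matrix
            patristic = [patristic_matrix(t, grid.species) for t in trees]
        pun = np.full(n_cells, np.nan)
        mntd_cache: dict[bytes, float] = {}
        for i in range(n_cells):
            if sr[i] < 2:
                continue
            key = pres[i].tobytes()
            if key not in mntd_cache:
                idx = np.flatnonzero(pres[i])
                mntd_cache[key] = float(np.mean([_mntd_from_matrix(D, idx) for D in patristic]))
            pun[i] = mntd_cache[key]
        table["PUn"] = pun

    score_cols = [c for c in ("ED2", "EDGE2") if phylo_table is not None and c in phylo_table]
    for name in ("FSp", "FUn", "FUSE"):
        if name in score_table:
            table[f"top25_{name}"] = top_quartile_counts(grid, score_table[name], cells)
    for name in score_cols:
        table[f"top25_{name}"] = top_quartile_counts(grid, phylo_table[name], cells)

    if table["FRic"].notna().sum() >= 3 and np.ptp(table.loc[table["FRic"].notna(), "SR"]) > 0:
        table["FRic_SR_residual"] = fric_sr_residuals(table)
    return table
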