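"""Fishing-pressure index, ordinary kriging, and MPA gap analysis.

Fishing effort arrives as (cell, gear, hours) records on a coarse
(1 degree) grid; hours are summed over the gear types that can target
elasmobranchs and interpolated to the analysis grid by ordinary
kriging with an exponential variogram and a 3-degree search radius.
Marine protected areas are filtered to fully protected management
categories (Ia, Ib, II, III) minus designations aimed at other taxa,
and overlaid on hotspot masks to quantify protection gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .core import ElasmodivError, GridSpec, ValidationError

logger = logging.getLogger(__name__)

#: Gear types known to potentially target elasmobranchs.
DEFAULT_GEAR_LIST = (
    "pole_and_line",
    "drifting_longlines",
    "tuna_purse_seines",
    "other_purse_seines",
    "trollers",
    "other_seines",
    "set_gillnets",
    "set_longlines",
    "trawlers",
)

DEFAULT_EXCLUSION_KEYWORDS = ("bird", "seabird", "turtle", "seal", "flora", "plant", "wetland")

MPA_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI")
FULLY_PROTECTED = frozenset({"Ia", "Ib", "II", "III"})


@dataclass
class EffortGrid:
    spec: GridSpec
    hours: np.ndarray          # per flat cell; NaN where no estimate
    has_data: np.ndarray       # bool per flat cell: at least one record
    gear_list: tuple[str, ...]
    idw_fallback: np.ndarray | None = field(default=None, repr=False)

    def to_series(self) -> pd.Series:
        cols = np.arange(self.spec.n_cells) % self.spec.n_cols
        rows = np.arange(self.spec.n_cells) // self.spec.n_cols
        ids = [self.spec.cell_id(int(c), int(r)) for c, r in zip(cols, rows)]
        return pd.Series(self.hours, index=ids, name="fishing_hours")


def fishing_index(records: pd.DataFrame, spec: GridSpec,
                  gear_list: tuple[str, ...] = DEFAULT_GEAR_LIST) -> EffortGrid:
    """Sum fishing hours per cell over the target gear types.

    ``records`` needs columns (cell_id | lon+lat), gear, hours.
    Records with other gears are ignored (count logged); negative
    hours raise.
    """
    required = {"gear", "hours"}
    if not required <= set(records.columns):
        raise ValidationError("effort records need gear and hours columns")
    if (records["hours"] < 0).any():
        raise ValidationError("negative fishing hours")
    hours = np.zeros(spec.n_cells)
    has_data = np.zeros(spec.n_cells, dtype=bool)
    ignored = 0
    gear_set = set(gear_list)
    for _, row in records.iterrows():
        if "cell_id" in records.columns:
            col, r = spec.parse_cell_id(str(row["cell_id"]))
        else:
            col, r = spec.cell_index(float(row["lon"]), float(row["lat"]))
        flat = spec.flat_index(col, r)
        has_data[flat] = True
        if row["gear"] not in gear_set:
            ignored += 1
            continue
        hours[flat] += float(row["hours"])
    if ignored:
        logger.info("fishing_index: ignored %d records with non-target gears", ignored)
    return EffortGrid(spec, hours, has_data, tuple(gear_list))


def _exponential_variogram(h, nugget, sill, rng):
    return nugget + sill * (1.0 - np.exp(-h / np.maximum(rng, 1e-9)))


def fit_exponential_variogram(points: np.ndarray, values: np.ndarray,
                              max_lag: float, n_bins: int = 12):
    """WLS (Cressie weights) fit of an exponential semivariogram.

    Returns (nugget, sill, range) or None when the fit fails.
    """
    n = len(points)
    if n < 10:
        return None
    rng = np.random.default_rng(0)
    idx = rng.choice(n, size=min(n, 600), replace=False)
    P, V = points[idx], values[idx]
    d = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    g = 0.5 * (V[:, None] - V[None, :]) ** 2
    iu = np.triu_indices(len(P), k=1)
    d, g = d[iu], g[iu]
    keep = d <= max_lag
    d, g = d[keep], g[keep]
    if len(d) < n_bins * 2:
        return None
    bins = np.linspace(0, max_lag, n_bins + 1)
    which = np.digitize(d, bins) - 1
    lags, gammas, counts = [], [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() >= 3:
            lags.append(d[sel].mean())
            gammas.append(g[sel].mean())
            counts.append(sel.sum())
    if len(lags) < 4:
        return None
    lags, gammas, counts = map(np.asarray, (lags, gammas, counts))
    var = max(values.var(), 1e-12)
    try:
        popt, _ = curve_fit(
            _exponential_variogram, lags, gammas,
            p0=[0.1 * var, var, max_lag / 3],
            sigma=np.maximum(gammas, 1e-12) / np.sqrt(counts),
            bounds=([0, 1e-12, 1e-6], [var * 10, var * 50, max_lag * 10]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    return tuple(popt)


def krige_to_grid(coarse: EffortGrid, target: GridSpec, radius: float = 3.0,
                  min_neighbors: int = 5, log_transform: bool = False) -> EffortGrid:
    """Ordinary kriging of the coarse effort field onto the target grid.

    Prediction at each target cell uses data cells within ``radius``
    degrees; fewer than ``min_neighbors`` leaves the cell NA.  Weights
    solve the ordinary-kriging system (they sum to one); predictions
    are clipped at zero.  When the variogram fit fails the whole field
    falls back to inverse-distance weighting, flagged per cell.
    """
    data_cells = np.flatnonzero(coarse.has_data)
    if data_cells.size == 0:
        raise ElasmodivError("no effort data cells to interpolate from")
    lon, lat = coarse.spec.centers()
    pts = np.column_stack([lon[data_cells], lat[data_cells]])
    vals = coarse.hours[data_cells].astype(float)
    if log_transform:
        vals = np.log1p(vals)

    model = fit_exponential_variogram(pts, vals, max_lag=2 * radius)
    use_idw = model is None
    if use_idw:
        logger.warning("variogram fit failed; falling back to inverse-distance weighting")

    tree = cKDTree(pts)
    tlon, tlat = target.centers()
    tpts = np.column_stack([tlon, tlat])
    out = np.full(target.n_cells, np.nan)
    fallback = np.zeros(target.n_cells, dtype=bool)
    neighborhoods = tree.query_ball_point(tpts, r=radius)
    for i, nb in enumerate(neighborhoods):
        if len(nb) < min_neighbors:
            continue
        nb = np.asarray(nb)
        local = pts[nb]
        lv = vals[nb]
        d0 = np.sqrt(((local - tpts[i]) ** 2).sum(-1))
        if use_idw:
            pred = _idw(d0, lv)
            fallback[i] = True
        else:
            nugget, sill, vrange = model
            dmat = np.sqrt(((local[:, None, :] - local[None, :, :]) ** 2).sum(-1))
            gamma = _exponential_variogram(dmat, nugget, sill, vrange)
            k = len(nb)
            A = np.empty((k + 1, k + 1))
            A[:k, :k] = gamma
            A[:k, k] = 1.0
            A[k, :k] = 1.0
            A[k, k] = 0.0
            rhs = np.append(_exponential_variogram(d0, nugget, sill, vrange), 1.0)
            try:
                sol = np.linalg.solve(A, rhs)
                w = sol[:k]
                pred = float(w @ lv)
            except np.linalg.LinAlgError:
                pred = _idw(d0, lv)
                fallback[i] = True
        if log_transform:
            pred = np.expm1(pred)
        out[i] = max(pred, 0.0)
    return EffortGrid(target, out, ~np.isnan(out), coarse.gear_list, idw_fallback=fallback)


def _idw(d0: np.ndarray, values: np.ndarray, power: float = 2.0) -> float:
    if np.any(d0 < 1e-12):
        return float(values[np.argmin(d0)])
    w = 1.0 / d0 ** power
    return float((w @ values) / w.sum())


# ---------------------------------------------------------------------------
# Marine protected areas
# ---------------------------------------------------------------------------


def filter_mpas(mpas: pd.DataFrame,
                allowed: frozenset[str] = FULLY_PROTECTED,
                exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
                ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep fully protected MPAs whose designation targets our taxa.

    Rows need columns mpa_id, category, designation, cell_id.  Returns
    the retained table and counts removed per rule.  Idempotent and
    order-invariant.
    """
    required = {"mpa_id", "category", "designation", "cell_id"}
    if not required <= set(mpas.columns):
        raise ValidationError(f"MPA table needs columns {sorted(required)}")
    bad = set(mpas["category"]) - set(MPA_CATEGORIES)
    if bad:
        raise ValidationError(f"unknown MPA categories {sorted(bad)}")
    by_cat = mpas["category"].isin(allowed)
    designation = mpas["designation"].fillna("").str.lower()
    by_kw = ~designation.str.contains("|".join(exclusion_keywords), regex=True)
    removed = {
        "category": int((~by_cat).groupby(mpas["mpa_id"]).any().sum()),
        "designation": int((by_cat & ~by_kw).groupby(mpas["mpa_id"]).any().sum()),
    }
    return mpas[by_cat & by_kw].reset_index(drop=True), removed


def mpa_cell_set(mpas: pd.DataFrame) -> set[str]:
    """Cells covered by at least one retained MPA (binary coverage)."""
    return set(mpas["cell_id"].astype(str))


def protection_overlap(hotspot_cells: set[str] | list[str],
                       protected_cells: set[str]) -> dict[str, float]:
    """Percent of hotspot cells inside / outside the MPA network."""
    hs = set(hotspot_cells)
    if not hs:
        raise ElasmodivError("empty hotspot mask")
    inside = len(hs & protected_cells)
    pct_inside = 100.0 * inside / len(hs)
    result = {
        "pct_hotspot_inside_mpa": pct_inside,
        "pct_hotspot_outside_mpa": 100.0 - pct_inside,
    }
    if protected_cells:
        result["pct_mpa_not_hotspot"] = 100.0 * len(protected_cells - hs) / len(protected_cells)
    return result


def cumulative_protection_curve(values: pd.Series, protected_cells: set[str]) -> pd.DataFrame:
    """Protected cells ranked least to most diverse vs cumulative % protected."""
    prot = values.dropna().loc[values.index.intersection(list(protected_cells))]
    if prot.empty:
        raise ElasmodivError("no protected cell with a defined value")
    prot = prot.sort_values(kind="stable")
    n = len(prot)
    return pd.DataFrame({
        "rank": np.arange(1, n + 1),
        "cell_id": prot.index,
        "value": prot.values,
        "cumulative_pct_protected": 100.0 * np.arange(1, n + 1) / n,
    })
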