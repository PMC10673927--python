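"""Species-level functional diversity metrics: FRic, FUn, FSp, FUSE.

All metrics live in the retained PCoA space.  Functional richness is
the percentage of the global pool's convex-hull volume occupied by a
species subset; uniqueness is the mean distance to the k nearest
neighbours (k=5 at species level); specialization is the distance to
the pool centroid.  FUSE combines min-max scaled uniqueness and
specialization with the species' 100-year extinction probability GE:

    FUSE = ln(1 + FUn01 * GE) + ln(1 + FSp01 * GE)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .core import ElasmodivError, ExtinctionProbabilityMap, SpeciesTraitRecord
from .functional_space import FunctionalSpace


@dataclass
class FRicResult:
    percent: float | None
    reason: str | None = None  # set when percent is None

    def __float__(self) -> float:
        return float("nan") if self.percent is None else self.percent


def hull_volume(points: np.ndarray) -> float | None:
    """Convex-hull volume of a point set, or None if degenerate."""
    m = points.shape[1]
    if points.shape[0] < m + 1:
        return None
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return None


def functional_richness(space: FunctionalSpace, subset: list[str] | None = None,
                        pool_volume: float | None = None) -> FRicResult:
    """Percent of the pool hull volume spanned by ``subset``.

    Returns NA with a reason code when the subset is too small
    (< m+1 species in m dimensions) or lies on a lower-dimensional
    flat (degenerate hull).
    """
    coords = space.coordinates
    if pool_volume is None:
        pool_volume = hull_volume(coords)
    if pool_volume is None or pool_volume <= 0:
        raise ElasmodivError("global pool hull is degenerate; cannot normalise FRic")
    if subset is None:
        sub = coords
    else:
        index = {s: i for i, s in enumerate(space.species)}
        try:
            rows = [index[s] for s in subset]
        except KeyError as exc:
            raise ElasmodivError(f"species {exc.args[0]!r} not in functional space") from exc
        sub = coords[rows]
    if sub.shape[0] < coords.shape[1] + 1:
        return FRicResult(None, reason="too_few_species")
    vol = hull_volume(sub)
    if vol is None:
        return FRicResult(None, reason="degenerate")
    return FRicResult(100.0 * vol / pool_volume)


def nearest_neighbour_distances(space: FunctionalSpace, k: int) -> pd.DataFrame:
    """Sorted distances of every species to its k nearest other species.

    Ties at the k-th distance are broken by the species order of the
    space (stable sort), which is logged as the tie rule.
    """
    n = len(space.species)
    if k >= n:
        raise ElasmodivError(f"k={k} must be smaller than pool size {n}")
    D = cdist(space.coordinates, space.coordinates)
    np.fill_diagonal(D, np.inf)
    part = np.sort(D, axis=1, kind="stable")[:, :k]
    return pd.DataFrame(part, index=space.species,
                        columns=[f"nn{i + 1}" for i in range(k)])


def functional_uniqueness(space: FunctionalSpace, k: int = 5) -> pd.Series:
    """Mean distance to the k nearest neighbours, per species."""
    nn = nearest_neighbour_distances(space, k)
    return pd.Series(nn.mean(axis=1), name=f"FUn_k{k}")


def functional_specialization(space: FunctionalSpace) -> pd.Series:
    """Distance of each species to the pool centroid."""
    centroid = space.coordinates.mean(axis=0)
    d = np.linalg.norm(space.coordinates - centroid, axis=1)
    return pd.Series(d, index=space.species, name="FSp")


def fuse(fun: pd.Series, fsp: pd.Series, ge: pd.Series) -> pd.DataFrame:
    """FUSE score from uniqueness, specialization and extinction risk.

    Components are scaled by their pool maxima (FUn01, FSp01) so the
    score is invariant to a common rescaling of the space's units.
    """
    if ((ge < 0) | (ge > 1)).any():
        raise ElasmodivError("GE probabilities must lie in [0,1]")
    if (fun < 0).any() or (fsp < 0).any():
        raise ElasmodivError("FUn/FSp must be non-negative")
    fun, fsp, ge = fun.align(ge, join="inner")[0], fsp.align(ge, join="inner")[0], ge
    if fun.max() <= 0 or fsp.max() <= 0:
        raise ElasmodivError("pool maxima of FUn and FSp must be positive")
    fun01 = fun / fun.max()
    fsp01 = fsp / fsp.max()
    score = np.log1p(fun01 * ge) + np.log1p(fsp01 * ge)
    return pd.DataFrame({"FUn01": fun01, "FSp01": fsp01, "GE": ge, "FUSE": score})


def species_score_table(space: FunctionalSpace,
                        records: list[SpeciesTraitRecord],
                        pext: ExtinctionProbabilityMap,
                        k: int = 5) -> pd.DataFrame:
    """Assemble the per-species FUn/FSp/GE/FUSE table with ranks."""
    ge = pext.for_records(records).reindex(space.species)
    if ge.isna().any():
        missing = list(ge[ge.isna()].index[:3])
        raise ElasmodivError(f"species without extinction probability (e.g. {missing})")
    fun = functional_uniqueness(space, k=k)
    fsp = functional_specialization(space)
    table = fuse(fun, fsp, ge)
    table.insert(0, "FSp", fsp)
    table.insert(0, "FUn", fun)
    table["FUSE_rank"] = table["FUSE"].rank(ascending=False, method="min").astype(int)
    return table
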