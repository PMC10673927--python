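"""Hotspot detection and the spatial congruence permutation test.

A hotspot layer is the upper tail (default 2.5%) of a per-cell metric.
The congruence of two layers is judged against the overlap expected
under independence, Oe = Ni * Nj / NT, with a one-sided permutation
test: the values of one layer are shuffled over the common defined
cells and the hotspot overlap recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ElasmodivError

logger = logging.getLogger(__name__)


@dataclass
class HotspotMask:
    cell_ids: list[str]
    mask: np.ndarray  # bool over cell_ids
    threshold: float
    q: float

    @property
    def n_hotspots(self) -> int:
        return int(self.mask.sum())

    def hotspot_cells(self) -> list[str]:
        return [c for c, m in zip(self.cell_ids, self.mask) if m]


def detect_hotspots(values: pd.Series, q: float = 0.025) -> HotspotMask:
    """Cells whose value reaches the upper-q empirical quantile.

    NA cells are excluded from both the quantile and the mask.  All
    boundary ties are included; the realised count is logged when ties
    push it past the nominal q fraction.  A constant layer has no
    meaningful upper tail and raises.
    """
    if not 0 < q <= 1:
        raise ElasmodivError("q must lie in (0, 1]")
    defined = values.dropna()
    if defined.empty:
        raise ElasmodivError("no defined cells")
    if defined.nunique() == 1 and q < 1.0:
        raise ElasmodivError("all values identical: no meaningful upper tail")
    threshold = float(np.quantile(defined.values, 1.0 - q))
    mask = defined.values >= threshold
    nominal = int(np.ceil(q * len(defined)))
    if mask.sum() > nominal:
        logger.info("hotspot ties at threshold %.6g: %d cells vs nominal %d",
                    threshold, mask.sum(), nominal)
    return HotspotMask(list(defined.index), mask, threshold, q)


def expected_overlap(ni: int, nj: int, nt: int) -> float:
    """Expected hotspot overlap under independence: Ni * Nj / NT."""
    if nt <= 0:
        raise ElasmodivError("NT must be positive")
    if not (0 <= ni <= nt and 0 <= nj <= nt):
        raise ElasmodivError("Ni and Nj must lie in [0, NT]")
    return ni * nj / nt


@dataclass
class CongruenceResult:
    observed_overlap: int
    overlap_percent: float
    expected: float
    ni: int
    nj: int
    nt: int
    p_value: float
    p_value_randomized: float
    n_perm: int
    seed: int
    permutation_overlaps: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "overlap_percent": self.overlap_percent,
            "expected_overlap": self.expected,
            "Ni": self.ni, "Nj": self.nj, "NT": self.nt,
            "p_value": self.p_value, "n_perm": self.n_perm, "seed": self.seed,
            "perm_overlap_mean": float(self.permutation_overlaps.mean()),
        }


def congruence_test(values_a: pd.Series, values_b: pd.Series,
                    q: float = 0.025, n_perm: int = 999,
                    seed: int = 0) -> CongruenceResult:
    """Permutation test of hotspot congruence between two cell layers.

    Both layers are restricted to their common defined cells (cells
    defined in only one layer are dropped and logged).  Layer B's
    values are permuted over those cells; since a permutation of the
    values leaves the hotspot threshold unchanged, this is carried out
    by permuting B's hotspot mask.  One-sided upper-tail p-value with
    the add-one correction; ``p_value_randomized`` additionally breaks
    ties between the observed and permuted overlaps with a uniform
    draw, which makes it exactly uniform under the independence null
    (the overlap count is heavily tied, so the add-one p is
    conservative) -- use it for calibration diagnostics.
    """
    common = values_a.dropna().index.intersection(values_b.dropna().index)
    dropped = (len(values_a.dropna()) - len(common)) + (len(values_b.dropna()) - len(common))
    if dropped:
        logger.info("congruence: dropped %d cells defined in only one layer", dropped)
    if len(common) < 2:
        raise ElasmodivError("fewer than 2 common defined cells")
    a = values_a.loc[common]
    b = values_b.loc[common]
    mask_a = detect_hotspots(a, q).mask
    mask_b = detect_hotspots(b, q).mask
    ni, nj, nt = int(mask_a.sum()), int(mask_b.sum()), len(common)
    oo = int(np.sum(mask_a & mask_b))
    denom = min(ni, nj)
    percent = 100.0 * oo / denom if denom else 0.0

    rng = np.random.default_rng(seed)
    perm_overlaps = np.empty(n_perm, dtype=np.int64)
    idx_a = np.flatnonzero(mask_a)
    for r in range(n_perm):
        perm = rng.permutation(nt)
        perm_overlaps[r] = np.sum(mask_b[perm][idx_a])
    p = (1 + int(np.sum(perm_overlaps >= oo))) / (n_perm + 1)
    greater = int(np.sum(perm_overlaps > oo))
    ties = int(np.sum(perm_overlaps == oo))
    p_rand = (greater + rng.random() * (1 + ties)) / (n_perm + 1)
    return CongruenceResult(
        observed_overlap=oo, overlap_percent=percent,
        expected=expected_overlap(ni, nj, nt),
        ni=ni, nj=nj, nt=nt, p_value=p, p_value_randomized=p_rand,
        n_perm=n_perm, seed=seed,
        permutation_overlaps=perm_overlaps,
    )
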