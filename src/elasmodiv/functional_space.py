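"""Mixed-trait dissimilarity and principal-coordinate functional space.

The trait space is built in two steps.  First a Gower-type
dissimilarity handles the mixture of trait kinds: continuous traits
contribute a range-normalised absolute difference (after an optional
log transform), nominal and binary traits a simple 0/1 mismatch, and
multichoice traits the Jaccard dissimilarity of their category sets.
Per-trait contributions are averaged with equal weights and the mean is
square-rooted, which brings the matrix close to Euclidean.  Second, a
principal coordinates analysis (metric MDS) embeds the matrix; the few
leading axes carry most of the inertia and define the functional space
used by every downstream metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .core import ElasmodivError, SpeciesTraitRecord, TraitSchema, ValidationError, default_schema

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    species: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)


@dataclass
class FunctionalSpace:
    """PCoA embedding: coordinates on retained axes plus diagnostics."""

    species: list[str]
    coordinates: np.ndarray          # (n_species, n_retained)
    eigenvalues: np.ndarray          # full spectrum, descending
    correction: str = "none"         # none | lingoes

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.species, columns=cols)

    def subspace(self, m: int) -> "FunctionalSpace":
        if not 1 <= m <= self.n_axes:
            raise ElasmodivError(f"cannot retain {m} of {self.n_axes} axes")
        return FunctionalSpace(self.species, self.coordinates[:, :m],
                               self.eigenvalues, self.correction)


def _transform_continuous(values: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None:
        return values
    if transform == "log10":
        return np.log10(values)
    raise ValidationError(f"unknown transform {transform!r}")


def trait_gower_matrix(records: Sequence[SpeciesTraitRecord],
                       schema: TraitSchema | None = None,
                       sqrt_combine: bool = True) -> DissimilarityMatrix:
    """Equal-weight Gower-type dissimilarity over the mixed trait set.

    Every trait contributes a value in [0, 1]; the combined
    dissimilarity is ``sqrt(mean_t d_t)`` (or the plain mean when
    ``sqrt_combine`` is off).  Traits with zero global range contribute
    0 and are logged.  Missing trait values are an error: impute first.
    """
    schema = schema or default_schema()
    if len(records) < 2:
        raise ElasmodivError("need at least two species for a dissimilarity matrix")
    n = len(records)
    for rec in records:
        for tdef in schema:
            if rec.traits.get(tdef.name) is None:
                raise ElasmodivError(
                    f"species {rec.species_id!r} missing trait {tdef.name!r}; "
                    "run imputation before building the functional space"
                )
    total = np.zeros((n, n))
    for tdef in schema:
        if tdef.kind == "continuous":
            x = _transform_continuous(
                np.array([float(r.traits[tdef.name]) for r in records]), tdef.transform
            )
            rng = x.max() - x.min()
            if rng == 0:
                logger.info("trait %s has zero range; contributes 0", tdef.name)
                continue
            contrib = np.abs(x[:, None] - x[None, :]) / rng
        elif tdef.kind == "multichoice":
            sets = [r.traits[tdef.name] for r in records]
            cats = list(tdef.categories)
            member = np.array([[c in s for c in cats] for s in sets], dtype=float)
            inter = member @ member.T
            sizes = member.sum(axis=1)
            union = sizes[:, None] + sizes[None, :] - inter
            with np.errstate(invalid="ignore"):
                contrib = 1.0 - np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
            np.fill_diagonal(contrib, 0.0)
        else:  # nominal / binary: simple matching
            x = np.array([r.traits[tdef.name] for r in records], dtype=object)
            contrib = (x[:, None] != x[None, :]).astype(float)
        total += contrib
    mean = total / len(schema.names)
    values = np.sqrt(mean) if sqrt_combine else mean
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix([r.species_id for r in records], values)


def pcoa(dissim: DissimilarityMatrix, correction_threshold: float = 1e-8) -> FunctionalSpace:
    """Principal coordinates analysis of a dissimilarity matrix.

    The Gower-centred matrix ``-0.5 * J D^2 J`` is eigendecomposed.  If
    the most negative eigenvalue exceeds ``correction_threshold`` times
    the largest, the Lingoes correction (add a constant to all squared
    off-diagonal dissimilarities) is applied; otherwise negative axes
    are truncated.  Axes are ordered by descending eigenvalue and each
    axis is signed so its largest-magnitude coordinate is positive.
    """
    D = dissim.values
    if not np.any(D):
        raise ElasmodivError("all-zero dissimilarity matrix")
    n = D.shape[0]

    def _decompose(d2: np.ndarray):
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ d2 @ J
        B = (B + B.T) / 2.0
        w, v = eigh(B)
        order = np.argsort(w)[::-1]
        return w[order], v[:, order]

    eigval, eigvec = _decompose(D ** 2)
    correction = "none"
    if eigval[-1] < 0 and abs(eigval[-1]) > correction_threshold * max(eigval[0], 1e-300):
        # Lingoes: d'_ij^2 = d_ij^2 + 2c with c = |lambda_min|
        c = abs(eigval[-1])
        d2 = D ** 2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        eigval, eigvec = _decompose(d2)
        correction = "lingoes"

    tol = max(eigval[0], 0) * 1e-12 + 1e-15
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    # deterministic sign convention
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return FunctionalSpace(list(dissim.species), coords, eigval, correction)


def inertia_explained(space: FunctionalSpace, k: int) -> float:
    """Fraction of total inertia carried by the first k positive axes."""
    if k <= 0:
        raise ElasmodivError("k must be positive")
    pos = space.eigenvalues[space.eigenvalues > 0]
    if k > len(pos):
        raise ElasmodivError(f"only {len(pos)} positive eigenvalues, requested {k}")
    return float(pos[:k].sum() / pos.sum())


def space_quality_msd(dissim: DissimilarityMatrix, space: FunctionalSpace,
                      dims: Sequence[int] = (2, 3, 4, 5, 6)) -> dict[int, float]:
    """Mean squared deviation between original and embedded distances.

    Both distance sets are scaled by their maxima before comparison;
    lower is better.  Reported per candidate dimensionality so the
    retained-axis choice can trade distortion against dimensionality.
    """
    orig = squareform(dissim.values, checks=False)
    orig_scaled = orig / orig.max()
    out: dict[int, float] = {}
    for m in dims:
        if m > space.n_axes:
            continue
        emb = pdist(space.coordinates[:, :m])
        emb_scaled = emb / emb.max() if emb.max() > 0 else emb
        out[m] = float(np.mean((orig_scaled - emb_scaled) ** 2))
    return out
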