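"""Phylogenetic diversity metrics on dendropy trees.

Faith's PD (rooted convention: the spanning subtree includes the path
to the root), ED2 -- the expected phylogenetic diversity uniquely
contributed by a species given the extinction probabilities of its
relatives (equivalent to heightened evolutionary distinctiveness, HED)
-- its risk-weighted companion EDGE2 = ED2 * p_ext, and the mean
nearest taxon distance (MNTD, the phylogenetic uniqueness of an
assemblage).  Every metric can be averaged over a sample of trees to
absorb topological uncertainty.
"""

from __future__ import annotations

import itertools
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import ElasmodivError


def _edge_length(node: dendropy.Node) -> float:
    return node.edge.length or 0.0


def faith_pd(tree: dendropy.Tree, tipset: Sequence[str]) -> float:
    """Total branch length of the minimal rooted subtree spanning ``tipset``.

    The root path is included, so the PD of a single tip is its
    distance to the root.
    """
    tips = set(tipset)
    if not tips:
        raise ElasmodivError("tipset must be non-empty")
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = tips - labels
    if unknown:
        raise ElasmodivError(f"tips not on tree: {sorted(unknown)[:3]}")
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._spans = node.taxon.label in tips
        else:
            node._spans = any(ch._spans for ch in node.child_nodes())
        if node._spans and node.parent_node is not None:
            total += _edge_length(node)
    return total


def patristic_matrix(tree: dendropy.Tree, species: Sequence[str]) -> np.ndarray:
    """Dense pairwise patristic (branch-length path) distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(species)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
        D[i, j] = D[j, i] = d
    return D


def mntd(tree: dendropy.Tree, assemblage: Sequence[str]) -> float:
    """Mean distance of each member to its nearest co-occurring relative."""
    members = list(assemblage)
    if len(members) < 2:
        raise ElasmodivError("MNTD undefined for assemblages of fewer than 2 species")
    D = patristic_matrix(tree, members)
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


def ed2(tree: dendropy.Tree, pext: Mapping[str, float]) -> pd.Series:
    """Expected unique PD contribution of every tip.

    For tip i, each edge e on its root path contributes
    ``length(e) * prod_{j in tips(e), j != i} p_j`` where p_j is the
    extinction probability of tip j: the edge is uniquely attributable
    to i exactly when all other descendants of e are extinct.  The
    terminal edge always counts in full.
    """
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in pext:
            raise ElasmodivError(f"no extinction probability for tip {label!r}")
    # product of extinction probabilities over each clade's tips
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._pprod = float(pext[node.taxon.label])
        else:
            node._pprod = float(np.prod([ch._pprod for ch in node.child_nodes()]))
    scores: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        total = 0.0
        exclusive = 1.0  # prod of p over tips(e) \ {i} for the current edge
        node = leaf
        while node.parent_node is not None:
            total += _edge_length(node) * exclusive
            for sib in node.parent_node.child_nodes():
                if sib is not node:
                    exclusive *= sib._pprod
            node = node.parent_node
        scores[leaf.taxon.label] = total
    return pd.Series(scores, name="ED2").sort_index()


def ed2_by_enumeration(tree: dendropy.Tree, pext: Mapping[str, float]) -> pd.Series:
    """Brute-force ED2 as E[PD(S + {i}) - PD(S)] over survivor sets S.

    Enumerates every survival outcome of the other tips (2^(n-1)
    terms), weighting by the product of survival/extinction
    probabilities.  Exponential: use only on small trees, as an oracle.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(labels) > 16:
        raise ElasmodivError("enumeration oracle limited to 16 tips")
    out: dict[str, float] = {}
    for focal in labels:
        others = [t for t in labels if t != focal]
        expectation = 0.0
        for survivors in itertools.chain.from_iterable(
            itertools.combinations(others, r) for r in range(len(others) + 1)
        ):
            s = set(survivors)
            weight = 1.0
            for t in others:
                weight *= (1.0 - pext[t]) if t in s else pext[t]
            if weight == 0.0:
                continue
            gain = faith_pd(tree, s | {focal}) - (faith_pd(tree, s) if s else 0.0)
            expectation += weight * gain
        out[focal] = expectation
    return pd.Series(out, name="ED2").sort_index()


def edge2(ed2_scores: pd.Series, pext: Mapping[str, float]) -> pd.Series:
    """EDGE2 = ED2 * own extinction probability."""
    p = pd.Series({s: pext[s] for s in ed2_scores.index})
    return (ed2_scores * p).rename("EDGE2")


def average_over_trees(trees: Sequence[dendropy.Tree],
                       metric: Callable[[dendropy.Tree], pd.Series]) -> pd.DataFrame:
    """Apply a per-tree metric and average; per-tree values retained.

    Returns a frame with one ``tree{i}`` column per tree plus ``mean``
    and ``sd`` columns.  Raises if the trees disagree on species.
    """
    if not trees:
        raise ElasmodivError("need at least one tree")
    values = []
    for i, tree in enumerate(trees):
        s = metric(tree)
        values.append(s.rename(f"tree{i + 1}"))
    frame = pd.concat(values, axis=1)
    if frame.isna().any().any():
        raise ElasmodivError("species missing from some trees")
    frame["mean"] = frame.iloc[:, : len(trees)].mean(axis=1)
    frame["sd"] = frame.iloc[:, : len(trees)].std(axis=1, ddof=0)
    return frame


def phylo_score_table(trees: Sequence[dendropy.Tree],
                      pext: Mapping[str, float]) -> pd.DataFrame:
    """Per-species ED2 and EDGE2 averaged over the tree sample."""
    ed2_frame = average_over_trees(trees, lambda t: ed2(t, pext))
    result = pd.DataFrame({
        "ED2": ed2_frame["mean"],
        "ED2_sd": ed2_frame["sd"],
    })
    result["EDGE2"] = edge2(result["ED2"], pext)
    result["EDGE2_rank"] = result["EDGE2"].rank(ascending=False, method="min").astype(int)
    return result
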