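"""Desk-scale tree building and Newick ingestion.

Neighbor-joining (Saitou & Nei agglomeration) on p-distance matrices with a
deterministic tie rule, nonparametric bootstrap supports from column
resampling, and ingestion of externally built trees (RAxML/MrBayes-style
Newick with support labels).  Trees are dendropy ``Tree`` objects; internal
nodes carry a ``support`` attribute in [0, 1] (None when unknown).

The discrimination statistics downstream are tree-agnostic: any tree whose
tips are accession ids works, whether built here or ingested.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional

import dendropy
import numpy as np

from .variation import DistanceMatrix, MultipleAlignment, pairwise_divergence

logger = logging.getLogger(__name__)

PhyloTree = dendropy.Tree

TreeBuilder = Callable[[MultipleAlignment], dendropy.Tree]


def neighbor_joining(distance_matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic and additive-exact.

    Among minimal Q-criterion pairs the lexicographically smallest (i, j)
    index pair (current node ordering; merged nodes append at the end) is
    joined.  Negative branch lengths are clamped to 0 with the deficit
    transferred to the sibling edge.  The result is an unrooted tree whose
    path distances reproduce any additive input matrix exactly.
    """
    ids = list(distance_matrix.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(distance_matrix.p, dtype=float)
    if np.isnan(D).any():
        bad = np.argwhere(np.isnan(D))[0]
        raise ValueError(
            f"undefined distance between {ids[bad[0]]!r} and {ids[bad[1]]!r}"
        )

    tns = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for label in ids:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        node.support = None
        nodes.append(node)

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # lexicographically smallest (i, j), i < j, among minima
        ii, jj = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=0.0) | (Q == qmin))[0]
        i, j = (int(ii), int(jj)) if ii < jj else (int(jj), int(ii))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.support = None
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        newD[m - 2, : m - 2] = newD[: m - 2, m - 2] = np.maximum(dk[keep], 0.0)
        D = newD
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-node join: closed-form three-point formulas
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    center = dendropy.Node()
    center.support = None
    for node, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def p_distance_nj(alignment: MultipleAlignment) -> dendropy.Tree:
    """Default tree builder: NJ on pairwise-deletion p-distances."""
    return neighbor_joining(pairwise_divergence(alignment))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> dict[frozenset, "dendropy.Edge"]:
    """Nontrivial bipartitions of an (un)rooted tree.

    Key = frozenset of the two frozensets of tip labels; invariant to
    rooting and tip order.  A bifurcating root's twin edges map to the same
    key (deduplicated, preferring the edge that carries a support value).
    """
    all_tips = frozenset(tip_labels(tree))
    out: dict[frozenset, dendropy.Edge] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_tips - below
        if len(below) < 2 or len(other) < 2:
            continue
        key = frozenset({below, other})
        if key in out and getattr(out[key].head_node, "support", None) is not None:
            continue
        out[key] = node.edge
    return out


def edge_support(edge: "dendropy.Edge") -> Optional[float]:
    node = edge.head_node
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def bootstrap_support(
    alignment: MultipleAlignment,
    n_replicates: int,
    seed: int,
    tree_builder: TreeBuilder | None = None,
) -> dendropy.Tree:
    """Tree on the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of
    each internal edge is the fraction of replicate trees containing the
    same bipartition.  Reproducible given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if alignment.length < 4:
        raise ValueError("alignment too short to bootstrap (< 4 columns)")
    builder = tree_builder or p_distance_nj
    rng = np.random.default_rng(seed)
    main = builder(alignment)
    main_bips = bipartitions(main)
    counts = {key: 0 for key in main_bips}
    for _ in range(n_replicates):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        replicate = MultipleAlignment(
            ids=list(alignment.ids),
            matrix=alignment.matrix[:, cols],
            region_name=alignment.region_name,
        )
        rep_bips = bipartitions(builder(replicate))
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    for key, edge in main_bips.items():
        edge.head_node.support = counts[key] / n_replicates
    return main


SUPPORT_CONVENTIONS = ("bs", "pp", "fraction")


def ingest_newick(path, support_convention: str) -> dendropy.Tree:
    """Read an externally built Newick tree, normalising supports to [0, 1].

    ``support_convention``: 'bs' for bootstrap percentages (divided by 100),
    'pp' for posterior probabilities, 'fraction' for already-normalised
    values.  Internal-node labels carry the support; polytopies are kept.
    """
    if support_convention not in SUPPORT_CONVENTIONS:
        raise ValueError(
            f"support_convention must be one of {SUPPORT_CONVENTIONS}, "
            f"got {support_convention!r}"
        )
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"cannot parse Newick file {path}: {exc}") from exc
    labels = tip_labels(tree)
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in {path}: {sorted(dupes)}")
    scale = 100.0 if support_convention == "bs" else 1.0
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.label is None:
            continue
        try:
            raw = float(node.label)
        except ValueError:
            continue
        sup = raw / scale
        if not 0.0 <= sup <= 1.0:
            raise ValueError(
                f"support {raw} out of range for convention {support_convention!r}"
            )
        node.support = sup
    return tree


def write_newick(tree: dendropy.Tree, path, support_digits: int = 3) -> None:
    """Write Newick with supports as internal-node labels (fractions)."""
    for node in tree.preorder_node_iter():
        sup = getattr(node, "support", None)
        if not node.is_leaf() and sup is not None:
            node.label = f"{sup:.{support_digits}f}"
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
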