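"""Distance-based phylogeny with bootstrap support.

This is the PROTDIST/NEIGHBOR/SEQBOOT/CONSENSE-style branch of the pipeline:
Kimura-corrected protein distances, Saitou-Nei neighbor-joining, bootstrap
resampling of alignment columns, and mapping of split supports from the
replicate forest onto the tree inferred from the full alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import dendropy
import numpy as np

from .errors import DataError
from .msa import Alignment
from .trees import SupportTree

logger = logging.getLogger(__name__)

#: Kimura correction saturates as p -> 0.8541 (argument of the log -> 0);
#: saturated pairs are capped at this distance instead of aborting the run.
MAX_DISTANCE = 10.0

GAP = ord("-")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise evolutionary distances."""

    labels: List[str]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise DataError("distances must be finite and non-negative")


def kimura_distance(p: float) -> float:
    """Kimura's empirical correction d = -ln(1 - p - p^2/5).

    ``p`` is the proportion of differing residues over mutually ungapped
    columns.  The argument hits zero near p = 0.8541; beyond that (and for
    any correction exceeding MAX_DISTANCE) the distance is capped.
    """
    arg = 1.0 - p - p * p / 5.0
    if arg <= 0:
        return MAX_DISTANCE
    return min(-np.log(arg), MAX_DISTANCE)


def _encode_rows(aln: Alignment) -> np.ndarray:
    return np.array(
        [np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8) for rec in aln.records]
    )


def protein_distance(aln: Alignment) -> DistanceMatrix:
    """Kimura-corrected distance matrix from a (trimmed) alignment.

    Every pair must share at least one mutually ungapped column.
    """
    labels = [rec.id for rec in aln.records]
    rows = _encode_rows(aln)
    return _distance_from_rows(labels, rows)


def _distance_from_rows(labels: Sequence[str], rows: np.ndarray) -> DistanceMatrix:
    n = len(labels)
    ungapped = rows != GAP  # (n, L)
    comparable = ungapped[:, None, :] & ungapped[None, :, :]  # (n, n, L)
    diff = (rows[:, None, :] != rows[None, :, :]) & comparable
    n_comp = comparable.sum(axis=2)
    bad = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if n_comp[i, j] == 0
    ]
    if bad:
        raise DataError(f"no mutually ungapped columns for pairs: {bad[:3]}")
    with np.errstate(invalid="ignore"):
        p = diff.sum(axis=2) / n_comp
    d = np.zeros((n, n))
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            dist = kimura_distance(p[i, j])
            if dist >= MAX_DISTANCE:
                saturated = True
            d[i, j] = d[j, i] = dist
    if saturated:
        logger.warning("saturated pair(s) capped at distance %.1f", MAX_DISTANCE)
    return DistanceMatrix(list(labels), d)


# ------------------------------------------------------------------- NJ


def nj_tree(dm: DistanceMatrix, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> SupportTree:
    """Saitou-Nei neighbor-joining.

    Ties in the Q matrix are broken by the lowest (row, column) index pair;
    negative branch-length estimates are clamped to zero.  The returned tree
    is unrooted (trifurcation at the seed node).
    """
    labels = dm.labels
    n = len(labels)
    if n < 3:
        raise DataError("neighbor-joining requires at least 3 taxa")
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        taxon = taxon_namespace.get_taxon(lab)
        if taxon is None:
            taxon = taxon_namespace.new_taxon(lab)
        nodes.append(dendropy.Node(taxon=taxon))
    # pending edge length for each active node, set when it is joined
    d = dm.d.astype(float).copy()
    active = list(range(n))
    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major argmin -> lowest (i, j) on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = dendropy.Node()
        child_i, child_j = node_of[i], node_of[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = bi
        child_j.edge.length = bj
        # distances from the new node u to every other active node k
        new_row = np.full(d.shape[0] + 1, 0.0)
        for ak, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        d[u, : u + 1] = new_row
        d[: u + 1, u] = new_row
        node_of[u] = parent
        active = [k for k in active if k not in (i, j)] + [u]
    # attach the final three (closed-form branch lengths)
    i, j, k = active
    bi = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    bj = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    bk = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    seed = tree.seed_node
    for idx, blen in zip((i, j, k), (bi, bj, bk)):
        seed.add_child(node_of[idx])
        node_of[idx].edge.length = blen
    tree.is_rooted = False
    return SupportTree(tree)


# -------------------------------------------------------------- bootstrap


def bootstrap_trees(
    aln: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
) -> List[SupportTree]:
    """Column-resampled replicate NJ trees (SEQBOOT-style pseudoreplicates).

    Each replicate resamples alignment columns with replacement to the
    original length; a replicate in which some pair has no comparable
    columns is redrawn (at most 10 retries, logged).
    """
    labels = [rec.id for rec in aln.records]
    rows = _encode_rows(aln)
    L = rows.shape[1]
    rng = np.random.default_rng(seed)
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(labels)
    out: List[SupportTree] = []
    for rep in range(n_reps):
        for attempt in range(10):
            cols = rng.integers(0, L, size=L)
            try:
                dm = _distance_from_rows(labels, rows[:, cols])
            except DataError:
                logger.warning("replicate %d attempt %d had an incomparable pair; redrawn", rep, attempt)
                continue
            break
        else:
            raise DataError(f"replicate {rep}: no comparable columns after 10 retries")
        out.append(nj_tree(dm, taxon_namespace=taxon_namespace))
    return out


def map_support(best_tree: SupportTree, replicate_trees: Sequence[SupportTree]) -> SupportTree:
    """Annotate each internal split of ``best_tree`` with its bootstrap support.

    Support is the percentage of replicates whose split set contains the
    split, rounded half-up to the nearest integer (PHYLIP convention).
    """
    leaves = best_tree.leaf_set()
    for rep in replicate_trees:
        if rep.leaf_set() != leaves:
            raise DataError("replicate tree leaf set differs from best tree")
    n = len(replicate_trees)
    if n == 0:
        raise DataError("no replicate trees supplied")
    counts = {}
    for rep in replicate_trees:
        for side in rep.split_set():
            counts[side] = counts.get(side, 0) + 1
    supports = {}
    for split in best_tree.splits():
        pct = 100.0 * counts.get(split.side, 0) / n
        supports[split.side] = int(np.floor(pct + 0.5))
    annotated = best_tree.clone()
    annotated.set_split_supports(supports)
    return annotated


def majority_consensus(replicate_trees: Sequence[SupportTree]) -> SupportTree:
    """Majority-rule consensus of the replicate forest (CONSENSE-style)."""
    tl = dendropy.TreeList([t.tree for t in replicate_trees])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cons = tl.consensus(min_freq=0.5)
    # dendropy labels consensus nodes with split frequencies in [0, 1];
    # convert to integer percentages so the tree round-trips as a SupportTree
    for node in cons.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            freq = float(node.label)
        except ValueError:
            node.label = None
            continue
        if freq <= 1.0:
            freq *= 100.0
        node.label = str(int(np.floor(freq + 0.5)))
    return SupportTree(cons)
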