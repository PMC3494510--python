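"""Independent reference implementations used only to check the package.

Each oracle is deliberately written with a different algorithmic route from
the code under test: plain-python dynamic programming, a literal codon
table, and graph-component split enumeration via networkx.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def naive_local_affine(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Textbook O(nm) Smith-Waterman with affine gaps (gap of g costs open + g*ext)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            diag = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = s + diag
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def table_translate_six_frames(nt: str) -> list:
    """Literal codon-table six-frame translation (transeq convention)."""
    nt = nt.upper()
    rc = nt.translate(_COMPLEMENT)[::-1]
    peptides = []
    for strand in (nt, rc):
        for off in (0, 1, 2):
            pep = []
            for i in range(off, len(strand) - 2, 3):
                pep.append(_CODON_TABLE.get(strand[i : i + 3], "X"))
            peptides.append("".join(pep))
    return peptides


def tree_graph(support_tree):
    """networkx graph of a SupportTree, with supports on internal edges."""
    g = nx.Graph()
    counter = itertools.count()
    names = {}

    def name(node):
        if node not in names:
            names[node] = (
                node.taxon.label if node.taxon else f"__internal_{next(counter)}"
            )
        return names[node]

    for node in support_tree.tree.preorder_node_iter():
        for child in node.child_nodes():
            sup = None
            if not child.is_leaf() and child.label not in (None, ""):
                sup = int(float(child.label))
            g.add_edge(name(node), name(child), support=sup)
    return g


def graph_splits(support_tree):
    """All splits (leafset side, support) by deleting each graph edge."""
    g = tree_graph(support_tree)
    leaves = {n for n in g.nodes if not n.startswith("__internal_")}
    ref = min(leaves)
    out = {}
    for u, v, data in list(g.edges(data=True)):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v, **data)
        side = frozenset(comp & leaves)
        if not side or side == leaves:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        prev = out.get(side)
        if prev is None or (prev[0] is None and data["support"] is not None):
            out[side] = (data["support"], min(len(side), len(leaves) - len(side)) == 1)
    return out  # side -> (support or None, trivial)


def brute_force_monophyly(support_tree, recipients, donors, support_min=70):
    """Exhaustive split enumeration verdict, independent of the package logic."""
    leaves = frozenset(l for l in graph_splits_leafset(support_tree))
    recipients = frozenset(recipients)
    donors = frozenset(donors) & leaves
    if not (leaves - recipients - donors):
        return "uninformative"
    splits = graph_splits(support_tree)
    qualifying, supported = [], []
    for side, (sup, trivial) in splits.items():
        for s in (side, frozenset(leaves - side)):
            if recipients <= s and s <= (recipients | donors) and s & donors:
                comp = leaves - s
                if len(comp) == 1 and not (comp & (recipients | donors)):
                    continue  # tautological one-outside-leaf complement
                eff = 100 if trivial else (sup if sup is not None else 0)
                qualifying.append(s)
                if eff >= support_min:
                    supported.append(s)
    if supported:
        return "pass"
    return "fail"


def graph_splits_leafset(support_tree):
    g = tree_graph(support_tree)
    return {n for n in g.nodes if not n.startswith("__internal_")}


def union_find_components(ids, edges):
    """Transitive closure by explicit union-find (oracle for clustering)."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(s) for s in groups.values())


def random_tree_newick(labels, rng, blen_range=(0.1, 1.0)) -> str:
    """Random unrooted topology with uniform branch lengths, as Newick."""
    def bl():
        return round(float(rng.uniform(*blen_range)), 6)

    nodes = [f"{lab}:{bl()}" for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{bl()}")
    return "(" + ",".join(nodes) + ");"
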