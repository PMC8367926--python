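"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computation paths: set algebra
for the incidence indices, explicit root-to-tip edge enumeration (via raw
dendropy traversal) for the branch-length indices, exhaustive spanning-tree
search for the truncation threshold, and per-column OLS for RDA.
"""
from __future__ import annotations

import itertools

import dendropy
import numpy as np


# --- taxonomic indices from plain set algebra ------------------------------

def sorensen_oracle(si: set, sj: set) -> float:
    a = len(si & sj)
    b = len(si - sj)
    c = len(sj - si)
    return (b + c) / (2 * a + b + c)


def turnover_oracle(si: set, sj: set) -> float:
    a = len(si & sj)
    m = min(len(si - sj), len(sj - si))
    return m / (a + m) if m else 0.0


# --- branch-length indices by explicit path enumeration --------------------

def edge_sets(newick: str):
    """Map each tip label to the ids of edges on its root-to-tip path."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    lengths = {}
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(id(node.edge))
            lengths[id(node.edge)] = float(node.edge.length)
            node = node.parent_node
        paths[leaf.taxon.label] = frozenset(path)
    return paths, lengths


def pd_oracle(tips, newick: str) -> float:
    paths, lengths = edge_sets(newick)
    union = frozenset().union(*(paths[t] for t in tips))
    return sum(lengths[e] for e in union)


def phylosor_total_oracle(si, sj, newick: str) -> float:
    pdi = pd_oracle(si, newick)
    pdj = pd_oracle(sj, newick)
    pdt = pd_oracle(set(si) | set(sj), newick)
    return (2 * pdt - pdi - pdj) / (pdi + pdj)


def phylosor_turnover_oracle(si, sj, newick: str) -> float:
    pdi = pd_oracle(si, newick)
    pdj = pd_oracle(sj, newick)
    pdt = pd_oracle(set(si) | set(sj), newick)
    a = pdi + pdj - pdt
    m = min(pdt - pdj, pdt - pdi)
    return m / (a + m) if m > 0 else 0.0


def cophenetic_oracle(x: str, y: str, newick: str) -> float:
    """Patristic distance as symmetric difference of root paths."""
    paths, lengths = edge_sets(newick)
    return sum(lengths[e] for e in paths[x] ^ paths[y])


# --- minimax spanning-tree edge by exhaustion ------------------------------

def minimax_spanning_edge_oracle(d: np.ndarray) -> float:
    """min over all spanning trees of the longest edge (n <= 7)."""
    n = d.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, max(d[i, j] for i, j in combo))
    return best


# --- RDA R^2 via independent per-column regressions ------------------------

def rda_r2_oracle(y: np.ndarray, x: np.ndarray) -> float:
    """1 - residual SS from separate per-column OLS fits / total SS."""
    yc = y - y.mean(axis=0)
    xc = np.column_stack([np.ones(len(x)), x])
    ss_res = 0.0
    for col in range(yc.shape[1]):
        beta, *_ = np.linalg.lstsq(xc, yc[:, col], rcond=None)
        resid = yc[:, col] - xc @ beta
        ss_res += float(resid @ resid)
    ss_tot = float((yc * yc).sum())
    return 1.0 - ss_res / ss_tot


def random_community(rng, n_plots: int, species) -> list:
    """Random non-empty plots as python sets over a species pool."""
    species = list(species)
    out = []
    for _ in range(n_plots):
        k = int(rng.integers(1, len(species) + 1))
        out.append(set(rng.choice(species, size=k, replace=False)))
    return out
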