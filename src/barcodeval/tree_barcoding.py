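"""Tree-based barcoding: neighbor joining, site-resampling bootstrap,
and per-species monophyly scoring.

The NJ implementation is the canonical agglomerative algorithm on the
Q-criterion Q(i,j) = (n-2) d(i,j) - R_i - R_j, with deterministic
tie-breaking (the pair whose sorted clade labels are lexicographically
smallest) and negative branch lengths clamped to zero with the deficit
moved to the sister branch so the joined path length is preserved.
Monophyly of a species is the existence of an internal edge whose removal
bipartitions the leaves into exactly that species' individuals versus all
the rest.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distance_barcoding import DistanceMatrix, encode_alignment
from .io_formats import MarkerAlignment, SpeciesMap


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[int] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class NJTree:
    """An unrooted binary tree, stored rooted at a degree-3 internal node."""

    root: Node

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Non-trivial bipartitions keyed by canonical leaf-set side.

        The canonical side is the one not containing the lexicographically
        smallest leaf name, so orientation is well defined on an unrooted
        tree.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], Node] = {}

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if anchor in below else below
                out[side] = node
            return below

        walk(self.root)
        return out

    def to_newick(self, escape: str = "underscore") -> str:
        def esc(name: str) -> str:
            if any(c.isspace() for c in name):
                if escape == "quote":
                    return f"'{name}'"
                return name.replace(" ", "_")
            return name

        def render(node: Node) -> str:
            if node.is_leaf:
                return f"{esc(node.name)}:{node.length:.10g}"
            inner = ",".join(render(ch) for ch in node.children)
            label = "" if node.support is None else str(int(node.support))
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"

        return render(self.root) + ";"


def nj_tree(dm: DistanceMatrix) -> NJTree:
    """Canonical neighbor joining on a complete p-distance matrix.

    On an additive distance matrix the generating topology and branch
    lengths are recovered exactly. NA distances are not accepted: impute
    or drop the offending individuals first.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.d).any():
        raise ValueError(
            "distance matrix contains NA pairs; impute them or remove the "
            "individuals with no shared sites before building a tree"
        )
    D = dm.d.astype(float).copy()
    nodes = [Node(name=i) for i in dm.ids]
    # clade label = smallest leaf name under the node, for tie-breaking
    labels = list(dm.ids)

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in ties if i < j
        )
        _, i, j = best
        dij = D[i, j]
        li = dij / 2.0 + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = Node(children=[child_i, child_j])
        new_label = min(labels[i], labels[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [new_label]

    # final three-way join at the central node
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, (dab + dac - dbc) / 2.0)
    b.length = max(0.0, (dab + dbc - dac) / 2.0)
    c.length = max(0.0, (dac + dbc - dab) / 2.0)
    order = sorted(range(3), key=lambda k: labels[k])
    root = Node(children=[nodes[k] for k in order])
    return NJTree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _distance_matrix_from_encoded(enc: np.ndarray, valid: np.ndarray,
                                  ids: list[str]) -> Optional[np.ndarray]:
    """p-distance matrix via one-hot inner products; None when a pair
    shares no valid column."""
    n, L = enc.shape
    onehot = np.zeros((n, 4 * L), dtype=np.float32)
    for s in range(4):
        onehot[:, s * L:(s + 1) * L] = (enc == s)
    matches = onehot @ onehot.T
    shared = valid.astype(np.float32) @ valid.astype(np.float32).T
    if (shared[np.triu_indices(n, 1)] == 0).any():
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (shared - matches) / shared
    np.fill_diagonal(d, 0.0)
    return d.astype(float)


def bootstrap_support(aln: MarkerAlignment, species_map: SpeciesMap,
                      n_boot: int = 1000, seed: int = 0) -> NJTree:
    """NJ tree from the full alignment with column-bootstrap edge supports.

    Columns are resampled with replacement ``n_boot`` times; the support of
    an internal edge is the percentage of replicate trees containing the
    same leaf bipartition. Replicate r draws from a generator seeded with
    seed + r, so supports are reproducible bit for bit. Replicates in
    which some pair shares no sampled column are dropped from the
    denominator.
    """
    from .distance_barcoding import p_distance_matrix

    dm = p_distance_matrix(aln)
    tree = nj_tree(dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    enc = encode_alignment(aln)
    valid = enc >= 0
    L = enc.shape[1]
    n_used = 0
    for r in range(n_boot):
        rng = np.random.default_rng(seed + r)
        idx = rng.integers(0, L, size=L)
        d = _distance_matrix_from_encoded(enc[:, idx], valid[:, idx],
                                          list(aln.ids))
        if d is None:
            continue
        rep_dm = DistanceMatrix(list(aln.ids), d,
                                np.full_like(d, L, dtype=np.int64))
        rep_bps = nj_tree(rep_dm).bipartitions()
        n_used += 1
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in target.items():
        node.support = round(100.0 * counts[bp] / n_used) if n_used else 0
    return tree


def monophyly(tree: NJTree, species_map: SpeciesMap,
              min_individuals: int = 2) -> dict[str, bool]:
    """Per-species monophyly on an unrooted tree.

    A species with at least ``min_individuals`` leaves is monophyletic iff
    removing one edge separates exactly its leaf set from the rest.
    """
    leaf_names = set(tree.leaf_names())
    all_leaves = frozenset(leaf_names)
    anchor = min(all_leaves)
    sides = set(tree.bipartitions())
    out: dict[str, bool] = {}
    for sp in species_map.species():
        inds = [i for i in species_map.individuals_of(sp) if i in leaf_names]
        missing = [i for i in species_map.individuals_of(sp)
                   if i not in leaf_names]
        if missing and inds:
            raise ValueError(
                f"species {sp!r} has leaves absent from the tree: {missing}"
            )
        if len(inds) < min_individuals:
            continue
        clade = frozenset(inds)
        if len(clade) == len(all_leaves):
            out[sp] = True
            continue
        side = all_leaves - clade if anchor in clade else clade
        # an (n-1)-leaf side is the trivial bipartition of a single leaf's
        # pendant edge: the complement clade is still monophyletic
        out[sp] = side in sides or len(clade) == len(all_leaves) - 1
    return out


def score_tree(tree: NJTree, species_map: SpeciesMap,
               min_individuals: int = 2
               ) -> tuple[float, list[str], list[str]]:
    """(rate %, monophyletic species, singleton species not counted)."""
    mono = monophyly(tree, species_map, min_individuals)
    leaf_names = set(tree.leaf_names())
    singletons = [
        sp for sp in species_map.species()
        if 0 < len([i for i in species_map.individuals_of(sp)
                    if i in leaf_names]) < min_individuals
    ]
    identified = [sp for sp, ok in mono.items() if ok]
    rate = 100.0 * len(identified) / len(mono) if mono else 0.0
    return rate, identified, singletons
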