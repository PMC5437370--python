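"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import collections

import numpy as np
import pytest

from barcodeval.io_formats import MarkerAlignment, SpeciesMap

BASES = np.array(list("ACGT"))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, length))


def substitute(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths.

    Returns (distance matrix, leaf names, non-trivial bipartitions as
    canonical frozensets). Built by sequential leaf attachment; serves as
    the construction oracle for neighbor joining.
    """
    adj: dict = {0: [], 1: [], 2: [], "c0": []}
    for lf in range(3):
        w = float(rng.uniform(0.1, 1.0))
        adj["c0"].append((lf, w))
        adj[lf].append(("c0", w))
    nxt = 1
    for lf in range(3, n_leaves):
        edges = [(x, y) for x in adj for y, _ in adj[x] if repr(x) < repr(y)]
        a, b = edges[rng.integers(0, len(edges))]
        w = dict(adj[a])[b]
        mid = f"c{nxt}"
        nxt += 1
        adj[a] = [(x, l) for x, l in adj[a] if x != b]
        adj[b] = [(x, l) for x, l in adj[b] if x != a]
        w1 = w * float(rng.uniform(0.2, 0.8))
        adj[mid] = [(a, w1), (b, w - w1)]
        adj[a].append((mid, w1))
        adj[b].append((mid, w - w1))
        wl = float(rng.uniform(0.1, 1.0))
        adj[lf] = [(mid, wl)]
        adj[mid].append((lf, wl))
    names = [f"L{i:02d}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for s in range(n_leaves):
        dist = {s: 0.0}
        queue = collections.deque([s])
        while queue:
            u = queue.popleft()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    queue.append(v)
        for t in range(n_leaves):
            D[s, t] = dist[t]
    bips = set()
    allv = frozenset(names)
    for x in adj:
        for y, _ in adj[x]:
            if repr(x) < repr(y):
                seen = {x, y}
                queue = collections.deque([y])
                side = set()
                while queue:
                    u = queue.popleft()
                    if isinstance(u, int):
                        side.add(names[u])
                    for v, _ in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            queue.append(v)
                if 1 < len(side) < n_leaves - 1:
                    s_ = frozenset(side)
                    if min(allv) in s_:
                        s_ = allv - s_
                    bips.add(s_)
    return D, names, bips


def brute_force_p_distance(row_a: str, row_b: str) -> float:
    """Independent per-column p-distance loop (pairwise deletion)."""
    shared = mism = 0
    for a, b in zip(row_a, row_b):
        if a in "ACGT" and b in "ACGT":
            shared += 1
            if a != b:
                mism += 1
    return mism / shared if shared else float("nan")


@pytest.fixture
def two_species_alignment():
    ids = ["x1", "x2", "x3", "y1", "y2", "y3"]
    rows = ["AAAAGGGG", "AAAAGGGG", "AAATGGGG",
            "CCCCGGGG", "CCCCGGGG", "CCCCGGGT"]
    aln = MarkerAlignment("m1", ids, rows)
    smap = SpeciesMap({i: ("X" if i.startswith("x") else "Y", None, None)
                       for i in ids})
    return aln, smap


@pytest.fixture
def clean_dataset():
    from barcodeval.synthetic_data import preset_config, simulate_dataset
    return simulate_dataset(preset_config("clean", seed=17))
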