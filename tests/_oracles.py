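"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive — direct enumeration or Monte-Carlo
sampling — and shares no code with the corresponding fps routine.
"""

from __future__ import annotations

import math

import numpy as np


def mc_atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_points: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo solvent-accessible area per atom.

    Samples points uniformly on each atom's expanded sphere (r + probe) and
    counts the fraction not buried inside any other expanded sphere.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    areas = np.zeros(n)
    for i in range(n):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * exposed.mean()
    return areas


def brute_betweenness(adjacency: dict) -> dict:
    """Raw betweenness by exhaustive enumeration of all shortest paths."""
    nodes = sorted(adjacency)

    def all_shortest_paths(s, t):
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adjacency[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    cbw = {n: 0.0 for n in nodes}
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            paths = all_shortest_paths(nodes[a], nodes[b])
            if not paths:
                continue
            for n in nodes:
                if n in (nodes[a], nodes[b]):
                    continue
                through = sum(1 for p in paths if n in p[1:-1])
                cbw[n] += through / len(paths)
    return cbw


def brute_rvet(sequences: dict, newick: str, column: int) -> float:
    """rvET of one column by explicit partition enumeration via Bio.Phylo.

    Same grouping convention as the package (open internal nodes root-first
    by depth, ties by smallest leaf label; weights 1/n), but independently
    coded on a different tree library.
    """
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    root = tree.root

    def leaves(clade):
        return sorted(term.name for term in clade.get_terminals())

    depths = tree.depths(unit_branch_lengths=all(
        cl.branch_length is None for cl in tree.find_clades()
    ))
    internal = [cl for cl in tree.find_clades() if not cl.is_terminal()]

    def entropy(ids):
        col = [sequences[i][column - 1] for i in ids]
        col = [c for c in col if c != "-"]
        if not col:
            return 0.0
        counts = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        tot = len(col)
        return -sum((v / tot) * math.log(v / tot) for v in counts.values())

    opened = []
    remaining = list(internal)
    partitions = [[leaves(root)]]
    while remaining:
        openable = [
            cl for cl in remaining
            if cl is root or any(cl in p.clades for p in opened)
        ]
        if not openable:
            break
        nxt = min(openable, key=lambda cl: (depths[cl], leaves(cl)[0]))
        opened.append(nxt)
        remaining.remove(nxt)
        if remaining:
            groups = []
            for op in opened:
                for child in op.clades:
                    if child not in opened:
                        groups.append(leaves(child))
            partitions.append(sorted(groups))

    total = 0.0
    for groups in partitions:
        n = len(groups)
        total += (1.0 / n) * sum((1.0 / n) * entropy(g) for g in groups)
    return 1.0 + total


def brute_parsimony_score(sequences: dict, newick: str, column: int) -> int:
    """Minimum number of state changes on the tree by exhaustive assignment."""
    import itertools
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    internal = [cl for cl in tree.find_clades() if not cl.is_terminal()]
    states = sorted({sequences[t.name][column - 1] for t in tree.get_terminals()})

    def score(assign):
        changes = 0
        for parent in tree.find_clades(order="level"):
            for child in parent.clades:
                ps = assign[id(parent)] if not parent.is_terminal() else None
                cs = (
                    assign[id(child)]
                    if not child.is_terminal()
                    else sequences[child.name][column - 1]
                )
                if ps is not None and ps != cs:
                    changes += 1
        return changes

    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        assign = {id(cl): s for cl, s in zip(internal, combo)}
        sc = score(assign)
        best = sc if best is None else min(best, sc)
    return best if best is not None else 0
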