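"""Real-valued evolutionary trace (rvET) scoring.

The rvET score of an alignment column combines its Shannon entropy with the
phylogenetic tree: for each partition of the tree into n groups (obtained by
opening internal nodes root-first, n = 1 … N−1 for N leaves), the column's
entropy is evaluated *within* each group, the group entropies are combined
with group weights, the per-partition sums are combined with node weights,
and 1 is added:

    rvET_i = 1 + sum_n w_node(n) * sum_g w_group(g) * s_i(g)
    s_i    = - sum_a f_ia ln f_ia            (a over the 20 amino acids)

A column that is invariant (identical residue in every sequence) scores
exactly 1; lower scores mark evolutionarily more important positions.  Gaps
are excluded from the frequency counts and an all-gap group contributes
zero entropy.  Default weights are w_node = w_group = 1/n at partition depth
n; both are pluggable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass
class Alignment:
    """Aligned amino-acid sequences keyed by id."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")

    @property
    def ncols(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return sorted(self.sequences)

    def column(self, i: int, ids: Sequence[str] | None = None) -> list[str]:
        """Residues of 1-based column ``i`` (optionally restricted to ids)."""
        if not (1 <= i <= self.ncols):
            raise IndexError(f"column {i} out of range 1..{self.ncols}")
        use = ids if ids is not None else self.ids
        return [self.sequences[s][i - 1] for s in use]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(sequences=seqs)


@dataclass
class RvETProfile:
    """Per-column entropy and rvET score; rank 1 = most important."""

    entropy: dict[int, float]  # column -> nats; missing for all-gap columns
    scores: dict[int, float]  # column -> rvET >= 1

    def ranked(self) -> list[int]:
        """Columns sorted by (score ascending, index ascending)."""
        return sorted(self.scores, key=lambda i: (self.scores[i], i))


def _entropy(column: Sequence[str]) -> float | None:
    """Shannon entropy (nats) over amino-acid counts; None for all-gap."""
    counts: dict[str, int] = {}
    for aa in column:
        if aa in AMINO_ACIDS:
            counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None
    return -sum((c / total) * math.log(c / total) for c in counts.values()) + 0.0


def position_entropy(aln: Alignment, i: int) -> float | None:
    """Column entropy in nats, gaps excluded; None when the column is all gaps."""
    return _entropy(aln.column(i))


def load_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def neighbor_joining_tree(aln: Alignment) -> dendropy.Tree:
    """Convenience NJ tree from pairwise p-distances (not a server pipeline)."""
    import skbio

    ids = aln.ids
    n = len(ids)
    dm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = aln.sequences[ids[a]], aln.sequences[ids[b]]
            compared = [(x, y) for x, y in zip(sa, sb) if x != GAP and y != GAP]
            if compared:
                p = sum(1 for x, y in compared if x != y) / len(compared)
            else:
                p = 1.0
            dm[a, b] = dm[b, a] = p
    newick = str(skbio.tree.nj(skbio.DistanceMatrix(dm, ids)))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree


def _tree_partitions(tree: dendropy.Tree) -> list[list[list[str]]]:
    """Successive partitions of the leaf set, opening internal nodes root-first.

    Partition k (k = 0, 1, ...) opens the k shallowest internal nodes (the
    root first; a node only after its parent), and its groups are the leaf
    sets hanging below each unopened child of an opened node — with partition
    0 being the single group of all leaves.  For a binary tree this yields
    partitions into 1, 2, ..., N-1 groups.
    """
    tree = tree.clone(depth=1)
    if tree.seed_node is None:
        raise ValueError("empty tree")
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]

    def sort_key(nd):
        depth = nd.distance_from_root() or 0.0
        label = min(lf.taxon.label for lf in nd.leaf_iter())
        return (depth, label)

    # open root-first; a node becomes openable only once its parent is open
    opened: list = []
    candidates = set(internal)
    partitions: list[list[list[str]]] = []

    def groups_for(opened_set: set) -> list[list[str]]:
        groups = []
        if tree.seed_node not in opened_set:
            return [sorted(lf.taxon.label for lf in tree.seed_node.leaf_iter())]
        for nd in opened_set:
            for child in nd.child_nodes():
                if child not in opened_set:
                    groups.append(sorted(lf.taxon.label for lf in child.leaf_iter()))
        return sorted(groups)

    partitions.append(groups_for(set()))
    opened_set: set = set()
    while len(opened_set) < len(internal):
        openable = [
            nd for nd in candidates - opened_set
            if nd.parent_node is None or nd.parent_node in opened_set
        ]
        if not openable:
            break
        nxt = min(openable, key=sort_key)
        opened_set.add(nxt)
        if len(opened_set) < len(internal):  # the fully-open cut (all leaves) is unused
            partitions.append(groups_for(opened_set))
    return partitions


def rvet_scores(
    aln: Alignment,
    tree: dendropy.Tree | None = None,
    w_node: Callable[[int], float] | None = None,
    w_group: Callable[[int], float] | None = None,
) -> RvETProfile:
    """rvET score per column from an alignment and its tree.

    Tree leaves must match the alignment ids exactly; without a tree a
    neighbor-joining tree from p-distances is built.  ``w_node(n)`` and
    ``w_group(n)`` receive the group count of a partition and default to 1/n.
    """
    if len(aln.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if tree is None:
        tree = neighbor_joining_tree(aln)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    aln_ids = set(aln.ids)
    if leaf_labels != aln_ids:
        orphans = sorted(leaf_labels ^ aln_ids)
        raise ValueError(f"tree/alignment id mismatch; orphans: {orphans}")

    wn = w_node if w_node is not None else (lambda n: 1.0 / n)
    wg = w_group if w_group is not None else (lambda n: 1.0 / n)
    partitions = _tree_partitions(tree)

    entropy: dict[int, float] = {}
    scores: dict[int, float] = {}
    for i in range(1, aln.ncols + 1):
        s_full = _entropy(aln.column(i))
        if s_full is None:
            continue  # all-gap column: reported as missing
        entropy[i] = s_full
        total = 0.0
        for groups in partitions:
            n = len(groups)
            group_sum = 0.0
            for g in groups:
                s_g = _entropy(aln.column(i, ids=g))
                group_sum += wg(n) * (s_g if s_g is not None else 0.0)
            total += wn(n) * group_sum
        scores[i] = 1.0 + total
    return RvETProfile(entropy=entropy, scores=scores)


def rank_top_fraction(profile: RvETProfile, fraction: float) -> list[int]:
    """The floor(fraction * ncols) best-ranked columns, ties by lower index."""
    if not profile.scores:
        raise ValueError("empty profile")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.floor(fraction * len(profile.scores))
    return profile.ranked()[:k]


def branch_substitutions(
    aln: Alignment,
    tree: dendropy.Tree,
    column: int,
) -> list[tuple[str, str, str, str]]:
    """Edges where the Fitch-parsimony state of a column changes.

    Ancestral states are inferred by small parsimony (Fitch; at
    multifurcations the states shared by the most children are kept) with
    deterministic tie resolution (alphabetically smallest state).  Returns
    ``(parent_label, child_label, parent_state, child_state)`` per changing
    edge; internal nodes are labelled by their smallest descendant leaf id
    prefixed with ``anc:``.
    """
    tree = tree.clone(depth=1)
    states = {lab: aln.sequences[lab][column - 1] for lab in aln.ids}

    # bottom-up state sets; for multifurcations keep the states present in
    # the largest number of child sets (reduces to intersection-else-union
    # on binary nodes)
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.fitch = frozenset({states[nd.taxon.label]})
        else:
            child_sets = [c.fitch for c in nd.child_nodes()]
            counts: dict[str, int] = {}
            for cs in child_sets:
                for s in cs:
                    counts[s] = counts.get(s, 0) + 1
            top = max(counts.values())
            nd.fitch = frozenset(s for s, c in counts.items() if c == top)

    # top-down assignment with deterministic ties
    def label(nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label
        leaves = [lf.taxon.label for lf in nd.leaf_iter()]
        return f"anc:{min(leaves)}+{len(leaves)}"

    changes = []
    root = tree.seed_node
    root.state = min(root.fitch)
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        parent_state = nd.parent_node.state
        nd.state = parent_state if parent_state in nd.fitch else min(nd.fitch)
        if nd.state != parent_state:
            changes.append((label(nd.parent_node), label(nd), parent_state, nd.state))
    return changes


def load_chey_sequence() -> str:
    """The packaged E. coli CheY sequence (129 residues)."""
    import importlib.resources

    ref = importlib.resources.files("fps.data") / "chey_ecoli.fasta"
    rec = next(SeqIO.parse(StringIO(ref.read_text()), "fasta"))
    return str(rec.seq)
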