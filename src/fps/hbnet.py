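"""Protein–water hydrogen-bond networks and betweenness centrality.

Nodes are residue sidechains and crystallographic waters; an undirected edge
joins two nodes whose polar heavy atoms (sidechain N/O, water O) lie within
the hydrogen-bond distance cutoff (default 3.5 Å).  Crystal structures
usually lack hydrogens, so the donor–hydrogen–acceptor angle criterion
(default 60°) is applied only when hydrogen positions are present in the
file.  Backbone atoms are excluded throughout.

Betweenness centrality is reported raw (unnormalized): for node n it is the
sum over unordered node pairs (n1, n2), both different from n, of the
fraction of shortest n1–n2 paths that pass through n, with unit edge
weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import biotite.structure as struc
import networkx as nx
import numpy as np

from fps.solvation import load_structure, _one_letter

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: sidechain hydrogen-bond donor/acceptor heavy atoms per residue type
POLAR_SIDECHAIN_ATOMS: Mapping[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "CYS": ("SG",),
    "MET": (),
    "MSE": (),
}


@dataclass(frozen=True)
class GroupStats:
    """Mean ± SD of centrality per residue group plus a detected/undetected ratio."""

    means: dict[str, tuple[float, float]]  # label -> (mean, sd); NaNs when empty
    ratio: float
    ratio_se: float


def _water_mask(atoms: struc.AtomArray) -> np.ndarray:
    return np.isin(atoms.res_name, list(WATER_NAMES))


def count_waters(structure: str | Path | struc.AtomArray, chain: str | None = None) -> int:
    """Number of water (HOH) residues in the structure.

    With ``chain`` given, each water is assigned to the protein chain owning
    its nearest protein atom and only waters of that chain are counted.
    """
    atoms = structure if isinstance(structure, struc.AtomArray) else load_structure(structure)
    waters = atoms[_water_mask(atoms)]
    if waters.array_length() == 0:
        return 0
    water_ids = {
        (waters.chain_id[i], waters.res_id[i]) for i in range(waters.array_length())
    }
    if chain is None:
        return len(water_ids)
    protein = atoms[struc.filter_amino_acids(atoms)]
    if protein.array_length() == 0:
        return 0
    count = 0
    # one representative O per water
    for cid, rid in water_ids:
        mask = (waters.chain_id == cid) & (waters.res_id == rid)
        pos = waters.coord[mask][0]
        dists = np.linalg.norm(protein.coord - pos, axis=1)
        nearest_chain = protein.chain_id[int(np.argmin(dists))]
        if nearest_chain == chain:
            count += 1
    return count


def _node_label(chain: str, res_id: int, res_name: str) -> str:
    if res_name in WATER_NAMES:
        return f"HOH:{chain}:{res_id}"
    return f"{_one_letter(res_name)}{res_id}:{chain}"


def build_hbond_graph(
    structure: str | Path | struc.AtomArray,
    d_max: float = 3.5,
    angle_max: float = 60.0,
    chain: str | None = None,
) -> nx.Graph:
    """Undirected H-bond graph over residue sidechains and waters.

    Edges join polar sidechain heavy atoms / water oxygens within ``d_max``
    Å; parallel atom–atom contacts between the same residue pair collapse to
    one edge annotated with the closest atom pair.  The angle criterion uses
    donor hydrogens when the file has them and is otherwise skipped.  Waters
    with no partner within the cutoff are left out of the graph (use
    :func:`count_waters` for the full inventory).
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    atoms = structure if isinstance(structure, struc.AtomArray) else load_structure(structure)
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]

    polar_idx: list[int] = []
    for i in range(atoms.array_length()):
        rn = atoms.res_name[i]
        an = atoms.atom_name[i]
        if rn in WATER_NAMES:
            if atoms.element[i] == "O":
                polar_idx.append(i)
        elif an in POLAR_SIDECHAIN_ATOMS.get(rn, ()):
            polar_idx.append(i)
    graph = nx.Graph()
    if not polar_idx:
        logger.warning("no polar sidechain/water atoms found; graph is empty")
        return graph

    idx = np.array(polar_idx)
    coords = atoms.coord[idx]
    has_h = bool(np.any(atoms.element == "H"))
    hydrogens = atoms[atoms.element == "H"] if has_h else None

    def node_of(i: int) -> str:
        return _node_label(str(atoms.chain_id[i]), int(atoms.res_id[i]), str(atoms.res_name[i]))

    order = sorted(
        range(len(idx)),
        key=lambda k: (str(atoms.chain_id[idx[k]]), int(atoms.res_id[idx[k]]), str(atoms.atom_name[idx[k]])),
    )
    idx = idx[order]
    coords = coords[order]

    n = len(idx)
    for a in range(n):
        ia = idx[a]
        for b in range(a + 1, n):
            ib = idx[b]
            same_residue = (
                atoms.chain_id[ia] == atoms.chain_id[ib]
                and atoms.res_id[ia] == atoms.res_id[ib]
                and atoms.res_name[ia] == atoms.res_name[ib]
            )
            if same_residue:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[b]))
            if dist > d_max:
                continue
            if has_h and not _angle_ok(atoms, hydrogens, ia, ib, angle_max):
                continue
            u, v = node_of(ia), node_of(ib)
            if graph.has_edge(u, v):
                if dist < graph[u][v]["distance"]:
                    graph[u][v].update(
                        distance=dist,
                        atoms=(str(atoms.atom_name[ia]), str(atoms.atom_name[ib])),
                    )
            else:
                graph.add_edge(
                    u, v,
                    distance=dist,
                    atoms=(str(atoms.atom_name[ia]), str(atoms.atom_name[ib])),
                )
    for node in graph.nodes:
        graph.nodes[node]["kind"] = "water" if node.startswith("HOH:") else "residue"
    return graph


def _angle_ok(atoms, hydrogens, ia: int, ib: int, angle_max: float) -> bool:
    """Accept the pair when either atom donates via a hydrogen within the cone.

    The criterion is the deviation of the H from the donor–acceptor axis:
    angle(A–D–H) must be <= angle_max for some hydrogen H bonded to (within
    1.2 Å of) donor D.  Pairs where neither atom has a hydrogen are accepted,
    mirroring distance-only behaviour for partially protonated files.
    """
    checked = False
    for d, a in ((ia, ib), (ib, ia)):
        dpos = atoms.coord[d]
        apos = atoms.coord[a]
        hd = np.linalg.norm(hydrogens.coord - dpos, axis=1)
        for hpos in hydrogens.coord[hd < 1.2]:
            checked = True
            v1 = hpos - dpos
            v2 = apos - dpos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang <= angle_max:
                return True
    return not checked


def betweenness_centrality(graph: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Raw betweenness (shortest-path counts) per node, unit edge weights.

    Disconnected pairs contribute nothing; leaves score 0.  Set
    ``normalized=True`` for cross-graph comparison (divides by the number of
    node pairs).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    return dict(nx.betweenness_centrality(graph, normalized=normalized))


def group_centrality_stats(
    profile: Mapping[str, float],
    groups: Mapping[str, str],
    detected_labels: Sequence[str] = ("low", "normal"),
    undetected_label: str = "not_detected",
) -> GroupStats:
    """Mean ± SD of centrality per group and the detected/undetected ratio.

    ``groups`` maps node names (as in the graph) to labels.  Nodes listed in
    ``groups`` but absent from ``profile`` are logged and ignored — a missing
    node is not imputed as zero.  The ratio's uncertainty propagates the
    standard errors of the two group means.
    """
    values: dict[str, list[float]] = {}
    for node, label in groups.items():
        if node not in profile:
            logger.warning("grouped node %s absent from centrality profile", node)
            continue
        values.setdefault(label, []).append(profile[node])

    means: dict[str, tuple[float, float]] = {}
    for label in sorted(set(groups.values())):
        vals = values.get(label, [])
        if not vals:
            means[label] = (float("nan"), float("nan"))
            continue
        arr = np.array(vals)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        means[label] = (float(arr.mean()), sd)

    detected = [v for lab in detected_labels for v in values.get(lab, [])]
    undetected = values.get(undetected_label, [])
    if detected and undetected and np.mean(undetected) > 0:
        md, mu = float(np.mean(detected)), float(np.mean(undetected))
        sem_d = np.std(detected, ddof=1) / np.sqrt(len(detected)) if len(detected) > 1 else 0.0
        sem_u = np.std(undetected, ddof=1) / np.sqrt(len(undetected)) if len(undetected) > 1 else 0.0
        ratio = md / mu
        ratio_se = ratio * float(np.sqrt((sem_d / md) ** 2 + (sem_u / mu) ** 2)) if md > 0 else float("nan")
    else:
        ratio, ratio_se = float("nan"), float("nan")
    return GroupStats(means=means, ratio=ratio, ratio_se=ratio_se)


def merged_network_ratio(
    per_structure: Sequence[GroupStats],
) -> tuple[float, float]:
    """Mean ± SD of the detected/undetected ratio across structures."""
    ratios = [g.ratio for g in per_structure if np.isfinite(g.ratio)]
    if not ratios:
        raise ValueError("no finite ratios to merge")
    arr = np.array(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd
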