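"""Synthetic inputs with machine-readable ground truth.

Everything the toolkit consumes — MASCOT-style identification tables and
LC-MS peak lists, toy PDB structures with planted hydrogen-bond geometry,
and multiple sequence alignments with per-column entropy targets — can be
generated here with a known ground truth, written alongside as a truth CSV.
Identical parameters and seed give byte-identical files: rows are written in
canonical order with a fixed float format.

The dose–response generator emulates a footprinting titration: per residue,
peak areas follow ``1 - F = exp(-PF * IR * dose)`` for a total ion current
of 1000 area units per dose, with optional Gaussian area noise of standard
deviation ``sigma * 1000``.  Each peptide contributes an unoxidized form and
one singly-oxidized form per planted residue, at distinct retention times
and with the oxidized form shifted by +15.9949/z Th.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import numpy as np
import pandas as pd
from scipy.optimize import brentq

FLOAT_FMT = "%.10g"
TOTAL_AREA = 1000.0
OXYGEN_MASS = 15.9949


# ---------------------------------------------------------------------------
# dose-response fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResiduePlan:
    """One planted residue: position, type, true protection factor."""

    residue: int
    residue_type: str
    pf: float


DEFAULT_DOSES = (0.0, 0.01, 0.02, 0.05, 0.1, 0.5, 1.0, 2.0)


def synth_dose_series(
    plan: Sequence[ResiduePlan],
    ir_table: Mapping[str, float],
    doses: Sequence[float] = DEFAULT_DOSES,
    sigma: float = 0.02,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (ids, peaks, truth) tables for a planted dose–response.

    Returns the three DataFrames and, when ``outdir`` is given, writes
    ``ids.csv``, ``peaks.csv`` and ``truth.csv`` there.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    doses = list(doses)
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be strictly increasing")
    for p in plan:
        if p.pf <= 0:
            raise ValueError(f"PF must be positive, got {p.pf} for residue {p.residue}")
        if p.residue_type not in ir_table:
            raise ValueError(f"no IR for residue type {p.residue_type}")

    rng = np.random.default_rng(seed)
    id_rows, peak_rows, truth_rows = [], [], []
    for k, p in enumerate(sorted(plan, key=lambda r: r.residue)):
        start = p.residue - 2
        peptide = "AG" + p.residue_type + "AGL"
        rt_unox = 10.0 + 3.0 * k
        rt_ox = rt_unox + 1.0
        mz_unox = 400.0 + 17.0 * k
        mz_ox = mz_unox + OXYGEN_MASS / 2.0
        charge = 2
        id_rows.append(
            dict(peptide=peptide, start=start, mod_site="", mod_mass="",
                 rt=rt_unox, mz=mz_unox, charge=charge)
        )
        id_rows.append(
            dict(peptide=peptide, start=start, mod_site=p.residue,
                 mod_mass=OXYGEN_MASS, rt=rt_ox, mz=mz_ox, charge=charge)
        )
        S = p.pf * ir_table[p.residue_type]
        truth_rows.append(
            dict(residue=p.residue, residue_type=p.residue_type,
                 true_pf=p.pf, true_slope=S, ir=ir_table[p.residue_type])
        )
        for dose in doses:
            frac = 1.0 - math.exp(-S * dose)
            a_ox = frac * TOTAL_AREA + rng.normal(0.0, sigma * TOTAL_AREA)
            a_unox = (1.0 - frac) * TOTAL_AREA + rng.normal(0.0, sigma * TOTAL_AREA)
            peak_rows.append(
                dict(dose_id=FLOAT_FMT % dose, rt=rt_ox, mz=mz_ox,
                     area=max(a_ox, 0.0))
            )
            peak_rows.append(
                dict(dose_id=FLOAT_FMT % dose, rt=rt_unox, mz=mz_unox,
                     area=max(a_unox, 0.0))
            )

    ids = pd.DataFrame(id_rows)
    peaks = pd.DataFrame(peak_rows).sort_values(
        ["dose_id", "rt", "mz"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ids.to_csv(outdir / "ids.csv", index=False, float_format=FLOAT_FMT)
        peaks.to_csv(outdir / "peaks.csv", index=False, float_format=FLOAT_FMT)
        truth.to_csv(outdir / "truth.csv", index=False, float_format=FLOAT_FMT)
    return ids, peaks, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass
class GeometryPlan:
    """Explicit atom placements for a toy PDB structure."""

    atoms: list[tuple[str, int, str, str, str, tuple[float, float, float]]] = field(
        default_factory=list
    )  # (chain, res_id, res_name, atom_name, element, xyz)

    def add(self, chain: str, res_id: int, res_name: str,
            atom_name: str, element: str, xyz: tuple[float, float, float]) -> "GeometryPlan":
        self.atoms.append((chain, res_id, res_name, atom_name, element, xyz))
        return self

    def add_water(self, chain: str, res_id: int, xyz: tuple[float, float, float]) -> "GeometryPlan":
        return self.add(chain, res_id, "HOH", "O", "O", xyz)

    def n_waters(self) -> int:
        return len({(c, r) for c, r, rn, *_ in self.atoms if rn == "HOH"})


def synth_toy_structure(plan: GeometryPlan, path: str | Path | None = None) -> struc.AtomArray:
    """Build an AtomArray (and optionally a PDB file) from a geometry plan.

    Raises when atoms of different residues clash below 1 Å (a physically
    impossible plan that would corrupt downstream geometry tests).
    """
    n = len(plan.atoms)
    if n == 0:
        raise ValueError("empty geometry plan")
    arr = struc.AtomArray(n)
    coords = np.zeros((n, 3), dtype=np.float32)
    for i, (chain, res_id, res_name, atom_name, element, xyz) in enumerate(plan.atoms):
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom_name
        arr.element[i] = element
        arr.hetero[i] = res_name == "HOH"
        coords[i] = xyz
    arr.coord = coords

    for i in range(n):
        for j in range(i + 1, n):
            same = (
                plan.atoms[i][0] == plan.atoms[j][0]
                and plan.atoms[i][1] == plan.atoms[j][1]
            )
            if same:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < 1.0:
                raise ValueError(
                    f"steric overlap {d:.2f} Å between atoms {i} and {j}"
                )
    if path is not None:
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    return arr


def bridge_plan() -> GeometryPlan:
    """Ser-OG —2.9 Å— water —3.0 Å— Asp-OD1: a single planted water bridge."""
    p = GeometryPlan()
    # SER 1: OG at origin, rest of the residue pointing away
    p.add("A", 1, "SER", "N", "N", (-3.9, 1.2, 0.0))
    p.add("A", 1, "SER", "CA", "C", (-2.6, 1.0, 0.0))
    p.add("A", 1, "SER", "CB", "C", (-1.4, 0.2, 0.0))
    p.add("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0))
    # bridging water
    p.add_water("A", 101, (2.9, 0.0, 0.0))
    # ASP 3: OD1 3.0 Å from the water; OD2 kept beyond 3.5 Å of it
    p.add("A", 3, "ASP", "OD1", "O", (5.9, 0.0, 0.0))
    p.add("A", 3, "ASP", "OD2", "O", (7.1, 1.6, 0.0))
    p.add("A", 3, "ASP", "CG", "C", (6.7, 0.5, 0.0))
    p.add("A", 3, "ASP", "CB", "C", (7.5, -0.7, 0.0))
    p.add("A", 3, "ASP", "CA", "C", (8.9, -0.3, 0.4))
    p.add("A", 3, "ASP", "N", "N", (9.9, -1.3, 0.2))
    return p


def hub_plan(n_waters: int = 6) -> GeometryPlan:
    """A serine hub hydrogen-bonded to waters placed on octahedron vertices.

    Waters sit 3.0 Å from the hub OG and > 3.5 Å from each other, so the
    hydrogen-bond graph is an exact star with the residue at the center.
    """
    if not (1 <= n_waters <= 6):
        raise ValueError("octahedral hub supports 1..6 waters")
    p = GeometryPlan()
    p.add("A", 1, "SER", "N", "N", (-3.9, 5.2, 0.0))
    p.add("A", 1, "SER", "CA", "C", (-2.6, 5.0, 0.0))
    p.add("A", 1, "SER", "CB", "C", (-1.6, 4.0, 0.0))
    p.add("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0))
    directions = [
        (3.0, 0.0, 0.0), (-3.0, 0.0, 0.0),
        (0.0, 3.0, 0.0), (0.0, -3.0, 0.0),
        (0.0, 0.0, 3.0), (0.0, 0.0, -3.0),
    ]
    # avoid the CB direction: CB is 4+ Å away, no clash at radius 3
    for k in range(n_waters):
        p.add_water("A", 101 + k, directions[k])
    return p


def contact_plan() -> GeometryPlan:
    """A buried valine pair and an isolated surface pair at equal distance.

    Both pairs sit 5 Å apart (sidechain centroids).  The buried pair is
    surrounded by six alanine neighbors within 6.5 Å of the contact
    midpoint; the surface pair has none.
    """
    p = GeometryPlan()

    def add_ala(res_id: int, cb: tuple[float, float, float]) -> None:
        ca = (cb[0], cb[1], cb[2] + 1.5)
        p.add("A", res_id, "ALA", "CA", "C", ca)
        p.add("A", res_id, "ALA", "CB", "C", cb)

    add_ala(1, (0.0, 0.0, 0.0))  # buried pair
    add_ala(3, (5.0, 0.0, 0.0))
    ring_center = (2.5, 0.0, 0.0)
    for k in range(6):
        ang = 2.0 * math.pi * k / 6.0
        cb = (ring_center[0], ring_center[1] + 3.0 * math.cos(ang),
              ring_center[2] + 3.0 * math.sin(ang))
        add_ala(5 + 2 * k, cb)
    add_ala(31, (40.0, 0.0, 0.0))  # surface pair, far from everything
    add_ala(33, (45.0, 0.0, 0.0))
    return p


def three_residue_plan() -> GeometryPlan:
    """Three small residues in mutual contact — a SASA test article."""
    p = GeometryPlan()
    p.add("A", 1, "ALA", "N", "N", (-1.2, 1.0, 0.0))
    p.add("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0))
    p.add("A", 1, "ALA", "CB", "C", (1.5, 0.5, 0.0))
    p.add("A", 2, "SER", "N", "N", (0.0, -1.5, 1.2))
    p.add("A", 2, "SER", "CA", "C", (1.2, -2.2, 1.6))
    p.add("A", 2, "SER", "CB", "C", (2.4, -1.5, 2.2))
    p.add("A", 2, "SER", "OG", "O", (3.5, -2.3, 2.6))
    p.add("A", 3, "VAL", "CA", "C", (3.4, 1.8, 1.0))
    p.add("A", 3, "VAL", "CB", "C", (3.9, 0.5, 1.7))
    p.add("A", 3, "VAL", "CG1", "C", (5.4, 0.5, 1.9))
    p.add("A", 3, "VAL", "CG2", "C", (3.5, -0.8, 1.0))
    return p


def single_residue_plan(res_name: str = "ALA") -> GeometryPlan:
    """One residue with backbone, for free-reference SASA checks."""
    p = GeometryPlan()
    p.add("A", 1, res_name, "N", "N", (-1.46, 0.0, 0.0))
    p.add("A", 1, res_name, "CA", "C", (0.0, 0.0, 0.0))
    p.add("A", 1, res_name, "C", "C", (0.8, 0.0, 1.3))
    p.add("A", 1, res_name, "O", "O", (0.3, 0.3, 2.4))
    p.add("A", 1, res_name, "CB", "C", (0.6, 1.3, -0.6))
    return p


# ---------------------------------------------------------------------------
# alignments and trees
# ---------------------------------------------------------------------------

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _composition_for_entropy(target: float, n_seq: int) -> list[tuple[str, int]]:
    """Integer residue counts over ``n_seq`` sequences hitting an entropy target.

    Uses a one-vs-rest probability family over k letters (smallest k with
    ln k >= target), solved for the mixing parameter, then largest-remainder
    rounding to counts.
    """
    max_entropy = math.log(min(20, n_seq))
    if not (0.0 <= target <= max_entropy + 1e-12):
        raise ValueError(
            f"entropy target {target:.4f} infeasible for n_seq={n_seq} "
            f"(max {max_entropy:.4f})"
        )
    if target < 1e-12:
        return [(_ALPHABET[0], n_seq)]
    k = 2
    while math.log(k) < target - 1e-12:
        k += 1

    def entropy_of(x: float) -> float:
        # probs ∝ (1, x, ..., x) over k letters
        z = 1.0 + (k - 1) * x
        ps = [1.0 / z] + [x / z] * (k - 1)
        return -sum(q * math.log(q) for q in ps if q > 0)

    if abs(entropy_of(1.0) - target) < 1e-12:
        x = 1.0
    else:
        x = brentq(lambda t: entropy_of(t) - target, 1e-9, 1.0)
    z = 1.0 + (k - 1) * x
    probs = [1.0 / z] + [x / z] * (k - 1)
    raw = [p * n_seq for p in probs]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n_seq - sum(counts)
    order = sorted(range(k), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return [(_ALPHABET[i], c) for i, c in enumerate(counts) if c > 0]


def _balanced_newick(ids: Sequence[str]) -> str:
    def build(sub: Sequence[str]) -> str:
        if len(sub) == 1:
            return f"{sub[0]}:1.0"
        mid = len(sub) // 2
        return f"({build(sub[:mid])},{build(sub[mid:])}):1.0"

    return build(list(ids)).rsplit(":", 1)[0] + ";"


def _star_newick(ids: Sequence[str]) -> str:
    return "(" + ",".join(f"{i}:1.0" for i in ids) + ");"


def synth_msa(
    n_seq: int,
    ncols: int,
    entropy_plan: Mapping[int, float] | None = None,
    tree_shape: str = "balanced",
    clade_columns: Mapping[int, tuple[str, str]] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[dict[str, str], str, pd.DataFrame]:
    """Generate an alignment, a matching tree and a truth table.

    ``entropy_plan`` maps 1-based columns to target entropies (nats); columns
    not listed are invariant.  ``clade_columns`` maps columns to a residue
    pair fixed within the first and second half of the leaf order — with the
    balanced tree these halves are the two clades under the root, so such a
    column changes state on exactly the root edge.  Returns
    ``(sequences, newick, truth)``; with ``outdir`` writes ``msa.fasta``,
    ``tree.nwk`` and ``truth.csv``.
    """
    if n_seq < 2:
        raise ValueError("need at least 2 sequences")
    ids = [f"s{i:03d}" for i in range(n_seq)]
    rng = np.random.default_rng(seed)
    entropy_plan = dict(entropy_plan or {})
    clade_columns = dict(clade_columns or {})

    columns: dict[int, list[str]] = {}
    truth_rows = []
    for col in range(1, ncols + 1):
        if col in clade_columns:
            a, b = clade_columns[col]
            half = n_seq // 2
            letters = [a] * half + [b] * (n_seq - half)
            target = None
        else:
            target = entropy_plan.get(col, 0.0)
            comp = _composition_for_entropy(target, n_seq)
            letters = [aa for aa, c in comp for _ in range(c)]
            perm = rng.permutation(n_seq)
            letters = [letters[p] for p in perm]
        columns[col] = letters
        counts = {aa: letters.count(aa) for aa in set(letters)}
        realized = -sum(
            (c / n_seq) * math.log(c / n_seq) for c in counts.values()
        )
        truth_rows.append(
            dict(column=col,
                 target_entropy=float("nan") if target is None else target,
                 realized_entropy=realized,
                 n_states=len(counts))
        )

    sequences = {
        ids[s]: "".join(columns[col][s] for col in range(1, ncols + 1))
        for s in range(n_seq)
    }
    if tree_shape == "balanced":
        newick = _balanced_newick(ids)
    elif tree_shape == "star":
        newick = _star_newick(ids)
    else:
        raise ValueError(f"unknown tree_shape '{tree_shape}'")
    truth = pd.DataFrame(truth_rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "msa.fasta", "w") as fh:
            for sid in ids:
                fh.write(f">{sid}\n{sequences[sid]}\n")
        (outdir / "tree.nwk").write_text(newick + "\n")
        truth.to_csv(outdir / "truth.csv", index=False, float_format=FLOAT_FMT)
    return sequences, newick, truth
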