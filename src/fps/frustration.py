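"""Decoy-based energetic frustration of native residue contacts.

For a native contact between residues i and j, the frustration index is the
z-score of the native pair energy against the distribution of decoy energies
obtained by randomizing the two residue identities (geometry fixed):

    dE_fr = (E_native - mean(E_decoy)) / sd(E_decoy)

with the population standard deviation over the decoy set.  Under this sign
convention a *positive* index marks a contact whose native energy is higher
(less favourable) than typical decoys — an energetically stressed contact —
and a strongly negative index a minimally frustrated one.  Note the widely
used Frustratometer index carries the opposite sign.

The pairwise potential is pluggable.  The shipped default is a simple
quasichemical-style potential built from the Kyte–Doolittle hydrophobicity
scale plus a charge–charge term; it reproduces the qualitative pattern that
hydrophobic–hydrophobic contacts are favourable and like-charge contacts are
penalized, and it is *not* a reimplementation of any published force field.
Because the index is a z-score, every result is invariant under affine
rescaling of the potential.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import biotite.structure as struc
import numpy as np

from fps.solvation import BACKBONE_ATOMS, load_structure, _one_letter

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte–Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

PairPotential = Callable[[str, str], float]


def default_potential(a: str, b: str) -> float:
    """Hydrophobicity-product + electrostatic default contact potential.

    E(a, b) = -h_a * h_b / 10 + q_a * q_b, arbitrary units; lower is more
    favourable.
    """
    h = -KYTE_DOOLITTLE[a] * KYTE_DOOLITTLE[b] / 10.0
    q = CHARGE.get(a, 0.0) * CHARGE.get(b, 0.0)
    return h + q


class DegenerateDecoyError(RuntimeError):
    """The decoy energy distribution has zero spread (constant potential)."""


@dataclass(frozen=True)
class ContactPair:
    chain_i: str
    res_i: int
    type_i: str
    chain_j: str
    res_j: int
    type_j: str
    distance: float  # sidechain-centroid distance, Å
    contact_class: str  # 'direct' | 'water_mediated' | 'long'


@dataclass(frozen=True)
class FrustrationResult:
    pair: ContactPair
    e_native: float
    decoy_mean: float
    decoy_sd: float
    delta_e_fr: float
    n_decoys: int
    seed: int | None


def _sidechain_centroids(atoms: struc.AtomArray, chain: str | None = None):
    """(chain, res_id, one-letter, centroid) per residue; Cα for glycine."""
    protein = atoms[struc.filter_amino_acids(atoms) & (atoms.element != "H")]
    if chain is not None:
        protein = protein[protein.chain_id == chain]
    out = []
    for start in struc.get_residue_starts(protein):
        mask = (protein.chain_id == protein.chain_id[start]) & (
            protein.res_id == protein.res_id[start]
        )
        names = protein.atom_name[mask]
        side = ~np.isin(names, list(BACKBONE_ATOMS))
        if protein.res_name[start] == "GLY" or not side.any():
            side = names == "CA"
        centroid = protein.coord[mask][side].mean(axis=0)
        out.append(
            (
                str(protein.chain_id[start]),
                int(protein.res_id[start]),
                _one_letter(str(protein.res_name[start])),
                centroid,
            )
        )
    return out


def native_contacts(
    structure: str | Path | struc.AtomArray,
    cutoff: float = 6.5,
    *,
    long_cutoff: float | None = None,
    density_radius: float = 6.5,
    min_neighbors: int = 6,
    chain: str | None = None,
) -> list[ContactPair]:
    """Residue pairs whose sidechain centroids lie within the cutoff.

    Pairs must be at least 2 apart in sequence.  A contact is classed
    ``direct`` when the local burial density (number of other residue
    centroids within ``density_radius`` of the contact midpoint) reaches
    ``min_neighbors``, ``water_mediated`` when it does not, and ``long`` when
    its distance exceeds ``cutoff`` but lies within ``long_cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = structure if isinstance(structure, struc.AtomArray) else load_structure(structure)
    cents = _sidechain_centroids(atoms, chain=chain)
    reach = long_cutoff if long_cutoff is not None else cutoff
    coords = np.array([c[3] for c in cents])
    pairs: list[ContactPair] = []
    for a, b in itertools.combinations(range(len(cents)), 2):
        ca, ra, ta, pa = cents[a]
        cb, rb, tb, pb = cents[b]
        if ca == cb and abs(ra - rb) < 2:
            continue
        dist = float(np.linalg.norm(pa - pb))
        if dist > reach:
            continue
        if dist > cutoff:
            klass = "long"
        else:
            midpoint = (pa + pb) / 2.0
            dists = np.linalg.norm(coords - midpoint, axis=1)
            neighbors = int(np.sum(dists <= density_radius)) - 2  # exclude i, j
            klass = "direct" if neighbors >= min_neighbors else "water_mediated"
        pairs.append(
            ContactPair(
                chain_i=ca, res_i=ra, type_i=ta,
                chain_j=cb, res_j=rb, type_j=tb,
                distance=dist, contact_class=klass,
            )
        )
    return pairs


def decoy_frustration_index(
    pair: ContactPair,
    potential: PairPotential = default_potential,
    n_decoys: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> FrustrationResult:
    """Frustration z-score of one native contact against identity decoys.

    Decoys substitute *both* residue identities uniformly at random over the
    20 amino acids (geometry fixed).  ``exhaustive=True`` enumerates all 400
    ordered identity pairs instead of sampling and is seed-independent.
    """
    e_native = potential(pair.type_i, pair.type_j)
    if exhaustive:
        energies = np.array(
            [potential(a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS]
        )
        seed_used = None
    else:
        if n_decoys < 100:
            raise ValueError("n_decoys must be >= 100 (or use exhaustive=True)")
        rng = np.random.default_rng(seed)
        ai = rng.integers(0, 20, size=n_decoys)
        bi = rng.integers(0, 20, size=n_decoys)
        energies = np.array(
            [potential(AMINO_ACIDS[i], AMINO_ACIDS[j]) for i, j in zip(ai, bi)]
        )
        seed_used = seed
    mean = float(energies.mean())
    sd = float(energies.std(ddof=0))
    if sd == 0:
        raise DegenerateDecoyError(
            "degenerate decoy distribution: potential is constant over identities"
        )
    return FrustrationResult(
        pair=pair,
        e_native=float(e_native),
        decoy_mean=mean,
        decoy_sd=sd,
        delta_e_fr=(float(e_native) - mean) / sd,
        n_decoys=len(energies),
        seed=seed_used,
    )


def classify_frustration(
    results: Sequence[FrustrationResult],
    hi: float = 0.78,
    lo: float = -1.0,
) -> tuple[dict[tuple[int, int], str], dict[int, int]]:
    """Label contacts by thresholding the frustration index.

    Index above ``hi`` -> 'highly' (energetically stressed), below ``lo`` ->
    'minimally', otherwise 'neutral'.  The default thresholds are the
    conventional frustration-classification magnitudes transposed to this
    package's sign convention; they are configuration, not measured values.
    Returns (labels keyed by (res_i, res_j), per-residue count of 'highly'
    contacts).
    """
    if hi <= lo:
        raise ValueError("hi threshold must exceed lo")
    labels: dict[tuple[int, int], str] = {}
    stressed_count: dict[int, int] = {}
    for r in results:
        if r.delta_e_fr > hi:
            label = "highly"
        elif r.delta_e_fr < lo:
            label = "minimally"
        else:
            label = "neutral"
        labels[(r.pair.res_i, r.pair.res_j)] = label
        for res in (r.pair.res_i, r.pair.res_j):
            stressed_count.setdefault(res, 0)
            if label == "highly":
                stressed_count[res] += 1
    return labels, stressed_count
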