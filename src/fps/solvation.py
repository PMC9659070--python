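"""Per-residue SASA, the SASA–Log(PF) calibration and ALPF classification.

Residues whose Log(PF) falls below the lower 95% confidence limit of the
linear SASA–Log(PF) calibration (fitted on non-polar reference residues) are
anomalously reactive for their solvent exposure — the ALPF set, diagnostic of
nearby structured water.

SASA is computed with a Shrake–Rupley rolling-probe algorithm (probe 1.4 Å)
over sidechain heavy atoms only (Cβ and beyond; Cα for glycine), because
hydroxy-radical chemistry targets sidechains; whole-residue SASA is available
via ``sidechain_only=False``.  Waters and hetero-ions are excluded from the
surface calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResidueSASA:
    chain: str
    residue: int  # author numbering, 1-based
    residue_type: str  # one-letter code (or 3-letter when unknown)
    sasa: float  # Å^2


@dataclass
class SasaPfRegression:
    """OLS of logPF on SASA with a pointwise confidence band for the mean."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    level: float
    residual_sd: float
    x_mean: float
    sxx: float
    prediction: bool = False  # True -> prediction interval instead of mean band

    def predict(self, sasa: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(sasa, dtype=float)

    def band_halfwidth(self, sasa: float | np.ndarray) -> np.ndarray:
        x = np.asarray(sasa, dtype=float)
        tcrit = stats.t.ppf(0.5 + self.level / 2.0, self.n - 2)
        extra = 1.0 if self.prediction else 0.0
        return tcrit * self.residual_sd * np.sqrt(
            extra + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )

    def lower(self, sasa: float | np.ndarray) -> np.ndarray:
        return self.predict(sasa) - self.band_halfwidth(sasa)

    def upper(self, sasa: float | np.ndarray) -> np.ndarray:
        return self.predict(sasa) + self.band_halfwidth(sasa)


@dataclass(frozen=True)
class ALPFCall:
    residue: int
    logPF: float
    sasa: float
    status: str  # 'normal' | 'anomalous_low' | 'not_detected'


def load_structure(path: str | Path, model: int = 1) -> struc.AtomArray:
    """Read one model of a PDB file, keeping the highest-occupancy altloc."""
    pdb_file = pdb.PDBFile.read(str(path))
    return pdb_file.get_structure(model=model, altloc="occupancy", extra_fields=["occupancy"])


def _one_letter(res_name: str) -> str:
    try:
        code = struc.info.one_letter_code(res_name)
    except KeyError:
        code = None
    return code if code else res_name


def residue_sasa(
    structure: str | Path | struc.AtomArray,
    chain: str | None = None,
    probe: float = 1.4,
    *,
    sidechain_only: bool = True,
    point_number: int = 1000,
    vdw_set: str = "Single",
) -> list[ResidueSASA]:
    """Rolling-probe SASA per residue over sidechain heavy atoms.

    The surface is computed on all protein atoms of the structure (occlusion
    by other chains included); waters, ions and hydrogens are excluded.  When
    ``chain`` is given only that chain's residues are reported.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    atoms = structure if isinstance(structure, struc.AtomArray) else load_structure(structure)
    protein = atoms[struc.filter_amino_acids(atoms) & (atoms.element != "H")]
    if protein.array_length() == 0:
        raise ValueError("no protein atoms in structure")
    chains = sorted(set(protein.chain_id))
    if chain is not None and chain not in chains:
        raise ValueError(f"chain '{chain}' not found; available chains: {chains}")

    atom_sasa = struc.sasa(
        protein, probe_radius=probe, point_number=point_number, vdw_radii=vdw_set
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)

    out: list[ResidueSASA] = []
    for start in struc.get_residue_starts(protein):
        res_mask = (
            (protein.chain_id == protein.chain_id[start])
            & (protein.res_id == protein.res_id[start])
        )
        if chain is not None and protein.chain_id[start] != chain:
            continue
        names = protein.atom_name[res_mask]
        res_name = protein.res_name[start]
        if sidechain_only:
            keep = ~np.isin(names, list(BACKBONE_ATOMS))
            if res_name == "GLY" or not keep.any():
                keep = names == "CA"
        else:
            keep = np.ones(len(names), dtype=bool)
        total = float(atom_sasa[res_mask][keep].sum())
        out.append(
            ResidueSASA(
                chain=str(protein.chain_id[start]),
                residue=int(protein.res_id[start]),
                residue_type=_one_letter(res_name),
                sasa=total,
            )
        )
    return out


def fit_sasa_logpf(
    points: Sequence[tuple[float, float]],
    level: float = 0.95,
    prediction: bool = False,
) -> SasaPfRegression:
    """Ordinary least squares of logPF on SASA with a confidence band.

    ``points`` are (sasa, logPF) pairs from the calibration residue set.  The
    band is for the mean response at ``level`` (prediction interval with
    ``prediction=True``); it widens away from the mean SASA.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError(f"need >= 3 calibration points, got {0 if pts.ndim != 2 else pts.shape[0]}")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate calibration: all SASA values equal")
    res = stats.linregress(x, y)
    n = len(x)
    yhat = res.intercept + res.slope * x
    dof = n - 2
    residual_sd = float(np.sqrt(np.sum((y - yhat) ** 2) / dof)) if dof > 0 else 0.0
    return SasaPfRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=n,
        level=level,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
        prediction=prediction,
    )


def classify_alpf(
    records: Sequence[tuple[int, float, float]],
    model: SasaPfRegression,
) -> list[ALPFCall]:
    """Flag residues whose logPF lies strictly below the lower band.

    ``records`` are (residue, sasa, logPF) triples; entries with a
    non-finite SASA are returned as ``not_detected`` and logged.
    """
    calls = []
    for residue, sasa, log_pf in records:
        if not np.isfinite(sasa) or not np.isfinite(log_pf):
            logger.warning("residue %s lacks SASA or logPF; not classified", residue)
            calls.append(ALPFCall(residue=int(residue), logPF=float(log_pf), sasa=float(sasa), status="not_detected"))
            continue
        status = "anomalous_low" if log_pf < float(model.lower(sasa)) else "normal"
        calls.append(ALPFCall(residue=int(residue), logPF=float(log_pf), sasa=float(sasa), status=status))
    return calls


def delta_metrics(
    state_a: dict[int, dict[str, float]],
    state_b: dict[int, dict[str, float]],
    groups: dict[int, str] | None = None,
) -> tuple[dict[int, dict[str, float]], dict[str, dict[str, tuple[float, float]]]]:
    """Per-residue deltas (A − B) of logPF and SASA, with group mean ± SD.

    States map residue index -> {'logPF': ..., 'sasa': ...}.  Residues are
    matched by index, so substituted positions (e.g. a 13D→K construct)
    compare by position.  Returns ``(per_residue, per_group)`` where
    per_group[label][metric] = (mean, sd).
    """
    shared = sorted(set(state_a) & set(state_b))
    if not shared:
        raise ValueError("states share no residues")
    per_residue: dict[int, dict[str, float]] = {}
    for res in shared:
        per_residue[res] = {
            "dlogPF": state_a[res]["logPF"] - state_b[res]["logPF"],
            "dsasa": state_a[res]["sasa"] - state_b[res]["sasa"],
        }
    per_group: dict[str, dict[str, tuple[float, float]]] = {}
    if groups:
        for label in sorted(set(groups.values())):
            members = [r for r in shared if groups.get(r) == label]
            if not members:
                continue
            stats_ = {}
            for metric in ("dlogPF", "dsasa"):
                vals = np.array([per_residue[r][metric] for r in members])
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                stats_[metric] = (float(vals.mean()), sd)
            per_group[label] = stats_
    return per_residue, per_group
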