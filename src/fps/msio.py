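"""Parsing and matching of MS identification tables and LC-MS peak lists.

A footprinting experiment yields, per X-ray dose point, a list of
chromatographic peaks (retention time, m/z, integrated area) and a list of
peptide identifications from MS/MS database search (MASCOT-style export).
Oxidized peptide forms carry the modified residue's position; the unoxidized
form of the same peptide carries none.  Matching identifications to peaks by
retention time and m/z, and summing the matched areas per residue, produces
the per-residue oxidized/unoxidized area table that the dose–response module
consumes.

The aggregation convention: the oxidized area of residue *i* is the summed
area of all peaks assigned to forms modified at *i*; the unoxidized area of
residue *i* is the unmodified-peptide area **plus** the oxidized areas of the
other residues of the same peptide, so that the oxidized fraction at *i* is
conditional on that site only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: default column names for identification tables; override via ``columns=``
ID_COLUMNS = {
    "peptide": "peptide",
    "start": "start",
    "mod_site": "mod_site",
    "mod_mass": "mod_mass",
    "rt": "rt",
    "mz": "mz",
    "charge": "charge",
}

#: default column names for LC-MS peak tables
PEAK_COLUMNS = {
    "dose_id": "dose_id",
    "rt": "rt",
    "mz": "mz",
    "area": "area",
}


class FormatError(ValueError):
    """Input table does not have the expected columns or row values."""


@dataclass(frozen=True)
class PeptideIdentification:
    """One MS/MS identification row.

    ``mod_residue`` is the 1-based protein index of the oxidized residue;
    ``None`` marks the unoxidized form of the peptide.
    """

    peptide_seq: str
    protein_start: int  # 1-based index of the peptide's first residue
    mod_residue: int | None
    mod_mass_shift: float
    rt: float  # minutes
    mz: float  # Th
    charge: int

    def __post_init__(self) -> None:
        if self.protein_start < 1:
            raise ValueError(f"protein_start must be >= 1, got {self.protein_start}")
        if self.rt <= 0:
            raise ValueError(f"rt must be > 0, got {self.rt}")
        if self.mz <= 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.mod_residue is not None:
            end = self.protein_start + len(self.peptide_seq) - 1
            if not (self.protein_start <= self.mod_residue <= end):
                raise ValueError(
                    f"mod_residue {self.mod_residue} outside peptide span "
                    f"[{self.protein_start}, {end}]"
                )

    @property
    def residue_span(self) -> range:
        """1-based protein indices covered by this peptide."""
        return range(self.protein_start, self.protein_start + len(self.peptide_seq))

    def residue_type(self, index: int) -> str:
        """One-letter type of protein residue ``index`` within this peptide."""
        return self.peptide_seq[index - self.protein_start]


@dataclass(frozen=True)
class PeakRecord:
    """One chromatographic peak at one dose point."""

    dose_id: str
    rt: float
    mz: float
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise FormatError(f"peak area must be >= 0, got {self.area}")


@dataclass
class ResidueAreaTable:
    """Per-dose oxidized/unoxidized areas for one residue.

    ``areas`` maps dose_id -> (area_oxidized, area_unoxidized); both are
    non-negative and their sum is positive for every retained dose point.
    """

    residue: int  # 1-based protein index
    residue_type: str  # one-letter code
    areas: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": self.residue,
                "residue_type": self.residue_type,
                "dose_id": dose,
                "area_ox": ox,
                "area_unox": unox,
            }
            for dose, (ox, unox) in sorted(self.areas.items())
        ]
        return pd.DataFrame(rows)


def tables_to_frame(tables: Sequence[ResidueAreaTable]) -> pd.DataFrame:
    """Concatenate ResidueAreaTables into one tidy frame (the CSV layout)."""
    if not tables:
        return pd.DataFrame(
            columns=["residue", "residue_type", "dose_id", "area_ox", "area_unox"]
        )
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def _read_csv(path: str | Path, columns: Mapping[str, str], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for key in required:
        if columns[key] not in df.columns:
            raise FormatError(
                f"missing column '{columns[key]}' (for field '{key}') in {path.name}; "
                f"found columns {list(df.columns)}"
            )
    return df


def parse_identifications(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[PeptideIdentification]:
    """Read a MASCOT-style identification CSV.

    Rows with an empty modification-site cell are unoxidized forms.  Raises
    :class:`FormatError` naming the column when one is missing, or carrying
    the 1-based data row number when a row cannot be parsed.
    """
    cols = dict(ID_COLUMNS, **(columns or {}))
    df = _read_csv(path, cols, ["peptide", "start", "mod_site", "rt", "mz", "charge"])
    return parse_identifications_from_frame(df, columns=columns)


def parse_identifications_from_frame(
    df: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> list[PeptideIdentification]:
    """In-memory variant of :func:`parse_identifications`."""
    cols = dict(ID_COLUMNS, **(columns or {}))
    out: list[PeptideIdentification] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(row)
        try:
            mod_cell = rec[cols["mod_site"]]
            mod_residue = None if pd.isna(mod_cell) or str(mod_cell).strip() == "" else int(mod_cell)
            mod_mass = rec.get(cols["mod_mass"], 0.0)
            if pd.isna(mod_mass) or str(mod_mass).strip() == "":
                mod_mass = 0.0
            out.append(
                PeptideIdentification(
                    peptide_seq=str(rec[cols["peptide"]]).strip().upper(),
                    protein_start=int(rec[cols["start"]]),
                    mod_residue=mod_residue,
                    mod_mass_shift=float(mod_mass),
                    rt=float(rec[cols["rt"]]),
                    mz=float(rec[cols["mz"]]),
                    charge=int(rec[cols["charge"]]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"unparseable identification row {row_no}: {exc}") from exc
    return out


def parse_peak_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[PeakRecord]:
    """Read an LC-MS peak list CSV (dose_id, rt, mz, area).

    Duplicate (dose, rt, mz) rows are all kept — peaks may legitimately
    co-elute.  Negative areas raise :class:`FormatError`; an empty file
    returns an empty list with a warning.
    """
    cols = dict(PEAK_COLUMNS, **(columns or {}))
    df = _read_csv(path, cols, ["dose_id", "rt", "mz", "area"])
    if df.empty:
        logger.warning("peak table %s is empty", path)
        return []
    return parse_peaks_from_frame(df, columns=columns)


def parse_peaks_from_frame(
    df: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> list[PeakRecord]:
    """In-memory variant of :func:`parse_peak_table`."""
    cols = dict(PEAK_COLUMNS, **(columns or {}))
    out: list[PeakRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            out.append(
                PeakRecord(
                    dose_id=str(rec[cols["dose_id"]]),
                    rt=float(rec[cols["rt"]]),
                    mz=float(rec[cols["mz"]]),
                    area=float(rec[cols["area"]]),
                )
            )
        except FormatError:
            raise
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable peak row {row_no}: {exc}") from exc
    return out


def _match_area(
    ident: PeptideIdentification,
    peaks: Sequence[PeakRecord],
    rt_tol: float,
    mz_tol: float,
) -> float | None:
    """Summed area of peaks within tolerance of ``ident``; None if no match."""
    matched = [
        p
        for p in peaks
        if abs(p.rt - ident.rt) <= rt_tol and abs(p.mz - ident.mz) <= mz_tol
    ]
    if not matched:
        return None
    if len(matched) > 1:
        logger.info(
            "ambiguous match for peptide %s rt=%.2f mz=%.4f: %d peaks summed",
            ident.peptide_seq, ident.rt, ident.mz, len(matched),
        )
    return float(sum(p.area for p in matched))


def match_and_aggregate(
    ids: Sequence[PeptideIdentification],
    peaks: Sequence[PeakRecord],
    rt_tol: float = 0.5,
    mz_tol: float = 0.02,
) -> list[ResidueAreaTable]:
    """Match identifications to per-dose peaks and compile residue area tables.

    For every dose point each identification is matched to the peak(s) within
    ``rt_tol`` minutes and ``mz_tol`` Th; matched areas (all charge states,
    all co-eluting peaks) are summed.  Residues never seen as an oxidation
    site are absent from the output ("not detected").  An identification with
    no matching peak at a dose invalidates that dose point for the residues
    it informs (the modified residue, or the whole peptide for the unoxidized
    form) and is logged.
    """
    if rt_tol <= 0 or mz_tol <= 0:
        raise ValueError("rt_tol and mz_tol must be positive")

    dose_ids = sorted({p.dose_id for p in peaks})
    peaks_by_dose: dict[str, list[PeakRecord]] = {d: [] for d in dose_ids}
    for p in peaks:
        peaks_by_dose[p.dose_id].append(p)

    # peptide key -> residue type lookup and per-dose ox/unox accumulation
    ox: dict[tuple[str, int], dict[int, dict[str, float]]] = {}
    unox: dict[tuple[str, int], dict[str, float]] = {}
    invalid: dict[tuple[str, int], set[str]] = {}
    restype: dict[int, str] = {}
    peptides: dict[tuple[str, int], PeptideIdentification] = {}

    for ident in sorted(ids, key=lambda i: (i.protein_start, i.peptide_seq, i.mod_residue or 0, i.mz)):
        key = (ident.peptide_seq, ident.protein_start)
        peptides.setdefault(key, ident)
        for dose in dose_ids:
            area = _match_area(ident, peaks_by_dose[dose], rt_tol, mz_tol)
            if area is None:
                logger.warning(
                    "unmatched identification %s (mod=%s) at dose %s",
                    ident.peptide_seq, ident.mod_residue, dose,
                )
                invalid.setdefault(key, set()).add(dose)
                continue
            if ident.mod_residue is None:
                per = unox.setdefault(key, {})
                per[dose] = per.get(dose, 0.0) + area
            else:
                per = ox.setdefault(key, {}).setdefault(ident.mod_residue, {})
                per[dose] = per.get(dose, 0.0) + area
                restype[ident.mod_residue] = ident.residue_type(ident.mod_residue)

    # assemble per-residue tables (summing across peptides covering a residue)
    acc: dict[int, dict[str, tuple[float, float]]] = {}
    for key, per_res in ox.items():
        bad = invalid.get(key, set())
        for dose in dose_ids:
            if dose in bad:
                continue
            pep_unox = unox.get(key, {}).get(dose, 0.0)
            dose_ox = {r: per[dose] for r, per in per_res.items() if dose in per}
            total_ox = sum(dose_ox.values())
            for res, a_ox in dose_ox.items():
                # other residues' oxidized forms count as "not oxidized at res"
                a_unox = pep_unox + (total_ox - a_ox)
                prev = acc.setdefault(res, {}).get(dose, (0.0, 0.0))
                acc[res][dose] = (prev[0] + a_ox, prev[1] + a_unox)

    tables = []
    for res in sorted(acc):
        areas = {
            d: (a_ox, a_unox)
            for d, (a_ox, a_unox) in acc[res].items()
            if a_ox + a_unox > 0
        }
        if areas:
            tables.append(ResidueAreaTable(residue=res, residue_type=restype[res], areas=areas))
    return tables
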