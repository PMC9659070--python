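"""Oxidized fractions, exponential-decay fits and protection factors.

The unoxidized fraction of a residue decays with X-ray dose as
``1 - F = exp(-S * dose)`` where ``F`` is the oxidized fraction and ``S`` the
oxidation rate per dose unit.  Dividing the fitted slope by the residue
type's intrinsic hydroxy-radical reactivity gives the protection factor,

    PF = S / IR,

and ``Log10(PF)`` is the quantity that scales with solvent accessibility.
Intrinsic reactivities are dimensionless on the relative scale on which
lysine is 2.2 and aspartate 0.42; the shipped table contains exactly those
two published values and users extend it for other residue types.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import curve_fit

from fps.msio import ResidueAreaTable

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Decay fit could not be performed (too few points or no convergence)."""


class ConfigurationError(KeyError):
    """A residue type is missing from the intrinsic-reactivity table."""


@dataclass
class DoseResponseSeries:
    """Ordered dose grid with oxidized fraction (and optional SE) per dose."""

    residue: int
    residue_type: str
    doses: np.ndarray  # strictly increasing
    F: np.ndarray  # oxidized fraction in [0, 1]
    se: np.ndarray | None = None  # standard error of F, same length

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any((self.F < 0) | (self.F > 1)):
            raise ValueError("oxidized fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ProtectionRecord:
    """Fitted slope, intrinsic reactivity and protection factor of a residue."""

    residue: int
    residue_type: str
    S: float
    S_se: float
    IR: float
    PF: float
    logPF: float  # base-10 by default; see protection_factor(log_base=...)


def load_ir_table(path: str | Path | None = None) -> dict[str, float]:
    """Load an intrinsic-reactivity table (one-letter code -> IR > 0).

    Without ``path`` the packaged default is used, which carries the two
    published values K = 2.2 and D = 0.42.
    """
    if path is None:
        ref = importlib.resources.files("fps.data") / "intrinsic_reactivity.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    table = {str(k).upper(): float(v) for k, v in raw.items()}
    bad = [k for k, v in table.items() if v <= 0]
    if bad:
        raise ConfigurationError(f"non-positive IR for residue type(s) {bad}")
    return table


def oxidized_fraction(table: ResidueAreaTable, dose_values: dict[str, float] | None = None) -> DoseResponseSeries:
    """Convert an area table to F = ox / (ox + unox) per dose.

    ``dose_values`` maps dose_id labels to numeric exposures; when omitted the
    labels themselves must parse as numbers.  Doses with zero total area are
    dropped with a warning.
    """
    pairs = []
    for dose_id, (a_ox, a_unox) in table.areas.items():
        total = a_ox + a_unox
        if total <= 0:
            logger.warning("residue %d dose %s has zero total area; dropped", table.residue, dose_id)
            continue
        dose = dose_values[dose_id] if dose_values is not None else float(dose_id)
        pairs.append((dose, a_ox / total))
    pairs.sort()
    doses = np.array([d for d, _ in pairs])
    F = np.array([f for _, f in pairs])
    return DoseResponseSeries(residue=table.residue, residue_type=table.residue_type, doses=doses, F=F)


def fit_decay(series: DoseResponseSeries, weights: str = "reciprocal-se") -> tuple[float, float]:
    """Fit ``1 - F = exp(-S * dose)`` and return ``(S, S_se)``.

    The fit is a weighted linear regression through the origin in
    ``ln(1 - F)`` space when every F < 1 (the transform is exact for a pure
    single-exponential), falling back to a nonlinear least-squares fit of the
    exponential itself when saturated points (F = 1) are present.  With
    ``weights='reciprocal-se'`` and per-point standard errors available, each
    point is weighted by the reciprocal of its (transformed) standard error;
    ``weights='uniform'`` ignores the SEs.  S is constrained to be
    non-negative.
    """
    x = series.doses
    F = series.F
    if len(x) < 3:
        raise FitError(f"need >= 3 dose points, got {len(x)}")
    se = series.se if (weights == "reciprocal-se" and series.se is not None) else None

    if np.all(F < 1.0):
        y = np.log1p(-F)  # ln(1 - F), exactly 0 at F = 0
        if se is not None:
            # delta method: SE[ln(1-F)] = se / (1-F); weight = 1/SE^2
            sig = np.where(se > 0, se / (1.0 - F), np.nan)
            w = np.where(np.isfinite(sig), 1.0 / sig**2, 0.0)
            if not np.any(w > 0):
                w = np.ones_like(y)
        else:
            w = np.ones_like(y)
        sxx = np.sum(w * x * x)
        if sxx == 0:
            # all information at dose 0; decay rate indeterminate -> 0
            return 0.0, 0.0
        S = -np.sum(w * x * y) / sxx
        S = max(S, 0.0)
        resid = y + S * x
        dof = max(len(x) - 1, 1)
        s2 = np.sum(w * resid**2) / dof
        return float(S), float(math.sqrt(s2 / sxx))

    # saturated points present: fit the exponential directly
    def model(d, s):
        return np.exp(-s * d)

    mask = F < 1.0
    if mask.sum() >= 2 and np.any(x[mask] > 0):
        y0 = np.log1p(-F[mask])
        sxx0 = np.sum(x[mask] ** 2)
        p0 = max(-np.sum(x[mask] * y0) / sxx0, 1e-9) if sxx0 > 0 else 1.0
    else:
        p0 = 1.0
    sigma = None
    if se is not None and np.all(se > 0):
        sigma = se
    try:
        popt, pcov = curve_fit(
            model, x, 1.0 - F, p0=[p0], sigma=sigma, bounds=(0.0, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        resid = (1.0 - F) - model(x, p0)
        raise FitError(f"nonlinear decay fit did not converge (residuals {resid})") from exc
    return float(popt[0]), float(math.sqrt(pcov[0, 0]))


def protection_factor(
    S: float,
    residue_type: str,
    ir_table: dict[str, float] | None = None,
    *,
    residue: int = 0,
    S_se: float = float("nan"),
    log_base: float = 10.0,
) -> ProtectionRecord:
    """PF = S / IR for one residue, with log-PF in the requested base.

    Raises :class:`ConfigurationError` naming the residue type when it has no
    IR entry.  ``logPF`` is NaN when S = 0 (PF = 0 has no logarithm).
    """
    if S < 0:
        raise ValueError(f"slope must be >= 0, got {S}")
    table = ir_table if ir_table is not None else load_ir_table()
    rt = residue_type.upper()
    if rt not in table:
        raise ConfigurationError(
            f"no intrinsic reactivity for residue type '{rt}'; extend the IR table"
        )
    ir = table[rt]
    pf = S / ir
    log_pf = math.log(pf, log_base) if pf > 0 else float("nan")
    return ProtectionRecord(
        residue=residue, residue_type=rt, S=S, S_se=S_se, IR=ir, PF=pf, logPF=log_pf
    )


def average_replicates(
    replicate_series: Sequence[DoseResponseSeries],
) -> DoseResponseSeries:
    """Average technical replicates per dose; SE = SD / sqrt(n_replicates).

    All replicates must share the dose grid and residue.
    """
    if not replicate_series:
        raise ValueError("no replicates given")
    first = replicate_series[0]
    for s in replicate_series[1:]:
        if not np.array_equal(s.doses, first.doses) or s.residue != first.residue:
            raise ValueError("replicates must share residue and dose grid")
    stack = np.vstack([s.F for s in replicate_series])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else None
    return DoseResponseSeries(
        residue=first.residue,
        residue_type=first.residue_type,
        doses=first.doses.copy(),
        F=mean,
        se=se,
    )


def protection_factors_from_tables(
    tables: Sequence[ResidueAreaTable],
    ir_table: dict[str, float] | None = None,
    dose_values: dict[str, float] | None = None,
    weights: str = "reciprocal-se",
) -> list[ProtectionRecord]:
    """Convenience pipeline: area tables -> fits -> ProtectionRecords.

    Residues whose type lacks an IR entry, or with too few dose points, are
    skipped with a log message rather than aborting the batch.
    """
    table = ir_table if ir_table is not None else load_ir_table()
    records = []
    for t in tables:
        try:
            series = oxidized_fraction(t, dose_values=dose_values)
            S, S_se = fit_decay(series, weights=weights)
            records.append(
                protection_factor(
                    S, t.residue_type, table, residue=t.residue, S_se=S_se
                )
            )
        except (FitError, ConfigurationError) as exc:
            logger.warning("residue %d skipped: %s", t.residue, exc)
    return records
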