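"""Binding-parameter tables: reading, writing, validation and unit conversions.

A binding-parameter table has one row per (cell type, ligand, temperature)
combination and carries the five kinetic constants that describe monovalent
receptor-ligand binding:

* ``K_d``   -- equilibrium dissociation constant, molar,
* ``t_1/2`` -- complex half-life, seconds,
* ``k_on``  -- association rate in solution, s^-1 M^-1,
* ``k_+``   -- per receptor-ligand-pair association rate, s^-1,
* ``k_-``   -- dissociation rate, s^-1.

The five are not independent: ``k_- = ln(2)/t_1/2``, ``K_d = k_-/k_on`` and
``k_on = k_+ * V * N_A`` with ``V`` the reaction volume and ``N_A`` Avogadro's
number.  :func:`validate_consistency` checks the first two identities against
a relative tolerance; the ratio ``k_on/k_+`` must be a single table-level
constant, which pins down the (otherwise unstated) assay volume.

Units are fixed throughout the package: molar, seconds, litres, counts.

A reference table for the T1 TCR system (ligands 4P, 4A, 4N on SP and DP
thymocytes at 37 C) ships with the package; load it with
``load_binding_table("bundled:table1")``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from scipy.constants import Avogadro

__all__ = [
    "AVOGADRO",
    "BindingParams",
    "CellContext",
    "ConsistencyReport",
    "SchemaError",
    "ValidationError",
    "BUNDLED_TABLE1",
    "load_binding_table",
    "write_binding_table",
    "koff_from_halflife",
    "halflife_from_koff",
    "kd_from_rates",
    "kplus_from_kon",
    "volume_from_rates",
    "table_volume_constant",
    "validate_consistency",
    "validate_table",
]

AVOGADRO = Avogadro  # mol^-1

#: Spelled "bundled:table1" in table paths to request the packaged fixture.
BUNDLED_TABLE1 = "bundled:table1"

_COLUMNS = [
    "cell_type",
    "ligand",
    "temperature_C",
    "Kd_M",
    "t_half_s",
    "kon_per_M_s",
    "kplus_per_s",
    "kminus_per_s",
]
_NUMERIC_COLUMNS = _COLUMNS[2:]


class SchemaError(ValueError):
    """The table file does not have the expected columns."""


class ValidationError(ValueError):
    """A table cell violates a positivity or consistency requirement."""


@dataclass(frozen=True)
class BindingParams:
    """Kinetic constants for one cell-type x ligand x temperature combination.

    ``k_on`` and ``k_minus`` are the authoritative inputs to every model
    computation; ``K_d`` and ``t_half`` are retained as printed and used only
    for consistency checking, since they are redundant with the rates.
    """

    cell_type: str
    ligand: str
    temperature: float  # degrees Celsius
    K_d: float          # M
    t_half: float       # s
    k_on: float         # s^-1 M^-1
    k_plus: float       # s^-1
    k_minus: float      # s^-1

    def __post_init__(self) -> None:
        for name in ("K_d", "t_half", "k_on", "k_plus", "k_minus"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValidationError(
                    f"{self.cell_type}/{self.ligand}: field {name!r} must be "
                    f"a positive finite number, got {value!r}"
                )


@dataclass(frozen=True)
class CellContext:
    """Cellular setting for the 3-D (soluble-ligand) model.

    Parameters
    ----------
    N_R : mean TCR copies per T cell (3000 for DP, 30 000 for SP thymocytes).
    N_c : number of T cells in the reaction volume.
    volume : reaction volume in litres.
    rho : initial ligand concentration in molar.
    """

    N_R: float
    N_c: float = 1.0
    volume: float = 1.0e-9
    rho: float = 1.0e-8

    def __post_init__(self) -> None:
        if self.N_R < 1 or self.N_c < 1:
            raise ValidationError("N_R and N_c must each be >= 1")
        if not (self.volume > 0 and self.rho > 0):
            raise ValidationError("volume and rho must be positive")

    @property
    def M_R(self) -> float:
        """Total receptor count in the system (N_c * N_R)."""
        return self.N_c * self.N_R

    @property
    def M_L(self) -> float:
        """Total free-ligand count at t = 0 (rho * V * N_A)."""
        return self.rho * self.volume * AVOGADRO


# ---------------------------------------------------------------------------
# conversions

def koff_from_halflife(t_half: float) -> float:
    """Dissociation rate ln(2)/t_half, s^-1."""
    if not t_half > 0:
        raise ValueError(f"t_half must be positive, got {t_half!r}")
    return math.log(2.0) / t_half


def halflife_from_koff(k_off: float) -> float:
    """Complex half-life ln(2)/k_off, s."""
    if not k_off > 0:
        raise ValueError(f"k_off must be positive, got {k_off!r}")
    return math.log(2.0) / k_off


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant k_off/k_on, molar."""
    if not (k_on > 0 and k_off > 0):
        raise ValueError("k_on and k_off must be positive")
    return k_off / k_on


def kplus_from_kon(k_on: float, volume: float) -> float:
    """Per-pair association rate k_on/(V * N_A), s^-1."""
    if not (k_on > 0 and volume > 0):
        raise ValueError("k_on and volume must be positive")
    return k_on / (volume * AVOGADRO)


def volume_from_rates(k_on: float, k_plus: float) -> float:
    """Reaction volume (litres) implied by the pair k_on, k_plus."""
    if not (k_on > 0 and k_plus > 0):
        raise ValueError("k_on and k_plus must be positive")
    return k_on / (k_plus * AVOGADRO)


def table_volume_constant(params: Sequence[BindingParams]) -> float:
    """Table-level constant V*N_A (M^-1) from the row-wise ratio k_on/k_plus.

    Raises :class:`ValidationError` if the ratio spreads by more than 0.5%
    across rows, since a single table is assumed to come from one assay
    volume.
    """
    ratios = [p.k_on / p.k_plus for p in params]
    if not ratios:
        raise ValidationError("empty parameter list")
    lo, hi = min(ratios), max(ratios)
    if (hi - lo) / lo > 0.005:
        raise ValidationError(
            f"k_on/k_plus is not constant across rows: spread {lo:g}..{hi:g}"
        )
    return sum(ratios) / len(ratios)


# ---------------------------------------------------------------------------
# I/O

def _bundled_path() -> Path:
    return Path(resources.files("tsi.data") / "table1_t1_tcr_37C.csv")


def load_binding_table(source: Union[str, Path]) -> list[BindingParams]:
    """Read a binding-parameter table from CSV or TSV.

    ``source`` may be a file path or the literal string ``"bundled:table1"``
    for the packaged T1 TCR reference table (six rows: SP/DP x 4P/4A/4N at
    37 C).  The file must have a header with the columns

    ``cell_type, ligand, temperature_C, Kd_M, t_half_s, kon_per_M_s,
    kplus_per_s, kminus_per_s``

    Lines starting with ``#`` are comments.  Numeric cells must be positive.
    """
    if str(source) == BUNDLED_TABLE1:
        source = _bundled_path()
    path = Path(source)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[BindingParams] = []
    for idx, row in df.iterrows():
        for col in _NUMERIC_COLUMNS:
            value = row[col]
            if col != "temperature_C" and not value > 0:
                raise ValidationError(
                    f"{path} row {idx}: column {col!r} must be positive, "
                    f"got {value!r}"
                )
        records.append(
            BindingParams(
                cell_type=str(row["cell_type"]),
                ligand=str(row["ligand"]),
                temperature=float(row["temperature_C"]),
                K_d=float(row["Kd_M"]),
                t_half=float(row["t_half_s"]),
                k_on=float(row["kon_per_M_s"]),
                k_plus=float(row["kplus_per_s"]),
                k_minus=float(row["kminus_per_s"]),
            )
        )
    return records


def write_binding_table(params: Iterable[BindingParams],
                        dest: Union[str, Path]) -> None:
    """Write records to CSV/TSV with full round-trip precision."""
    path = Path(dest)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for p in params:
        rows.append({
            "cell_type": p.cell_type,
            "ligand": p.ligand,
            "temperature_C": p.temperature,
            "Kd_M": p.K_d,
            "t_half_s": p.t_half,
            "kon_per_M_s": p.k_on,
            "kplus_per_s": p.k_plus,
            "kminus_per_s": p.k_minus,
        })
    df = pd.DataFrame(rows, columns=_COLUMNS)
    # default float formatting is shortest round-trip repr: bit-identical reload
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class ConsistencyReport:
    """Relative residuals of the redundant columns of one table row.

    ``resid_kminus`` compares the printed k_- against ln(2)/t_half;
    ``resid_Kd`` compares the printed K_d against k_-/k_on.  ``passed`` is
    True when both residuals are within the tolerance the report was built
    with.
    """

    cell_type: str
    ligand: str
    resid_kminus: float
    resid_Kd: float
    tol: float

    @property
    def passed(self) -> bool:
        return self.resid_kminus <= self.tol and self.resid_Kd <= self.tol


def validate_consistency(params: BindingParams,
                         tol: float = 0.02) -> ConsistencyReport:
    """Check the printed redundant columns of one row against the rates.

    The default 2% tolerance accommodates rounding in published tables (the
    bundled reference table has one row whose printed k_- differs from
    ln(2)/t_half by about 1.7%).
    """
    if not 0 < tol <= 1:
        raise ValueError("tol must be in (0, 1]")
    koff_implied = koff_from_halflife(params.t_half)
    kd_implied = kd_from_rates(params.k_on, params.k_minus)
    return ConsistencyReport(
        cell_type=params.cell_type,
        ligand=params.ligand,
        resid_kminus=abs(params.k_minus - koff_implied) / koff_implied,
        resid_Kd=abs(params.K_d - kd_implied) / kd_implied,
        tol=tol,
    )


def validate_table(params: Sequence[BindingParams],
                   tol: float = 0.02) -> list[ConsistencyReport]:
    """Per-row consistency reports plus the table-level volume check."""
    reports = [validate_consistency(p, tol) for p in params]
    table_volume_constant(params)  # raises if k_on/k_plus is not constant
    return reports
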