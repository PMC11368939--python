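"""Measurement tables for aqueous amino acid + choline chloride solutions.

The raw input of the whole pipeline is a table of state points: for a given
amino-acid background (the "system", e.g. 0.0500 mol kg^-1 l-glycine in
water) and temperature, the density ``d`` and speed of sound ``u`` were
measured over a grid of choline chloride molalities, always including the
choline-chloride-free solvent baseline (``m_chcl = 0``).  The bundled
fixture carries the complete measured data set of the study: 9 systems
x 7 molalities x 4 temperatures = 252 records at P = 871.5 hPa.

CSV dialect: UTF-8, comma separated, dot decimal, one row per state point,
mandatory header ``amino_acid, m_aa_molal, T_K, m_chcl_molal,
density_kg_m3, speed_of_sound_m_s``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    DomainError,
    DuplicateRecordError,
    MissingBaselineError,
    TableFormatError,
)

CSV_COLUMNS = [
    "amino_acid",
    "m_aa_molal",
    "T_K",
    "m_chcl_molal",
    "density_kg_m3",
    "speed_of_sound_m_s",
]

#: Molar masses in g mol^-1.  The choline chloride value (C5H14ClNO) is a
#: fixed package default, overridable wherever a molar mass is accepted.
DEFAULT_MOLAR_MASSES: dict[str, float] = {
    "choline chloride": 139.62,
    "choline": 104.171,
    "chloride": 35.453,
    "water": 18.0153,
    "l-glycine": 75.07,
    "d,l-alanine": 89.09,
    "l-proline": 115.13,
}

#: Molar mass of choline chloride in kg mol^-1, the ``M`` of the apparent
#: molar property definitions.
M_CHCL_KG_MOL = DEFAULT_MOLAR_MASSES["choline chloride"] * 1e-3

BUNDLED_PRESSURE_HPA = 871.5


@dataclass(frozen=True)
class SoluteSpec:
    """A named species with its molar mass (g mol^-1) and role."""

    name: str
    molar_mass: float
    role: str  # {"electrolyte", "amino_acid", "water"}

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise DomainError(f"molar mass of {self.name!r} must be positive")
        if self.role not in {"electrolyte", "amino_acid", "water"}:
            raise DomainError(f"unknown role {self.role!r}")


@dataclass(frozen=True, order=True)
class SystemKey:
    """Identifies an amino-acid background: species and nominal molality."""

    amino_acid: str
    amino_acid_molality: float

    def __post_init__(self):
        if self.amino_acid_molality < 0:
            raise DomainError("amino-acid molality must be >= 0")

    def __str__(self):
        return f"{self.amino_acid} {self.amino_acid_molality:.4f} mol/kg"


@dataclass(frozen=True)
class MeasurementRecord:
    """One (system, T, m_chcl) state point."""

    system: SystemKey
    T: float  # K
    m_chcl: float  # mol (kg water)^-1
    d: float  # kg m^-3
    u: float  # m s^-1

    def __post_init__(self):
        if self.T <= 0:
            raise DomainError("temperature must be positive")
        if self.m_chcl < 0:
            raise DomainError("molality must be >= 0")
        if self.d <= 0 or self.u <= 0:
            raise DomainError("density and speed of sound must be positive")


@dataclass
class ValidationReport:
    """Collected invariant violations; empty means the table is valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self):
        return "valid table" if self.ok else "\n".join(self.violations)


class MeasurementTable:
    """An ordered collection of measurement records with pressure metadata.

    Invariants (checked on construction unless ``validate=False``): each
    (system, T) group carries exactly one baseline row with ``m_chcl = 0``
    and its molalities are strictly increasing.
    """

    def __init__(
        self,
        records: Iterable[MeasurementRecord],
        pressure_hpa: float = BUNDLED_PRESSURE_HPA,
        validate: bool = True,
    ):
        self.records = sorted(
            records, key=lambda r: (r.system, r.T, r.m_chcl)
        )
        self.pressure_hpa = pressure_hpa
        if validate:
            report = validate_table(self)
            if not report.ok:
                raise TableFormatError(str(report))

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def groups(self) -> dict[tuple[SystemKey, float], list[MeasurementRecord]]:
        """Records grouped by (system, temperature), molality-sorted."""
        out: dict[tuple[SystemKey, float], list[MeasurementRecord]] = {}
        for r in self.records:
            out.setdefault((r.system, r.T), []).append(r)
        return out

    def baseline(self, system: SystemKey, T: float) -> MeasurementRecord:
        for r in self.records:
            if r.system == system and r.T == T and r.m_chcl == 0.0:
                return r
        raise MissingBaselineError(f"no baseline row for {system} at {T} K")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "amino_acid": r.system.amino_acid,
                    "m_aa_molal": r.system.amino_acid_molality,
                    "T_K": r.T,
                    "m_chcl_molal": r.m_chcl,
                    "density_kg_m3": r.d,
                    "speed_of_sound_m_s": r.u,
                }
                for r in self.records
            ]
        )


def validate_table(table: MeasurementTable) -> ValidationReport:
    """Report every invariant violation without raising."""
    report = ValidationReport()
    seen: set[tuple[SystemKey, float, float]] = set()
    for r in table.records:
        key = (r.system, r.T, r.m_chcl)
        if key in seen:
            report.violations.append(f"duplicate record {key}")
        seen.add(key)
    for (system, T), recs in table.groups().items():
        n_base = sum(1 for r in recs if r.m_chcl == 0.0)
        if n_base == 0:
            report.violations.append(f"missing baseline row for {system} at {T} K")
        elif n_base > 1:
            report.violations.append(f"multiple baseline rows for {system} at {T} K")
        ms = [r.m_chcl for r in recs]
        if any(b <= a for a, b in zip(ms, ms[1:])):
            report.violations.append(
                f"molalities not strictly increasing for {system} at {T} K"
            )
        for r in recs:
            # dataclass construction already enforces positivity, but tables
            # built with validate=False may bypass it
            if r.d <= 0 or r.u <= 0:
                report.violations.append(
                    f"nonpositive density/speed for {system} at {T} K, m={r.m_chcl}"
                )
    return report


def _parse_rows(rows, origin: str) -> list[MeasurementRecord]:
    records = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        vals = {}
        for col in CSV_COLUMNS[1:]:
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{origin}: non-numeric value {row[col]!r} in column "
                    f"{col!r}, line {i}"
                ) from None
        system = SystemKey(row["amino_acid"], vals["m_aa_molal"])
        records.append(
            MeasurementRecord(
                system=system,
                T=vals["T_K"],
                m_chcl=vals["m_chcl_molal"],
                d=vals["density_kg_m3"],
                u=vals["speed_of_sound_m_s"],
            )
        )
    return records


def read_measurement_csv(
    path: str | Path,
    molar_masses: Mapping[str, float] | None = None,
    pressure_hpa: float = BUNDLED_PRESSURE_HPA,
) -> MeasurementTable:
    """Read and validate a measurement CSV in the documented dialect.

    ``molar_masses`` is accepted for interface symmetry with the writers of
    downstream tables; names present in the file must be registered there
    (defaults to the package registry).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as f:
        reader = csv.DictReader(f)
        if reader.fieldnames is None or list(reader.fieldnames) != CSV_COLUMNS:
            raise TableFormatError(
                f"{path}: header must be exactly {','.join(CSV_COLUMNS)}"
            )
        records = _parse_rows(reader, str(path))
    masses = DEFAULT_MOLAR_MASSES if molar_masses is None else molar_masses
    for r in records:
        if r.system.amino_acid not in masses:
            raise TableFormatError(
                f"{path}: unknown amino acid {r.system.amino_acid!r} "
                "(no molar mass registered)"
            )
    # construction raises DuplicateRecordError/MissingBaselineError messages
    report = validate_table(MeasurementTable(records, pressure_hpa, validate=False))
    for v in report.violations:
        if "duplicate" in v:
            raise DuplicateRecordError(v)
        if "baseline" in v:
            raise MissingBaselineError(v)
    if not report.ok:
        raise TableFormatError(str(report))
    return MeasurementTable(records, pressure_hpa)


def write_measurement_csv(table: MeasurementTable, path: str | Path) -> None:
    """Write a table in the documented dialect (round-trips bit-for-bit at
    the bundled 2/4-decimal precision)."""
    with Path(path).open("w", newline="", encoding="utf-8") as f:
        w = csv.writer(f)
        w.writerow(CSV_COLUMNS)
        for r in table.records:
            w.writerow(
                [
                    r.system.amino_acid,
                    f"{r.system.amino_acid_molality:.4f}",
                    f"{r.T:.2f}",
                    f"{r.m_chcl:.4f}",
                    f"{r.d:.2f}",
                    f"{r.u:.2f}",
                ]
            )


def _fixture_text(name: str) -> str:
    return resources.files("aminochol").joinpath("_fixtures", name).read_text()


def load_bundled_table1() -> MeasurementTable:
    """The complete bundled measurement set (252 records, P = 871.5 hPa)."""
    reader = csv.DictReader(io.StringIO(_fixture_text("table1.csv")))
    records = _parse_rows(reader, "bundled table")
    return MeasurementTable(records, BUNDLED_PRESSURE_HPA)
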