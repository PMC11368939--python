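"""Mapping quantum-chemistry cavity output to equation-of-state parameters.

A continuum-solvation (COSMO) calculation yields, per molecule, a cavity
volume V (Angstrom^3) and cavity surface area A (Angstrom^2).  Treating the
molecule as a chain of m tangent spheres of diameter sigma whose combined
volume and surface match the cavity gives

    sigma = 3 V / A            m = A / (pi sigma^2)

(for a single sphere, 3V/A is exactly the radius).  Note the widely quoted
form sigma = 6V/A equals the sphere *diameter* route and yields twice the
tabulated segment diameters of the compounds handled here; this module uses
the 3V/A form, which reproduces them.  Composing the two relations gives
the algebraic identity m = A^3 / (9 pi V^2).

Dispersion and association energies follow from empirical inverse-sixth-
power correlations in sigma, u0/kB = a/sigma^6 + b and
eps_AB/kB = c/sigma^6 + d, whose constants come from a literature
correlation and must be supplied by the user; the effective association
volume is a configurable constant in the customary 0.01-0.03 bracket.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DEFAULT_MOLAR_MASSES, _fixture_text
from .errors import ConfigurationError, DomainError
from .epcsaft.params import ParamSet, PureParams


@dataclass(frozen=True)
class CosmoCavityRecord:
    """Cavity geometry (+ optional orbital metadata) of one compound."""

    name: str
    cavity_area: float  # Angstrom^2
    cavity_volume: float  # Angstrom^3
    solvation_energy: float | None = None  # kcal mol^-1
    homo_ev: float | None = None
    lumo_ev: float | None = None

    def __post_init__(self):
        if self.cavity_area <= 0 or self.cavity_volume <= 0:
            raise DomainError(f"{self.name}: cavity area and volume must be positive")


@dataclass(frozen=True)
class CorrelationConstants:
    """Constants of the sigma^-6 energy correlations (all in K except kappa)."""

    a_disp: float
    b_disp: float
    c_assoc: float
    d_assoc: float
    kappa_default: float = 0.02

    def __post_init__(self):
        if not 0.01 <= self.kappa_default <= 0.03:
            raise DomainError("kappa_default must lie in [0.01, 0.03]")


def sigma_from_cavity(V: float, A: float) -> float:
    """Segment diameter sigma = 3V/A in Angstrom."""
    if V <= 0 or A <= 0:
        raise DomainError("cavity volume and area must be positive")
    return 3.0 * V / A


def m_from_cavity(A: float, sigma: float) -> float:
    """Segment number m = A / (pi sigma^2)."""
    if A <= 0 or sigma <= 0:
        raise DomainError("cavity area and sigma must be positive")
    return A / (np.pi * sigma**2)


def energy_correlations(sigma: float, k: CorrelationConstants | None):
    """(u0/kB, eps_AB/kB) in K from the sigma^-6 correlations."""
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if k is None:
        raise ConfigurationError(
            "energy-correlation constants (a, b, c, d) are not bundled; "
            "supply CorrelationConstants from a literature correlation"
        )
    s6 = sigma**6
    return k.a_disp / s6 + k.b_disp, k.c_assoc / s6 + k.d_assoc


def cosmo_parameter_set(
    records: list[CosmoCavityRecord],
    k: CorrelationConstants | None = None,
    schemes: dict[str, str] | None = None,
    molar_masses: dict[str, float] | None = None,
) -> ParamSet:
    """Assemble a full parameter set from cavity records.

    Geometry (sigma, m) comes from the cavity; energies require the
    correlation constants.  ``schemes`` assigns association schemes per
    species (default: 2B for every compound, the convention for the amino
    acids handled here).
    """
    schemes = schemes or {}
    masses = molar_masses or DEFAULT_MOLAR_MASSES
    params = []
    for r in records:
        sigma = sigma_from_cavity(r.cavity_volume, r.cavity_area)
        m_seg = m_from_cavity(r.cavity_area, sigma)
        u0, eps_ab = energy_correlations(sigma, k)
        scheme = schemes.get(r.name, "2B")
        if r.name not in masses:
            raise ConfigurationError(f"no molar mass registered for {r.name!r}")
        params.append(
            PureParams(
                name=r.name,
                m_seg=m_seg,
                sigma=sigma,
                eps_k=u0,
                assoc_scheme=scheme,
                eps_assoc_k=eps_ab if scheme != "none" else 0.0,
                kappa_assoc=k.kappa_default if scheme != "none" else 0.0,
                charge=0,
                molar_mass=masses[r.name],
            )
        )
    return ParamSet(params)


def _parse_cavity_rows(reader, origin: str) -> list[CosmoCavityRecord]:
    out = []
    for row in reader:
        try:
            area = float(row["area_A2"])
            volume = float(row["volume_A3"])
        except (KeyError, TypeError, ValueError):
            raise ConfigurationError(
                f"{origin}: record {row.get('species')!r} lacks numeric "
                "area_A2/volume_A3 cells"
            ) from None

        def opt(col):
            v = (row.get(col) or "").strip()
            return float(v) if v else None

        out.append(
            CosmoCavityRecord(
                name=row["species"],
                cavity_area=area,
                cavity_volume=volume,
                solvation_energy=opt("solvation_energy_kcal_mol"),
                homo_ev=opt("e_homo_ev"),
                lumo_ev=opt("e_lumo_ev"),
            )
        )
    return out


def read_cavity_csv(path: str | Path) -> list[CosmoCavityRecord]:
    with Path(path).open(newline="", encoding="utf-8") as f:
        return _parse_cavity_rows(csv.DictReader(f), str(path))


def load_bundled_cavities() -> list[CosmoCavityRecord]:
    """The bundled cavity records of the four studied compounds."""
    reader = csv.DictReader(io.StringIO(_fixture_text("table5_cavities.csv")))
    return _parse_cavity_rows(reader, "bundled cavity table")
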