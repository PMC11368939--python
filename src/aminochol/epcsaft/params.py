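"""Pure-component parameter sets for the equation of state.

A species is described by a segment number ``m_seg``, segment diameter
``sigma`` (Angstrom; water uses a stored temperature formula instead of a
constant), dispersion energy ``eps_k`` (K), an association scheme (none,
2B for the amino acids, 4C for water) with its energy and effective volume,
an integer charge, and the molar mass.

Two bundled sets ship with the package: ``experimental`` (literature
parameters regressed from macroscopic data; choline chloride enters as
dissociated m=1 hard-sphere ions) and ``cosmo`` (parameters mapped from
quantum-chemistry cavity output; choline chloride enters as one neutral
associating component).  ``cosmo_alt`` carries the alternative reading of
the association columns of the source tabulation, whose typography is
ambiguous.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

from ..data import _fixture_text
from ..errors import ConfigurationError, DomainError
from .constants import water_segment_diameter

PARAM_COLUMNS = [
    "species",
    "m_seg",
    "sigma_A",
    "eps_k_K",
    "scheme",
    "eps_assoc_k_K",
    "kappa_assoc",
    "charge",
    "molar_mass",
    "sigma_formula",
]

SIGMA_FORMULAS = {"water": water_segment_diameter}

ASSOC_SITES = {"none": (0, 0), "2B": (1, 1), "4C": (2, 2)}  # (acceptors, donors)


@dataclass(frozen=True)
class PureParams:
    name: str
    m_seg: float
    sigma: float | None  # Angstrom; None when sigma_formula is set
    eps_k: float  # K
    assoc_scheme: str = "none"
    eps_assoc_k: float = 0.0
    kappa_assoc: float = 0.0
    charge: int = 0
    molar_mass: float = 0.0  # g mol^-1
    sigma_formula: str | None = None

    def __post_init__(self):
        if self.m_seg <= 0:
            raise DomainError(f"{self.name}: segment number must be positive")
        if self.sigma is None and self.sigma_formula is None:
            raise DomainError(f"{self.name}: need sigma or a sigma formula")
        if self.sigma is not None and self.sigma <= 0:
            raise DomainError(f"{self.name}: sigma must be positive")
        if self.assoc_scheme not in ASSOC_SITES:
            raise DomainError(f"{self.name}: unknown association scheme")
        if not 0.0 <= self.kappa_assoc < 1.0:
            raise DomainError(f"{self.name}: kappa_assoc must be in [0, 1)")
        if self.assoc_scheme == "none" and (self.eps_assoc_k or self.kappa_assoc):
            raise DomainError(
                f"{self.name}: association constants set but scheme is 'none'"
            )

    def sigma_at(self, T: float) -> float:
        """Segment diameter in Angstrom at temperature T."""
        if self.sigma_formula is not None:
            try:
                return float(SIGMA_FORMULAS[self.sigma_formula](T))
            except KeyError:
                raise ConfigurationError(
                    f"{self.name}: unknown sigma formula {self.sigma_formula!r}"
                ) from None
        return self.sigma

    @property
    def n_assoc_sites(self) -> tuple[int, int]:
        return ASSOC_SITES[self.assoc_scheme]


class ParamSet:
    """An ordered, name-indexed collection of pure-component parameters."""

    def __init__(self, params: list[PureParams]):
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species in parameter set")
        self.params = list(params)
        self._by_name = {p.name: p for p in params}

    def __iter__(self):
        return iter(self.params)

    def __len__(self):
        return len(self.params)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> PureParams:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"no parameters for species {name!r}") from None

    @property
    def has_ions(self) -> bool:
        return any(p.charge != 0 for p in self.params)

    def subset(self, names) -> "ParamSet":
        return ParamSet([self[n] for n in names])


def _parse_param_rows(reader, origin: str) -> ParamSet:
    params = []
    for row in reader:
        def num(col, default=None):
            v = (row.get(col) or "").strip()
            if v == "":
                if default is None:
                    raise ConfigurationError(f"{origin}: missing {col} for {row['species']!r}")
                return default
            return float(v)

        params.append(
            PureParams(
                name=row["species"],
                m_seg=num("m_seg"),
                sigma=(float(row["sigma_A"]) if (row.get("sigma_A") or "").strip() else None),
                eps_k=num("eps_k_K"),
                assoc_scheme=(row.get("scheme") or "none").strip() or "none",
                eps_assoc_k=num("eps_assoc_k_K", 0.0),
                kappa_assoc=num("kappa_assoc", 0.0),
                charge=int(num("charge", 0.0)),
                molar_mass=num("molar_mass"),
                sigma_formula=(row.get("sigma_formula") or "").strip() or None,
            )
        )
    return ParamSet(params)


def load_params_csv(path: str | Path) -> ParamSet:
    """Read a parameter file in the documented tabular format."""
    with Path(path).open(newline="", encoding="utf-8") as f:
        reader = csv.DictReader(f)
        missing = set(PARAM_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
        return _parse_param_rows(reader, str(path))


_BUNDLED = {
    "experimental": "params_experimental.csv",
    "cosmo": "params_cosmo.csv",
    "cosmo_alt": "params_cosmo_alt.csv",
}


def load_bundled_params(source: str = "experimental") -> ParamSet:
    """One of the bundled parameter sets: experimental, cosmo, cosmo_alt."""
    try:
        name = _BUNDLED[source]
    except KeyError:
        raise ConfigurationError(
            f"unknown parameter source {source!r}; choose from {sorted(_BUNDLED)}"
        ) from None
    reader = csv.DictReader(io.StringIO(_fixture_text(name)))
    return _parse_param_rows(reader, name)
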