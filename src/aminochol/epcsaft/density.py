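"""Liquid-density solution of the equation of state and deviation metrics.

P(eta) is scanned over the physical packing range, every root of
P(eta) = P_target is bracketed and polished, and the liquid root is the
largest-eta root that is mechanically stable (dP/drho > 0).  Number
density follows from the packing fraction, mass density from the mole
fractions and molar masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..data import MeasurementTable
from ..errors import ConfigurationError, NoSolutionError
from .composition import mixture_from_molality
from .constants import ETA_MAX, N_AV
from .eos import EpcSaft

_ETA_FLOOR = 1e-10
_LIQUID_ETA = 0.15  # roots below this are labelled vapor-like


@dataclass
class DensityResult:
    mass_density: float  # kg m^-3
    packing_fraction: float
    root_type: str  # {"liquid", "vapor"}
    iterations: int
    residual: float  # Pa
    number_density: float  # Angstrom^-3
    multiple_liquid_roots: bool = False


def _eta_factor(eos: EpcSaft, T: float, x: dict[str, float]) -> float:
    """eta / rho at this temperature and composition."""
    return eos.packing_fraction(T, 1.0, x)


def solve_density(
    eos: EpcSaft,
    T: float,
    P: float,
    composition: dict[str, float],
    eta_guess: float | None = None,
    scan_points: int = 120,
) -> DensityResult:
    """Find the liquid-density root of P(eta) = P at (T, composition).

    ``eta_guess`` (e.g. the solution of a neighbouring state) restricts the
    scan to a local bracket first and falls back to the full scan.
    """
    if P <= 0:
        raise NoSolutionError("target pressure must be positive")
    fac = _eta_factor(eos, T, composition)
    n_evals = 0

    def f(eta: float) -> float:
        nonlocal n_evals
        n_evals += 1
        _, p = eos.compressibility_and_pressure(T, eta / fac, composition)
        return p - P

    def polish(lo, hi, flo, fhi):
        return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)

    roots: list[float] = []
    if eta_guess is not None:
        lo = max(_ETA_FLOOR, eta_guess - 0.02)
        hi = min(ETA_MAX - 1e-6, eta_guess + 0.02)
        grid = np.linspace(lo, hi, 9)
        vals = [f(e) for e in grid]
        for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
            if not (np.isfinite(fa) and np.isfinite(fb)):
                continue
            if fa == 0.0:
                roots.append(a)
            elif fa * fb < 0:
                roots.append(polish(a, b, fa, fb))
        # keep only a stable root; otherwise rescan globally
        roots = [r for r in roots if _stable(f, r)]
    if not roots:
        grid = np.concatenate(
            [
                np.geomspace(_ETA_FLOOR, 5e-3, 10),
                np.linspace(6e-3, ETA_MAX - 1e-4, scan_points),
            ]
        )
        vals = [f(e) for e in grid]
        for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
            if not (np.isfinite(fa) and np.isfinite(fb)):
                continue
            if fa == 0.0:
                roots.append(a)
            elif fa * fb < 0:
                roots.append(polish(a, b, fa, fb))
        if not roots:
            raise NoSolutionError(
                f"no density root in eta ({_ETA_FLOOR}, {ETA_MAX}) at T={T} K, P={P} Pa"
            )
        roots = [r for r in roots if _stable(f, r)] or roots

    liquid_like = [r for r in roots if r >= _LIQUID_ETA]
    eta_root = max(roots)
    multiple = len(liquid_like) > 1
    rho = eta_root / fac

    names = list(composition)
    mbar_kg = sum(composition[n] * eos.params[n].molar_mass for n in names) * 1e-3
    mass_density = rho * 1e30 / N_AV * mbar_kg
    residual = f(eta_root)
    return DensityResult(
        mass_density=float(mass_density),
        packing_fraction=float(eta_root),
        root_type="liquid" if eta_root >= _LIQUID_ETA else "vapor",
        iterations=n_evals,
        residual=float(residual),
        number_density=float(rho),
        multiple_liquid_roots=multiple,
    )


def _stable(f, eta: float, h: float = 1e-6) -> bool:
    """Mechanical stability dP/deta > 0 by a centered difference."""
    return f(eta + h) > f(eta - h)


def predict_density_table(
    table: MeasurementTable,
    eos: EpcSaft,
    pressure_pa: float | None = None,
) -> np.ndarray:
    """One predicted mass density per record, in input order.

    Choline chloride is dissociated into ions when the parameter set
    contains charged species, and kept molecular otherwise.  Baseline rows
    (m_chcl = 0) are predicted as binary water + amino acid solutions.
    """
    dissociate = eos.params.has_ions
    required = {"water"}
    for r in table.records:
        required.add(r.system.amino_acid)
        if r.m_chcl > 0:
            required.update(
                {"choline", "chloride"} if dissociate else {"choline chloride"}
            )
    missing = [n for n in sorted(required) if n not in eos.params]
    if missing:
        raise ConfigurationError(f"parameter set lacks species: {missing}")

    if pressure_pa is None:
        pressure_pa = table.pressure_hpa * 100.0

    out = np.empty(len(table.records))
    guesses: dict[tuple, float] = {}
    for i, r in enumerate(table.records):
        x = mixture_from_molality(
            r.m_chcl, r.system.amino_acid_molality, r.system.amino_acid, dissociate
        )
        key = (r.system, r.T)
        res = solve_density(
            eos, r.T, pressure_pa, x, eta_guess=guesses.get(key)
        )
        guesses[key] = res.packing_fraction
        out[i] = res.mass_density
    return out


def ard_percent(experimental, predicted) -> float:
    """Average relative deviation percent, 100/N sum |d_exp - d_calc| / d_exp."""
    e = np.asarray(experimental, dtype=float)
    c = np.asarray(predicted, dtype=float)
    if e.shape != c.shape:
        raise ConfigurationError("experimental and predicted lengths differ")
    if np.any(e <= 0):
        raise ConfigurationError("experimental densities must be positive")
    return float(100.0 * np.mean(np.abs(e - c) / e))
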