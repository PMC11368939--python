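"""Redlich-Mayer concentration fits and the Hepler structural analysis.

An apparent molar property Y (volume or isentropic compressibility) is
expanded in molality as

    Y(m) = Y0 + S sqrt(m) + B m                    (Redlich-Mayer)

by unweighted ordinary least squares; the intercept Y0 is the
infinite-dilution (standard) value.  The temperature dependence of the
standard volume is then captured by a quadratic

    V0_phi(T) = A + B T + C T^2

whose derivatives give the standard apparent molar expansibility
E0_phi = B + 2 C T, the apparent isobaric thermal expansion
alpha = E0_phi / V0_phi, and Hepler's structural criterion

    (dCp/dP)_T = -T (d^2 V0_phi / dT^2)_P = -2 C T.

A positive curvature 2C marks the solute as a water-structure maker, a
negative one as a breaker; the package adds a configurable dead band below
which the sign is reported as indeterminate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apparent import ApparentPropertyRecord
from .data import SystemKey
from .errors import DomainError, FitError


class StructureClass(str, enum.Enum):
    MAKER = "maker"
    BREAKER = "breaker"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RedlichMayerFit:
    """OLS fit of Y on [1, sqrt(m), m]; all fields in the units of Y."""

    property: str  # {"volume", "compressibility"}
    intercept: float  # Y0
    s_coeff: float  # S, units Y * kg^(1/2) mol^(-1/2)
    b_coeff: float  # B, units Y * kg mol^-1
    residual_sd: float
    n_points: int
    #: covariance of (intercept, s, b) from the residual variance
    covariance: np.ndarray = field(repr=False, default=None)

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    def predict(self, m):
        m = np.asarray(m, dtype=float)
        return self.intercept + self.s_coeff * np.sqrt(m) + self.b_coeff * m


@dataclass(frozen=True)
class TemperaturePolyFit:
    """Quadratic V0_phi(T) = a0 + b1 T + c2 T^2 (units of the input)."""

    a0: float
    b1: float
    c2: float
    temperatures: tuple[float, ...]

    def value(self, T):
        T = np.asarray(T, dtype=float)
        return self.a0 + self.b1 * T + self.c2 * T * T


@dataclass(frozen=True)
class VolumetricSummary:
    """Derived temperature-dependent quantities of one system."""

    e_phi0: dict[float, float]  # E0_phi(T), input units per K
    alpha: dict[float, float]  # K^-1
    hepler_d2: float  # 2C, input units per K^2
    dcp_dp: dict[float, float]  # -2CT, input units K^-1... per T
    structure_class: StructureClass


def fit_redlich_mayer(points, property: str = "volume") -> RedlichMayerFit:
    """Unweighted OLS of Y on [1, sqrt(m), m] for >= 3 distinct molalities."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (m, y) pairs")
    m, y = pts[:, 0], pts[:, 1]
    if len(m) < 3:
        raise FitError("at least 3 points are required")
    if np.any(m <= 0):
        raise DomainError("all molalities must be positive")
    if len(np.unique(m)) < len(m):
        raise FitError("duplicate molalities make the design singular")
    X = np.column_stack([np.ones_like(m), np.sqrt(m), m])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient Redlich-Mayer design")
    resid = y - X @ beta
    dof = len(m) - 3
    ssr = float(resid @ resid)
    sd = float(np.sqrt(ssr / dof)) if dof > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = xtx_inv * (ssr / dof if dof > 0 else 0.0)
    return RedlichMayerFit(
        property=property,
        intercept=float(beta[0]),
        s_coeff=float(beta[1]),
        b_coeff=float(beta[2]),
        residual_sd=sd,
        n_points=len(m),
        covariance=cov,
    )


def fit_vphi0_temperature(v0_by_T) -> TemperaturePolyFit:
    """OLS quadratic in T through >= 3 (T, V0_phi) pairs.

    The fit is performed in a centered basis for conditioning and the
    coefficients are reported in the raw A + B T + C T^2 basis.
    """
    pts = np.asarray(sorted(v0_by_T), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise FitError("at least 3 (T, V0) pairs are required")
    T, y = pts[:, 0], pts[:, 1]
    if len(np.unique(T)) < 3:
        raise FitError("at least 3 distinct temperatures are required")
    Tc = T - T.mean()
    X = np.column_stack([np.ones_like(Tc), Tc, Tc * Tc])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    # expand (a + b Tc + c Tc^2) back to the raw-T basis
    t0 = T.mean()
    a, b, c = beta
    return TemperaturePolyFit(
        a0=float(a - b * t0 + c * t0 * t0),
        b1=float(b - 2 * c * t0),
        c2=float(c),
        temperatures=tuple(T),
    )


def expansibility_and_alpha(fit: TemperaturePolyFit, temperatures=None):
    """E0_phi(T) = B + 2CT and alpha(T) = E0_phi(T)/V0_phi(T).

    alpha uses the *fitted* V0_phi(T): the smooth polynomial is the only
    self-consistent denominator once E0_phi comes from its derivative.
    """
    Ts = fit.temperatures if temperatures is None else tuple(temperatures)
    e = {}
    a = {}
    for T in Ts:
        e0 = fit.b1 + 2.0 * fit.c2 * T
        v0 = float(fit.value(T))
        if v0 == 0:
            raise DomainError(f"fitted V0_phi({T}) is zero; alpha undefined")
        e[T] = e0
        a[T] = e0 / v0
    return e, a


def hepler_analysis(
    fit: TemperaturePolyFit, indeterminate_threshold: float = 1e-4
) -> VolumetricSummary:
    """Hepler constant 2C, (dCp/dP)_T = -2CT and the structure class.

    ``indeterminate_threshold`` is in the units of the fitted V0 per K^2;
    the default 1e-4 matches inputs on the customary 10^6 m^3 mol^-1 scale.
    """
    two_c = 2.0 * fit.c2
    if abs(two_c) < indeterminate_threshold:
        cls = StructureClass.INDETERMINATE
    elif two_c > 0:
        cls = StructureClass.MAKER
    else:
        cls = StructureClass.BREAKER
    e, a = expansibility_and_alpha(fit)
    return VolumetricSummary(
        e_phi0=e,
        alpha=a,
        hepler_d2=two_c,
        dcp_dp={T: -two_c * T for T in fit.temperatures},
        structure_class=cls,
    )


def fit_system_groups(
    records: list[ApparentPropertyRecord],
) -> dict[SystemKey, dict]:
    """Run the full volumetric analysis per system.

    Returns, per system: ``{"volume": {T: fit}, "compressibility": {T: fit},
    "poly": TemperaturePolyFit, "summary": VolumetricSummary}``.  Fits are
    done on the customary reporting scales (10^6 m^3 mol^-1 for volume,
    10^14 m^3 mol^-1 Pa^-1 for compressibility) so the coefficients read
    like the usual tabulations.
    """
    by_system: dict[SystemKey, dict[float, list[ApparentPropertyRecord]]] = {}
    for r in records:
        by_system.setdefault(r.system, {}).setdefault(r.T, []).append(r)

    out: dict[SystemKey, dict] = {}
    for system, by_T in sorted(by_system.items()):
        vol_fits = {}
        comp_fits = {}
        for T, recs in sorted(by_T.items()):
            pts_v = [(r.m_chcl, r.v_phi * 1e6) for r in recs]
            pts_k = [(r.m_chcl, r.kappa_phi * 1e14) for r in recs]
            vol_fits[T] = fit_redlich_mayer(pts_v, "volume")
            comp_fits[T] = fit_redlich_mayer(pts_k, "compressibility")
        poly = fit_vphi0_temperature(
            [(T, f.intercept) for T, f in vol_fits.items()]
        )
        summary = hepler_analysis(poly)
        out[system] = {
            "volume": vol_fits,
            "compressibility": comp_fits,
            "poly": poly,
            "summary": summary,
        }
    return out


def fits_to_frame(fits: dict[SystemKey, dict]) -> pd.DataFrame:
    """Flatten the per-system analysis into one row per (system, T)."""
    rows = []
    for system, d in fits.items():
        for T, vf in d["volume"].items():
            kf = d["compressibility"][T]
            rows.append(
                {
                    "amino_acid": system.amino_acid,
                    "m_aa_molal": system.amino_acid_molality,
                    "T_K": T,
                    "v_phi0_1e6": vf.intercept,
                    "s_v_1e6": vf.s_coeff,
                    "b_v_1e6": vf.b_coeff,
                    "sd_v_1e6": vf.residual_sd,
                    "e_phi0_1e6": d["summary"].e_phi0[T],
                    "alpha_1e4_K": d["summary"].alpha[T] * 1e4,
                    "hepler_2c_1e6": d["summary"].hepler_d2,
                    "structure_class": d["summary"].structure_class.value,
                    "kappa_phi0_1e14": kf.intercept,
                    "s_k_1e14": kf.s_coeff,
                    "b_k_1e14": kf.b_coeff,
                    "sd_k_1e14": kf.residual_sd,
                }
            )
    return pd.DataFrame(rows)
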