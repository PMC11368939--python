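"""Electrolyte PC-SAFT residual Helmholtz energy and derived properties.

The reduced residual Helmholtz energy per molecule, a = A_res/(N k_B T), is
the sum of four contributions:

* hard chain: Boublik-Mansoori-Carnahan-Starling hard-sphere mixture term
  plus the chain-connectivity correction through the contact value of the
  hard-sphere radial distribution function;
* dispersion: second-order perturbation theory with the universal I1/I2
  coefficient tables and the compressibility correction C1, one-fluid
  mixing of the m^2 eps sigma^3 moments (Lorentz-Berthelot combining,
  k_ij = 0);
* association: Wertheim first-order theory; site fractions X solved from
  the mass-action system by damped successive substitution.  Water carries
  a 4C scheme (2 donors + 2 acceptors), amino acids 2B (1 + 1);
  cross-association uses the arithmetic mean of the energies and the
  size-scaled geometric mean of the effective volumes;
* ion: a Debye-Hueckel Helmholtz term for fully dissociated electrolytes,
  with ion diameters as the size parameter and the static permittivity of
  pure water from an empirical temperature correlation.

The compressibility factor Z = 1 + rho d(a)/d(rho) is evaluated from
analytic density derivatives of every contribution (the association part
via the stationarity of the Wertheim functional, so no dX/drho is needed),
and P = Z rho k_B T.

Internal units: lengths in Angstrom, number density in Angstrom^-3,
energies divided by k_B (K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, ConvergenceError, DomainError, StateError
from .constants import (
    A_UNIV,
    B_UNIV,
    E_CHARGE,
    EPS_0,
    ETA_MAX,
    K_B,
    N_AV,
    water_relative_permittivity,
)
from .params import ParamSet


@dataclass(frozen=True)
class MixtureState:
    """A (T, P, composition) state with an optional trial number density."""

    T: float  # K
    P: float  # Pa
    mole_fractions: dict[str, float]
    number_density: float | None = None  # Angstrom^-3

    def __post_init__(self):
        if self.T <= 0 or self.P <= 0:
            raise DomainError("temperature and pressure must be positive")
        total = sum(self.mole_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise DomainError(f"mole fractions sum to {total}, not 1")


@dataclass
class HelmholtzBreakdown:
    """Per-contribution reduced residual Helmholtz energy (per molecule, /kT)."""

    a_hc: float
    a_disp: float
    a_assoc: float
    a_ion: float
    site_fractions: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.a_hc + self.a_disp + self.a_assoc + self.a_ion


class _Prepared:
    """Temperature-level arrays for a fixed species list."""

    __slots__ = (
        "names", "m", "sigma", "d", "eps", "charge", "molar_mass",
        "n_acc", "n_don", "assoc_mask", "delta_T", "sigma_ij3", "eps_ij_T",
        "eps_r",
    )


def _chi(u):
    """Debye-Hueckel size function chi(u) = 3 u^-3 [ln(1+u) - u + u^2/2]."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 1e-3
    us = u[small]
    # series 1 - 3u/4 + 3u^2/5 - u^3/2 + 3u^4/7 ...
    out[small] = 1.0 - 0.75 * us + 0.6 * us**2 - 0.5 * us**3 + (3.0 / 7.0) * us**4
    ub = u[~small]
    out[~small] = 3.0 / ub**3 * (np.log1p(ub) - ub + 0.5 * ub**2)
    return out


def _chi_prime(u):
    """d chi / d u."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 1e-3
    us = u[small]
    out[small] = -0.75 + 1.2 * us - 1.5 * us**2 + (12.0 / 7.0) * us**3
    ub = u[~small]
    out[~small] = -3.0 * _chi(ub) / ub + 3.0 / (ub * (1.0 + ub))
    return out


class EpcSaft:
    """Equation of state over a fixed parameter set.

    Parameters
    ----------
    params
        Pure-component parameter set; every species used in a state must
        be present.
    ion_dispersion
        Which dispersion interactions charged species take part in:
        ``"solvent"`` (default) applies Lorentz-Berthelot dispersion
        between an ion and every neutral species but none between two
        ions (the convention of the electrolyte extension the ion
        parameters were regressed with); ``"none"`` removes every pair
        involving an ion, leaving charged hard spheres that interact only
        through the hard-sphere and Debye-Hueckel terms; ``"full"``
        applies Lorentz-Berthelot everywhere.
    permittivity
        Callable T -> relative permittivity of the solvent background for
        the ion term.
    """

    #: site-fraction solver settings (deterministic)
    ASSOC_DAMPING = 0.5
    ASSOC_TOL = 1e-12
    ASSOC_MAX_ITER = 500

    def __init__(
        self,
        params: ParamSet,
        ion_dispersion: str = "solvent",
        permittivity=water_relative_permittivity,
    ):
        if ion_dispersion not in {"none", "solvent", "full"}:
            raise ConfigurationError(
                "ion_dispersion must be 'none', 'solvent' or 'full'"
            )
        self.params = params
        self.ion_dispersion = ion_dispersion
        self.permittivity = permittivity
        self._cache: dict = {}

    # ------------------------------------------------------------------
    def _prepare(self, T: float, names: tuple[str, ...]) -> _Prepared:
        key = (T, names)
        if key in self._cache:
            return self._cache[key]
        ps = [self.params[n] for n in names]
        p = _Prepared()
        p.names = names
        p.m = np.array([q.m_seg for q in ps])
        p.sigma = np.array([q.sigma_at(T) for q in ps])
        p.eps = np.array([q.eps_k for q in ps])
        p.charge = np.array([q.charge for q in ps], dtype=float)
        p.molar_mass = np.array([q.molar_mass for q in ps])
        # temperature-dependent effective hard-sphere diameter; ions keep
        # their bare diameter (no dispersion well to soften them)
        shield = 1.0 - 0.12 * np.exp(-3.0 * p.eps / T)
        p.d = np.where(p.charge != 0.0, p.sigma, p.sigma * shield)
        p.n_acc = np.array([q.n_assoc_sites[0] for q in ps], dtype=float)
        p.n_don = np.array([q.n_assoc_sites[1] for q in ps], dtype=float)

        n = len(ps)
        sig_ij = 0.5 * (p.sigma[:, None] + p.sigma[None, :])
        p.sigma_ij3 = sig_ij**3
        eps_ij = np.sqrt(np.outer(p.eps, p.eps))
        ion = p.charge != 0.0
        if self.ion_dispersion == "none":
            zero = ion[:, None] | ion[None, :]
            eps_ij = np.where(zero, 0.0, eps_ij)
        elif self.ion_dispersion == "solvent":
            zero = ion[:, None] & ion[None, :]
            eps_ij = np.where(zero, 0.0, eps_ij)
        p.eps_ij_T = eps_ij / T

        # association Delta prefactor (independent of density):
        # sigma_ij^3 kappa_ij (exp(eps_ij/T) - 1)
        kappa = np.array([q.kappa_assoc for q in ps])
        eps_ab = np.array([q.eps_assoc_k for q in ps])
        assoc = (p.n_acc + p.n_don) > 0
        p.assoc_mask = assoc
        delta_T = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if not (assoc[i] and assoc[j]):
                    continue
                if i == j:
                    k_ij = kappa[i]
                    e_ij = eps_ab[i]
                else:
                    size = (
                        np.sqrt(p.sigma[i] * p.sigma[j])
                        / (0.5 * (p.sigma[i] + p.sigma[j]))
                    ) ** 3
                    k_ij = np.sqrt(kappa[i] * kappa[j]) * size
                    e_ij = 0.5 * (eps_ab[i] + eps_ab[j])
                delta_T[i, j] = p.sigma_ij3[i, j] * k_ij * np.expm1(e_ij / T)
        p.delta_T = delta_T
        p.eps_r = float(self.permittivity(T))
        self._cache[key] = p
        return p

    # ------------------------------------------------------------------
    @staticmethod
    def _zetas(p: _Prepared, x: np.ndarray, rho: float) -> np.ndarray:
        return (np.pi / 6.0) * rho * np.array(
            [np.sum(x * p.m * p.d**k) for k in range(4)]
        )

    def packing_fraction(self, T: float, rho: float, x: dict[str, float]) -> float:
        names, xv = self._split(x)
        p = self._prepare(T, names)
        return float(self._zetas(p, xv, rho)[3])

    @staticmethod
    def _split(x: dict[str, float]):
        names = tuple(x.keys())
        xv = np.array([x[n] for n in names], dtype=float)
        if np.any(xv < 0):
            raise DomainError("mole fractions must be >= 0")
        return names, xv

    # ------------------------------------------------------------------
    @staticmethod
    def _g_contact(p: _Prepared, z: np.ndarray):
        z1, z2, z3 = z[1], z[2], z[3]
        om = 1.0 - z3
        dd = np.outer(p.d, p.d) / (p.d[:, None] + p.d[None, :])
        return 1.0 / om + dd * 3.0 * z2 / om**2 + dd**2 * 2.0 * z2**2 / om**3

    @staticmethod
    def _rho_dg_contact(p: _Prepared, z: np.ndarray):
        """rho * d g_ij / d rho at fixed composition."""
        z2, z3 = z[2], z[3]
        om = 1.0 - z3
        dd = np.outer(p.d, p.d) / (p.d[:, None] + p.d[None, :])
        return (
            z3 / om**2
            + dd * (3.0 * z2 / om**2 + 6.0 * z2 * z3 / om**3)
            + dd**2 * (4.0 * z2**2 / om**3 + 6.0 * z2**2 * z3 / om**4)
        )

    # ------------------------------------------------------------------
    def _solve_sites(self, p: _Prepared, x, rho, X0=None):
        """Damped successive substitution for (X_acc, X_don) per species."""
        idx = np.where(p.assoc_mask)[0]
        if len(idx) == 0 or rho == 0.0:
            return None, 0
        z = self._zetas(p, x, rho)
        g = self._g_contact(p, z)
        delta = p.delta_T * g  # full matrix; only assoc rows/cols nonzero
        sub = np.ix_(idx, idx)
        D = delta[sub]
        xa = x[idx]
        nA, nB = p.n_acc[idx], p.n_don[idx]
        if X0 is None:
            XA = np.full(len(idx), 0.5)
            XB = np.full(len(idx), 0.5)
        else:
            XA, XB = X0[0].copy(), X0[1].copy()
        damping = self.ASSOC_DAMPING
        for it in range(1, self.ASSOC_MAX_ITER + 1):
            XA_new = 1.0 / (1.0 + rho * D @ (xa * nB * XB))
            XB_new = 1.0 / (1.0 + rho * D.T @ (xa * nA * XA))
            XA_next = damping * XA_new + (1.0 - damping) * XA
            XB_next = damping * XB_new + (1.0 - damping) * XB
            res = max(np.max(np.abs(XA_next - XA)), np.max(np.abs(XB_next - XB)))
            XA, XB = XA_next, XB_next
            if res < self.ASSOC_TOL:
                # polish: residual of the mass-action equations themselves
                return (XA, XB, idx, D), it
        raise ConvergenceError(
            "association site-fraction solver did not converge in "
            f"{self.ASSOC_MAX_ITER} iterations (last update {res:.3e})",
            trace={"iterations": self.ASSOC_MAX_ITER, "last_update": res},
        )

    # ------------------------------------------------------------------
    def helmholtz(
        self,
        T: float,
        rho: float,
        x: dict[str, float],
        _X0=None,
    ) -> HelmholtzBreakdown:
        """Reduced residual Helmholtz energy a(T, rho, x) with breakdown."""
        names, xv = self._split(x)
        p = self._prepare(T, names)
        if rho < 0:
            raise DomainError("number density must be >= 0")
        if rho == 0.0:
            return HelmholtzBreakdown(0.0, 0.0, 0.0, 0.0)
        z = self._zetas(p, xv, rho)
        eta = z[3]
        if eta >= ETA_MAX:
            raise StateError(f"packing fraction {eta:.4f} >= {ETA_MAX}")

        a_hc = self._a_hc(p, xv, z)
        a_disp = self._a_disp(p, xv, rho, eta)
        a_assoc, sites = self._a_assoc(p, xv, rho, _X0)
        a_ion = self._a_ion(p, xv, rho, T)
        bd = HelmholtzBreakdown(a_hc, a_disp, a_assoc, a_ion)
        if sites is not None:
            XA, XB, idx, _ = sites
            bd.site_fractions = {
                p.names[i]: (float(XA[k]), float(XB[k])) for k, i in enumerate(idx)
            }
        return bd

    def _a_hc(self, p, x, z):
        z0, z1, z2, z3 = z
        om = 1.0 - z3
        a_hs = (
            3.0 * z1 * z2 / om
            + z2**3 / (z3 * om**2)
            + (z2**3 / z3**2 - z0) * np.log(om)
        ) / z0
        g = self._g_contact(p, z)
        mbar = float(np.sum(x * p.m))
        return mbar * a_hs - float(np.sum(x * (p.m - 1.0) * np.log(np.diag(g))))

    @staticmethod
    def _I_coeffs(mbar):
        f1 = (mbar - 1.0) / mbar
        f2 = f1 * (mbar - 2.0) / mbar
        a = A_UNIV[:, 0] + f1 * A_UNIV[:, 1] + f2 * A_UNIV[:, 2]
        b = B_UNIV[:, 0] + f1 * B_UNIV[:, 1] + f2 * B_UNIV[:, 2]
        return a, b

    def _a_disp(self, p, x, rho, eta):
        mbar = float(np.sum(x * p.m))
        a, b = self._I_coeffs(mbar)
        powers = eta ** np.arange(7)
        I1 = float(a @ powers)
        I2 = float(b @ powers)
        om = 1.0 - eta
        C1 = 1.0 / (
            1.0
            + mbar * (8.0 * eta - 2.0 * eta**2) / om**4
            + (1.0 - mbar)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (om * (2.0 - eta)) ** 2
        )
        mm = np.outer(x * p.m, x * p.m)
        m2es3 = float(np.sum(mm * p.eps_ij_T * p.sigma_ij3))
        m2e2s3 = float(np.sum(mm * p.eps_ij_T**2 * p.sigma_ij3))
        return -2.0 * np.pi * rho * I1 * m2es3 - np.pi * rho * mbar * C1 * I2 * m2e2s3

    def _a_assoc(self, p, x, rho, X0=None):
        sites, _ = (None, 0) if not p.assoc_mask.any() else self._solve_sites(p, x, rho, X0)
        if sites is None:
            return 0.0, None
        XA, XB, idx, _ = sites
        xa = x[idx]
        nA, nB = p.n_acc[idx], p.n_don[idx]
        a = np.sum(
            xa
            * (
                nA * (np.log(XA) - XA / 2.0 + 0.5)
                + nB * (np.log(XB) - XB / 2.0 + 0.5)
            )
        )
        return float(a), sites

    def _kappa_debye(self, p, x, rho, T):
        """Inverse Debye length in m^-1 for number density rho in A^-3."""
        sum_xz2 = float(np.sum(x * p.charge**2))
        if sum_xz2 == 0.0:
            return 0.0, 0.0
        rho_si = rho * 1e30
        kappa2 = (
            E_CHARGE**2 * rho_si * sum_xz2 / (EPS_0 * p.eps_r * K_B * T)
        )
        return float(np.sqrt(kappa2)), sum_xz2

    def _a_ion(self, p, x, rho, T):
        kappa, sum_xz2 = self._kappa_debye(p, x, rho, T)
        if kappa == 0.0:
            return 0.0
        u = kappa * p.sigma * 1e-10  # kappa * a_j with a_j the ion diameter
        chi = _chi(u)
        pref = E_CHARGE**2 / (12.0 * np.pi * EPS_0 * p.eps_r * K_B * T)
        return float(-pref * kappa * np.sum(x * p.charge**2 * chi))

    # ------------------------------------------------------------------
    def compressibility_and_pressure(
        self, T: float, rho: float, x: dict[str, float], _X0=None
    ):
        """Analytic (Z, P) with P in Pa; rho in Angstrom^-3."""
        names, xv = self._split(x)
        p = self._prepare(T, names)
        if rho == 0.0:
            return 1.0, 0.0
        z = self._zetas(p, xv, rho)
        eta = z[3]
        if eta >= ETA_MAX:
            raise StateError(f"packing fraction {eta:.4f} >= {ETA_MAX}")
        Z = 1.0 + self._z_hc(p, xv, z) + self._z_disp(p, xv, rho, eta)
        Z += self._z_assoc(p, xv, rho, _X0)
        Z += self._z_ion(p, xv, rho, T)
        P = Z * rho * 1e30 * K_B * T
        return float(Z), float(P)

    def _z_hc(self, p, x, z):
        z0, z1, z2, z3 = z
        om = 1.0 - z3
        z_hs = (
            z3 / om
            + 3.0 * z1 * z2 / (z0 * om**2)
            + (3.0 * z2**3 - z3 * z2**3) / (z0 * om**3)
        )
        g = np.diag(self._g_contact(p, z))
        rho_dg = np.diag(self._rho_dg_contact(p, z))
        mbar = float(np.sum(x * p.m))
        return mbar * z_hs - float(np.sum(x * (p.m - 1.0) * rho_dg / g))

    def _z_disp(self, p, x, rho, eta):
        mbar = float(np.sum(x * p.m))
        a, b = self._I_coeffs(mbar)
        j = np.arange(7)
        powers = eta**j
        I2 = float(b @ powers)
        detaI1 = float(a @ ((j + 1) * powers))
        detaI2 = float(b @ ((j + 1) * powers))
        om = 1.0 - eta
        C1 = 1.0 / (
            1.0
            + mbar * (8.0 * eta - 2.0 * eta**2) / om**4
            + (1.0 - mbar)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (om * (2.0 - eta)) ** 2
        )
        C2 = -(C1**2) * (
            mbar * (-4.0 * eta**2 + 20.0 * eta + 8.0) / om**5
            + (1.0 - mbar)
            * (2.0 * eta**3 + 12.0 * eta**2 - 48.0 * eta + 40.0)
            / (om * (2.0 - eta)) ** 3
        )
        mm = np.outer(x * p.m, x * p.m)
        m2es3 = float(np.sum(mm * p.eps_ij_T * p.sigma_ij3))
        m2e2s3 = float(np.sum(mm * p.eps_ij_T**2 * p.sigma_ij3))
        return (
            -2.0 * np.pi * rho * detaI1 * m2es3
            - np.pi * rho * mbar * (C1 * detaI2 + C2 * eta * I2) * m2e2s3
        )

    def _z_assoc(self, p, x, rho, X0=None):
        if not p.assoc_mask.any():
            return 0.0
        sites, _ = self._solve_sites(p, x, rho, X0)
        XA, XB, idx, D = sites
        z = self._zetas(p, x, rho)
        g = self._g_contact(p, z)[np.ix_(idx, idx)]
        rho_dg = self._rho_dg_contact(p, z)[np.ix_(idx, idx)]
        # Delta + rho dDelta/drho = Delta_T * (g + rho dg/drho)
        DT = p.delta_T[np.ix_(idx, idx)]
        D_tot = DT * (g + rho_dg)
        xa = x[idx]
        nA, nB = p.n_acc[idx], p.n_don[idx]
        # bilinear site sum over acceptor(i)-donor(j) and donor(i)-acceptor(j)
        s = (xa * nA * XA) @ D_tot @ (xa * nB * XB) + (xa * nB * XB) @ D_tot.T @ (
            xa * nA * XA
        )
        return float(-0.5 * rho * s)

    def _z_ion(self, p, x, rho, T):
        kappa, sum_xz2 = self._kappa_debye(p, x, rho, T)
        if kappa == 0.0:
            return 0.0
        u = kappa * p.sigma * 1e-10
        chi = _chi(u)
        chi_p = _chi_prime(u)
        pref = E_CHARGE**2 / (12.0 * np.pi * EPS_0 * p.eps_r * K_B * T)
        # a_ion = -pref * kappa * S(kappa); rho d/drho = (kappa/2) d/dkappa
        return float(
            -pref * (kappa / 2.0) * np.sum(x * p.charge**2 * (chi + u * chi_p))
        )
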